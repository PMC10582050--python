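"""Random-/mixed-effects meta-regression with maximum-likelihood
heterogeneity estimation, heterogeneity statistics, and AICc all-subsets
moderator search.

Model: y_i = x_i' beta + u_i + e_i with u_i ~ N(0, tau2) between-site
heterogeneity and e_i ~ N(0, v_i) known sampling variances.  tau2 is
estimated by maximising the marginal normal log-likelihood (ML, not REML);
coefficients come from weighted least squares at tau2-hat with weights
1 / (v_i + tau2).  The intercept of the moderator-free or moderator-
centred model is the inverse-variance-weighted average effect (SMD_w or
RR_w).  Confidence intervals for tau2 are obtained by Q-profile inversion;
I^2 intervals by plugging in the tau2 bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

_Z = stats.norm.ppf(0.975)


class InsufficientDataError(ValueError):
    pass


@dataclass
class MetaModel:
    """A fitted mixed-effects meta-regression."""

    response: str
    moderators: list[str]
    coefficients: pd.DataFrame        # index: term; columns: estimate, se, ci_low, ci_high
    tau2_hat: float
    logLik: float
    k: int
    effects: np.ndarray = field(repr=False)
    variances: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)

    @property
    def p_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def intercept(self) -> float:
        return float(self.coefficients.loc["intercept", "estimate"])

    @property
    def intercept_ci(self) -> tuple[float, float]:
        row = self.coefficients.loc["intercept"]
        return float(row["ci_low"]), float(row["ci_high"])


def _loglik(tau2: float, y: np.ndarray, v: np.ndarray,
            X: np.ndarray, method: str = "ML") -> tuple[float, np.ndarray]:
    """Profile log-likelihood over beta at a given tau2 (with constant).

    REML subtracts the information of the fixed effects (restricted
    likelihood) and is offered for sensitivity analyses only.
    """
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    XtWX = XtW @ X
    beta = np.linalg.solve(XtWX, XtW @ y)
    resid = y - X @ beta
    ll = -0.5 * np.sum(np.log(2.0 * np.pi / w) + w * resid ** 2)
    if method == "REML":
        p = X.shape[1]
        ll += (0.5 * p * np.log(2.0 * np.pi)
               + 0.5 * np.linalg.slogdet(X.T @ X)[1]
               - 0.5 * np.linalg.slogdet(XtWX)[1])
    return float(ll), beta


def fit_ml_meta(effects, variances, design_matrix=None,
                moderators: list[str] | None = None,
                response: str = "spatial", method: str = "ML") -> MetaModel:
    """ML mixed-effects meta-regression.

    Parameters
    ----------
    effects, variances : array-like, length k
        Observed effect sizes and their (positive) sampling variances.
    design_matrix : array-like (k, p), optional
        Fixed-effects design; first column must be the intercept.  Default
        is intercept-only (the random-effects model).
    moderators : names for the non-intercept columns.
    method : "ML" (the default, used throughout) or "REML" for
        sensitivity checks of the heterogeneity estimate.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"unknown estimation method {method!r}")
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sampling variances must be strictly positive")
    k = y.size
    X = (np.ones((k, 1)) if design_matrix is None
         else np.asarray(design_matrix, dtype=float))
    p = X.shape[1]
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first design column must be the intercept")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if k <= p:
        raise InsufficientDataError(f"k={k} effects cannot identify {p} "
                                    "fixed effects plus tau2")
    moderators = list(moderators or [f"x{i}" for i in range(1, p)])
    if len(moderators) != p - 1:
        raise ValueError("moderator names must match design columns")

    upper = max(10.0 * float(np.var(y, ddof=1)) if k > 1 else 1.0, 1e-3)
    res = optimize.minimize_scalar(
        lambda t2: -_loglik(t2, y, v, X, method)[0],
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10})
    tau2 = float(res.x)
    # The bounded optimiser never quite reaches the boundary; snap to 0
    # when the boundary is at least as good.
    ll_tau, _ = _loglik(tau2, y, v, X, method)
    ll0, _ = _loglik(0.0, y, v, X, method)
    if ll0 >= ll_tau:
        tau2 = 0.0
    ll, beta = _loglik(tau2, y, v, X, method)

    w = 1.0 / (v + tau2)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    terms = ["intercept"] + moderators
    coef = pd.DataFrame({
        "estimate": beta, "se": se,
        "ci_low": beta - _Z * se, "ci_high": beta + _Z * se,
    }, index=pd.Index(terms, name="term"))
    return MetaModel(response=response, moderators=moderators,
                     coefficients=coef, tau2_hat=tau2, logLik=ll, k=k,
                     effects=y, variances=v, X=X)


def _typical_within_variance(v: np.ndarray) -> float:
    """Higgins-Thompson 'typical' within-study variance s^2."""
    w = 1.0 / v
    return (v.size - 1) * w.sum() / (w.sum() ** 2 - (w ** 2).sum())


def i_squared(tau2: float, v: np.ndarray) -> float:
    """I^2 (percent) from tau2 and the typical within-study variance."""
    s2 = _typical_within_variance(v)
    return 100.0 * tau2 / (tau2 + s2)


def _q_gen(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Generalised Q at a candidate tau2 (WLS residual sum of squares)."""
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    return float(np.sum(w * resid ** 2))


def heterogeneity(model: MetaModel, level: float = 0.95) -> dict:
    """Heterogeneity point estimates and CIs for a fitted model.

    tau2 CI by Q-profile inversion: the bounds solve
    Q_gen(tau2) = chi2 quantiles with k - p degrees of freedom.  I^2 and
    its CI come from plugging tau2 (and its bounds) into
    ``100 tau2 / (tau2 + s^2)``.
    """
    y, v, X = model.effects, model.variances, model.X
    k, p = model.k, model.p_fixed
    if k < 3:
        raise InsufficientDataError("need k >= 3 for heterogeneity CIs")
    df = k - p
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df)
    q_lo = stats.chi2.ppf(alpha / 2.0, df)

    def solve(target: float) -> float:
        # Q_gen is decreasing in tau2.
        if _q_gen(0.0, y, v, X) <= target:
            return 0.0
        hi = max(1.0, 10.0 * float(np.var(y, ddof=1)))
        while _q_gen(hi, y, v, X) > target:
            hi *= 10.0
            if hi > 1e8:
                return float(np.inf)
        return float(optimize.brentq(
            lambda t2: _q_gen(t2, y, v, X) - target, 0.0, hi, xtol=1e-12))

    tau2_lo = solve(q_hi)
    tau2_hi = solve(q_lo)
    return {
        "tau2": model.tau2_hat,
        "tau2_ci": (tau2_lo, tau2_hi),
        "I2": i_squared(model.tau2_hat, v),
        "I2_ci": (i_squared(tau2_lo, v), i_squared(tau2_hi, v)),
    }


def qe_test(model: MetaModel) -> tuple[float, int, float]:
    """Test for residual heterogeneity.

    Q_E is the weighted residual sum of squares of the *fixed-effects*
    (tau2 = 0) WLS fit with weights 1/v_i, referred to a chi-square with
    k - p degrees of freedom.
    """
    qe = _q_gen(0.0, model.effects, model.variances, model.X)
    df = model.k - model.p_fixed
    return qe, df, float(stats.chi2.sf(qe, df))


def aicc(model: MetaModel) -> float:
    """AICc counting tau2 as a parameter: p = p_fixed + 1."""
    p = model.p_fixed + 1
    k = model.k
    if k - p - 1 <= 0:
        raise InsufficientDataError(
            f"AICc undefined: k={k} too small for p={p} parameters")
    return -2.0 * model.logLik + 2.0 * p + 2.0 * p * (p + 1.0) / (k - p - 1.0)


def model_search(effects, variances, covariates: pd.DataFrame,
                 moderators: list[str] | None = None,
                 forbidden_pairs: list[tuple[str, str]] | None = None,
                 response: str = "spatial") -> pd.DataFrame:
    """All-subsets moderator search ranked by AICc.

    Fits every subset of the moderators (from the intercept-only model to
    the global model), skipping subsets that contain a forbidden
    (collinear) pair, and returns a table with AICc, delta-AICc, Akaike
    weights and the fitted models, sorted best first.
    """
    moderators = list(moderators
                      or [c for c in covariates.columns if c != "site_id"])
    forbidden = [frozenset(p) for p in (forbidden_pairs or [])]
    y = np.asarray(effects, dtype=float)
    rows = []
    for r in range(len(moderators) + 1):
        for subset in combinations(moderators, r):
            if any(f <= set(subset) for f in forbidden):
                continue
            if len(y) - (len(subset) + 2) - 1 <= 0:
                continue    # AICc undefined: too few effects for this subset
            X = np.column_stack(
                [np.ones(len(y))] + [covariates[m].to_numpy(dtype=float)
                                     for m in subset])
            model = fit_ml_meta(y, variances, X, moderators=list(subset),
                                response=response)
            rows.append({"moderators": " + ".join(subset) or "(intercept only)",
                         "n_moderators": len(subset),
                         "AICc": aicc(model), "logLik": model.logLik,
                         "tau2": model.tau2_hat,
                         "intercept": model.intercept,
                         "model": model})
    table = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    rel = np.exp(-0.5 * table["dAICc"].to_numpy())
    table["weight"] = rel / rel.sum()
    return table


def forest_table(model: MetaModel, site_ids=None) -> pd.DataFrame:
    """Per-site estimates, 95% CIs and inverse-variance weights (forest plot)."""
    v = model.variances
    w = 1.0 / v
    return pd.DataFrame({
        "site_id": site_ids if site_ids is not None
        else [f"site_{i:02d}" for i in range(model.k)],
        "estimate": model.effects,
        "ci_low": model.effects - _Z * np.sqrt(v),
        "ci_high": model.effects + _Z * np.sqrt(v),
        "weight": w / w.sum(),
    })
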