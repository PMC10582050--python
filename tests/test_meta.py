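"""ML mixed-effects meta-regression: closed-form cases, a tau2 grid-search
likelihood oracle, heterogeneity statistics, AICc, the all-subsets search,
and a cross-check against the metafor reference implementation."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lionmeta.meta import (InsufficientDataError, MetaModel, _q_gen, aicc,
                           fit_ml_meta, heterogeneity, model_search, qe_test)


def grid_loglik(y, v, X, taus):
    """Vectorised profile log-likelihood over a tau2 grid (oracle)."""
    w = 1.0 / (v[None, :] + taus[:, None])            # (g, k)
    xtwx = np.einsum("gk,ki,kj->gij", w, X, X)
    xtwy = np.einsum("gk,ki,k->gi", w, X, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]   # (g, p)
    resid = y[None, :] - beta @ X.T
    return -0.5 * np.sum(np.log(2 * np.pi / w) + w * resid ** 2, axis=1)


class TestFitMlMeta:
    def test_two_identical_effects(self):
        m = fit_ml_meta([0.5, 0.5], [0.1, 0.1])
        assert m.intercept == pytest.approx(0.5)
        assert m.tau2_hat == 0.0

    def test_equal_variance_mean(self, rng):
        y = rng.normal(0, 0.01, 10)   # tiny spread: tau2 -> 0
        m = fit_ml_meta(y, np.full(10, 0.5))
        assert m.tau2_hat == 0.0
        assert m.intercept == pytest.approx(y.mean(), abs=1e-10)

    def test_shift_invariance(self, rng):
        y = rng.normal(-0.3, 0.6, 15)
        v = rng.uniform(0.02, 0.2, 15)
        x = rng.normal(0, 1, 15)
        X = np.column_stack([np.ones(15), x])
        a = fit_ml_meta(y, v, X, moderators=["x"])
        b = fit_ml_meta(y + 2.5, v, X, moderators=["x"])
        assert b.intercept == pytest.approx(a.intercept + 2.5, abs=1e-8)
        assert b.tau2_hat == pytest.approx(a.tau2_hat, abs=1e-8)
        assert b.logLik == pytest.approx(a.logLik, abs=1e-8)
        assert (b.coefficients.loc["x", "estimate"]
                == pytest.approx(a.coefficients.loc["x", "estimate"], abs=1e-8))

    def test_loglik_matches_grid_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(5, 30))
            y = rng.normal(0, 1, k)
            v = rng.uniform(0.01, 0.5, k)
            X = np.column_stack([np.ones(k), rng.normal(0, 1, k)])
            m = fit_ml_meta(y, v, X)
            best = grid_loglik(y, v, X, np.arange(0, 2.0001, 1e-4)).max()
            assert m.logLik >= best - 1e-3

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_ml_meta([0.1], [0.1])

    def test_rank_deficiency(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError):
            fit_ml_meta(np.zeros(5), np.full(5, 0.1), X)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_ml_meta([0.1, 0.2], [0.1, 0.0])


class TestHeterogeneity:
    def test_zero_tau2_gives_zero_i2(self, rng):
        m = fit_ml_meta(np.full(5, 0.3), np.full(5, 0.1))
        h = heterogeneity(m)
        assert h["I2"] == 0.0

    def test_equal_weights_closed_form(self, rng):
        # with all v = 0.1, s^2 = (k-1) * k*w / ((k*w)^2 - k*w^2) = 0.1
        y = rng.normal(0, 0.8, 5)
        v = np.full(5, 0.1)
        m = fit_ml_meta(y, v)
        h = heterogeneity(m)
        s2 = 0.1
        assert h["I2"] == pytest.approx(
            100 * m.tau2_hat / (m.tau2_hat + s2), abs=1e-9)

    def test_q_profile_bounds_reevaluate(self, rng):
        y = rng.normal(-0.2, 0.7, 12)
        v = rng.uniform(0.02, 0.3, 12)
        m = fit_ml_meta(y, v)
        h = heterogeneity(m)
        lo, hi = h["tau2_ci"]
        df = m.k - 1
        if lo > 0:
            assert _q_gen(lo, m.effects, m.variances, m.X) == pytest.approx(
                stats.chi2.ppf(0.975, df), abs=1e-6)
        assert _q_gen(hi, m.effects, m.variances, m.X) == pytest.approx(
            stats.chi2.ppf(0.025, df), abs=1e-6)
        assert lo <= m.tau2_hat <= hi or m.tau2_hat == 0.0

    def test_i2_within_range(self, rng):
        y = rng.normal(0, 1.5, 20)
        v = rng.uniform(0.01, 0.2, 20)
        h = heterogeneity(fit_ml_meta(y, v))
        assert 0 <= h["I2"] <= 100
        assert h["I2_ci"][0] <= h["I2_ci"][1]


class TestQeTest:
    def test_perfect_fit(self):
        m = fit_ml_meta([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        qe, df, p = qe_test(m)
        assert qe == pytest.approx(0.0, abs=1e-12)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_example(self):
        m = fit_ml_meta([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        qe, df, p = qe_test(m)
        assert qe == pytest.approx(2.0)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(2.0, 2))


class TestAicc:
    def make_model(self, loglik, k, p_fixed):
        X = np.column_stack([np.ones(k)] + [np.zeros(k)] * (p_fixed - 1))
        return MetaModel(response="spatial",
                         moderators=[f"x{i}" for i in range(1, p_fixed)],
                         coefficients=pd.DataFrame(), tau2_hat=0.0,
                         logLik=loglik, k=k, effects=np.zeros(k),
                         variances=np.ones(k), X=X)

    def test_closed_form(self):
        # k = 10, p = 2 (intercept + tau2), logLik = -5
        m = self.make_model(-5.0, 10, 1)
        assert aicc(m) == pytest.approx(14 + 12.0 / 7.0)

    def test_exceeds_aic(self, rng):
        m = self.make_model(float(rng.normal()), 12, 2)
        aic = -2 * m.logLik + 2 * (m.p_fixed + 1)
        assert aicc(m) > aic

    def test_undefined_for_tiny_k(self):
        with pytest.raises(InsufficientDataError):
            aicc(self.make_model(-1.0, 4, 2))


class TestModelSearch:
    def fixture(self, rng, k=40):
        cov = pd.DataFrame({f"m{i}": rng.normal(0, 1, k) for i in range(6)})
        y = -0.3 + 0.8 * cov["m0"].to_numpy() + rng.normal(0, 0.3, k)
        v = np.full(k, 0.05)
        return y, v, cov

    def test_all_subsets_of_six(self, rng):
        y, v, cov = self.fixture(rng)
        table = model_search(y, v, cov)
        assert len(table) == 64

    def test_forbidden_pair_prunes_sixteen(self, rng):
        y, v, cov = self.fixture(rng)
        table = model_search(y, v, cov, forbidden_pairs=[("m1", "m2")])
        assert len(table) == 48
        assert not any(("m1" in s and "m2" in s)
                       for s in table["moderators"])

    def test_akaike_weights_sum_to_one(self, rng):
        y, v, cov = self.fixture(rng)
        table = model_search(y, v, cov)
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table["dAICc"].iloc[0] == 0.0

    def test_strong_signal_moderator_selected(self, rng):
        y, v, cov = self.fixture(rng)
        table = model_search(y, v, cov)
        assert "m0" in table["moderators"].iloc[0]


class TestMetaforCrossCheck:
    def test_agrees_with_metafor(self, tmp_path, rng):
        """Same data through metafor (ML) must give the same coefficients,
        tau2, logLik, AICc and Q-profile tau2 CI."""
        k = 14
        y = rng.normal(-0.3, 0.6, k)
        v = rng.uniform(0.02, 0.25, k)
        x = rng.normal(0, 1, k)
        pd.DataFrame({"y": y, "v": v, "x": x}).to_csv(tmp_path / "d.csv",
                                                      index=False)
        script = textwrap.dedent("""
            suppressMessages(library(metafor))
            d <- read.csv(file.path("%s", "d.csv"))
            f <- rma(yi = d$y, vi = d$v, mods = ~ d$x, method = "ML")
            fr <- rma(yi = d$y, vi = d$v, mods = ~ d$x, method = "REML")
            ci <- suppressWarnings(confint(f))
            cat(jsonlite::toJSON(list(
                b = as.numeric(coef(f)), se = as.numeric(f$se),
                tau2 = f$tau2, ll = as.numeric(logLik(f)),
                aicc = as.numeric(fitstats(f)["AICc:", ]),
                tau2ci = as.numeric(ci$random[1, 2:3]),
                reml_tau2 = fr$tau2, reml_ll = as.numeric(logLik(fr))),
                digits = 12))
        """ % tmp_path)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)

        X = np.column_stack([np.ones(k), x])
        m = fit_ml_meta(y, v, X, moderators=["x"])
        h = heterogeneity(m)
        assert m.coefficients["estimate"].to_numpy() == pytest.approx(
            ref["b"], abs=1e-5)
        assert m.coefficients["se"].to_numpy() == pytest.approx(
            ref["se"], abs=1e-5)
        assert m.tau2_hat == pytest.approx(ref["tau2"][0], abs=1e-5)
        assert m.logLik == pytest.approx(ref["ll"][0], abs=1e-5)
        assert aicc(m) == pytest.approx(ref["aicc"][0], abs=1e-4)
        assert h["tau2_ci"] == pytest.approx(ref["tau2ci"], abs=1e-4)
        mr = fit_ml_meta(y, v, X, moderators=["x"], method="REML")
        assert mr.tau2_hat == pytest.approx(ref["reml_tau2"][0], abs=1e-5)
        assert mr.logLik == pytest.approx(ref["reml_ll"][0], abs=1e-5)
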