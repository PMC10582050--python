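"""The end-to-end pipeline on a synthetic observation-level study.

Writes 8 sites of camera-trap-style observations with planted effects
(d = -0.3 space-use difference; nocturnality 40% vs 50%, so
RR = ln(0.8) = -0.223), then runs the full chain: activity and
nocturnality classification, disturbance dichotomization, effect sizes,
and the weighted meta-analysis.
"""

import tempfile
from pathlib import Path

import numpy as np

from lionmeta.io import PipelineConfig, run_pipeline, write_synthetic_study

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    truth = write_synthetic_study(data, n_sites=8, n_units=60,
                                  p_low=0.40, p_high=0.50, target_d=-0.3,
                                  seed=7)
    cfg = PipelineConfig(data_dir=str(data), out_dir=str(Path(tmp) / "out"),
                         min_group=30, search=False, seed=7)
    bundle = run_pipeline(cfg)

print(f"planted: d = {truth['d']}, RR = {truth['rr']:.3f}")
for response in ("spatial", "temporal"):
    m = bundle["models"][response]["overall"]
    lo, hi = m.intercept_ci
    print(f"{response:8s} intercept = {m.intercept:+.3f} "
          f"(95% CI {lo:+.3f}, {hi:+.3f}), k = {m.k}")
print("both intervals should cover their planted values: the pipeline "
      "recovers the ground truth from raw observation tables")
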