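#!/usr/bin/env python
"""Fit the ATP-consumption model to OxPhos-dependent failures end to end.

Runs the full reproduction pipeline at study scale (14 cells, three
100 Hz x 150 s trains): simulate control and OxPhos-blocked cohorts,
convert successes to OxPhos-dependent failure rates by subtraction, and
fit the bioenergetics model sequentially (train 1 fixes the shared
parameters; trains 2 and 3 add their time-varying consumption schedules).

Outputs (results/model_fit/): report.json, per-train observed-vs-predicted
failure curves and relative ATP / relative demand trajectories.
"""

import sys
from pathlib import Path

from calyxatp import ReproductionConfig, run_reproduction

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "model_fit"


def main() -> None:
    cfg = ReproductionConfig(seed=SEED, n_cells=14, train_duration=150.0,
                             n_starts=8)
    rep = run_reproduction(cfg, out_dir=OUT)

    p1 = rep["train1"]
    print("Train 1 (shared parameters, constant consumption):")
    print(f"  gamma_b = {p1['gamma_b']:.4f} 1/s   gamma_1 = "
          f"{p1['gamma_1']:.4f} 1/s")
    print(f"  h = {p1['h']:.2f}   K = {100 * p1['K_rel']:.2f}% of basal ATP")
    print(f"  -> {rep['fold_increase_gamma1_over_gammab']:.1f}-fold rise in "
          "consumption from rest to stimulation")
    for idx in (2, 3):
        p = rep[f"train{idx}"]
        print(f"Train {idx}: onset ATP {rep['atp_onset_pct'][idx]:.1f}% of "
              f"basal; end-of-train demand "
              f"{100 * (rep['end_demand_ratio'][idx] - 1):+.0f}% vs train 1")
    print("\nNote: with sampling noise from 25-stimulus bins over 14 cells "
          "the shared parameters are sloppy along a gamma_b-h-K valley, so "
          "individual estimates scatter even though the fitted curves track "
          "the data (see docs/methods.md); the fitted curves and the "
          "demand/ATP trajectories are the robust outputs.")
    print(f"report and curve tables -> {OUT}")


if __name__ == "__main__":
    sys.exit(main())
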