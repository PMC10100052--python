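#!/usr/bin/env python
"""Can the estimators find the truth? Quick recovery experiments.

Runs reduced-size versions of the simulation studies behind the test
suite: choice-exponent recovery at large and study-size samples,
AICc model-ranking behaviour under null and habitat-only truths, and
Wald coverage for the settlement coefficient.  Writes a summary CSV to
results/ and prints the headline rates.  Sizes here are trimmed for a
quick interactive look; the test suite runs the full versions.
"""

import argparse
from pathlib import Path

import pandas as pd

from settlemate.studies import (
    TRUE_ALPHA,
    TRUE_BETA_HAB,
    mate_choice_recovery,
    model_selection_study,
    ppm_recovery,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    big = mate_choice_recovery(seed=args.seed + 1, n_reps=10, n_events=2000)
    small = mate_choice_recovery(seed=args.seed + 2, n_reps=50, n_events=59)
    null_sel = model_selection_study(
        seed=args.seed + 3, n_reps=30, n_events=59, true_alpha=(0.0, 0.0)
    )
    cov = ppm_recovery(seed=args.seed + 4, n_reps=100)

    summary = pd.DataFrame(
        [
            {"check": "alpha1 MAE (n=2000)", "value": big["err_alpha1"].abs().mean()},
            {"check": "alpha2 MAE (n=2000)", "value": big["err_alpha2"].abs().mean()},
            {"check": "alpha1 median (n=59)", "value": small["alpha1_hat"].median()},
            {"check": "alpha2 median (n=59)", "value": small["alpha2_hat"].median()},
            {"check": "null best rate at (0,0)", "value": (null_sel["best"] == "null").mean()},
            {"check": "beta_hab mean", "value": cov["beta_hab_hat"].mean()},
            {"check": "beta_hab 95% coverage", "value": cov["covered"].mean()},
        ]
    )
    summary.to_csv(args.out / "recovery_summary.csv", index=False)

    print(f"true exponents {TRUE_ALPHA}, true beta_hab {TRUE_BETA_HAB}")
    for _, r in summary.iterrows():
        print(f"  {r['check']:<26} {r['value']:.3f}")


if __name__ == "__main__":
    main()
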