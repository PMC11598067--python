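#!/usr/bin/env python
"""End-to-end whole-bunch volume recovery on synthetic vineyards.

Two runs: a zero-noise control (exact per-view ratio, per-berry reference
volumes) that must recover every volume exactly, and a 200-bunch run at the
measured detector noise (count error N(-1.57, 1.9^2), radius error
N(0.15, 1.5^2) px) with R calibrated on a disjoint 30% subset.

Finds: the noisy pipeline is unbiased (volume MPE compatible with zero) and
~99% of views pass the k=2 compatibility check, at a per-bunch CoV of ~19%
-- the volume chain is honest about its (large) uncertainty.
Writes results/recovery_summary.csv and results/recovery_views.csv.
"""

from pathlib import Path

import pandas as pd

from berrymetrics import ErrorModel, RadiusErrorModel, run_recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def run(seed: int = 0) -> pd.DataFrame:
    exact = run_recovery_experiment(
        n_bunches=10,
        count_err=ErrorModel(0, 0),
        radius_err=RadiusErrorModel(0, 0),
        seed=seed,
        exact_r=True,
        per_berry_reference=True,
    )
    noisy = run_recovery_experiment(n_bunches=200, seed=seed + 1)
    rows = []
    for label, rep in (("zero_noise", exact), ("detector_noise", noisy)):
        rows.append(
            {
                "run": label,
                "n_bunches": rep.n_bunches,
                "n_eval_views": rep.n_eval_views,
                "ratio_r": rep.ratio.r_mean,
                "ratio_sigma": rep.ratio.r_sigma,
                "coverage_k2": rep.coverage,
                "volume_me_mm3": rep.volume_me_mm3,
                "volume_mpe_pct": rep.volume_mpe_pct,
                "volume_mpe_se_pct": rep.volume_mpe_se_pct,
                "mean_cov_pct": rep.mean_cov_pct,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "recovery_summary.csv", index=False)
    noisy.table.to_csv(OUT / "recovery_views.csv", index=False)
    return df


if __name__ == "__main__":
    df = run()
    for _, r in df.iterrows():
        print(
            f"{r.run:15s} R={r.ratio_r:.3f}+/-{r.ratio_sigma:.3f}  "
            f"coverage(k=2)={100 * r.coverage_k2:.1f}%  "
            f"volume MPE={r.volume_mpe_pct:+.2f}% (SE {r.volume_mpe_se_pct:.2f}%)  "
            f"CoV={r.mean_cov_pct:.1f}%"
        )
    print(f"wrote {OUT / 'recovery_summary.csv'} and recovery_views.csv")
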