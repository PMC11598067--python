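#!/usr/bin/env python
"""GUM uncertainty budget of the whole-bunch volume chain
V_b,mm = V_I,px * (d/f)^3 * R, with the Monte Carlo cross-check.

Finds: at plausible nominal values (the calibrated focal length is not
published, so f = 1000 px and R = 1.8 stand in), the estimated visible
volume dominates the budget (~59% UPC) but the distance d and the ratio R
together contribute ~41% -- depth sensing and a better-constrained R are
the highest-leverage improvements.  The linear and Monte Carlo budgets
agree on the ranking at these (large) relative sigmas.
Writes results/uncertainty_budget.csv.
"""

from pathlib import Path

import pandas as pd

from berrymetrics import (
    Quantity,
    UncertaintySource,
    monte_carlo_budget,
    propagate_power_product,
)

OUT = Path(__file__).resolve().parents[1] / "results"

SOURCES = [
    UncertaintySource("v_visible_px", Quantity(1.0e6, 2.8e5, "px3"), 1),
    UncertaintySource("d", Quantity(500.0, 25.0, "mm"), 3),
    UncertaintySource("f", Quantity(1000.0, 2.0, "px"), -3),
    UncertaintySource("R", Quantity(1.8, 0.32, "dimensionless"), 1),
]


def run(seed: int = 12345) -> pd.DataFrame:
    lin = propagate_power_product(SOURCES)
    mc = monte_carlo_budget(SOURCES, n_samples=400_000, seed=seed)
    rows = [
        {
            "source": s.name,
            "value": s.quantity.value,
            "sigma": s.quantity.sigma,
            "exponent": s.exponent,
            "upc_linear_pct": lin.upc[s.name],
            "upc_mc_pct": mc.upc[s.name],
        }
        for s in SOURCES
    ]
    df = pd.DataFrame(rows)
    df.attrs["relative_sigma_linear"] = lin.relative_sigma
    df.attrs["relative_sigma_mc"] = mc.relative_sigma
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "uncertainty_budget.csv", index=False)
    return df


if __name__ == "__main__":
    df = run()
    print("source         sigma        UPC(linear)  UPC(MC)")
    for _, r in df.iterrows():
        print(f"{r.source:14s} {r.sigma:<12.3g} {r.upc_linear_pct:10.1f}% {r.upc_mc_pct:8.1f}%")
    print(
        f"combined relative sigma: linear {df.attrs['relative_sigma_linear']:.3f}, "
        f"Monte Carlo {df.attrs['relative_sigma_mc']:.3f} "
        "(linearization degrades at sigma_R/R ~ 18%)"
    )
    print(f"wrote {OUT / 'uncertainty_budget.csv'}")
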