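#!/usr/bin/env python
"""Stage 2: quadratic QSPR models of seven physicochemical properties.

Fits P = A + B*TI + C*TI^2 for every index/property pair over the ten
drugs (published index values x published property table), writes the full
regression table and the 6x7 correlation matrix, and reports the strongest
index per property.
"""

from pathlib import Path

from topodrug import reference
from topodrug.qspr import correlation_table, fit_quadratic, regression_table

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    idx = reference.published_indices()
    props = reference.property_table()

    reg = regression_table(idx, props)
    reg.round(4).to_csv(OUT / "qspr_regressions.csv")
    corr = correlation_table(idx, props)
    corr.round(4).to_csv(OUT / "qspr_correlations.csv")

    print("Correlation matrix (R of the quadratic fit):")
    print(corr.round(4))
    print("\nStrongest index per property:")
    for prop, ti in corr.idxmax(axis=0).items():
        print(f"  {prop:4s} <- {ti:4s} (R = {corr.loc[ti, prop]:.4f})")

    nh_p = fit_quadratic(idx["NH"].to_numpy(), props["P"].to_numpy())
    print(
        f"\nPolarizability on the neighborhood harmonic index: "
        f"P = {nh_p.A:.4f} + {nh_p.B:.4f} NH + {nh_p.C:.4f} NH^2, "
        f"R^2 = {nh_p.R2:.4f}, F = {nh_p.F:.2f}, p = {nh_p.p:.4f}"
    )


if __name__ == "__main__":
    main()
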