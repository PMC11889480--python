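#!/usr/bin/env python
"""Cohort morphometry of the 15-specimen postnatal series: per-age
mean (SD) summaries, allometric scaling of the compartment volumes against
body mass, and the linear growth series of the vascular volumes.

Writes results/cohort_summary.csv, results/allometry.json,
results/growth_table.csv and two figures under results/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from vascmorph.cohort import (VOLUME_COLUMNS, allometric_fit, cohort_summary,
                              format_summary, growth_table,
                              load_reference_morphometry)

RESULTS = Path(__file__).resolve().parent.parent / "results"

LABELS = {
    "lung_volume_mm3": "$V_L$",
    "bronchial_tree_volume_mm3": "$V_{BT}$",
    "pulmonary_artery_volume_mm3": "$V_{PA}$",
    "pulmonary_vein_volume_mm3": "$V_{PV}$",
}


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    records = load_reference_morphometry()

    summary = cohort_summary(records)
    printed = format_summary(summary)
    printed.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print("Per-age cohort summary (mean (SD), printed rounding):")
    print(printed.to_string(index=False))

    fits = {}
    fig, ax = plt.subplots(figsize=(5, 4))
    for col in VOLUME_COLUMNS:
        fit = allometric_fit(records, col)
        fits[col] = {"slope": fit.slope, "intercept": fit.intercept,
                     "r_squared": fit.r_squared, "n": fit.n}
        ax.scatter(records["body_mass_g"], records[col], s=12,
                   label=f"{LABELS[col]}  b={fit.slope:.2f}")
        grid = np.logspace(np.log10(0.1), np.log10(35), 50)
        ax.plot(grid, 10 ** fit.intercept * grid ** fit.slope, lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("body mass (g)")
    ax.set_ylabel("volume (mm$^3$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(RESULTS / "allometry_loglog.png", dpi=150)
    (RESULTS / "allometry.json").write_text(json.dumps(fits, indent=1))
    print("\nAllometric exponents (log10 volume ~ log10 body mass):")
    for col, f in fits.items():
        print(f"  {col}: slope {f['slope']:.3f}, "
              f"intercept {f['intercept']:.3f}, r^2 {f['r_squared']:.3f}")

    growth = growth_table(records)
    growth.to_csv(RESULTS / "growth_table.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    for var, grp in growth.groupby("variable"):
        ax.plot(grp["age_dpn"], grp["value"], "o-", ms=4, label=LABELS[var])
    ax.set_xlabel("age (days post natum)")
    ax.set_ylabel("volume (mm$^3$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "growth_linear.png", dpi=150)
    print(f"\nGrowth series written for "
          f"{growth['variable'].nunique()} variables, "
          f"{growth['age_dpn'].nunique()} ages.")


if __name__ == "__main__":
    main()
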