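"""Cohort morphometry: per-age summaries, allometric scaling and growth.

The per-specimen record carries postnatal age (days post natum), body mass
(g) and the compartment volumes (mm^3): whole lung V_L, bronchial tree
V_BT, pulmonary artery V_PA and pulmonary vein V_PV.  V_L and V_BT were
reconstructed in earlier work on the same specimens and enter here as given
columns.

Summary convention: mean and *sample* standard deviation (n - 1 in the
denominator; the published {2.70, 1.73, 2.74} -> SD 0.57 only works with
n - 1), printed at two decimals with halves rounded away from zero
(mean 0.125 -> 0.13).  Allometric fits are ordinary least squares of
log10(volume) on log10(body mass) over individual specimens; V ~ M^b
appears as a line of slope b on double-logarithmic axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import numpy as np
import pandas as pd

from .segmentation import round_printed

__all__ = [
    "MORPHOMETRY_COLUMNS",
    "VOLUME_COLUMNS",
    "AllometryFit",
    "load_reference_morphometry",
    "cohort_summary",
    "format_summary",
    "allometric_fit",
    "growth_table",
]

MORPHOMETRY_COLUMNS = [
    "age_dpn", "specimen", "body_mass_g", "lung_volume_mm3",
    "bronchial_tree_volume_mm3", "pulmonary_artery_volume_mm3",
    "pulmonary_vein_volume_mm3",
]
VOLUME_COLUMNS = MORPHOMETRY_COLUMNS[3:]
_NUMERIC = MORPHOMETRY_COLUMNS[2:]


@dataclass(frozen=True)
class AllometryFit:
    """OLS fit of log10(y) on log10(body mass): y = 10**intercept * M**slope."""

    y_column: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("allometric fit needs at least 2 records")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite fit estimates")


def load_reference_morphometry() -> pd.DataFrame:
    """The bundled per-specimen cohort table (15 animals, neonate-57 dpn)."""
    with resources.files("vascmorph.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df[MORPHOMETRY_COLUMNS]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"morphometry table lacks columns {missing}")
    if records.empty:
        raise ValueError("no morphometry records")
    for col in VOLUME_COLUMNS:
        if (records[col] < 0).any():
            bad = records.loc[records[col] < 0, "specimen"].tolist()
            raise ValueError(f"negative {col} for specimens {bad}")
    return records


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of every numeric column per age group.

    Returns full-precision values, one row per age, columns ``<col>_mean``
    and ``<col>_sd`` (SD is NaN for singleton groups).  Use
    :func:`format_summary` for the printed 2-decimal "mean (SD)" form.
    """
    _validate(records)
    out = []
    for age, grp in records.groupby("age_dpn", sort=True):
        row = {"age_dpn": age, "n": len(grp)}
        for col in _NUMERIC:
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = (
                float(grp[col].std(ddof=1)) if len(grp) > 1 else float("nan")
            )
        out.append(row)
    return pd.DataFrame(out)


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Printed form: '2.39 (0.57)' cells, SD omitted for n = 1 groups."""
    rows = []
    for _, r in summary.iterrows():
        row = {"age_dpn": r["age_dpn"], "n": int(r["n"])}
        for col in _NUMERIC:
            mean = round_printed(r[f"{col}_mean"])
            sd = r[f"{col}_sd"]
            if np.isnan(sd):
                row[col] = f"{mean:.2f}"
            else:
                row[col] = f"{mean:.2f} ({round_printed(sd):.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def allometric_fit(records: pd.DataFrame, y_column: str,
                   per_age_mean: bool = False) -> AllometryFit:
    """OLS of log10(y_column) on log10(body mass).

    ``per_age_mean=True`` first averages specimens within each age group
    (the fit-point convention is a genuine modelling choice; the default
    uses individual specimens).  Nonpositive masses or volumes are an
    error naming the offending specimens.
    """
    import statsmodels.api as sm

    _validate(records)
    if y_column not in records.columns:
        raise ValueError(f"unknown column {y_column!r}")
    df = records[["age_dpn", "specimen", "body_mass_g", y_column]].copy()
    bad = df[(df["body_mass_g"] <= 0) | (df[y_column] <= 0)]
    if not bad.empty:
        raise ValueError(
            f"nonpositive mass or {y_column} for specimens "
            f"{bad['specimen'].tolist()}; cannot take logarithms"
        )
    if per_age_mean:
        df = df.groupby("age_dpn", as_index=False)[
            ["body_mass_g", y_column]].mean()
    if len(df) < 2:
        raise ValueError("allometric fit needs at least 2 points")
    x = np.log10(df["body_mass_g"].to_numpy(float))
    y = np.log10(df[y_column].to_numpy(float))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AllometryFit(
        y_column=y_column,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(df),
    )


def growth_table(records: pd.DataFrame,
                 variables=("pulmonary_artery_volume_mm3",
                            "pulmonary_vein_volume_mm3")) -> pd.DataFrame:
    """Tidy (age, variable, value) series for linear-scale growth plots.

    Values pass through unchanged; rows are sorted by age with stable order
    for ties.  Variables absent from the table are skipped with a warning.
    """
    import warnings

    _validate(records)
    keep = []
    for var in variables:
        if var not in records.columns:
            warnings.warn(f"variable {var!r} not in records; omitted",
                          stacklevel=2)
            continue
        keep.append(var)
    long = records.melt(
        id_vars=["age_dpn", "specimen"], value_vars=keep,
        var_name="variable", value_name="value",
    )
    return long.sort_values("age_dpn", kind="stable").reset_index(drop=True)
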