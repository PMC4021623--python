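"""EMR-style phenotype derivation from longitudinal records.

Quantitative traits measured repeatedly in an electronic medical record are
collapsed to one value per person by a two-stage median: the median within
each calendar year, then the median across yearly medians. A single
observation suffices for inclusion. Hypertension is dichotomized from blood
pressure readings and medication flags; BMI is range-cleaned before
aggregation to remove unit-conversion artefacts.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "median_of_yearly_medians",
    "dichotomize_hypertension",
    "clean_bmi",
    "read_longitudinal",
    "aggregate_quantitative",
    "write_phenotype_table",
]

#: default BMI plausibility bounds, kg/m^2
BMI_BOUNDS = (10.0, 100.0)

CASE, CONTROL, EXCLUDED = 1, 0, "excluded"


def median_of_yearly_medians(years: Iterable[int], values: Iterable[float]) -> float:
    """Two-stage median: within calendar year, then across yearly medians.

    Even-count medians are the midpoint of the two central order statistics.
    Returns NaN for an empty record list.
    """
    years = np.asarray(list(years))
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return math.nan
    if years.shape != values.shape:
        raise ValueError("years and values must have equal length")
    yearly = [np.median(values[years == y]) for y in np.unique(years)]
    return float(np.median(yearly))


def dichotomize_hypertension(sbp: Iterable[float] | None,
                             dbp: Iterable[float] | None,
                             current_med: bool = False,
                             med_history: bool = False):
    """Classify a person as hypertension case, control, or excluded.

    Case: any systolic reading >= 140 mmHg, any diastolic >= 90 mmHg, or
    currently on antihypertensive medication. Non-cases with a history of
    prescribed antihypertensives are excluded from the control pool;
    remaining non-cases are controls. Returns ``1`` (case), ``0`` (control),
    ``"excluded"``, or NaN when no information is available.
    """
    sbp = np.asarray(list(sbp) if sbp is not None else [], dtype=float)
    dbp = np.asarray(list(dbp) if dbp is not None else [], dtype=float)
    has_bp = sbp.size > 0 or dbp.size > 0
    if not has_bp and not current_med and not med_history:
        return math.nan
    if (sbp.size and np.nanmax(sbp) >= 140.0) or \
       (dbp.size and np.nanmax(dbp) >= 90.0) or current_med:
        return CASE
    if med_history:
        return EXCLUDED
    return CONTROL


def clean_bmi(values: Iterable[float],
              lower: float = BMI_BOUNDS[0],
              upper: float = BMI_BOUNDS[1]) -> np.ndarray:
    """Set BMI values outside [lower, upper] to NaN (pre-aggregation QC)."""
    if not (math.isfinite(lower) and math.isfinite(upper) and lower < upper):
        raise ValueError("bounds must be finite with lower < upper")
    v = np.asarray(list(values), dtype=float)
    out = v.copy()
    out[(v < lower) | (v > upper)] = math.nan
    return out


# ---------------------------------------------------------------------------
# Delimited longitudinal input -> per-sample phenotype table
# ---------------------------------------------------------------------------

def read_longitudinal(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read records ``sample_id, trait, date (ISO), value``; adds a ``year`` column."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "trait": str})
    df["year"] = pd.to_datetime(df["date"]).dt.year
    df["value"] = pd.to_numeric(df["value"])
    if not np.isfinite(df["value"]).all():
        raise ValueError("longitudinal values must be finite")
    return df


def aggregate_quantitative(records: pd.DataFrame,
                           bmi_trait: str = "bmi",
                           bmi_bounds: tuple[float, float] = BMI_BOUNDS) -> pd.DataFrame:
    """Collapse longitudinal records to one row per sample.

    Applies BMI range cleaning to the ``bmi_trait`` column before the
    two-stage median; other traits aggregate as-is. Also derives the age
    covariate as the median of per-record ages when an ``age`` column is
    present. Returns a wide table indexed by sample_id.
    """
    rec = records.copy()
    if bmi_trait in set(rec["trait"]):
        is_bmi = rec["trait"] == bmi_trait
        rec.loc[is_bmi, "value"] = clean_bmi(rec.loc[is_bmi, "value"], *bmi_bounds)
        rec = rec[~(is_bmi & rec["value"].isna())]

    rows = {}
    for (sid, trait), grp in rec.groupby(["sample_id", "trait"]):
        rows.setdefault(sid, {})[trait] = median_of_yearly_medians(
            grp["year"].to_numpy(), grp["value"].to_numpy())
    wide = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    wide.index.name = "sample_id"

    if "age" in records.columns:
        age = records.groupby("sample_id")["age"].median()
        wide["age"] = age.reindex(wide.index)
    return wide


def write_phenotype_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a per-sample phenotype table, missing values as ``NA``."""
    table.to_csv(path, sep=sep, na_rep="NA")
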