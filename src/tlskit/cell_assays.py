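"""Cell-level summaries: Rpa-focus positivity over time and UV survival.

Rpa (replication protein A) focus counts per nucleus report single-stranded
DNA gaps left behind replication forks after UV; the fraction of cells with
at least one focus is followed over hours post-irradiation.  Clonogenic
survival is the ratio of colonies on UV-irradiated to mock plates per dose.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import replicate_summary

__all__ = ["foci_positive_fraction", "survival_curve", "CellAssayError"]

#: minimum cells per condition/timepoint before a warning is issued
MIN_CELLS = 100


class CellAssayError(ValueError):
    pass


def foci_positive_fraction(
    records: pd.DataFrame, threshold: int = 1
) -> pd.DataFrame:
    """Percent of cells with at least ``threshold`` foci per condition and timepoint.

    ``records`` needs columns cell_id, condition_id, timepoint, focus_count;
    an optional experiment_id column defines independent experiments, whose
    per-experiment percentages give the reported mean and SD.  Manual
    scoring of "cells with foci" is presence/absence, hence threshold 1 by
    default.
    """
    required = {"cell_id", "condition_id", "timepoint", "focus_count"}
    missing = required - set(records.columns)
    if missing:
        raise CellAssayError(f"foci table missing columns: {sorted(missing)}")
    if records.empty:
        raise CellAssayError("foci table is empty")
    if threshold < 1:
        raise CellAssayError("threshold must be >= 1")
    if (records["focus_count"] < 0).any() or (records["timepoint"] < 0).any():
        raise CellAssayError("negative focus_count or timepoint")

    df = records.copy()
    if "experiment_id" not in df.columns:
        df["experiment_id"] = "exp1"
    df["positive"] = df["focus_count"] >= threshold

    rows = []
    for (cond, t), grp in df.groupby(["condition_id", "timepoint"], sort=True):
        n_cells = len(grp)
        if n_cells < MIN_CELLS:
            warnings.warn(
                f"{cond} at {t} h: only {n_cells} cells (< {MIN_CELLS})",
                stacklevel=2,
            )
        per_exp = [
            100.0 * g["positive"].mean() for _, g in grp.groupby("experiment_id", sort=True)
        ]
        mean, sd, n_exp = replicate_summary(per_exp)
        rows.append(
            {"condition_id": cond, "timepoint": t, "pct_positive": mean,
             "sd": sd, "n_cells": n_cells, "n_experiments": n_exp}
        )
    return pd.DataFrame(rows)


def survival_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Colony-forming ability (UV / mock colonies) per condition and dose.

    ``records`` needs columns condition_id, dose, colonies_uv,
    colonies_mock and optionally replicate_id; fractions are computed per
    replicate, then averaged with sample SD.
    """
    required = {"condition_id", "dose", "colonies_uv", "colonies_mock"}
    missing = required - set(records.columns)
    if missing:
        raise CellAssayError(f"survival table missing columns: {sorted(missing)}")
    if records.empty:
        raise CellAssayError("survival table is empty")
    if (records[["colonies_uv", "colonies_mock"]] < 0).any().any():
        raise CellAssayError("negative colony count")
    zero_mock = records["colonies_mock"] == 0
    if zero_mock.any():
        bad = records.loc[zero_mock].iloc[0]
        raise CellAssayError(
            f"{bad['condition_id']} at {bad['dose']} J/m2: zero mock colonies, "
            "survival fraction undefined"
        )
    df = records.copy()
    df["fraction"] = df["colonies_uv"] / df["colonies_mock"]
    rows = []
    for (cond, dose), grp in df.groupby(["condition_id", "dose"], sort=True):
        mean, sd, n = replicate_summary(grp["fraction"].to_numpy())
        rows.append(
            {"condition_id": cond, "dose": dose, "fraction": mean, "sd": sd, "n": n}
        )
    return pd.DataFrame(rows)
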