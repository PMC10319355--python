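"""cAMP bioluminescence reporter-assay normalization and summaries.

Receptor activation in transfected HEK cells drives a CRE-luciferase
reporter; each well is read twice (at 0 s and 5 s), wells are run in
triplicate, and the whole assay is repeated on independent days. Raw
counts vary with luminometer gain per session, so every well is expressed
relative to the mean of that assay's ligand-free control wells
("relative luminescence"), and assays — not wells — are the unit of
replication when conditions are summarized.

Tables follow a tidy schema with columns
``assay, plate, well, condition, construct, dose, read_0s, read_5s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PlateError

__all__ = [
    "WellRecord",
    "NormalizedResponse",
    "REQUIRED_COLUMNS",
    "read_plate_csv",
    "collapse_reads",
    "normalize_to_control",
    "summarize_conditions",
    "basal_activity_ratio",
]

REQUIRED_COLUMNS = ("assay", "condition", "read_0s", "read_5s")
OPTIONAL_COLUMNS = ("plate", "well", "construct", "dose")


@dataclass(frozen=True)
class WellRecord:
    """One plate well: two 5-s luminescence reads plus design labels."""

    assay: str
    condition: str
    read_0s: float
    read_5s: float
    plate: str = ""
    well: str = ""
    construct: str = "receptor"
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.read_0s is None or self.read_5s is None:
            raise ValueError("both reads must be present")
        if self.read_0s < 0 or self.read_5s < 0:
            raise ValueError("luminescence reads must be non-negative")


@dataclass(frozen=True)
class NormalizedResponse:
    """Per-assay mean relative luminescence of one condition."""

    condition: str
    assay: str
    relative_luminescence: float
    n_wells: int


def _as_frame(wells) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        df = wells.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PlateError(f"plate table missing required columns: {missing}")
        for c in OPTIONAL_COLUMNS:
            if c not in df.columns:
                df[c] = "" if c in ("plate", "well", "construct") else np.nan
        return df
    return pd.DataFrame([vars(w) for w in wells])


def read_plate_csv(path) -> pd.DataFrame:
    """Read and header-validate a plate CSV."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"plate CSV missing required columns: {missing}")
    if (df["read_0s"] < 0).any() or (df["read_5s"] < 0).any():
        raise PlateError("negative luminescence reads")
    return df


def collapse_reads(record, policy: str = "mean") -> float:
    """Combine the two 5-s reads of a well into one luminescence value.

    Policies: ``mean`` (default), ``first`` (0-s read only), ``max``.
    Accepts a :class:`WellRecord` or anything with read_0s/read_5s fields.
    """
    r0 = record.read_0s if hasattr(record, "read_0s") else record["read_0s"]
    r5 = record.read_5s if hasattr(record, "read_5s") else record["read_5s"]
    if r0 is None or r5 is None or (isinstance(r0, float) and math.isnan(r0)) or (
        isinstance(r5, float) and math.isnan(r5)
    ):
        raise PlateError("missing read")
    if policy == "mean":
        return (r0 + r5) / 2.0
    if policy == "first":
        return float(r0)
    if policy == "max":
        return float(max(r0, r5))
    raise ValueError(f"unknown read-collapse policy {policy!r}")


def _collapsed_column(df: pd.DataFrame, policy: str) -> pd.Series:
    if df[["read_0s", "read_5s"]].isna().any().any():
        raise PlateError("missing read in plate table")
    if policy == "mean":
        return (df["read_0s"] + df["read_5s"]) / 2.0
    if policy == "first":
        return df["read_0s"].astype(float)
    if policy == "max":
        return df[["read_0s", "read_5s"]].max(axis=1)
    raise ValueError(f"unknown read-collapse policy {policy!r}")


def normalize_to_control(
    wells, control_label: str, read_policy: str = "mean"
) -> pd.DataFrame:
    """Express every well relative to its own assay's ligand-free control.

    Within each assay, relative value = collapsed well value / mean of that
    assay's control wells, so the control mean maps to exactly 1. Returns a
    per-well tidy frame with a ``relative_luminescence`` column. Raises
    :class:`PlateError` for an assay without control wells or with a
    zero control mean.
    """
    df = _as_frame(wells)
    df["luminescence"] = _collapsed_column(df, read_policy)
    out = []
    for assay, grp in df.groupby("assay", sort=True):
        ctrl = grp.loc[grp["condition"] == control_label, "luminescence"]
        if ctrl.empty:
            raise PlateError(f"assay {assay!r} has no {control_label!r} control wells")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise PlateError(f"assay {assay!r}: control mean is 0")
        g = grp.copy()
        g["relative_luminescence"] = g["luminescence"] / ctrl_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def per_assay_means(normalized: pd.DataFrame) -> list[NormalizedResponse]:
    """Collapse a per-well normalized frame to per-(condition, assay) means."""
    return [
        NormalizedResponse(
            condition=str(cond),
            assay=str(assay),
            relative_luminescence=float(grp["relative_luminescence"].mean()),
            n_wells=len(grp),
        )
        for (cond, assay), grp in normalized.groupby(["condition", "assay"], sort=True)
    ]


def summarize_conditions(normalized: pd.DataFrame) -> pd.DataFrame:
    """Across-assay summary per condition, assays as the replication unit.

    Wells are first averaged within each (condition, assay), then the
    per-assay means are averaged across assays. SD is across assays and is
    reported as missing (NaN) when a condition appears in a single assay.
    """
    if normalized.empty:
        raise PlateError("nothing to summarize")
    responses = per_assay_means(normalized)
    df = pd.DataFrame([vars(r) for r in responses])
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        vals = grp["relative_luminescence"].to_numpy()
        rows.append(
            {
                "condition": cond,
                "n_assays": len(vals),
                "mean_relative_luminescence": float(np.mean(vals)),
                "sd_relative_luminescence": float(np.std(vals, ddof=1))
                if len(vals) > 1
                else np.nan,
                "n_wells": int(grp["n_wells"].sum()),
            }
        )
    return pd.DataFrame(rows)


def basal_activity_ratio(
    receptor_wells, empty_vector_wells, read_policy: str = "mean"
) -> float:
    """Ligand-independent signaling: receptor vs empty-vector luminescence.

    Computes, per assay, the ratio of the mean receptor-well to the mean
    empty-vector-well raw luminescence (ligand-free wells only), then
    averages the per-assay ratios. Both groups must cover the same assays.
    """
    rec = _as_frame(receptor_wells)
    emp = _as_frame(empty_vector_wells)
    if rec.empty or emp.empty:
        raise PlateError("both well groups must be non-empty")
    rec["luminescence"] = _collapsed_column(rec, read_policy)
    emp["luminescence"] = _collapsed_column(emp, read_policy)
    rec_means = rec.groupby("assay")["luminescence"].mean()
    emp_means = emp.groupby("assay")["luminescence"].mean()
    common = rec_means.index.intersection(emp_means.index)
    if len(common) == 0:
        raise PlateError("receptor and empty-vector wells share no assay")
    if (emp_means.loc[common] == 0).any():
        raise PlateError("empty-vector mean luminescence is 0 in some assay")
    return float((rec_means.loc[common] / emp_means.loc[common]).mean())
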