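"""Conversion of literature cell counts to percent of total cells.

Quantitative reports of adipose tissue composition use heterogeneous
units — counts per 100 adipocytes, per gram of tissue, percent of the
stromal vascular fraction (SVF, the non-adipocyte cells), per total
nuclei, per high-power field, per mm². Cross-study comparison requires a
common denominator; everything is converted to percent of *total* cells
under two explicit assumptions:

* ``adipocyte_fraction`` a — the fraction of all cells that are adipocytes;
* ``cells_per_gram`` c — total cells per gram of tissue.

The linear conversions are then

====================  =============================
unit                  percent of total cells
====================  =============================
per_100_adipocytes    ``x * a``
per_gram              ``100 * x / c``
percent_svf           ``x * (1 - a)``
per_total_nuclei      ``100 * x``  (x given as a fraction)
====================  =============================

Counts per high-power field or per mm² depend on section geometry, not on
the two assumptions, and are marked *excluded* rather than converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deconvolve import FractionEstimate

__all__ = [
    "LiteratureRecord",
    "ConversionAssumptions",
    "ConvertedRecord",
    "to_percent_total",
    "convert_records",
    "read_records",
    "summarize_vs_estimates",
    "CONVERTIBLE_UNITS",
    "EXCLUDED_UNITS",
]

CONVERTIBLE_UNITS = (
    "per_100_adipocytes",
    "per_gram",
    "percent_svf",
    "per_total_nuclei",
)
EXCLUDED_UNITS = ("per_high_power_field", "per_mm2")
ALL_UNITS = CONVERTIBLE_UNITS + EXCLUDED_UNITS


@dataclass(frozen=True)
class LiteratureRecord:
    """One study's reported count for one cell type, in its native unit."""

    study_id: str
    cell_type: str
    unit: str
    mean: float
    sd_or_se: float | None = None
    min: float | None = None
    max: float | None = None
    depot: str = "SAT"
    n_subjects: int | None = None
    method: str = ""
    bmi_over_35: bool = False

    def __post_init__(self) -> None:
        if self.unit not in ALL_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {ALL_UNITS}")
        if self.mean is not None and self.mean < 0:
            raise ValueError("mean count must be >= 0")


@dataclass(frozen=True)
class ConversionAssumptions:
    """Explicit parameters of the unit conversion; no silent defaults."""

    adipocyte_fraction: float
    cells_per_gram: float

    def __post_init__(self) -> None:
        if not 0 < self.adipocyte_fraction < 1:
            raise ValueError("adipocyte_fraction must be in (0, 1)")
        if self.cells_per_gram <= 0:
            raise ValueError("cells_per_gram must be positive")


@dataclass(frozen=True)
class ConvertedRecord:
    """A literature record expressed as percent of total cells."""

    record: LiteratureRecord
    status: str  # converted | excluded
    percent_mean: float | None = None
    percent_sd_or_se: float | None = None
    percent_min: float | None = None
    percent_max: float | None = None


def _factor(unit: str, a: ConversionAssumptions) -> float:
    """Multiplicative factor taking a value in ``unit`` to percent of total."""
    if unit == "per_100_adipocytes":
        # x cells per 100 adipocytes; 100 adipocytes stand for 100/a total
        # cells, so pct = 100 * x / (100 / a) = x * a
        return a.adipocyte_fraction
    if unit == "per_gram":
        return 100.0 / a.cells_per_gram
    if unit == "percent_svf":
        # x% of SVF cells; SVF is the (1 - a) non-adipocyte share of total
        return 1.0 - a.adipocyte_fraction
    if unit == "per_total_nuclei":
        return 100.0  # given as a fraction of nuclei ~ fraction of cells
    raise ValueError(f"unit {unit!r} is not convertible")


def to_percent_total(
    rec: LiteratureRecord, assumptions: ConversionAssumptions
) -> ConvertedRecord:
    """Convert one record; excluded units get status ``excluded``, no number.

    The same linear factor applies to mean, sd/se, min and max, so ordering
    (min <= mean <= max) is preserved.
    """
    if rec.unit in EXCLUDED_UNITS:
        return ConvertedRecord(record=rec, status="excluded")
    f = _factor(rec.unit, assumptions)
    conv = lambda v: None if v is None else float(v) * f
    return ConvertedRecord(
        record=rec,
        status="converted",
        percent_mean=conv(rec.mean),
        percent_sd_or_se=conv(rec.sd_or_se),
        percent_min=conv(rec.min),
        percent_max=conv(rec.max),
    )


def convert_records(
    records: Sequence[LiteratureRecord], assumptions: ConversionAssumptions
) -> pd.DataFrame:
    """Convert many records into a flat table with a ``status`` column."""
    rows = []
    for rec in records:
        c = to_percent_total(rec, assumptions)
        rows.append(
            {
                "study_id": rec.study_id,
                "cell_type": rec.cell_type,
                "unit": rec.unit,
                "depot": rec.depot,
                "status": c.status,
                "percent_total_mean": c.percent_mean,
                "percent_total_sd_or_se": c.percent_sd_or_se,
                "percent_total_min": c.percent_min,
                "percent_total_max": c.percent_max,
            }
        )
    return pd.DataFrame(rows)


def read_records(path: str | Path) -> list[LiteratureRecord]:
    """Read literature records from TSV (columns mirroring LiteratureRecord)."""
    df = pd.read_csv(path, sep="\t")
    required = {"study_id", "cell_type", "unit", "mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            study_id=str(row["study_id"]),
            cell_type=str(row["cell_type"]),
            unit=str(row["unit"]),
            mean=float(row["mean"]),
        )
        for opt in ("sd_or_se", "min", "max"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        for opt, cast in (("depot", str), ("n_subjects", int), ("method", str)):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = cast(row[opt])
        if "bmi_over_35" in df.columns and pd.notna(row["bmi_over_35"]):
            kwargs["bmi_over_35"] = bool(row["bmi_over_35"])
        out.append(LiteratureRecord(**kwargs))
    return out


def summarize_vs_estimates(
    records: Sequence[LiteratureRecord],
    estimates: Sequence[FractionEstimate],
    cell_type: str | Sequence[str],
    assumptions: ConversionAssumptions,
) -> pd.DataFrame:
    """Align converted literature ranges with deconvolution estimates.

    ``cell_type`` may be a single name or a combined class (e.g. macrophages
    plus monocytes, which share the classic CD14/CD68 staining markers): a
    sequence sums the member fractions per sample before summarizing.
    One output row per convertible literature record, each carrying the
    study's converted mean/min/max alongside the estimate distribution
    (mean, median, IQR) in percent of total cells.
    """
    members = [cell_type] if isinstance(cell_type, str) else list(cell_type)
    label = "+".join(members)
    recs = [r for r in records if r.cell_type in members]
    if not recs:
        raise ValueError(f"no literature records for cell type {label!r}")
    vals = []
    for e in estimates:
        missing = [m for m in members if m not in e.fractions]
        if missing:
            raise KeyError(f"estimate {e.sample_id!r} lacks cell types {missing}")
        vals.append(100.0 * sum(e.fractions[m] for m in members))
    if not vals:
        raise ValueError("no estimates supplied")
    vals = np.asarray(vals)
    est_stats = {
        "estimate_mean": float(vals.mean()),
        "estimate_median": float(np.median(vals)),
        "estimate_q1": float(np.percentile(vals, 25)),
        "estimate_q3": float(np.percentile(vals, 75)),
        "estimate_n": len(vals),
    }
    rows = []
    for rec in recs:
        c = to_percent_total(rec, assumptions)
        if c.status != "converted":
            continue
        rows.append(
            {
                "cell_type": label,
                "study_id": rec.study_id,
                "unit": rec.unit,
                "literature_mean": c.percent_mean,
                "literature_min": c.percent_min,
                "literature_max": c.percent_max,
                **est_stats,
            }
        )
    if not rows:
        raise ValueError(
            f"all literature records for {label!r} use excluded units"
        )
    return pd.DataFrame(rows)
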