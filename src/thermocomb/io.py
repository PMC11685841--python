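"""Table readers/writers for the campaign's CSV interfaces.

Labeled-variant table: ``variant,tm_celsius,relative_activity_percent,round``
(missing labels empty).  Raw-curve table: long format
``sample,series_type,x,y`` with ``series_type`` in
{dsf, cd, t50, dsc, decay, mm}.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .predictor import VariantRecord, records_from_dataframe, records_to_dataframe

CURVE_TYPES = ("dsf", "cd", "t50", "dsc", "decay", "mm")


def read_variant_table(path, wild_type: str | None = None) -> list[VariantRecord]:
    """Load labeled variants from CSV, validating against the wild type if given.

    Warns when no wild-type (order-0) row is present: several analyses
    (background effects, deviation-from-additivity) need the WT label, and
    datasets are reported inconsistently with and without it.
    """
    df = pd.read_csv(path)
    missing = {"variant"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns: {sorted(missing)}")
    records = records_from_dataframe(df, wild_type)
    if not any(r.variant.order == 0 for r in records):
        warnings.warn(
            f"{path}: no wild-type record found ({len(records)} mutant rows); "
            "WT-relative analyses will be unavailable unless a WT label is added",
            stacklevel=2,
        )
    return records


def write_variant_table(path, records: Sequence[VariantRecord]) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_curve_table(path) -> dict[tuple[str, str], pd.DataFrame]:
    """Load a long-format raw-curve CSV, grouped by (sample, series_type)."""
    df = pd.read_csv(path)
    needed = {"sample", "series_type", "x", "y"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(needed)}")
    bad = set(df["series_type"]) - set(CURVE_TYPES)
    if bad:
        raise ValueError(f"unknown series types {sorted(bad)}; expected {CURVE_TYPES}")
    out = {}
    for (sample, kind), grp in df.groupby(["sample", "series_type"]):
        out[(sample, kind)] = grp.sort_values("x").reset_index(drop=True)
    return out


def write_curve_table(path, frames: Sequence[pd.DataFrame]) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ranked_candidates(path, ranked: pd.DataFrame) -> None:
    """Persist a scored candidate table (variant,order,tm_score,acceptable,probability)."""
    cols = ["variant", "order", "tm_score", "acceptable", "probability"]
    ranked[cols].to_csv(path, index=False)
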