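"""Readers for wide and long quantification tables and design files.

Wide tables follow the MaxQuant convention: one row per protein group (or
peptide), per-sample intensity columns sharing a prefix such as
``"LFQ intensity "``, QC flag columns (``Reverse``, ``Potential
contaminant``) marked with ``"+"``, and ``0`` encoding a missing intensity.
Long tables follow the DIA-report convention (DIA-NN, Spectronaut): one row
per feature × sample observation, with missing pairs simply absent.  Key
column names are explicit arguments because DIA software dialects differ.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FormatError, QuantTable, validate_design

__all__ = [
    "read_wide_table",
    "wide_table_from_frame",
    "reshape_long",
    "melt",
    "make_unique",
    "parse_design",
]

# strings upstream tools use for "not quantified"
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "Filtered", "#N/A", "NULL"}


def make_unique(names: Sequence[str], fallback_ids: Sequence[str]) -> list[str]:
    """Produce pairwise-distinct labels from names with identifier fallback.

    Empty or missing names are replaced by the corresponding fallback id
    (first member of a ";"-joined group).  Duplicates are disambiguated
    deterministically: the first occurrence is unchanged, the k-th repeat
    gets suffix ``.k-1``.  Idempotent on already-unique input.
    """
    if len(names) != len(fallback_ids):
        raise ValueError("names and fallback_ids must have equal length")
    base: list[str] = []
    for i, (nm, fid) in enumerate(zip(names, fallback_ids)):
        nm = "" if nm is None or (isinstance(nm, float) and np.isnan(nm)) else str(nm).strip()
        fid = "" if fid is None or (isinstance(fid, float) and np.isnan(fid)) else str(fid).strip()
        label = nm if nm else fid.split(";")[0]
        if not label:
            raise ValueError(f"row {i}: both name and fallback identifier are empty")
        base.append(label)
    seen: dict[str, int] = {}
    out: list[str] = []
    for label in base:
        k = seen.get(label, 0)
        out.append(label if k == 0 else f"{label}.{k}")
        seen[label] = k + 1
    if len(set(out)) != len(out):  # collision with a pre-existing "X.1"-style name
        return make_unique(out, out)
    return out


def _to_numeric_missing(values: pd.Series, zero_is_missing: bool) -> pd.Series:
    s = values.astype(object).mask(values.astype(str).str.strip().isin(_MISSING_TOKENS))
    s = pd.to_numeric(s, errors="raise").astype(float)
    if zero_is_missing:
        s = s.mask(s == 0.0)
    if (s.dropna() < 0).any():
        raise FormatError("negative intensity encountered")
    return s


def wide_table_from_frame(
    frame: pd.DataFrame,
    intensity_prefix: str,
    id_column: str,
    name_column: str | None = None,
    flag_columns: Sequence[str] = (),
    zero_is_missing: bool = True,
) -> QuantTable:
    """Build a :class:`QuantTable` from an already-parsed wide DataFrame."""
    intensity_cols = [c for c in frame.columns if c.startswith(intensity_prefix)]
    if not intensity_cols:
        raise FormatError(f"no column starts with prefix {intensity_prefix!r}")
    samples = [c[len(intensity_prefix):] for c in intensity_cols]
    if len(set(samples)) != len(samples):
        raise FormatError(f"duplicate sample names after stripping prefix: {samples}")
    if id_column not in frame.columns:
        raise FormatError(f"id column {id_column!r} not found")
    for col in flag_columns:
        if col not in frame.columns:
            raise FormatError(f"flag column {col!r} not found")

    raw_ids = frame[id_column].astype(str)
    names = frame[name_column] if name_column and name_column in frame.columns else raw_ids
    feature_ids = make_unique(list(names), list(raw_ids))

    intens = pd.DataFrame(
        {s: _to_numeric_missing(frame[c], zero_is_missing) for s, c in zip(samples, intensity_cols)}
    )
    intens.index = pd.Index(feature_ids, name="feature_id")

    meta_cols = {"name": feature_ids, "raw_ids": list(raw_ids)}
    for col in frame.columns:
        if col in intensity_cols or col == id_column:
            continue
        meta_cols[col] = list(frame[col].astype(object).where(frame[col].notna(), ""))
    meta = pd.DataFrame(meta_cols, index=intens.index)
    return QuantTable(intens, meta)


def read_wide_table(
    path: str | Path,
    intensity_prefix: str,
    id_column: str,
    name_column: str | None = None,
    flag_columns: Sequence[str] = (),
    zero_is_missing: bool = True,
) -> QuantTable:
    """Read a tab-separated wide quantification table.

    Intensity columns are identified by ``intensity_prefix``; the prefix is
    stripped to obtain sample names.  In the MaxQuant dialect zeros encode
    missing values and are converted to ``NaN`` (``zero_is_missing=True``).
    Flag columns are preserved as annotations; filtering is a later stage.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return wide_table_from_frame(
        frame, intensity_prefix, id_column, name_column, flag_columns, zero_is_missing
    )


def reshape_long(
    rows: pd.DataFrame,
    feature_key: str,
    sample_key: str,
    value_key: str,
    duplicate_policy: str = "error",
) -> QuantTable:
    """Pivot a long (one row per feature × sample) report to a wide table.

    Pairs absent from the long table become missing cells.  Duplicate
    (feature, sample) pairs are an error unless ``duplicate_policy`` is
    ``"max"`` or ``"sum"`` — silent aggregation hides upstream problems.
    """
    for col in (feature_key, sample_key, value_key):
        if col not in rows.columns:
            raise FormatError(f"column {col!r} not found in long table")
    work = rows[[feature_key, sample_key, value_key]].copy()
    work[value_key] = _to_numeric_missing(work[value_key].astype(object), zero_is_missing=False)
    work = work.dropna(subset=[value_key])

    dup_mask = work.duplicated([feature_key, sample_key], keep=False)
    if dup_mask.any():
        if duplicate_policy == "error":
            first = work.loc[dup_mask, [feature_key, sample_key]].iloc[0]
            raise FormatError(
                "duplicate (feature, sample) pair "
                f"({first[feature_key]!r}, {first[sample_key]!r}); "
                "pass duplicate_policy='max' or 'sum' to aggregate"
            )
        if duplicate_policy not in ("max", "sum"):
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
        agg = {"max": "max", "sum": "sum"}[duplicate_policy]
        work = work.groupby([feature_key, sample_key], sort=False, as_index=False).agg(
            {value_key: agg}
        )

    features = list(dict.fromkeys(work[feature_key]))
    samples = list(dict.fromkeys(work[sample_key]))
    wide = work.pivot(index=feature_key, columns=sample_key, values=value_key)
    wide = wide.reindex(index=features, columns=samples)

    feature_ids = make_unique(features, features)
    wide.index = pd.Index(feature_ids, name="feature_id")
    wide.columns.name = None
    meta = pd.DataFrame(
        {"name": feature_ids, "raw_ids": features}, index=wide.index
    )
    return QuantTable(wide, meta)


def melt(qt: QuantTable, feature_key: str = "feature", sample_key: str = "sample",
         value_key: str = "intensity") -> pd.DataFrame:
    """Inverse of :func:`reshape_long`: emit one row per observed cell."""
    long = (
        qt.intensities.rename_axis(feature_key)
        .reset_index()
        .melt(id_vars=feature_key, var_name=sample_key, value_name=value_key)
    )
    return long.dropna(subset=[value_key]).reset_index(drop=True)


def parse_design(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read and validate a sample/condition/replicate design table.

    Accepts a TSV/CSV path (delimiter sniffed from the header line) or an
    in-memory DataFrame.  Single-replicate conditions produce a warning
    record stored in ``df.attrs["warnings"]``; hard violations raise.
    """
    if isinstance(source, pd.DataFrame):
        design = source.copy()
    else:
        with open(source, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        design = pd.read_csv(source, sep=sep)
    design.columns = [str(c).strip().lower() for c in design.columns]
    if "sample" not in design.columns and "label" in design.columns:
        design = design.rename(columns={"label": "sample"})
    warnings = validate_design(design)
    design = design[["sample", "condition", "replicate"]].copy()
    design["sample"] = design["sample"].astype(str)
    design["condition"] = design["condition"].astype(str)
    design["replicate"] = design["replicate"].astype(int)
    design = design.reset_index(drop=True)
    design.attrs["warnings"] = warnings
    return design
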