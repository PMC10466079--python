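"""Core in-memory containers for the quantitative-proteomics workflow.

Two containers move through the pipeline:

* :class:`QuantTable` — the ingest product: a raw feature × sample intensity
  table (``NaN`` marks missing) plus per-feature annotations such as the
  gene-level name, the original protein-group identifier and QC flag columns.
* :class:`QuantMatrix` — the working object: a (log2 or glog2) intensity
  matrix bound to an experimental design, carrying per-feature metadata and a
  provenance ``history`` in which every mutating step appends exactly one
  record (operation name, parameters, feature counts in/out).  The history is
  what the run log exports.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "QuantMatrix",
    "validate_design",
    "bind_design",
    "DesignError",
    "FormatError",
]


class FormatError(ValueError):
    """An input file does not conform to the expected dialect."""


class DesignError(ValueError):
    """The experimental design is inconsistent or does not match the data."""


@dataclass
class QuantTable:
    """Feature × sample intensity table with annotations.

    Parameters
    ----------
    intensities
        DataFrame of non-negative intensities, one row per feature and one
        column per sample; missing values are ``NaN``.  The index holds the
        unique ``feature_id``.
    feature_meta
        DataFrame aligned on the same index.  Must contain columns ``name``
        (unique human-readable label) and ``raw_ids`` (original identifier,
        possibly a ";"-joined protein group); any further columns are
        annotations (flags, sequences, site fields, ...).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ValueError("intensities and feature_meta must share an index")
        if not self.intensities.index.is_unique:
            dup = self.intensities.index[self.intensities.index.duplicated()][:3]
            raise ValueError(f"feature_id values must be unique; duplicates: {list(dup)}")
        for col in ("name", "raw_ids"):
            if col not in self.feature_meta.columns:
                raise ValueError(f"feature_meta must contain a {col!r} column")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    def subset(self, keep: pd.Index | np.ndarray | list[str]) -> "QuantTable":
        return QuantTable(self.intensities.loc[keep], self.feature_meta.loc[keep])


def validate_design(design: pd.DataFrame) -> list[str]:
    """Validate a sample/condition/replicate design table.

    Returns a list of warning strings (e.g. single-replicate conditions);
    raises :class:`DesignError` on hard violations.
    """
    required = {"sample", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design is missing columns: {sorted(missing)}")
    if design["sample"].duplicated().any():
        dup = design.loc[design["sample"].duplicated(), "sample"].iloc[0]
        raise DesignError(f"duplicated sample name in design: {dup!r}")
    pairs = design[["condition", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise DesignError(f"duplicated (condition, replicate) pair: {dup}")
    try:
        reps = design["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise DesignError("replicate column must be integer") from exc
    if (reps < 1).any():
        raise DesignError("replicate numbers must be positive")
    warnings = []
    counts = design.groupby("condition", sort=False)["sample"].count()
    for cond, n in counts.items():
        if n < 2:
            warnings.append(f"condition {cond!r} has a single replicate")
    return warnings


@dataclass
class QuantMatrix:
    """Intensity matrix bound to an experimental design, with provenance.

    ``scale`` tracks which transform the values are on: ``"raw"``, ``"log2"``
    or ``"glog2"`` (after variance-stabilizing normalization).  Stage
    functions refuse to run on the wrong scale.
    """

    X: pd.DataFrame
    design: pd.DataFrame
    feature_meta: pd.DataFrame
    scale: str = "raw"
    history: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(self.design["sample"]):
            raise DesignError(
                "matrix columns must equal design samples, in order: "
                f"{list(self.X.columns)} vs {list(self.design['sample'])}"
            )
        if not self.X.index.equals(self.feature_meta.index):
            raise ValueError("X and feature_meta must share an index")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return list(self.design.loc[mask, "sample"])

    def condition_means(self) -> pd.DataFrame:
        """Per-feature mean over the replicates of each condition."""
        cols = {c: self.X[self.samples_of(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(cols, index=self.X.index)

    def log(self, operation: str, n_in: int, n_out: int, **params: Any) -> None:
        self.history.append(
            {
                "operation": operation,
                "params": params,
                "features_in": int(n_in),
                "features_out": int(n_out),
            }
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.X.copy(),
            self.design.copy(),
            self.feature_meta.copy(),
            self.scale,
            copy.deepcopy(self.history),
        )


def bind_design(qt: QuantTable, design: pd.DataFrame) -> QuantMatrix:
    """Bind a design to a table, reordering columns to design order.

    Every design sample must name an intensity column; surplus intensity
    columns are an error too, so the design fully describes the matrix.
    """
    validate_design(design)
    samples = list(design["sample"])
    missing = [s for s in samples if s not in qt.intensities.columns]
    if missing:
        raise DesignError(f"design samples not found in matrix columns: {missing}")
    extra = [c for c in qt.intensities.columns if c not in samples]
    if extra:
        raise DesignError(f"matrix columns absent from design: {extra}")
    qm = QuantMatrix(
        qt.intensities[samples].copy(),
        design.reset_index(drop=True),
        qt.feature_meta.copy(),
        scale="raw",
    )
    qm.log("bind_design", qt.n_features, qt.n_features, samples=samples)
    return qm
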