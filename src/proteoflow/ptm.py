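"""PTM-site workflow: site identifiers from modified-peptide tables.

Modification-specific proteomics (phosphoproteomics, ubiquitylomics)
quantifies modified peptides; the natural feature unit is the modification
site — protein, residue, position — optionally split by multiplicity (how
many modifications the peptide carries).  Site keys render as
``PROTEIN_RposMmult``, e.g. ``P04637_S15_M1``.  After re-keying, the site
matrix runs through exactly the same filter → normalize → impute → test
chain as the protein pipeline; the stages are identifier-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QuantTable, bind_design
from .diffstats import DifferentialModel, DifferentialResults
from .impute import ImputeSpec, impute
from .ingest import make_unique
from .preprocess import filter_flags, filter_missing, log2_transform, normalize_vsn

__all__ = ["SiteKey", "build_site_ids", "run_ptm_pipeline"]


@dataclass(frozen=True)
class SiteKey:
    protein: str
    residue: str
    position: int
    multiplicity: int

    def __post_init__(self) -> None:
        if len(self.residue) != 1 or not self.residue.isalpha():
            raise ValueError(f"residue must be a single amino-acid letter, got {self.residue!r}")
        if self.position < 1 or self.multiplicity < 1:
            raise ValueError("position and multiplicity must be positive")

    def render(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}_M{self.multiplicity}"


def build_site_ids(
    qt: QuantTable,
    protein_col: str = "Protein",
    position_col: str = "Position",
    aa_col: str = "Amino acid",
    multiplicity_col: str | None = None,
) -> QuantTable:
    """Re-key a modified-peptide table on rendered site identifiers.

    Rows with missing site fields are dropped (count recorded in
    ``feature_meta.attrs["n_dropped_missing_site"]``); duplicate site keys
    are disambiguated with deterministic ``.k`` suffixes.  Unparseable
    positions raise, listing the offending rows.
    """
    meta = qt.feature_meta
    for col in (protein_col, position_col, aa_col):
        if col not in meta.columns:
            raise KeyError(f"site column {col!r} not found in feature annotations")

    prot = meta[protein_col].astype(str).str.strip()
    pos_raw = meta[position_col].astype(str).str.strip()
    aa = meta[aa_col].astype(str).str.strip()
    if multiplicity_col is not None and multiplicity_col in meta.columns:
        mult_raw = meta[multiplicity_col].astype(str).str.strip()
    else:
        mult_raw = pd.Series("1", index=meta.index)

    present = (prot != "") & (pos_raw != "") & (aa != "") & (mult_raw != "")
    bad_pos = []
    positions = np.zeros(len(meta), dtype=int)
    mult = np.ones(len(meta), dtype=int)
    for i, (ok, p, m) in enumerate(zip(present, pos_raw, mult_raw)):
        if not ok:
            continue
        try:
            positions[i] = int(float(p))
            mult[i] = int(float(m))
            if positions[i] < 1:
                raise ValueError
        except ValueError:
            bad_pos.append(meta.index[i])
    if bad_pos:
        raise ValueError(f"unparseable site positions in rows: {bad_pos[:10]}")

    keep_idx = meta.index[present.to_numpy()]
    n_dropped = int((~present).sum())
    sub = qt.subset(keep_idx)

    keys = [
        SiteKey(pr.split(";")[0], a[0], int(po), int(mu)).render()
        for pr, a, po, mu in zip(
            prot[present], aa[present], positions[present.to_numpy()], mult[present.to_numpy()]
        )
    ]
    feature_ids = make_unique(keys, keys)
    intens = sub.intensities.copy()
    intens.index = pd.Index(feature_ids, name="feature_id")
    new_meta = sub.feature_meta.copy()
    new_meta.index = intens.index
    new_meta["name"] = feature_ids
    new_meta["site_key"] = keys
    new_meta.attrs["n_dropped_missing_site"] = n_dropped
    return QuantTable(intens, new_meta)


def run_ptm_pipeline(
    qt: QuantTable,
    design: pd.DataFrame,
    contrasts: list[str],
    flag_columns: list[str] = (),
    localization_col: str | None = None,
    localization_min: float = 0.75,
    missing_thr: int = 0,
    impute_spec: ImputeSpec | None = None,
    normalize: str = "vsn",
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> DifferentialResults:
    """Run the full site-level chain and return differential results.

    When ``localization_col`` is given and non-empty, sites below
    ``localization_min`` probability are removed first (class-I site
    convention); an empty/absent column skips the filter with a log entry.
    All later stages have identical semantics to the protein pipeline.
    """
    loc_filtered = None
    if localization_col is not None and localization_col in qt.feature_meta.columns:
        probs = pd.to_numeric(qt.feature_meta[localization_col], errors="coerce")
        if probs.notna().any():
            keep = qt.intensities.index[(probs >= localization_min).fillna(False).to_numpy()]
            loc_filtered = qt.n_features - len(keep)
            qt = qt.subset(keep)

    qt = filter_flags(qt, list(flag_columns))
    qm = bind_design(qt, design)
    if loc_filtered is None:
        qm.log("localization_filter_skipped", qt.n_features, qt.n_features)
    else:
        qm.log("localization_filter", qt.n_features + loc_filtered, qt.n_features,
               min_probability=localization_min)
    qm = filter_missing(qm, thr=missing_thr)
    if normalize == "vsn":
        qm, _ = normalize_vsn(qm)
    else:
        qm = log2_transform(qm)
    qm = impute(qm, impute_spec or ImputeSpec())
    model = DifferentialModel(qm, contrasts)
    return model.fit(alpha=alpha, lfc=lfc)
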