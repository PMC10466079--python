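"""Peptide-to-protein summarization.

Re-aggregating protein abundance from peptide-level quantities (instead of
trusting upstream software's summaries) allows imputation to happen at the
peptide level, where missingness is better behaved, and lets the user pick
a summarization robust to outlier peptides.  Three strategies:

* ``median-polish`` — Tukey's iterative row/column median sweeping of the
  log2 peptide × sample block; the protein's abundance in sample s is the
  overall median plus the sample (column) effect.  Resistant to outlier
  cells.
* ``robust``        — a two-way fit ``y_ps = mu_s + pi_p`` by iteratively
  reweighted least squares with Huber weights and sum-to-zero peptide
  effects, so ``mu_s`` is the group-average abundance.  Resistant to
  outlier peptides/cells while more efficient than the median.
* ``sum``           — plain column sums of raw (unlogged) intensities,
  log2-transformed afterwards; missing peptides contribute 0.

The first two operate on complete (imputed) log-scale data; ``sum`` is the
only method defined on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QuantMatrix
from .ingest import make_unique

__all__ = [
    "AggregationSpec",
    "median_polish",
    "robust_summary",
    "sum_aggregate",
    "aggregate_peptides",
]


@dataclass
class AggregationSpec:
    method: str = "median-polish"
    grouping_key: str = "protein_group"
    max_iter: int = 50
    tol: float = 1e-6
    huber_k: float = 1.345

    def __post_init__(self) -> None:
        if self.method not in ("median-polish", "robust", "sum"):
            raise ValueError(f"unknown aggregation method {self.method!r}")
        if self.tol <= 0 or self.max_iter < 1 or self.huber_k <= 0:
            raise ValueError("tol, max_iter and huber_k must be positive")


def median_polish(
    Y: np.ndarray, max_iter: int = 50, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray]:
    """Tukey's median polish of a complete peptide × sample matrix.

    Alternately sweeps row and column medians until the largest absolute
    change of the (overall + column) effects drops below ``tol``.  Returns
    ``(overall, col_effects, residuals)``; per-sample protein abundance is
    ``overall + col_effects``.  The median of an even count is the midpoint
    of the central order statistics.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("median_polish requires a non-empty 2-D matrix")
    if np.isnan(Y).any():
        raise ValueError("median_polish requires a complete matrix; impute first")
    Z = Y.copy()
    n_rows, _ = Z.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        prev = np.concatenate([[overall], col_eff])
        rdelta = np.median(Z, axis=1)
        Z -= rdelta[:, None]
        row_eff += rdelta
        delta = float(np.median(col_eff))
        col_eff -= delta
        overall += delta
        cdelta = np.median(Z, axis=0)
        Z -= cdelta[None, :]
        col_eff += cdelta
        delta = float(np.median(row_eff))
        row_eff -= delta
        overall += delta
        if np.max(np.abs(np.concatenate([[overall], col_eff]) - prev)) < tol:
            break
    return overall, col_eff, Z


def _huber_weights(resid: np.ndarray, scale: float, k: float) -> np.ndarray:
    if scale <= 0:
        return np.ones_like(resid)
    a = np.abs(resid) / scale
    with np.errstate(divide="ignore"):
        return np.where(a <= k, 1.0, k / a)


def robust_summary(
    Y: np.ndarray, huber_k: float = 1.345, max_iter: int = 50, tol: float = 1e-6
) -> np.ndarray:
    """Huber IRLS fit of ``y_ps = mu_s + pi_p`` with sum-to-zero peptide
    effects; returns the per-sample coefficients ``mu_s``.

    As ``huber_k`` grows the weights become all-ones and the fit reduces to
    ordinary least squares.  On IRLS non-convergence the best iterate is
    returned with a warning.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("robust_summary requires a non-empty 2-D matrix")
    if np.isnan(Y).any():
        raise ValueError("robust_summary requires a complete matrix; impute first")
    n_pep, n_samp = Y.shape
    if n_pep == 1:
        return Y[0].copy()

    # design: sample indicators + sum-coded peptide effects (last = -others)
    y = Y.ravel()  # peptide-major
    S = np.tile(np.eye(n_samp), (n_pep, 1))
    P = np.zeros((n_pep * n_samp, n_pep - 1))
    for p in range(n_pep):
        rows = slice(p * n_samp, (p + 1) * n_samp)
        if p < n_pep - 1:
            P[rows, p] = 1.0
        else:
            P[rows, :] = -1.0
    X = np.hstack([S, P])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if scale < 1e-12:  # exact fit: OLS solution is final
            return beta[:n_samp]
        w = _huber_weights(resid, scale, huber_k)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new[:n_samp]
        beta = beta_new
    warnings.warn(
        f"robust_summary IRLS did not converge in {max_iter} iterations; "
        "returning best iterate",
        stacklevel=2,
    )
    return beta[:n_samp]


def sum_aggregate(Y_raw: np.ndarray) -> np.ndarray:
    """Column sums of raw peptide intensities, then log2.

    Missing cells contribute 0; a sample where every peptide is missing has
    sum 0 and is reported as missing (NaN) rather than -inf.
    """
    Y_raw = np.asarray(Y_raw, float)
    if Y_raw.ndim != 2 or Y_raw.size == 0:
        raise ValueError("sum_aggregate requires a non-empty 2-D matrix")
    sums = np.nansum(Y_raw, axis=0)
    with np.errstate(divide="ignore"):
        out = np.log2(sums)
    out[sums <= 0] = np.nan
    return out


def aggregate_peptides(qm: QuantMatrix, spec: AggregationSpec) -> QuantMatrix:
    """Summarize a peptide-level matrix into one row per protein group.

    ``median-polish`` and ``robust`` expect complete log-scale data (impute
    first); ``sum`` expects the raw scale and yields log2 output.  The
    peptide count per protein is recorded in ``feature_meta["n_peptides"]``.
    """
    if spec.grouping_key not in qm.feature_meta.columns:
        raise KeyError(f"grouping key {spec.grouping_key!r} not in feature_meta")
    if spec.method == "sum":
        if qm.scale != "raw":
            raise ValueError("'sum' aggregation operates on raw intensities")
    else:
        if qm.scale == "raw":
            raise ValueError(f"{spec.method!r} aggregation operates on log-scale data")

    groups = qm.feature_meta[spec.grouping_key].astype(str)
    X = qm.X.to_numpy(float)
    order = list(dict.fromkeys(groups))  # first-appearance order
    rows, names, counts, skipped = [], [], [], []
    for g in order:
        idx = np.where((groups == g).to_numpy())[0]
        block = X[idx]
        if spec.method == "sum":
            if np.all(np.isnan(block)):
                skipped.append(g)
                continue
            prof = sum_aggregate(block)
        elif block.shape[0] == 1:
            prof = block[0].copy()
        elif spec.method == "median-polish":
            overall, col_eff, _ = median_polish(block, spec.max_iter, spec.tol)
            prof = overall + col_eff
        else:
            prof = robust_summary(block, spec.huber_k, spec.max_iter, spec.tol)
        rows.append(prof)
        names.append(g)
        counts.append(len(idx))
    if not rows:
        raise ValueError("no protein groups survived aggregation")

    feature_ids = make_unique(names, names)
    Xp = pd.DataFrame(np.vstack(rows), index=pd.Index(feature_ids, name="feature_id"),
                      columns=qm.X.columns)
    meta = pd.DataFrame(
        {"name": feature_ids, "raw_ids": names, "n_peptides": counts},
        index=Xp.index,
    )
    out = QuantMatrix(
        Xp, qm.design, meta,
        scale="log2" if spec.method == "sum" else qm.scale,
        history=list(qm.history),
    )
    out.log(
        "aggregate_peptides", qm.X.shape[0], Xp.shape[0],
        method=spec.method, grouping_key=spec.grouping_key,
        huber_k=spec.huber_k, empty_groups_skipped=len(skipped),
    )
    return out
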