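"""Missing-value imputation under MNAR or MAR assumptions.

Label-free proteomics mixes two missingness mechanisms: left-censoring at
the detection limit (missing-not-at-random — low-abundance features drop
out) and stochastic loss unrelated to intensity (missing-at-random).  The
methods here mirror that split:

MNAR (left-censored) methods, all using per-sample statistics because the
detection limit is run-specific:

* ``left-shifted``  — draw from a Gaussian shifted below the sample
  distribution: ``Normal(mean_s - shift*sd_s, (width*sd_s)^2)`` (Perseus
  convention; defaults shift=1.8, width=0.3 in per-sample SD units).
* ``min-det``       — deterministic: the per-sample low quantile of
  observed values (default q=0.01).
* ``min-prob``      — stochastic around that quantile with SD
  ``width*sd_s``.

MAR methods:

* ``knn``           — feature-space k-nearest-neighbour average; distance
  is Euclidean over the columns observed in both rows, normalised by the
  number of shared columns; ties broken by feature order.
* ``zero``          — replace by 0 (for data where absence means absence).

All random draws come from one seeded generator; missing cells are filled
in row-major order, so results are reproducible for a given spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QuantMatrix

__all__ = ["ImputeSpec", "impute"]

_METHODS = ("left-shifted", "min-det", "min-prob", "knn", "zero")


@dataclass
class ImputeSpec:
    method: str = "left-shifted"
    shift: float = 1.8
    width: float = 0.3
    quantile: float = 0.01
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}; choose from {_METHODS}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _sample_stats(X: np.ndarray, need_sd: bool) -> tuple[np.ndarray, np.ndarray]:
    obs_counts = (~np.isnan(X)).sum(axis=0)
    if np.any(obs_counts == 0):
        bad = int(np.argmin(obs_counts))
        raise ValueError(f"sample column {bad} has no observed values; cannot impute")
    if need_sd and np.any(obs_counts < 2):
        bad = int(np.argmin(obs_counts))
        raise ValueError(
            f"sample column {bad} has < 2 observed values; SD-based imputation impossible"
        )
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=1) if need_sd else np.zeros_like(means)
    return means, sds


def _impute_knn(X: np.ndarray, k: int, fallbacks: list[int]) -> np.ndarray:
    """Fill each incomplete row from its k nearest complete-overlap rows."""
    out = X.copy()
    n = X.shape[0]
    obs = ~np.isnan(X)
    for i in range(n):
        miss_i = ~obs[i]
        if not miss_i.any():
            continue
        # eligible neighbours: observe every column this row observes AND
        # every column we need to fill (complete overlap on observed columns)
        need = obs[i] | miss_i
        cand = np.where((obs[:, need].all(axis=1)) & (np.arange(n) != i))[0]
        if cand.size == 0:
            out[i, miss_i] = np.nanmean(X[i])
            fallbacks.append(i)
            continue
        shared = obs[i]
        diffs = X[cand][:, shared] - X[i, shared]
        d2 = np.sum(diffs * diffs, axis=1) / max(int(shared.sum()), 1)
        order = np.argsort(d2, kind="stable")  # stable sort -> feature-order ties
        chosen = cand[order[: min(k, cand.size)]]
        out[i, miss_i] = X[chosen][:, miss_i].mean(axis=0)
    return out


def impute(qm: QuantMatrix, spec: ImputeSpec) -> QuantMatrix:
    """Return a complete matrix; observed cells are copied bit-identically."""
    if qm.scale == "raw":
        raise ValueError("imputation operates on log2/glog2-scale data")
    X = qm.X.to_numpy(float).copy()
    miss = np.isnan(X)
    n_missing = int(miss.sum())
    fallback_rows: list[int] = []

    if n_missing:
        rng = np.random.default_rng(spec.seed)
        if spec.method == "zero":
            X[miss] = 0.0
        elif spec.method == "min-det":
            _sample_stats(qm.X.to_numpy(float), need_sd=False)
            q = np.nanquantile(qm.X.to_numpy(float), spec.quantile, axis=0)
            X[miss] = np.broadcast_to(q, X.shape)[miss]
        elif spec.method in ("left-shifted", "min-prob"):
            means, sds = _sample_stats(qm.X.to_numpy(float), need_sd=True)
            if spec.method == "left-shifted":
                centers = means - spec.shift * sds
            else:
                centers = np.nanquantile(qm.X.to_numpy(float), spec.quantile, axis=0)
            widths = spec.width * sds
            # one draw per missing cell, row-major, so streams are reproducible
            z = rng.standard_normal(n_missing)
            rows, cols = np.nonzero(miss)
            X[rows, cols] = centers[cols] + widths[cols] * z
        elif spec.method == "knn":
            X = _impute_knn(X, spec.k, fallback_rows)

    out = QuantMatrix(
        pd.DataFrame(X, index=qm.X.index, columns=qm.X.columns),
        qm.design,
        qm.feature_meta,
        qm.scale,
        list(qm.history),
    )
    out.log(
        "impute", qm.X.shape[0], qm.X.shape[0],
        method=spec.method, shift=spec.shift, width=spec.width,
        quantile=spec.quantile, k=spec.k, seed=spec.seed,
        n_imputed=n_missing,
        knn_row_mean_fallbacks=len(fallback_rows),
    )
    return out
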