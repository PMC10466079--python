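"""Fuzzy c-means clustering of expression patterns.

For time-course or multi-group designs, regulated features are grouped by
the shape of their per-condition mean profile.  Profiles are row z-scored
first (so Euclidean distance is equivalent to correlation distance up to
scale), then clustered with Bezdek's fuzzy c-means: memberships

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)),

centers c_k = sum_i u_ik^m x_i / sum_i u_ik^m, alternated until the largest
center displacement falls below a tolerance.  The fuzzifier m (> 1)
controls membership softness; m → 1 approaches hard k-means, and m = 2 is
the conventional default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusterResult", "standardize_profiles", "fuzzy_cmeans"]


@dataclass
class ClusterResult:
    membership: pd.DataFrame     # features x k, rows sum to 1
    centers: np.ndarray          # k x conditions
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    def hard_labels(self) -> pd.Series:
        """Cluster of maximal membership per feature."""
        return self.membership.idxmax(axis=1)

    def max_membership(self) -> pd.Series:
        return self.membership.max(axis=1)


def standardize_profiles(X: pd.DataFrame) -> pd.DataFrame:
    """Row z-score a features × conditions matrix of condition means.

    Constant rows carry no pattern information and are dropped (their ids
    are recorded in ``result.attrs["dropped_constant"]``).
    """
    if X.shape[1] < 2:
        raise ValueError("pattern standardization needs >= 2 conditions")
    vals = X.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    Z = (vals[keep] - mean[keep]) / sd[keep]
    out = pd.DataFrame(Z, index=X.index[keep], columns=X.columns)
    out.attrs["dropped_constant"] = list(X.index[~keep])
    return out


def fuzzy_cmeans(
    X: pd.DataFrame | np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means on a standardized profile matrix.

    Centers are initialised from k distinct data rows drawn with the seeded
    generator; updates alternate memberships and centers until the maximal
    center displacement is below ``tol``.  A feature at zero distance from
    a center receives membership 1 on that center.  The objective
    J_m = sum_ik u_ik^m d_ik^2 is recorded each iteration and is
    non-increasing.
    """
    if isinstance(X, pd.DataFrame):
        idx = X.index
        V = X.to_numpy(float)
    else:
        V = np.asarray(X, float)
        idx = pd.RangeIndex(V.shape[0])
    n = V.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of features ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    centers = V[rng.choice(n, size=k, replace=False)].copy()
    expo = 2.0 / (m - 1.0)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # squared distances features x k
        d2 = ((V[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)  # (1/d)^{2/(m-1)}
            U = inv / inv.sum(axis=1, keepdims=True)
        any_zero = zero.any(axis=1)
        if any_zero.any():  # exact coincidence: all mass on (first) zero-distance center
            U[any_zero] = 0.0
            first_zero = np.argmax(zero[any_zero], axis=1)
            U[np.where(any_zero)[0], first_zero] = 1.0
        trace.append(float(np.sum((U ** m) * d2)))

        Um = U ** m
        new_centers = (Um.T @ V) / Um.sum(axis=0)[:, None]
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break

    d2 = ((V[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-expo / 2.0)
        U = inv / inv.sum(axis=1, keepdims=True)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        U[any_zero] = 0.0
        first_zero = np.argmax(zero[any_zero], axis=1)
        U[np.where(any_zero)[0], first_zero] = 1.0

    membership = pd.DataFrame(
        U, index=idx, columns=[f"cluster_{j+1}" for j in range(k)]
    )
    return ClusterResult(membership, centers, m, trace, n_iter)
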