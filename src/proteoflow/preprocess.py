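"""Feature filtering, log transformation and normalization.

The normalization of record is variance-stabilizing normalization (VSN): a
per-sample affine calibration followed by a generalised log transform,

    h_i(x) = glog2((x - a_i) / b_i),   glog2(y) = log2(y + sqrt(y^2 + 1)),

fitted by maximum likelihood under the model that transformed intensities
are, per feature, Gaussian around a feature mean with one common variance.
For large intensities glog2 behaves like log2, so differences of transformed
values are log2 ratios; near the detection limit the arsinh shape damps the
variance inflation that a plain log would produce.  The fit is robustified
by least-trimmed-squares: rows with the largest residuals are excluded from
the likelihood (10% by default) and the fit is iterated until the trimmed
set stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import QuantMatrix, QuantTable

__all__ = [
    "filter_flags",
    "filter_missing",
    "log2_transform",
    "normalize_vsn",
    "normalize_median",
    "VsnParams",
    "glog2",
]

_LN2 = np.log(2.0)


@dataclass
class VsnParams:
    """Per-sample affine calibration: offsets ``a`` and positive scales ``b``."""

    a: np.ndarray
    b: np.ndarray
    n_iterations: int = 0
    trimmed_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if np.any(self.b <= 0):
            raise ValueError("scales b must be strictly positive")


def glog2(y: np.ndarray) -> np.ndarray:
    """Generalised log2: ``log2(y + sqrt(y^2 + 1))`` = arsinh(y)/ln 2."""
    return np.arcsinh(y) / _LN2


def filter_flags(qt: QuantTable, flag_columns: list[str]) -> QuantTable:
    """Drop rows flagged ``"+"`` in any listed QC column (reverse hits,
    potential contaminants).  An empty column list is the identity."""
    for col in flag_columns:
        if col not in qt.feature_meta.columns:
            raise KeyError(f"unknown flag column {col!r}")
    if not flag_columns:
        return qt
    flagged = np.zeros(qt.n_features, dtype=bool)
    for col in flag_columns:
        flagged |= (qt.feature_meta[col].astype(str).str.strip() == "+").to_numpy()
    return qt.subset(qt.intensities.index[~flagged])


def filter_missing(
    qm: QuantMatrix,
    thr: int = 0,
    mode: str = "per-condition",
    fraction: float = 0.0,
) -> QuantMatrix:
    """Filter features on missing-value occupancy.

    ``per-condition`` keeps a feature iff at least one condition has at most
    ``thr`` missing replicates (the default ``thr=0`` requires full
    observation in some condition).  ``overall-fraction`` keeps features
    whose overall observed fraction is at least ``fraction``.
    """
    missing = qm.X.isna()
    if mode == "per-condition":
        max_reps = int(qm.design.groupby("condition")["sample"].count().max())
        if thr > max_reps:
            import warnings

            warnings.warn(
                f"thr={thr} exceeds the largest replicate count ({max_reps}); "
                "the filter keeps everything",
                stacklevel=2,
            )
        keep = np.zeros(qm.X.shape[0], dtype=bool)
        for cond in qm.conditions:
            n_miss = missing[qm.samples_of(cond)].sum(axis=1).to_numpy()
            keep |= n_miss <= thr
    elif mode == "overall-fraction":
        observed_frac = 1.0 - missing.sum(axis=1).to_numpy() / qm.X.shape[1]
        keep = observed_frac >= fraction
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = QuantMatrix(
        qm.X.loc[keep].copy(),
        qm.design,
        qm.feature_meta.loc[keep].copy(),
        qm.scale,
        list(qm.history),
    )
    out.log(
        "filter_missing", qm.X.shape[0], int(keep.sum()),
        thr=thr, mode=mode, fraction=fraction,
    )
    return out


def log2_transform(qm: QuantMatrix) -> QuantMatrix:
    """Elementwise log2 of raw intensities; missing cells stay missing."""
    if qm.scale != "raw":
        raise ValueError(f"matrix is on scale {qm.scale!r}, expected 'raw'")
    vals = qm.X.to_numpy(float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError(
            "non-positive observed intensity: log2 requires raw intensities > 0 "
            "(zeros should have been mapped to missing at ingest)"
        )
    out = QuantMatrix(
        pd.DataFrame(np.log2(vals), index=qm.X.index, columns=qm.X.columns),
        qm.design,
        qm.feature_meta,
        scale="log2",
        history=list(qm.history),
    )
    out.log("log2_transform", qm.X.shape[0], qm.X.shape[0])
    return out


def _vsn_nll_grad(params: np.ndarray, X: np.ndarray, obs: np.ndarray):
    """Profiled negative log-likelihood of the glog model and its gradient.

    Feature means and the common variance are profiled out; the Jacobian of
    the transform enters as -sum(log h'(x)).  Constant terms are dropped.
    """
    n_samples = X.shape[1]
    a = params[:n_samples]
    logb = params[n_samples:]
    b = np.exp(logb)

    y = (X - a) / b
    h = np.arcsinh(y) / _LN2
    h[~obs] = np.nan
    row_n = obs.sum(axis=1)
    mu = np.nansum(h, axis=1) / row_n
    r = np.where(obs, h - mu[:, None], 0.0)
    rss = float(np.sum(r * r))
    n_obs = float(obs.sum())
    rss = max(rss, 1e-300)

    one_plus_y2 = 1.0 + y * y
    jac = float(np.sum(np.where(obs, logb + 0.5 * np.log(one_plus_y2), 0.0)))
    nll = 0.5 * n_obs * np.log(rss / n_obs) + jac

    # dh/da = -1/(ln2 * b * sqrt(1+y^2)); dh/dlogb = -y/(ln2 * sqrt(1+y^2))
    inv_s = np.where(obs, 1.0 / np.sqrt(one_plus_y2), 0.0)
    dh_da = -inv_s / (_LN2 * b)
    dh_db = -np.where(obs, y, 0.0) * inv_s / _LN2
    coef = n_obs / rss  # d/dtheta of 0.5*n*log(rss/n) = (n/(2*rss)) * dRSS
    g_a = coef * np.sum(r * dh_da, axis=0)
    g_b = coef * np.sum(r * dh_db, axis=0)
    yy = np.where(obs, y, 0.0)
    g_a += np.sum(-yy * inv_s * inv_s / b, axis=0) * 1.0  # Jacobian part, d/da
    g_b += np.sum(np.where(obs, inv_s * inv_s, 0.0), axis=0)  # d/dlogb
    return nll, np.concatenate([g_a, g_b])


def _fit_vsn_ml(X: np.ndarray, obs: np.ndarray, x0: np.ndarray, max_iter: int):
    res = minimize(
        _vsn_nll_grad,
        x0,
        args=(X, obs),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not (res.success or res.status == 1):  # status 1 = maxiter, handled by caller
        # a perfect fit (e.g. duplicated samples) makes the profiled
        # likelihood unbounded; the iterate is then already exact
        a, b = res.x[:X.shape[1]], np.exp(res.x[X.shape[1]:])
        h = np.arcsinh((X - a) / b) / _LN2
        h[~obs] = np.nan
        resid = h - np.nanmean(h, axis=1, keepdims=True)
        if np.nanmean(resid**2) < 1e-10:
            return res
        raise RuntimeError(
            f"VSN likelihood optimization failed after {res.nit} iterations: {res.message}"
        )
    return res


def normalize_vsn(
    qm: QuantMatrix,
    lts_keep: float = 0.9,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[QuantMatrix, VsnParams]:
    """Variance-stabilizing normalization of a raw-scale matrix.

    Fits per-sample offsets/scales by maximum likelihood with
    least-trimmed-squares robustness (``lts_keep`` = fraction of rows kept,
    default 0.9), then returns ``glog2((x - a_i)/b_i)`` applied to every
    cell.  Missing entries are untouched.  Requires at least 2 samples and
    30 features with >= 2 observations for a stable fit.
    """
    if qm.scale != "raw":
        raise ValueError(f"VSN expects raw intensities, got scale {qm.scale!r}")
    if not 0 < lts_keep <= 1:
        raise ValueError("lts_keep must be in (0, 1]")
    X = qm.X.to_numpy(float)
    obs = ~np.isnan(X)
    if X.shape[1] < 2:
        raise ValueError("VSN needs at least 2 samples")
    eligible = obs.sum(axis=1) >= 2
    if eligible.sum() < 30:
        raise ValueError(
            f"VSN needs >= 30 features with >= 2 observations; have {int(eligible.sum())}"
        )

    # work on a globally rescaled copy so the optimizer sees O(1) numbers
    scale0 = float(np.nanmedian(X))
    if not np.isfinite(scale0) or scale0 <= 0:
        scale0 = 1.0
    Xs = X / scale0
    Xw, obsw = Xs[eligible], obs[eligible]

    q05 = np.nanquantile(Xs, 0.05, axis=0)
    q50 = np.nanquantile(Xs, 0.50, axis=0)
    a0 = q05
    b0 = np.maximum(q50 - q05, 1e-3)
    x0 = np.concatenate([a0, np.log(b0)])

    keep = np.ones(Xw.shape[0], dtype=bool)
    n_keep = max(int(np.floor(lts_keep * Xw.shape[0])), 30)
    params = x0
    total_nit = 0
    for _outer in range(12):
        res = _fit_vsn_ml(Xw[keep], obsw[keep], params, max_iter=max_iter)
        new_params = res.x
        total_nit += int(res.nit)
        # rank all eligible rows by mean squared residual under current fit
        n_samples = X.shape[1]
        a, b = new_params[:n_samples], np.exp(new_params[n_samples:])
        h = np.arcsinh((Xw - a) / b) / _LN2
        h[~obsw] = np.nan
        mu = np.nanmean(h, axis=1)
        msr = np.nanmean((h - mu[:, None]) ** 2, axis=1)
        order = np.argsort(msr, kind="stable")
        new_keep = np.zeros_like(keep)
        new_keep[order[:n_keep]] = True
        converged = np.array_equal(new_keep, keep) and (
            np.max(np.abs(new_params - params)) < tol or _outer > 0
        )
        params, keep = new_params, new_keep
        if converged:
            break
    else:
        raise RuntimeError(
            f"VSN LTS loop did not stabilise (total inner iterations: {total_nit})"
        )

    n_samples = X.shape[1]
    a = params[:n_samples] * scale0
    b = np.exp(params[n_samples:]) * scale0
    H = glog2((X - a) / b)
    H[~obs] = np.nan
    out = QuantMatrix(
        pd.DataFrame(H, index=qm.X.index, columns=qm.X.columns),
        qm.design,
        qm.feature_meta,
        scale="glog2",
        history=list(qm.history),
    )
    out.log(
        "normalize_vsn", qm.X.shape[0], qm.X.shape[0],
        lts_keep=lts_keep, iterations=total_nit,
    )
    return out, VsnParams(a, b, n_iterations=total_nit, trimmed_fraction=1.0 - lts_keep)


def normalize_median(qm: QuantMatrix) -> QuantMatrix:
    """Per-sample median centering on the log2 scale (simple alternative to
    VSN): each column is shifted so all sample medians agree with the grand
    median."""
    if qm.scale not in ("log2", "glog2"):
        raise ValueError("median normalization operates on log-scale data")
    med = qm.X.median(axis=0, skipna=True)
    shifted = qm.X.sub(med - med.mean(), axis=1)
    out = QuantMatrix(shifted, qm.design, qm.feature_meta, qm.scale, list(qm.history))
    out.log("normalize_median", qm.X.shape[0], qm.X.shape[0])
    return out
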