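"""Empirical-Bayes moderated t-tests for differential abundance.

Per feature g a cell-means linear model is fitted over conditions; a
contrast A - B has estimate beta_g (the log2 fold change), residual
variance s2_g on d_g degrees of freedom and unscaled standard-error factor
u_g = sqrt(1/n_A + 1/n_B).  The per-feature variances are then shrunk
toward a common prior by the hierarchical model

    s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g,
    1/sigma2_g      ~ (1/(d0 * s02)) * chi2(d0),

whose hyperparameters (prior df ``d0``, prior variance ``s02``) are
estimated by the method of moments on log s2 (solving a trigamma equation).
The posterior variance

    s2_tilde_g = (d0 * s02 + d_g * s2_g) / (d0 + d_g)

gives the moderated statistic t_g = beta_g / (u_g * s_tilde_g), referred to
a t distribution on d0 + d_g degrees of freedom (a normal reference when
d0 is infinite).  Borrowing strength across features in this way is what
makes small-replicate proteomics designs testable at all.

The module is organised as a Model/Results pair:
:class:`DifferentialModel` holds the data and design;
:meth:`DifferentialModel.fit` returns a :class:`DifferentialResults` with
per-contrast tables, BH-adjusted p-values, significance calls and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import QuantMatrix

__all__ = [
    "DifferentialModel",
    "DifferentialResults",
    "FitResult",
    "ShrinkageParams",
    "fit_linear_models",
    "squeeze_var",
    "trigamma_inverse",
    "moderated_test",
    "adjust_bh",
    "add_rejections",
    "parse_contrast",
]

_VAR_FLOOR = 1e-12


def parse_contrast(contrast: str | tuple[str, str]) -> tuple[str, str]:
    """Accept ``("A", "B")`` or the string form ``"A_vs_B"``."""
    if isinstance(contrast, tuple):
        return contrast
    if "_vs_" not in contrast:
        raise ValueError(f"contrast {contrast!r} is not of the form 'condA_vs_condB'")
    a, b = contrast.split("_vs_", 1)
    return a, b


@dataclass
class FitResult:
    """Per-feature OLS summaries feeding the moderated test."""

    beta: pd.DataFrame          # features x contrasts, log2 fold changes
    s2: pd.Series               # residual variance s2_g
    df_resid: pd.Series         # residual degrees of freedom d_g
    u: pd.DataFrame             # features x contrasts, sqrt(1/n_A + 1/n_B)
    contrast_names: list[str] = field(default_factory=list)


@dataclass
class ShrinkageParams:
    """Hyperparameters of the inverse-chi-squared variance prior."""

    d0: float        # prior degrees of freedom; may be +inf
    s0_2: float      # prior variance

    def __post_init__(self) -> None:
        if self.s0_2 <= 0:
            raise ValueError("prior variance s0_2 must be positive")
        if self.d0 < 0:
            raise ValueError("prior df d0 must be non-negative")


def fit_linear_models(
    qm: QuantMatrix, contrasts: list[str | tuple[str, str]]
) -> FitResult:
    """Cell-means OLS per feature plus contrast standard-error factors.

    Group means are computed over observed replicates; ``d_g`` is the
    observation count minus the number of conditions with data.  A contrast
    whose conditions lack data for a feature gets an infinite ``u`` there
    and is reported with missing statistics downstream.
    """
    pairs = [parse_contrast(c) for c in contrasts]
    conds = qm.conditions
    for a, b in pairs:
        for c in (a, b):
            if c not in conds:
                raise ValueError(f"contrast names unknown condition {c!r}; have {conds}")
    names = [f"{a}_vs_{b}" for a, b in pairs]

    X = qm.X.to_numpy(float)
    obs = ~np.isnan(X)
    n_feat = X.shape[0]
    means = np.full((n_feat, len(conds)), np.nan)
    counts = np.zeros((n_feat, len(conds)), dtype=int)
    rss = np.zeros(n_feat)
    for j, cond in enumerate(conds):
        cols = [qm.X.columns.get_loc(s) for s in qm.samples_of(cond)]
        block = X[:, cols]
        bobs = obs[:, cols]
        counts[:, j] = bobs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means[:, j] = np.where(
                counts[:, j] > 0, np.nansum(block, axis=1) / counts[:, j], np.nan
            )
        resid = np.where(bobs, block - means[:, j][:, None], 0.0)
        rss += np.nansum(resid * resid, axis=1)

    n_obs = counts.sum(axis=1)
    n_conds_with_data = (counts > 0).sum(axis=1)
    df = (n_obs - n_conds_with_data).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1e-300), np.nan)
    s2 = np.where(df > 0, s2, np.nan)

    beta = np.empty((n_feat, len(pairs)))
    u = np.empty((n_feat, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        ja, jb = conds.index(a), conds.index(b)
        beta[:, k] = means[:, ja] - means[:, jb]
        with np.errstate(divide="ignore"):
            u[:, k] = np.sqrt(
                np.where(counts[:, ja] > 0, 1.0 / counts[:, ja], np.inf)
                + np.where(counts[:, jb] > 0, 1.0 / counts[:, jb], np.inf)
            )

    idx = qm.X.index
    return FitResult(
        beta=pd.DataFrame(beta, index=idx, columns=names),
        s2=pd.Series(s2, index=idx, name="s2"),
        df_resid=pd.Series(df, index=idx, name="df_resid"),
        u=pd.DataFrame(u, index=idx, columns=names),
        contrast_names=names,
    )


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve ``trigamma(y) = x`` for y > 0 by monotone Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma is positive; x must be > 0")
    if x > 1e7:          # trigamma(y) ~ 1/y^2 for small y
        return 1.0 / np.sqrt(x)
    if x < 1e-6:         # trigamma(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            return y
    return y


def squeeze_var(s2: np.ndarray | pd.Series, df: np.ndarray | pd.Series) -> ShrinkageParams:
    """Estimate the variance prior (d0, s02) by moments on log s2.

    With ``e_g = log s2_g - psi(d_g/2) + log(d_g/2)`` (psi = digamma),
    ``E[e] = log s02`` and ``Var[e] = psi'(d0/2) + mean psi'(d_g/2)``; d0
    solves the trigamma equation.  When the observed spread of e is no
    larger than its sampling component, d0 = +inf (complete shrinkage).
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s2) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive residual df")
    s2, df = s2[ok], df[ok]
    s2 = np.maximum(s2, _VAR_FLOOR)  # psi undefined at 0; floored features flagged upstream

    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    sampling = float(np.mean(special.polygamma(1, df / 2.0)))
    excess = e_var - sampling
    if excess <= 0:
        # no excess spread beyond sampling noise: complete shrinkage to the
        # plain mean of the variances
        return ShrinkageParams(d0=np.inf, s0_2=float(np.mean(s2)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ShrinkageParams(d0=d0, s0_2=s0_2)


def moderated_test(fit: FitResult, prior: ShrinkageParams) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values, pre-adjustment.

    Returns one long DataFrame over (feature, contrast) with columns
    feature_id, contrast_name, log2fc, t_mod, df_total, p.  ``d0 = 0``
    reproduces the ordinary t-test; ``d0 = +inf`` uses a normal reference
    with the prior variance.
    """
    d0, s02 = prior.d0, prior.s0_2
    s2 = fit.s2.to_numpy(float)
    dg = fit.df_resid.to_numpy(float)
    s2_eff = np.where(np.isfinite(s2), s2, 0.0)

    if np.isinf(d0):
        post_var = np.full_like(s2_eff, s02)
        df_total = np.full_like(s2_eff, np.inf)
    else:
        denom = d0 + dg
        post_var = np.where(
            denom > 0, (d0 * s02 + dg * s2_eff) / np.maximum(denom, 1e-300), np.nan
        )
        df_total = d0 + dg

    frames = []
    for name in fit.contrast_names:
        beta = fit.beta[name].to_numpy(float)
        u = fit.u[name].to_numpy(float)
        se = u * np.sqrt(post_var)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        estimable = np.isfinite(u) & np.isfinite(beta) & (se > 0) & (df_total > 0)
        t = np.where(estimable, t, np.nan)
        p = np.full_like(t, np.nan)
        if np.isinf(d0):
            p[estimable] = 2.0 * stats.norm.sf(np.abs(t[estimable]))
        else:
            p[estimable] = 2.0 * stats.t.sf(np.abs(t[estimable]), df_total[estimable])
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": fit.beta.index,
                    "contrast_name": name,
                    "log2fc": beta,
                    "t_mod": t,
                    "df_total": df_total,
                    "p": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order restored.

    NaN entries propagate and are excluded from the test count n.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if np.any((q < 0) | (q > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


def add_rejections(results: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """Gate significance: ``padj <= alpha`` and ``|log2fc| >= lfc``."""
    if lfc < 0:
        raise ValueError("lfc threshold must be non-negative")
    out = results.copy()
    out["significant"] = (
        (out["padj"] <= alpha) & (out["log2fc"].abs() >= lfc)
    ).fillna(False)
    return out


class DifferentialModel:
    """Moderated-t differential abundance model on a complete log-scale matrix.

    Parameters
    ----------
    qm
        :class:`QuantMatrix` on log2/glog2 scale (normally filtered,
        normalized and imputed).
    contrasts
        Condition pairs to test, as ``("A", "B")`` tuples or ``"A_vs_B"``
        strings; each estimates mean(A) - mean(B) on the log2 scale.
    """

    def __init__(self, qm: QuantMatrix, contrasts: list[str | tuple[str, str]]):
        if qm.scale == "raw":
            raise ValueError("differential testing operates on log-scale data")
        if not contrasts:
            raise ValueError("at least one contrast is required")
        self.qm = qm
        self.contrasts = list(contrasts)

    @classmethod
    def from_dataframe(
        cls,
        X: pd.DataFrame,
        design: pd.DataFrame,
        contrasts: list[str | tuple[str, str]],
        scale: str = "log2",
    ) -> "DifferentialModel":
        """Build directly from a log-scale features x samples DataFrame."""
        meta = pd.DataFrame({"name": X.index, "raw_ids": X.index}, index=X.index)
        qm = QuantMatrix(X.copy(), design.reset_index(drop=True), meta, scale=scale)
        return cls(qm, contrasts)

    def fit(
        self,
        shrink: bool = True,
        alpha: float = 0.05,
        lfc: float = 1.0,
        adjust: str = "per-contrast",
    ) -> "DifferentialResults":
        """Fit, shrink variances, test contrasts, adjust and gate.

        ``shrink=False`` skips empirical Bayes (d0 = 0: ordinary t-test).
        ``adjust`` chooses BH per contrast (default) or ``"pooled"`` across
        all contrasts.
        """
        fitres = fit_linear_models(self.qm, self.contrasts)
        if shrink:
            prior = squeeze_var(fitres.s2, fitres.df_resid)
        else:
            prior = ShrinkageParams(d0=0.0, s0_2=1.0)
        table = moderated_test(fitres, prior)
        if adjust == "per-contrast":
            table["padj"] = np.nan
            for name in fitres.contrast_names:
                mask = table["contrast_name"] == name
                table.loc[mask, "padj"] = adjust_bh(table.loc[mask, "p"])
        elif adjust == "pooled":
            table["padj"] = adjust_bh(table["p"])
        else:
            raise ValueError(f"unknown adjust mode {adjust!r}")
        table = add_rejections(table, alpha=alpha, lfc=lfc)
        return DifferentialResults(self, fitres, prior, table, alpha=alpha, lfc=lfc)


class DifferentialResults:
    """Results of :meth:`DifferentialModel.fit`.

    Attributes
    ----------
    fit_result : FitResult
    prior : ShrinkageParams
    table : long DataFrame over (feature, contrast) with log2fc, t_mod,
        df_total, p, padj, significant.
    """

    def __init__(self, model, fit_result, prior, table, alpha, lfc):
        self.model = model
        self.fit_result = fit_result
        self.prior = prior
        self.table = table
        self.alpha = alpha
        self.lfc = lfc

    @property
    def contrast_names(self) -> list[str]:
        return self.fit_result.contrast_names

    def contrast_table(self, contrast: str) -> pd.DataFrame:
        if contrast not in self.contrast_names:
            raise KeyError(f"unknown contrast {contrast!r}; have {self.contrast_names}")
        sub = self.table[self.table["contrast_name"] == contrast]
        return sub.reset_index(drop=True)

    def significant_features(self, contrast: str | None = None) -> list[str]:
        tab = self.table if contrast is None else self.contrast_table(contrast)
        return list(dict.fromkeys(tab.loc[tab["significant"], "feature_id"]))

    def ranked_genes(self, contrast: str, by: str = "t_mod") -> pd.Series:
        """Sign-preserving ranking metric for downstream enrichment,
        sorted descending (default: moderated t)."""
        tab = self.contrast_table(contrast).dropna(subset=[by])
        return tab.set_index("feature_id")[by].sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            "Moderated t-test results",
            "=" * 48,
            f"features: {self.fit_result.s2.size}",
            f"prior df d0: {self.prior.d0:.4g}   prior variance s0^2: {self.prior.s0_2:.4g}",
            f"thresholds: padj <= {self.alpha}, |log2FC| >= {self.lfc}",
            "-" * 48,
        ]
        for name in self.contrast_names:
            tab = self.contrast_table(name)
            n_sig = int(tab["significant"].sum())
            med_fc = tab["log2fc"].median()
            lines.append(
                f"{name}: {n_sig} significant / {len(tab)} tested  "
                f"(median log2FC {med_fc:+.3f})"
            )
        return "\n".join(lines)
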