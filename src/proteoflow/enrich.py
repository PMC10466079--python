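"""Function mining: over-representation analysis and preranked GSEA.

Annotation databases (GO, Reactome, MSigDB exports) are consumed as local
GMT files; no network access.  ORA tests query/set overlap with the
hypergeometric upper tail against an explicit universe (by default the
features actually tested, which is the correct background).  GSEA here is
the preranked variant: a weighted Kolmogorov–Smirnov-like running sum over
a ranked gene list, with a gene-label permutation null — the appropriate
null when only a ranked list (not sample-level data) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import adjust_bh

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora_hypergeometric",
    "gsea",
    "enrichment_score",
]


@dataclass
class GeneSetCollection:
    """Named gene sets: set name → (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are counted once (first occurrence kept).
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in (s.strip() for s in members) if m]
            members = list(dict.fromkeys(members))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in gsc.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora_hypergeometric(
    query: Sequence[str],
    universe: Sequence[str],
    gsc: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the query.

    For a universe of N genes of which K belong to the set and a query of n
    genes with k in the set, p = P(X >= k), X ~ Hypergeometric(N, K, n).
    Query genes outside the universe are dropped with a warning; each set is
    intersected with the universe and excluded if its intersected size
    falls outside [min_size, max_size].  BH adjustment across tested sets.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    q = [g for g in q if g in uni_set]
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    q_set = set(q)
    N, n = len(uni), len(q)

    rows = []
    for name in gsc.names():
        members = [g for g in gsc.members(name) if g in uni_set]
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = sum(1 for g in members if g in q_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    out["padj"] = adjust_bh(out["p"]) if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def enrichment_score(
    ranked_genes: Sequence[str],
    scores: np.ndarray,
    member_set: set[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed maximal deviation of the weighted running sum.

    Hits increment by |score|^exponent normalised to sum 1; misses decrement
    by 1/(N - K).  The ES is the running-sum value of largest magnitude.
    """
    N = len(ranked_genes)
    hit = np.fromiter((g in member_set for g in ranked_genes), bool, N)
    K = int(hit.sum())
    if K == 0 or K == N:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.abs(np.asarray(scores, float)) ** weight_exponent
    hw = np.where(hit, w, 0.0)
    total = hw.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted
        hw = hit.astype(float)
        total = float(K)
    steps = hw / total - np.where(hit, 0.0, 1.0 / (N - K))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(
    ranked: pd.Series | Sequence[tuple[str, float]],
    gsc: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a descending (gene, score) ranking.

    The null permutes gene labels: for each set of size K, permutation ES
    values are computed on K genes drawn uniformly from the ranked list.
    NES normalises ES by the mean |ES| of same-sign permutations; perm_p is
    the fraction of same-sign permutation ES at least as extreme.  Sets
    with no ranked member are skipped.  BH adjustment over perm_p.
    """
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index.astype(str))
        scores = ranked.to_numpy(float)
    else:
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked gene list contains duplicates")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-scores, kind="stable")
    genes = [genes[i] for i in order]
    scores = scores[order]
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    w = np.abs(scores) ** weight_exponent
    rows = []
    for name in gsc.names():
        members = [g for g in gsc.members(name) if g in gene_pos]
        K = len(members)
        if K == 0:
            continue
        if not min_size <= K <= max_size:
            continue
        es = enrichment_score(genes, scores, set(members), weight_exponent)

        # permutation null: same-size random gene subsets
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(N, size=K, replace=False)
            hit = np.zeros(N, bool)
            hit[idx] = True
            hw = np.where(hit, w, 0.0)
            total = hw.sum()
            if total == 0:
                hw = hit.astype(float)
                total = float(K)
            steps = hw / total - np.where(hit, 0.0, 1.0 / (N - K))
            running = np.cumsum(steps)
            perm_es[b] = running[int(np.argmax(np.abs(running)))]

        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            nes = np.nan
            perm_p = 1.0 / (n_perm + 1)
        else:
            nes = es / float(np.mean(np.abs(same_sign)))
            perm_p = float(
                (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
            )
        rows.append(
            {
                "set_name": name,
                "set_size": K,
                "es": es,
                "nes": nes,
                "perm_p": perm_p,
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "es", "nes", "perm_p"])
    out["padj"] = adjust_bh(out["perm_p"]) if len(out) else []
    return out.sort_values("perm_p", kind="stable").reset_index(drop=True)
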