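"""GMT parsing, hypergeometric ORA and preranked GSEA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from proteoflow.enrich import (
    GeneSetCollection,
    enrichment_score,
    gsea,
    ora_hypergeometric,
    read_gmt,
    write_gmt,
)


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper tail by enumeration: sum_i C(K,i) C(N-K,n-i) / C(N,n)."""
    return sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / comb(N, n)


class TestReadGmt:
    def test_two_line_fixture(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc one\tG1\tG2\tG3\nSET2\t\tG2\tG4\n")
        gsc = read_gmt(path)
        assert gsc.names() == ["SET1", "SET2"]
        assert gsc.members("SET2") == ["G2", "G4"]

    def test_repeated_member_counted_once(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S\td\tG1\tG1\tG2\n")
        assert read_gmt(path).members("S") == ["G1", "G2"]

    def test_short_line_errors_with_line_number(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S\tdesc_only\n")
        with pytest.raises(ValueError, match=":1"):
            read_gmt(path)

    def test_roundtrip_random_collection(self, tmp_path, rng):
        genes = [f"G{i}" for i in range(200)]
        sets = {}
        for s in range(100):
            size = int(rng.integers(1, 20))
            members = list(rng.choice(genes, size=size, replace=False))
            sets[f"SET{s}"] = (f"description {s}", members)
        gsc = GeneSetCollection(sets)
        path = tmp_path / "round.gmt"
        write_gmt(gsc, path)
        assert read_gmt(path).sets == gsc.sets


class TestOra:
    def _gsc(self, members):
        return GeneSetCollection({"S": ("d", members)})

    def test_exact_tail_example(self):
        # N=20, K=5, n=5, k=3: p = 1126/15504
        universe = [f"G{i}" for i in range(20)]
        members = universe[:5]
        query = universe[:3] + universe[10:12]  # overlap 3
        out = ora_hypergeometric(query, universe, self._gsc(members), min_size=1)
        assert out["overlap"].iloc[0] == 3
        assert out["p"].iloc[0] == pytest.approx(1126 / 15504, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        out = ora_hypergeometric(universe[10:15], universe, self._gsc(universe[:5]), min_size=1)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_universe_certain_overlap(self):
        universe = [f"G{i}" for i in range(15)]
        out = ora_hypergeometric(universe, universe, self._gsc(universe[:6]), min_size=1)
        assert out["overlap"].iloc[0] == 6
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_enumeration_for_small_universes(self, rng):
        for _ in range(150):
            N = int(rng.integers(5, 61))
            universe = [f"G{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            members = list(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            out = ora_hypergeometric(query, universe, self._gsc(members),
                                     min_size=0, max_size=10**6)
            k = out["overlap"].iloc[0]
            assert out["p"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), abs=1e-10
            )

    def test_empty_query_after_intersection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ora_hypergeometric(["X"], ["G1", "G2"], self._gsc(["G1"]))

    def test_min_max_size_exclusion(self):
        universe = [f"G{i}" for i in range(30)]
        gsc = GeneSetCollection({"small": ("d", universe[:2]), "big": ("d", universe[:20])})
        out = ora_hypergeometric(universe[:5], universe, gsc, min_size=5, max_size=10)
        assert list(out["set_name"]) == []


def brute_force_es(genes, scores, members, exponent):
    """Literal running-sum evaluation, one step at a time."""
    N = len(genes)
    hits = [g in members for g in genes]
    K = sum(hits)
    denom = sum(abs(scores[i]) ** exponent for i in range(N) if hits[i])
    run, best = 0.0, 0.0
    for i in range(N):
        if hits[i]:
            run += abs(scores[i]) ** exponent / denom
        else:
            run -= 1.0 / (N - K)
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def test_top_k_set_has_es_one_at_exponent_zero(self):
        genes = [f"G{i}" for i in range(20)]
        scores = np.linspace(3, -3, 20)
        es = enrichment_score(genes, scores, set(genes[:5]), weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_bottom_k_set_has_es_minus_one_at_exponent_zero(self):
        genes = [f"G{i}" for i in range(20)]
        scores = np.linspace(3, -3, 20)
        es = enrichment_score(genes, scores, set(genes[-5:]), weight_exponent=0)
        assert es == pytest.approx(-1.0)

    def test_es_matches_bruteforce_running_sum(self, rng):
        for _ in range(25):
            N = int(rng.integers(8, 40))
            genes = [f"G{i}" for i in range(N)]
            scores = np.sort(rng.normal(0, 2, N))[::-1]
            K = int(rng.integers(2, max(3, N // 2)))
            members = set(rng.choice(genes, K, replace=False))
            es = enrichment_score(genes, scores, members, weight_exponent=1)
            assert es == pytest.approx(brute_force_es(genes, scores, list(members), 1),
                                       abs=1e-12)

    def test_es_invariant_to_positive_rescaling_at_exponent_zero(self, rng):
        genes = [f"G{i}" for i in range(15)]
        scores = np.sort(rng.normal(0, 1, 15))[::-1]
        members = set(genes[2:6])
        a = enrichment_score(genes, scores, members, weight_exponent=0)
        b = enrichment_score(genes, scores * 7.3, members, weight_exponent=0)
        assert a == pytest.approx(b, abs=1e-14)

    def test_perm_p_matches_exact_enumeration_null(self):
        # N=10, K=3: only C(10,3)=120 label placements exist, so the exact
        # permutation p is enumerable
        genes = [f"G{i}" for i in range(10)]
        scores = np.array([5, 4, 3, 2.5, 2, 1.5, 1, 0.8, 0.5, 0.2])
        members = {genes[0], genes[3], genes[7]}  # hits at ranks 1, 4, 8
        es = enrichment_score(genes, scores, members, weight_exponent=1)

        all_es = [
            brute_force_es(genes, scores, [genes[i] for i in combo], 1)
            for combo in combinations(range(10), 3)
        ]
        same_sign = [e for e in all_es if np.sign(e) == np.sign(es)]
        exact_p = sum(abs(e) >= abs(es) for e in same_sign) / len(same_sign)

        gsc = GeneSetCollection({"S": ("d", sorted(members))})
        ranked = pd.Series(scores, index=genes)
        out = gsea(ranked, gsc, n_perm=4000, min_size=1, seed=11)
        # permutation estimate within binomial error of the exact null
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert out["perm_p"].iloc[0] == pytest.approx(exact_p, abs=max(4 * se, 0.02))

    def test_set_without_ranked_members_skipped(self, rng):
        genes = [f"G{i}" for i in range(12)]
        ranked = pd.Series(np.sort(rng.normal(0, 1, 12))[::-1], index=genes)
        gsc = GeneSetCollection(
            {"present": ("d", genes[:4]), "absent": ("d", ["X1", "X2", "X3", "X4", "X5"])}
        )
        out = gsea(ranked, gsc, n_perm=50, min_size=1, seed=0)
        assert list(out["set_name"]) == ["present"]

    def test_padj_preserves_p_order(self, rng):
        genes = [f"G{i}" for i in range(40)]
        ranked = pd.Series(np.sort(rng.normal(0, 1, 40))[::-1], index=genes)
        sets = {f"S{j}": ("d", list(rng.choice(genes, 6, replace=False))) for j in range(8)}
        out = gsea(ranked, GeneSetCollection(sets), n_perm=100, min_size=1, seed=0)
        sorted_out = out.sort_values("perm_p")
        assert (sorted_out["padj"].diff().dropna() >= -1e-12).all()
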