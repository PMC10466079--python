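"""Wide/long table ingestion, identifier uniqueness, design parsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteoflow.containers import DesignError, FormatError, bind_design
from proteoflow.ingest import make_unique, melt, parse_design, read_wide_table, reshape_long

WIDE = """Protein IDs\tGene names\tReverse\tPotential contaminant\tLFQ intensity A\tLFQ intensity B
P1;P9\tGENA\t\t\t100\t200
P2\tGENB\t+\t\t300\t0
P3\t\t\t+\t500\t600
P4\tGEND\t\t\t0\t800
P5\tGENE\t\t\t900\t1000
"""


@pytest.fixture
def wide_path(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    path.write_text(WIDE)
    return path


class TestReadWideTable:
    def test_prefix_stripping_and_shape(self, wide_path):
        qt = read_wide_table(wide_path, "LFQ intensity ", "Protein IDs", "Gene names",
                             ["Reverse", "Potential contaminant"])
        assert qt.sample_names == ["A", "B"]
        assert qt.n_features == 5  # flagged rows retained; filtering is a later stage

    def test_zero_becomes_missing(self, wide_path):
        qt = read_wide_table(wide_path, "LFQ intensity ", "Protein IDs")
        assert np.isnan(qt.intensities.loc[qt.feature_meta["raw_ids"] == "P2", "B"]).all()
        assert np.isnan(qt.intensities.loc[qt.feature_meta["raw_ids"] == "P4", "A"]).all()

    def test_flags_and_fallback_ids_preserved(self, wide_path):
        qt = read_wide_table(wide_path, "LFQ intensity ", "Protein IDs", "Gene names",
                             ["Reverse", "Potential contaminant"])
        # hand-parsed expectations: P2 is reverse-flagged, P3 contaminant-flagged
        flags = qt.feature_meta.set_index("raw_ids")
        assert flags.loc["P2", "Reverse"] == "+"
        assert flags.loc["P3", "Potential contaminant"] == "+"
        # empty gene name falls back to first protein-group member
        assert "P3" in qt.feature_ids
        # group identifier kept in full
        assert flags.index[0] == "P1;P9"
        assert qt.feature_ids[0] == "GENA"

    def test_no_prefix_match_is_format_error(self, wide_path):
        with pytest.raises(FormatError, match="prefix"):
            read_wide_table(wide_path, "Intensity X ", "Protein IDs")


class TestMakeUnique:
    @pytest.mark.parametrize(
        "names, ids, expected",
        [
            (["A", "B", "C"], ["i1", "i2", "i3"], ["A", "B", "C"]),
            (["A", "A", "A"], ["i1", "i2", "i3"], ["A", "A.1", "A.2"]),
            (["", "X"], ["P1;P8", "P2"], ["P1", "X"]),
        ],
    )
    def test_examples(self, names, ids, expected):
        assert make_unique(names, ids) == expected

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            make_unique(["", "ok"], ["", "P2"])

    @given(st.lists(st.text(alphabet="ABab", min_size=0, max_size=3), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_unique_and_idempotent(self, names):
        ids = [f"ID{i}" for i in range(len(names))]
        once = make_unique(names, ids)
        assert len(set(once)) == len(once)
        assert make_unique(once, once) == once


class TestReshapeLong:
    def _long(self, rows):
        return pd.DataFrame(rows, columns=["feat", "samp", "val"])

    def test_complete_crossing(self):
        rows = [(f, s, 10 * i + j) for i, f in enumerate("xyz") for j, s in enumerate("AB")]
        qt = reshape_long(self._long(rows), "feat", "samp", "val")
        assert qt.intensities.shape == (3, 2)
        assert not qt.intensities.isna().any().any()

    def test_absent_pair_becomes_missing(self):
        rows = [("x", "A", 1), ("x", "B", 2), ("y", "A", 3), ("y", "B", 4), ("z", "A", 5)]
        qt = reshape_long(self._long(rows), "feat", "samp", "val")
        assert qt.intensities.shape == (3, 2)
        assert int(qt.intensities.isna().sum().sum()) == 1
        assert np.isnan(qt.intensities.loc["z", "B"])

    def test_duplicate_default_errors_naming_pair(self):
        rows = [("x", "A", 1), ("x", "A", 2)]
        with pytest.raises(FormatError, match=r"'x'.*'A'"):
            reshape_long(self._long(rows), "feat", "samp", "val")

    @pytest.mark.parametrize("policy, expected", [("max", 7.0), ("sum", 12.0)])
    def test_duplicate_policies_match_groupby_oracle(self, policy, expected):
        rows = [("x", "A", 5), ("x", "A", 7), ("y", "A", 1)]
        qt = reshape_long(self._long(rows), "feat", "samp", "val", duplicate_policy=policy)
        assert qt.intensities.loc["x", "A"] == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_melt_roundtrip_preserves_values_and_missing(self, seed):
        from conftest import make_qt

        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 8)), int(rng.integers(2, 5))
        X = rng.uniform(1, 100, (n, m))
        X[rng.random((n, m)) < 0.25] = np.nan
        X[:, 0] = rng.uniform(1, 100, n)  # every feature observed somewhere
        qt = make_qt(X, [f"s{j}" for j in range(m)])
        back = reshape_long(melt(qt), "feature", "sample", "intensity")
        aligned = back.intensities.reindex(index=qt.intensities.index,
                                           columns=qt.intensities.columns)
        pd.testing.assert_frame_equal(aligned, qt.intensities, check_names=False)


class TestParseDesign:
    def test_valid_design(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text(
            "sample\tcondition\treplicate\n"
            + "".join(f"{c}_{r}\t{c}\t{r}\n" for c in "AB" for r in (1, 2, 3))
        )
        design = parse_design(path)
        assert len(design) == 6
        assert design.attrs["warnings"] == []

    def test_duplicate_condition_replicate_errors(self):
        bad = pd.DataFrame(
            {"sample": ["s1", "s2"], "condition": ["ctrl", "ctrl"], "replicate": [1, 1]}
        )
        with pytest.raises(DesignError, match="condition, replicate"):
            parse_design(bad)

    def test_single_replicate_condition_warns(self):
        design = parse_design(
            pd.DataFrame(
                {"sample": ["a1", "a2", "b1"], "condition": ["A", "A", "B"],
                 "replicate": [1, 2, 1]}
            )
        )
        assert any("single replicate" in w for w in design.attrs["warnings"])

    def test_binding_unknown_sample_errors(self):
        from conftest import make_qt

        qt = make_qt(np.ones((3, 2)), ["s1", "s2"])
        design = parse_design(
            pd.DataFrame(
                {"sample": ["s1", "s3"], "condition": ["A", "B"], "replicate": [1, 1]}
            )
        )
        with pytest.raises(DesignError, match="s3"):
            bind_design(qt, design)
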