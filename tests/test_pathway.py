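import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plasmapanel import (BiomarkerSet, PathwayAnnotation,
                         build_association_matrix, build_ppfcm,
                         fisher_enrichment, matrix_similarity,
                         percent_truncated, rank_pathways, set_similarity)
from plasmapanel.pathway import ppfcm_long

ids = st.sets(st.sampled_from([f"P{i}" for i in range(10)]), max_size=10)


def bset(name, members):
    return BiomarkerSet(name, frozenset(members))


def annotation(pathways, universe=None):
    pw = {k: frozenset(v) for k, v in pathways.items()}
    uni = frozenset(universe) if universe is not None else frozenset().union(*pw.values())
    return PathwayAnnotation(pathways=pw, universe=uni)


def hypergeom_tail_oracle(overlap, list_size, pathway_size, universe_size):
    """Upper-tail hypergeometric probability via exact binomial coefficients."""
    total = math.comb(universe_size, list_size)
    acc = 0
    for k in range(overlap, min(list_size, pathway_size) + 1):
        acc += (math.comb(pathway_size, k)
                * math.comb(universe_size - pathway_size, list_size - k))
    return acc / total


class TestAssociationMatrix:
    def test_hand_membership(self):
        ann = annotation({"P1": "abc", "P2": "cd"})
        mat = build_association_matrix(bset("panel", "ac"), ann)
        assert list(mat.columns) == ["a", "c"]
        assert mat.loc["P1"].tolist() == [1, 1]
        assert mat.loc["P2"].tolist() == [0, 1]

    def test_empty_panel_zero_columns(self):
        ann = annotation({"P1": "ab"})
        mat = build_association_matrix(BiomarkerSet("e", frozenset("x")),
                                       ann)
        assert mat.shape[1] == 0  # member outside universe dropped

    def test_panel_inside_one_pathway_row_all_ones(self):
        ann = annotation({"P1": "abcd", "P2": "xy"}, universe="abcdxy")
        mat = build_association_matrix(bset("panel", "abc"), ann)
        assert (mat.loc["P1"] == 1).all()

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            build_association_matrix(bset("p", "a"),
                                     PathwayAnnotation({}, frozenset("a")))


class TestPPFCM:
    def test_hand_counts(self):
        ann = annotation({"P1": "abc", "P2": "cd"})
        ppfcm = build_ppfcm({"S": bset("S", "ac")}, ann)
        assert ppfcm.loc["P1", "S"] == 2
        assert ppfcm.loc["P2", "S"] == 1

    def test_empty_panel_zero_column(self):
        ann = annotation({"P1": "abc"})
        ppfcm = build_ppfcm({"S": BiomarkerSet("S", frozenset())}, ann)
        assert (ppfcm["S"] == 0).all()

    def test_panel_equal_universe_gives_pathway_sizes(self):
        ann = annotation({"P1": "abc", "P2": "cd"})
        ppfcm = build_ppfcm({"S": bset("S", "abcd")}, ann)
        assert ppfcm["S"].tolist() == [3, 2]

    def test_duplicate_study_labels_rejected(self):
        ann = annotation({"P1": "ab"})
        with pytest.raises(ValueError):
            build_ppfcm([("S", bset("S", "a")), ("S", bset("S2", "b"))], ann)

    def test_column_equals_association_row_sums(self):
        # cross-module consistency: PPFCM column = row sums of the study's
        # association matrix
        ann = annotation({"P1": "abcde", "P2": "cdef", "P3": "fg"})
        panel = bset("S", "acdf")
        ppfcm = build_ppfcm({"S": panel}, ann)
        assoc = build_association_matrix(panel, ann)
        pd.testing.assert_series_equal(ppfcm["S"], assoc.sum(axis=1),
                                       check_names=False)

    def test_long_form(self):
        ann = annotation({"P1": "ab", "P2": "c"})
        ppfcm = build_ppfcm({"S": bset("S", "a")}, ann)
        long = ppfcm_long(ppfcm)
        assert set(long.columns) == {"pathway", "study", "count"}
        assert len(long) == 2


class TestRankPathways:
    def test_descending_counts(self):
        ppfcm = pd.DataFrame({"S": [2, 1]}, index=["P1", "P2"])
        assert rank_pathways(ppfcm, "S") == ["P1", "P2"]

    def test_tie_broken_lexicographically(self):
        ppfcm = pd.DataFrame({"S": [1, 1, 1]}, index=["Pb", "Pa", "Pc"])
        assert rank_pathways(ppfcm, "S") == ["Pa", "Pb", "Pc"]

    def test_unknown_study_rejected(self):
        ppfcm = pd.DataFrame({"S": [1]}, index=["P1"])
        with pytest.raises(KeyError):
            rank_pathways(ppfcm, "T")


class TestFisherEnrichment:
    def test_pathway_equal_universe_p_one(self):
        ann = annotation({"P1": "abcde"}, universe="abcde")
        out = fisher_enrichment(bset("list", "abc"), ann)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_exact_extreme_table(self):
        # universe 10, list 5, pathway 5, overlap 5 -> 1 / C(10,5)
        uni = [f"x{i}" for i in range(10)]
        ann = annotation({"P1": uni[:5]}, universe=uni)
        out = fisher_enrichment(bset("list", uni[:5]), ann)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 252, rel=1e-9)

    def test_matches_hypergeometric_tail_oracle(self, rng):
        uni = [f"x{i}" for i in range(40)]
        pathways = {f"P{k}": rng.choice(uni, size=rng.integers(3, 15),
                                        replace=False).tolist()
                    for k in range(6)}
        ann = annotation(pathways, universe=uni)
        query = bset("list", rng.choice(uni, size=12, replace=False).tolist())
        out = fisher_enrichment(query, ann).set_index("pathway")
        for name, row in out.iterrows():
            expected = hypergeom_tail_oracle(int(row["overlap"]),
                                             int(row["list_size"]),
                                             int(row["pathway_size"]),
                                             int(row["universe_size"]))
            assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_members_outside_universe_dropped(self, caplog):
        ann = annotation({"P1": "ab"}, universe="abcd")
        with caplog.at_level("WARNING"):
            out = fisher_enrichment(bset("list", ["a", "zzz"]), ann)
        assert out["list_size"].iloc[0] == 1


class TestSetSimilarity:
    def test_printed_study_overlaps(self):
        a = bset("A", [f"p{i}" for i in range(25)])
        b = bset("B", [f"p{i}" for i in range(13)]
                 + [f"q{i}" for i in range(7)])
        c = bset("C", [f"p{i}" for i in range(13)]
                 + [f"r{i}" for i in range(12)])
        s_ab = set_similarity(a, b)
        s_ac = set_similarity(a, c)
        assert s_ab == pytest.approx(13 / 32)
        assert s_ac == pytest.approx(13 / 37)
        assert percent_truncated(s_ab) == 40
        assert percent_truncated(s_ac) == 35

    def test_identity_and_disjoint(self):
        a = bset("A", "abc")
        assert set_similarity(a, bset("B", "abc")) == 1.0
        assert set_similarity(a, bset("B", "xyz")) == 0.0
        assert set_similarity(bset("A", []), bset("B", [])) == 1.0

    @given(s1=ids, s2=ids)
    def test_symmetry_bounds_and_bruteforce(self, s1, s2):
        a, b = bset("A", s1), bset("B", s2)
        s = set_similarity(a, b)
        assert s == set_similarity(b, a)
        assert 0.0 <= s <= 1.0
        union = s1 | s2
        brute = (sum(1 for m in union if m in s1 and m in s2) / len(union)
                 if union else 1.0)
        assert s == pytest.approx(brute)
        assert (s == 1.0) == (s1 == s2)
        if s1 and s2:
            assert (s == 0.0) == (not s1 & s2)


class TestMatrixSimilarity:
    def test_identical_columns(self):
        ppfcm = pd.DataFrame({"A": [1, 2, 3], "B": [1, 2, 3]},
                             index=["P1", "P2", "P3"])
        assert matrix_similarity(ppfcm, "A", "B") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        ppfcm = pd.DataFrame({"A": [1, 2, 3], "B": [3, 2, 1]},
                             index=list("xyz"))
        assert matrix_similarity(ppfcm, "A", "B") == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        ppfcm = pd.DataFrame({"A": [1, 0, 2], "B": [2, 1, 0]},
                             index=list("xyz"))
        assert matrix_similarity(ppfcm, "A", "B") == pytest.approx(-0.5)

    def test_symmetric_and_row_order_invariant(self, rng):
        ppfcm = pd.DataFrame({"A": rng.integers(0, 9, 8),
                              "B": rng.integers(0, 9, 8)},
                             index=[f"P{i}" for i in range(8)])
        r = matrix_similarity(ppfcm, "A", "B")
        assert r == pytest.approx(matrix_similarity(ppfcm, "B", "A"))
        shuffled = ppfcm.sample(frac=1.0, random_state=1)
        assert matrix_similarity(shuffled, "A", "B") == pytest.approx(r)

    def test_constant_column_undefined(self, caplog):
        ppfcm = pd.DataFrame({"A": [1, 1], "B": [1, 2]}, index=["P1", "P2"])
        with caplog.at_level("WARNING"):
            assert math.isnan(matrix_similarity(ppfcm, "A", "B"))

    def test_unknown_study_rejected(self):
        ppfcm = pd.DataFrame({"A": [1, 2]}, index=["P1", "P2"])
        with pytest.raises(KeyError):
            matrix_similarity(ppfcm, "A", "Z")


class TestGMT:
    def test_roundtrip(self, tmp_path):
        ann = annotation({"P1": "abc", "P2": "cd"})
        ann.to_gmt(tmp_path / "x.gmt")
        back = PathwayAnnotation.from_gmt(tmp_path / "x.gmt")
        assert back.pathways == ann.pathways

    def test_malformed_line_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("only_name\tdesc\n")
        with pytest.raises(ValueError):
            PathwayAnnotation.from_gmt(tmp_path / "bad.gmt")
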