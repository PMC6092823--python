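"""The seven conservation metrics, the UPGMA guide tree, and grouping mode."""

import itertools
import math
import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from msavar import (
    Alignment,
    AlignmentError,
    DistanceMatrix,
    PseudocountSettings,
    apply_grouping,
    column_profile,
    henikoff_weights,
    load_substitution_matrix,
    pairwise_distance_matrix,
    read_grouping_scheme,
    score_alignment,
    score_cre,
    score_landgraf,
    score_ret,
    upgma_tree,
)

from conftest import AA, columns_to_alignment, random_alignment


def toy_matrix(scores):
    """Square substitution matrix from {(a, b): s} (symmetric fill)."""
    alphabet = "".join(sorted({c for pair in scores for c in pair}))
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for (x, y), s in scores.items():
        m[x, y] = s
        if (y, x) not in scores:
            m[y, x] = s
    return m


class TestColumnProfile:
    def test_gaps_in_denominator(self):
        a = columns_to_alignment(["AAA-"])
        prof = column_profile(a, 1)
        assert prof.p["A"] == pytest.approx(0.75)
        assert prof.n_types == 1

    def test_two_types(self):
        prof = column_profile(columns_to_alignment(["AACC"]), 1)
        assert max(prof.p.values()) == pytest.approx(0.5)
        assert prof.n_types == 2

    def test_all_gap_column_flagged(self):
        a = Alignment(ids=("x", "y"), rows=("-A", "-A"))
        prof = column_profile(a, 1)
        assert prof.is_all_gap and prof.n_types == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(AlignmentError):
            column_profile(columns_to_alignment(["AA"]), 2)


class TestEscore:
    def test_worked_fixture(self, worked_alignment):
        """Columns AAAA/AAA-/AACC give P = (1, 0.75, 0.25) and thus
        E = (0, 0.2075, 1.0)."""
        e = score_alignment(worked_alignment, "escore").values
        np.testing.assert_allclose(np.round(e, 4), [0.0, 0.2075, 1.0])

    def test_range_and_attained_max(self, rng):
        for _ in range(50):
            a = random_alignment(rng, rng.integers(3, 9), rng.integers(3, 20),
                                 gap_prob=0.15)
            e = score_alignment(a, "escore").values
            finite = e[np.isfinite(e)]
            assert ((finite >= 0) & (finite <= 1)).all()
            if len(np.unique(finite)) > 1:
                assert finite.max() == pytest.approx(1.0)

    def test_invariant_gapless_column_scores_zero(self):
        a = columns_to_alignment(["AAAA", "ACAC"])
        e = score_alignment(a, "escore").values
        assert e[0] == pytest.approx(0.0)

    def test_all_equal_p_degenerates_to_zero(self):
        a = columns_to_alignment(["AAAA", "CCCC"])
        e = score_alignment(a, "escore").values
        np.testing.assert_allclose(e, 0.0)

    def test_all_gap_column_is_nan_and_excluded_from_maxima(self):
        a = columns_to_alignment(["AAAA", "----", "AACC"])
        with pytest.warns(UserWarning, match="all gaps"):
            e = score_alignment(a, "escore").values
        assert math.isnan(e[1])
        np.testing.assert_allclose(np.round(e[[0, 2]], 4), [0.0, 1.0])


class TestEntropyFamily:
    def test_shannon_matches_brute_force(self, rng):
        for _ in range(50):
            a = random_alignment(rng, rng.integers(2, 10), 8, gap_prob=0.2)
            got = score_alignment(a, "shannon").values
            for j in range(a.n_col):
                col = [c for c in a.column(j + 1) if c not in "-X"]
                if not col:
                    assert math.isnan(got[j])
                    continue
                expected = -sum(
                    (col.count(s) / len(col)) * math.log(col.count(s) / len(col))
                    for s in set(col)
                )
                assert got[j] == pytest.approx(expected, abs=1e-12)

    def test_worked_column_values(self):
        a = columns_to_alignment(["AACC"])
        assert score_alignment(a, "shannon").values[0] == pytest.approx(math.log(2))
        assert score_alignment(a, "schneider").values[0] == pytest.approx(
            math.log(2) / math.log(20)
        )
        assert score_alignment(a, "kabat").values[0] == pytest.approx(4.0)

    def test_invariant_column_extremes(self):
        a = columns_to_alignment(["AAAA"])
        assert score_alignment(a, "shannon").values[0] == 0.0
        assert score_alignment(a, "schneider").values[0] == 0.0
        assert score_alignment(a, "kabat").values[0] == 1.0

    def test_schneider_hits_one_on_twenty_distinct_residues(self):
        a = columns_to_alignment([AA])  # one column, all 20 residues
        assert score_alignment(a, "schneider").values[0] == pytest.approx(1.0)

    def test_kabat_one_iff_invariant(self, rng):
        for _ in range(30):
            a = random_alignment(rng, 6, 10, gap_prob=0.2)
            v = score_alignment(a, "kabat").values
            for j in range(a.n_col):
                col = {c for c in a.column(j + 1) if c not in "-X"}
                if not col:
                    assert math.isnan(v[j])
                elif len(col) == 1:
                    assert v[j] == pytest.approx(1.0)
                else:
                    assert v[j] > 1.0

    def test_kabat_ignores_gaps_in_depth(self):
        # k=2, N=3 non-gap, n1=2 -> 2*3/2 = 3
        a = columns_to_alignment(["AAC-"])
        assert score_alignment(a, "kabat").values[0] == pytest.approx(3.0)

    def test_uniform_weights_match_unweighted(self, rng):
        a = random_alignment(rng, 5, 12, gap_prob=0.1)
        w = np.full(5, 0.2)
        for metric in ("shannon", "schneider", "kabat", "escore"):
            np.testing.assert_allclose(
                score_alignment(a, metric, weights=w).values,
                score_alignment(a, metric).values,
                atol=1e-12, equal_nan=True,
            )

    def test_henikoff_weighting_tempers_duplicates(self):
        """Mass duplication of one sequence drags unweighted entropy down;
        Henikoff weights largely restore the two-cluster picture."""
        base = columns_to_alignment(["AC"])  # one A, one C: H = ln 2
        dup = columns_to_alignment(["AAAAAC"])
        w = henikoff_weights(dup)
        unweighted = score_alignment(dup, "shannon").values[0]
        weighted = score_alignment(dup, "shannon", weights=w).values[0]
        target = score_alignment(base, "shannon").values[0]
        assert unweighted < weighted <= target + 1e-9

    def test_pseudocounts_smooth_toward_background(self):
        a = columns_to_alignment(["AAAA"])
        raw = score_alignment(a, "shannon").values[0]
        adj = score_alignment(
            a, "shannon", pseudocounts=PseudocountSettings(B=5.0)
        ).values[0]
        assert raw == 0.0 and adj > 0.0

    def test_row_permutation_invariance(self, rng):
        a = random_alignment(rng, 6, 10, gap_prob=0.1)
        perm = rng.permutation(6)
        b = Alignment(
            ids=tuple(a.ids[i] for i in perm),
            rows=tuple(a.rows[i] for i in perm),
        )
        for metric in ("shannon", "schneider", "kabat", "escore"):
            np.testing.assert_allclose(
                score_alignment(a, metric).values,
                score_alignment(b, metric).values,
                atol=1e-12, equal_nan=True,
            )

    def test_unknown_metric_rejected(self):
        with pytest.raises(AlignmentError, match="unknown metric"):
            score_alignment(columns_to_alignment(["AA"]), "bogus")


class TestLandgraf:
    def test_invariant_column_is_zero(self):
        a = columns_to_alignment(["AAAA"])
        assert score_landgraf(a).values[0] == pytest.approx(0.0)

    def test_toy_matrix_fixture(self):
        """AACC, equal weights, S(A,A)=S(C,C)=4 and zero off-diagonal:
        8 ordered mixed pairs each contributing 0.25*4, over 12."""
        m = toy_matrix({("A", "A"): 4, ("C", "C"): 4, ("A", "C"): 0})
        a = columns_to_alignment(["AACC"])
        assert score_landgraf(a, matrix=m).values[0] == pytest.approx(8 / 12)

    def test_lower_similarity_substitution_increases_score(self):
        """Replacing one A by a residue scoring lower against A strictly
        raises the column score, for every toy matrix tried."""
        for sAC, sAD in itertools.product((3, 1, 0), (2, 0, -2)):
            if sAD >= sAC:
                continue
            m = toy_matrix({
                ("A", "A"): 5, ("C", "C"): 5, ("D", "D"): 5,
                ("A", "C"): sAC, ("A", "D"): sAD, ("C", "D"): 0,
            })
            close = score_landgraf(columns_to_alignment(["AAAC"]), matrix=m)
            far = score_landgraf(columns_to_alignment(["AAAD"]), matrix=m)
            assert far.values[0] > close.values[0]

    def test_gapped_rows_excluded(self):
        m = toy_matrix({("A", "A"): 4, ("C", "C"): 4, ("A", "C"): 0})
        full = columns_to_alignment(["AACC"])
        padded = columns_to_alignment(["AACC--"])
        w6 = np.full(6, 1 / 6)
        # same pair set, weights 1/6 instead of 1/4 -> 2/3 of the value
        got = score_landgraf(padded, weights=w6, matrix=m).values[0]
        ref = score_landgraf(full, matrix=m).values[0]
        assert got == pytest.approx(ref * (1 / 6) / (1 / 4))

    def test_symbol_missing_from_matrix_rejected(self):
        m = toy_matrix({("A", "A"): 1, ("C", "C"): 1, ("A", "C"): 0})
        with pytest.raises(AlignmentError, match="absent"):
            score_landgraf(columns_to_alignment(["AW"]), matrix=m)

    def test_default_gonnet_orders_chemistry(self):
        """With the bundled Gonnet matrix, an I/L column (conservative) is
        less variable than a D/W column (radical)."""
        conservative = score_landgraf(columns_to_alignment(["IILL"])).values[0]
        radical = score_landgraf(columns_to_alignment(["DDWW"])).values[0]
        assert 0 < conservative < radical

    def test_load_matrix_by_name_and_file(self, tmp_path):
        g = load_substitution_matrix("GONNET1992")
        assert g["A", "A"] == pytest.approx(2.4)
        p = tmp_path / "m.txt"
        p.write_text(str(toy_matrix({("A", "A"): 2, ("C", "C"): 2, ("A", "C"): 1})))
        m = load_substitution_matrix(p)
        assert m["A", "C"] == 1


def brute_force_upgma(ids, dmat):
    """Independent oracle: clusters as frozensets, cluster distance
    recomputed each step as the plain mean over all original cross pairs."""
    index = {sid: i for i, sid in enumerate(ids)}
    clusters = {frozenset([sid]): 0.0 for sid in ids}  # cluster -> height
    merges = {}
    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(sorted(clusters, key=sorted), 2):
            d = np.mean([
                dmat[index[x], index[y]] for x in c1 for y in c2
            ])
            key = (d, min(min(c1), min(c2)), max(min(c1), min(c2)))
            if best is None or key < best[0]:
                best = (key, c1, c2)
        (d, _, _), c1, c2 = best
        merged = c1 | c2
        clusters.pop(c1), clusters.pop(c2)
        clusters[merged] = d / 2.0
        merges[merged] = d / 2.0
    return merges


def tree_heights(node, out=None):
    out = {} if out is None else out
    if not node.is_leaf:
        out[frozenset(node.leaves)] = node.height
        for c in node.children:
            tree_heights(c, out)
    return out


class TestUpgma:
    def test_hand_example(self):
        d = DistanceMatrix(
            ids=("A", "B", "C"),
            values=np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        t = upgma_tree(d)
        assert t.root.height == pytest.approx(0.2)
        heights = tree_heights(t.root)
        assert heights[frozenset({"A", "B"})] == pytest.approx(0.1)

    def test_equal_distances_tie_break_lexicographic(self):
        n = 4
        ids = ("b", "d", "a", "c")
        d = DistanceMatrix(ids=ids, values=np.ones((n, n)) - np.eye(n))
        t = upgma_tree(d)
        heights = tree_heights(t.root)
        assert frozenset({"a", "b"}) in heights  # smallest pair merged first
        assert all(h == pytest.approx(0.5) for h in heights.values())

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            ids = tuple(f"t{i}" for i in range(n))
            t = upgma_tree(DistanceMatrix(ids=ids, values=m))
            assert tree_heights(t.root) == pytest.approx(
                brute_force_upgma(ids, m)
            )

    def test_heights_nondecreasing_toward_root(self, rng):
        n = 8
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        t = upgma_tree(DistanceMatrix(ids=tuple(f"s{i}" for i in range(n)),
                                      values=m))

        def walk(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                walk(c)

        walk(t.root)

    def test_matches_scipy_average_linkage(self, rng):
        """Cross-check against scipy's average linkage on matrices with
        distinct entries (where tie-breaking cannot differ)."""
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(3, 8))
            vals = rng.permutation(np.linspace(0.1, 0.9, n * (n - 1) // 2))
            m = squareform(vals)
            t = upgma_tree(
                DistanceMatrix(ids=tuple(f"s{i}" for i in range(n)), values=m)
            )
            ours = sorted(tree_heights(t.root).values())
            scipy_heights = sorted(average(vals)[:, 2] / 2.0)
            np.testing.assert_allclose(ours, scipy_heights, atol=1e-12)

    def test_cut_top_partitions(self):
        d = DistanceMatrix(
            ids=("A", "B", "C", "D"),
            values=np.array([
                [0, 0.1, 0.8, 0.8],
                [0.1, 0, 0.8, 0.8],
                [0.8, 0.8, 0, 0.2],
                [0.8, 0.8, 0.2, 0],
            ]),
        )
        t = upgma_tree(d)
        assert sorted(t.cut_top(2)) == [("A", "B"), ("C", "D")]
        assert len(t.cut_top(4)) == 4

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            upgma_tree(DistanceMatrix(ids=("A",), values=np.zeros((1, 1))))


class TestRet:
    def test_identical_sequences_floor_at_one(self):
        a = Alignment(ids=("a", "b", "c"), rows=("ACD",) * 3)
        np.testing.assert_allclose(score_ret(a).values, 1.0)

    def test_two_identical_pairs_fixture(self):
        """AA|CC with the tree pairing the clusters: only the single-group
        level contributes ln 2."""
        a = Alignment(ids=("p1", "p2", "q1", "q2"),
                      rows=("AAA", "AAA", "CCC", "CCC"))
        np.testing.assert_allclose(score_ret(a).values, 1 + math.log(2))

    def test_floor_and_within_group_substitution_raises(self, rng):
        for _ in range(20):
            a = random_alignment(rng, 4, 6, gap_prob=0.1)
            tree = upgma_tree(pairwise_distance_matrix(a))
            base = score_ret(a, tree).values
            assert (base[np.isfinite(base)] >= 1.0 - 1e-12).all()
        # explicit within-group substitution on an invariant column
        a0 = Alignment(ids=("p1", "p2", "q1", "q2"),
                       rows=("AW", "AW", "CW", "CW"))
        a1 = Alignment(ids=("p1", "p2", "q1", "q2"),
                       rows=("AW", "GW", "CW", "CW"))
        tree = upgma_tree(pairwise_distance_matrix(a0))
        assert score_ret(a1, tree).values[0] > score_ret(a0, tree).values[0]

    def test_leaf_mismatch_rejected(self):
        a = Alignment(ids=("a", "b"), rows=("AC", "AC"))
        other = Alignment(ids=("x", "y"), rows=("AC", "AC"))
        tree = upgma_tree(pairwise_distance_matrix(other))
        with pytest.raises(AlignmentError, match="leaves"):
            score_ret(a, tree)


class TestCre:
    def test_identical_sequences_zero(self):
        a = Alignment(ids=("a", "b", "c", "d"), rows=("ACD",) * 4)
        np.testing.assert_allclose(
            score_cre(a, groups=[("a", "b"), ("c", "d")]).values, 0.0
        )

    def test_identical_group_distributions_zero(self):
        a = Alignment(ids=("a", "b", "c", "d"), rows=("A", "C", "A", "C"))
        np.testing.assert_allclose(
            score_cre(a, groups=[("a", "b"), ("c", "d")]).values, 0.0,
            atol=1e-12,
        )

    def test_disjoint_groups_fixture(self):
        """AACC with groups {AA},{CC}: 0.5 ln2 + 0.5 ln2 = ln 2."""
        a = Alignment(ids=("a", "b", "c", "d"), rows=("A", "A", "C", "C"))
        v = score_cre(a, groups=[("a", "b"), ("c", "d")]).values
        assert v[0] == pytest.approx(math.log(2))

    def test_nonnegative_on_random_fixtures(self, rng):
        for _ in range(20):
            a = random_alignment(rng, 6, 8, gap_prob=0.1)
            v = score_cre(a, groups=[a.ids[:3], a.ids[3:]]).values
            assert (v[np.isfinite(v)] >= -1e-12).all()

    def test_default_partition_from_tree(self, rng):
        a = random_alignment(rng, 6, 10)
        v = score_cre(a).values
        assert v.shape == (10,)
        assert (v[np.isfinite(v)] >= -1e-12).all()

    def test_group_without_residues_skipped_with_warning(self):
        a = Alignment(ids=("a", "b", "c", "d"), rows=("-", "-", "A", "C"))
        with pytest.warns(UserWarning, match="skipped"):
            v = score_cre(a, groups=[("a", "b"), ("c", "d")]).values
        assert np.isfinite(v[0])

    def test_bad_partition_rejected(self):
        a = Alignment(ids=("a", "b", "c"), rows=("A", "A", "C"))
        with pytest.raises(AlignmentError):
            score_cre(a, groups=[("a",), ("b",)])  # not a partition
        with pytest.raises(AlignmentError):
            score_cre(a, groups=[("a", "b", "c")])  # single group


class TestGrouping:
    SCHEME = {
        **{aa: "h" for aa in "AVLIMFWC"},
        **{aa: "+" for aa in "KRH"},
        **{aa: "n" for aa in "DE"},
        **{aa: "p" for aa in "STYNQG"},
        "P": "p",
    }

    def test_maps_by_definition(self):
        a = Alignment(ids=("s1",), rows=("AVLK",))
        g = apply_grouping(a, self.SCHEME)
        assert g.rows == ("hhh+",)

    def test_identity_scheme_preserves(self):
        a = Alignment(ids=("s1", "s2"), rows=("AC-D", "ACXD"))
        ident = {aa: aa for aa in AA}
        assert apply_grouping(a, ident).rows == a.rows

    def test_gaps_and_x_pass_through(self):
        a = Alignment(ids=("s1",), rows=("A-X",))
        assert apply_grouping(a, self.SCHEME).rows == ("h-X",)

    def test_grouped_shannon_never_exceeds_ungrouped(self, rng):
        for _ in range(25):
            a = random_alignment(rng, 8, 12, gap_prob=0.1)
            g = apply_grouping(a, self.SCHEME)
            h0 = score_alignment(a, "shannon").values
            h1 = score_alignment(g, "shannon").values
            ok = np.isfinite(h0)
            assert (h1[ok] <= h0[ok] + 1e-12).all()

    def test_incomplete_scheme_rejected(self):
        with pytest.raises(AlignmentError, match="cover"):
            apply_grouping(Alignment(ids=("s1",), rows=("A",)), {"A": "h"})

    def test_scheme_file_parsing(self, tmp_path):
        p = tmp_path / "scheme.txt"
        p.write_text("# hydrophobicity\n" + "\n".join(
            f"{aa} {grp}" for aa, grp in self.SCHEME.items()))
        scheme = read_grouping_scheme(p)
        assert scheme == self.SCHEME
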