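"""NJ, progressive alignment, pruning likelihood, co-estimation loop."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from anchorlign import trees
from anchorlign.coestimate import (
    coestimate,
    jc_distance_matrix,
    kmer_distance_matrix,
    nj,
    progressive_align,
    score_alignment_tree,
)
from anchorlign.records import InvalidInputError, Msa, SequenceRecord
from anchorlign.seqprep import DEFAULT_SCORING, global_alignment


class TestKmerDistance:
    def _recs(self, seqs):
        return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]

    def test_identical_sequences_distance_zero(self):
        recs = self._recs(["ACGTACGTACGT"] * 3)
        d = kmer_distance_matrix(recs, k=4)
        assert np.allclose(d.values, 0.0)

    def test_disjoint_alphabets_distance_one(self):
        recs = self._recs(["A" * 20, "T" * 20, "ACGT" * 5])
        d = kmer_distance_matrix(recs, k=4)
        assert d.iloc[0, 1] == 1.0

    def test_symmetry_range_zero_diagonal(self):
        rng = random.Random(5)
        recs = self._recs(
            ["".join(rng.choice("ACGT") for _ in range(50)) for _ in range(10)]
        )
        d = kmer_distance_matrix(recs).values
        assert np.allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 1))
        assert np.allclose(np.diag(d), 0.0)


def _ls_fit(D, ids, topology):
    """Least-squares branch lengths (non-negative) for a 4-taxon topology.

    topology is ((a,b),(c,d)): 5 branches; returns the minimal residual
    sum of squares over branch lengths >= 0 (grid-free via nnls).
    """
    from scipy.optimize import nnls

    (a, b), (c, d) = topology
    idx = {t: i for i, t in enumerate(ids)}
    pairs = list(itertools.combinations(ids, 2))
    # design matrix: columns = branches ea, eb, ec, ed, internal
    A = np.zeros((len(pairs), 5))
    y = np.zeros(len(pairs))
    br = {a: 0, b: 1, c: 2, d: 3}
    for r, (x, z) in enumerate(pairs):
        A[r, br[x]] = 1
        A[r, br[z]] = 1
        same_side = {x, z} in ({a, b}, {c, d})
        if not same_side:
            A[r, 4] = 1
        y[r] = D[idx[x], idx[z]]
    _, rss = nnls(A, y)
    return rss


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]], index=ids, columns=ids
        )
        tree = nj(D)
        term = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert term["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert term["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert term["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_recovery_vs_least_squares(self):
        # additive matrix from ((a,b),(c,d)) with every branch 0.1
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0.0, 0.2, 0.3, 0.3],
                [0.2, 0.0, 0.3, 0.3],
                [0.3, 0.3, 0.0, 0.2],
                [0.3, 0.3, 0.2, 0.0],
            ]
        )
        tree = nj(pd.DataFrame(D, index=ids, columns=ids))
        bips = set(trees.bipartitions(tree))
        assert frozenset({"c", "d"}) in bips or frozenset({"a", "b"}) in bips
        # brute-force least squares over all three topologies agrees
        topos = [(("a", "b"), ("c", "d")), (("a", "c"), ("b", "d")),
                 (("a", "d"), ("b", "c"))]
        rss = [_ls_fit(D, ids, t) for t in topos]
        assert int(np.argmin(rss)) == 0
        assert rss[0] == pytest.approx(0.0, abs=1e-12)

    def test_tie_break_deterministic_on_equal_matrix(self):
        ids = ["d", "b", "a", "c"]
        D = pd.DataFrame(1.0 - np.eye(4), index=ids, columns=ids)
        t1 = trees.to_newick(nj(D))
        t2 = trees.to_newick(nj(D))
        assert t1 == t2
        # the lexicographically smallest pair joins first
        tree = nj(D)
        assert frozenset({"c", "d"}) in trees.bipartitions(tree) or \
            frozenset({"a", "b"}) in trees.bipartitions(tree)

    def test_asymmetric_matrix_rejected(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=ids, columns=ids
        )
        with pytest.raises(InvalidInputError):
            nj(D)

    def test_matches_dendropy_on_random_additive_matrices(self):
        """Independent oracle: dendropy's NJ recovers the same topology on
        clean additive distances."""
        import dendropy

        rng = random.Random(9)
        for _ in range(5):
            src = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8, rng=rng
            )
            pdm = src.phylogenetic_distance_matrix()
            taxa = sorted(src.taxon_namespace, key=lambda t: t.label)
            ids = [t.label for t in taxa]
            D = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
            ours = nj(pd.DataFrame(D, index=ids, columns=ids))
            theirs = pdm.nj_tree()
            assert set(trees.bipartitions(ours)) == set(trees.bipartitions(theirs))


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(4)]
        guide = nj(kmer_distance_matrix(recs, k=4))
        msa = progressive_align(recs, guide)
        assert msa.ncol == 10
        assert all(row == "ACGTACGTAC" for row in msa.rows.values())

    def test_two_sequences_reduce_to_pairwise_dp(self):
        a, b = "ACGTACGGTACGT", "ACGTACTACGT"
        ra, rb, _ = global_alignment(a, b)
        recs = [SequenceRecord("x", a), SequenceRecord("y", b),
                SequenceRecord("z", "ACGTACGGTACGT")]
        guide = nj(kmer_distance_matrix(recs, k=4))
        msa = progressive_align([recs[0], recs[1]],
                                _two_leaf_guide("x", "y"))
        assert msa.rows["x"] == ra and msa.rows["y"] == rb

    def test_three_sequences_follow_guide_merge_order(self):
        """Small-case oracle: for every merge order, the guide encoding it
        reproduces the explicit pairwise-then-profile brute-force result,
        and the best-scoring guide attains the enumerated optimum."""
        seqs = {"a": "ACGT", "b": "AGT", "c": "ACT"}
        recs = {k: SequenceRecord(k, v) for k, v in seqs.items()}
        orders = [("a", "b", "c"), ("a", "c", "b"), ("b", "c", "a")]
        from anchorlign.coestimate import _merge

        guide_scores = []
        for first, second, third in orders:
            pair = _merge(Msa({first: seqs[first]}), Msa({second: seqs[second]}),
                          DEFAULT_SCORING)
            full = _merge(pair, Msa({third: seqs[third]}), DEFAULT_SCORING)
            guide = _three_leaf_guide(first, second, third)
            ours = progressive_align(list(recs.values()), guide)
            assert {k: ours.rows[k] for k in full.rows} == full.rows
            guide_scores.append(_sp_score(ours))
        assert max(guide_scores) == pytest.approx(
            max(_sp_score(m) for m in _all_merge_results(seqs))
        )

    def test_degap_preservation(self, small_truth):
        recs = small_truth.records
        guide = nj(kmer_distance_matrix(recs))
        msa = progressive_align(recs, guide)
        for rec in recs:
            assert msa.degap(rec.id) == rec.residues

    def test_guide_mismatch_rejected(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        with pytest.raises(InvalidInputError):
            progressive_align(recs, _two_leaf_guide("a", "zzz"))


def _sp_score(msa: Msa) -> float:
    sc = DEFAULT_SCORING
    ids = msa.ids
    total = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ra, rb = msa.rows[ids[i]], msa.rows[ids[j]]
            gap_a = gap_b = False
            for x, y in zip(ra, rb):
                if x == "-" and y == "-":
                    continue
                if x == "-":
                    total += -sc["gap_extend"] if gap_a else -sc["gap_open"]
                    gap_a, gap_b = True, False
                elif y == "-":
                    total += -sc["gap_extend"] if gap_b else -sc["gap_open"]
                    gap_b, gap_a = True, False
                else:
                    total += sc["match"] if x == y else sc["mismatch"]
                    gap_a = gap_b = False
    return total


def _two_leaf_guide(a, b):
    return trees.parse_newick(f"({a}:1,{b}:1);")


def _three_leaf_guide(a, b, c):
    return trees.parse_newick(f"(({a}:1,{b}:1):1,{c}:1);")


def _all_merge_results(seqs):
    from anchorlign.coestimate import _merge

    ids = list(seqs)
    for i in range(3):
        first, second = [k for j, k in enumerate(ids) if j != i]
        third = ids[i]
        pair = _merge(Msa({first: seqs[first]}), Msa({second: seqs[second]}),
                      DEFAULT_SCORING)
        yield _merge(pair, Msa({third: seqs[third]}), DEFAULT_SCORING)


class TestScoreAlignmentTree:
    def test_single_column_closed_form_at_t_zero(self):
        msa = Msa({"a": "A", "b": "A"})
        tree = trees.parse_newick("(a:0.0,b:0.0);")
        assert score_alignment_tree(msa, tree) == pytest.approx(math.log(0.25))

    def test_single_column_closed_form_at_positive_t(self):
        t = 0.3
        p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        msa = Msa({"a": "A", "b": "A"})
        tree = trees.parse_newick(f"(a:{t},b:0.0);")
        assert score_alignment_tree(msa, tree) == pytest.approx(
            math.log(0.25) + math.log(p_same)
        )

    def test_invariant_to_row_order_and_rerooting(self, small_truth):
        recs = small_truth.records[:6]
        guide = nj(kmer_distance_matrix(recs))
        msa = progressive_align(recs, guide)
        tree = nj(jc_distance_matrix(msa))
        s1 = score_alignment_tree(msa, tree)
        shuffled = Msa(dict(reversed(list(msa.rows.items()))))
        assert score_alignment_tree(shuffled, tree) == pytest.approx(s1)
        rerooted = tree.clone(depth=1)
        rerooted.reroot_at_midpoint(update_bipartitions=False)
        assert score_alignment_tree(msa, rerooted) == pytest.approx(s1)

    def test_four_taxon_brute_force_state_sum(self):
        """Oracle: explicit sum over the 16 internal-state assignments of
        an unrooted 4-taxon tree, 10 columns."""
        rng = random.Random(17)
        cols = ["".join(rng.choice("ACGT") for _ in range(4)) for _ in range(10)]
        rows = {t: "".join(c[i] for c in cols) for i, t in enumerate("abcd")}
        msa = Msa(rows)
        bl = {"a": 0.1, "b": 0.25, "c": 0.4, "d": 0.05, "internal": 0.2}
        tree = trees.parse_newick(
            f"((a:{bl['a']},b:{bl['b']}):{bl['internal']},c:{bl['c']},d:{bl['d']});"
        )

        def p(d):
            same = 0.25 + 0.75 * math.exp(-4 * d / 3)
            return lambda x, y: same if x == y else (1 - same) / 3

        pa, pb, pc, pd, pi = (p(bl[k]) for k in ("a", "b", "c", "d", "internal"))
        expected = 0.0
        idx = {t: i for i, t in enumerate("abcd")}
        for col in cols:
            site = 0.0
            for u in range(4):       # state at the (a,b) node
                for v in range(4):   # state at the (c,d) node
                    xa, xb, xc, xd = ("ACGT".index(col[idx[t]]) for t in "abcd")
                    site += (
                        0.25
                        * pa(u, xa) * pb(u, xb)
                        * pi(u, v)
                        * pc(v, xc) * pd(v, xd)
                    )
            expected += math.log(site)
        assert score_alignment_tree(msa, tree) == pytest.approx(expected)

    def test_gap_columns_are_missing_data(self):
        """A column with one residue and gaps elsewhere contributes exactly
        the stationary log(1/4); gap rows act as missing data."""
        msa1 = Msa({"a": "AC", "b": "AC", "c": "AC"})
        msa2 = Msa({"a": "ACT", "b": "AC-", "c": "AC-"})
        tree = trees.parse_newick("(a:0.1,b:0.1,c:0.1);")
        s1 = score_alignment_tree(msa1, tree)
        assert score_alignment_tree(msa2, tree) == pytest.approx(
            s1 + math.log(0.25)
        )

    def test_negative_branch_length_rejected(self):
        msa = Msa({"a": "A", "b": "A"})
        tree = trees.parse_newick("(a:-0.1,b:0.1);")
        with pytest.raises(InvalidInputError):
            score_alignment_tree(msa, tree)


class TestCoestimate:
    def test_degenerate_loop_equals_single_pass(self, small_truth):
        recs = small_truth.records
        trace = coestimate(recs, runs=1, iterations=1, seed=3)
        guide = nj(kmer_distance_matrix(recs))
        direct = progressive_align(recs, guide)
        assert trace.best_msa.rows == direct.rows
        assert len(trace.scores) == 1

    def test_running_best_non_decreasing_within_runs(self, small_truth):
        trace = coestimate(small_truth.records, runs=2, iterations=5, seed=1)
        frame = trace.as_frame()
        for _, sub in frame.groupby("run"):
            running = sub["score"].cummax()
            assert (running.diff().dropna() >= 0).all()
        assert trace.best_score == frame["score"].max()

    def test_trace_reproducible_from_seed(self, small_truth):
        t1 = coestimate(small_truth.records, runs=2, iterations=3, seed=5)
        t2 = coestimate(small_truth.records, runs=2, iterations=3, seed=5)
        assert t1.scores == t2.scores
        assert t1.best_msa.rows == t2.best_msa.rows

    def test_duplicate_record_becomes_sibling(self, small_truth):
        recs = list(small_truth.records[:7])
        dup = SequenceRecord("dup_of_" + recs[0].id, recs[0].residues)
        recs.append(dup)
        trace = coestimate(recs, runs=1, iterations=2, seed=2)
        tree = trace.best_tree
        # identical sequences: pairwise distance 0 forces NJ to join them
        pair = frozenset({recs[0].id, dup.id})
        leaf_parents = {
            lf.taxon.label: lf.parent_node for lf in tree.leaf_node_iter()
        }
        assert leaf_parents[recs[0].id] is leaf_parents[dup.id]
        for lf in tree.leaf_node_iter():
            if lf.taxon.label in pair:
                assert lf.edge.length == pytest.approx(0.0, abs=1e-9)

    def test_zero_divergence_best_score_closed_form(self):
        recs = [SequenceRecord(f"s{i}", "ACGT" * 10) for i in range(5)]
        trace = coestimate(recs, runs=1, iterations=1, seed=0)
        assert trace.best_msa.ncol == 40
        assert all("-" not in r for r in trace.best_msa.rows.values())
        assert trace.best_score == pytest.approx(40 * math.log(0.25))
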