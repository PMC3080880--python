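"""Pairwise similarity, orientation correction, exclusion filters."""

import random

import pytest

from anchorlign.records import (
    InvalidInputError,
    RegionMap,
    SequenceRecord,
    reverse_complement,
)
from anchorlign.seqprep import (
    filter_records,
    global_alignment,
    global_similarity,
    orient,
)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of global alignments
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (as two gapped rows) of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def affine_score(ra: str, rb: str, match, mismatch, go, ge) -> float:
    s = 0.0
    gap_a = gap_b = False
    for x, y in zip(ra, rb):
        if x == "-":
            s += -ge if gap_a else -go
            gap_a, gap_b = True, False
        elif y == "-":
            s += -ge if gap_b else -go
            gap_b, gap_a = True, False
        else:
            s += match if x == y else mismatch
            gap_a = gap_b = False
    return s


def brute_force_best(a, b, scoring):
    sc = scoring
    best = None
    for ra, rb in enumerate_alignments(a, b):
        s = affine_score(ra, rb, sc["match"], sc["mismatch"],
                         sc["gap_open"], sc["gap_extend"])
        if best is None or s > best[0]:
            best = (s, [(ra, rb)])
        elif s == best[0]:
            best[1].append((ra, rb))
    return best


class TestGlobalSimilarity:
    def test_identity_is_one(self):
        assert global_similarity("ACGTACGT", "ACGTACGT") == 1.0

    def test_disjoint_bases_zero(self):
        assert global_similarity("AAAA", "TTTT") == 0.0

    def test_small_case_matches_brute_force(self):
        """'ACGT' vs 'ACT' under (+1, -1, open 2, extend 1): the canonical
        optimum is ACGT / AC-T, score 1, similarity 3/4 (enumerated)."""
        scoring = {"match": 1, "mismatch": -1, "gap_open": 2, "gap_extend": 1}
        best_score, optima = brute_force_best("ACGT", "ACT", scoring)
        ra, rb, score = global_alignment("ACGT", "ACT", scoring)
        assert score == best_score == 1.0
        assert (ra, rb) in optima
        sims = {sum(1 for x, y in zip(p, q) if x == y and x != "-") / len(p)
                for p, q in optima}
        assert global_similarity("ACGT", "ACT", scoring) in sims
        assert global_similarity("ACGT", "ACT", scoring) == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_score_optimal_on_short_strings(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
        scoring = {"match": 5, "mismatch": -4, "gap_open": 10, "gap_extend": 0.5}
        best_score, optima = brute_force_best(a, b, scoring)
        ra, rb, score = global_alignment(a, b, scoring)
        assert score == pytest.approx(best_score)
        assert (ra, rb) in optima

    def test_dp_score_matches_biopython_on_random_pairs(self):
        """Independent oracle at realistic lengths: optimal affine score
        equals Bio.Align.PairwiseAligner's."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = random.Random(42)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 70)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 70)))
            _, _, score = global_alignment(a, b)
            assert score == pytest.approx(aligner.score(a, b))

    def test_symmetry_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            assert global_similarity(a, b) == pytest.approx(global_similarity(b, a))

    def test_self_similarity_is_one(self):
        rng = random.Random(1)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 60)))
            assert global_similarity(a, a) == 1.0

    def test_ambiguity_codes_do_not_match_unless_identical(self):
        assert global_similarity("NNNN", "NNNN") == 1.0
        assert global_similarity("ACGN", "ACGT") == 0.75

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            global_alignment("", "ACGT")


class TestOrient:
    def _refs(self):
        rng = random.Random(3)
        return [
            SequenceRecord(f"ref{i}",
                           "".join(rng.choice("ACGT") for _ in range(120)),
                           label="G1")
            for i in range(3)
        ]

    def test_forward_record_kept(self):
        refs = self._refs()
        rec = SequenceRecord("q", refs[0].residues)
        out, report = orient([rec], refs)
        assert out[0].residues == rec.residues
        assert report.kept == ["q"]

    def test_reverse_complement_flipped_and_involution(self):
        refs = self._refs()
        rc = SequenceRecord("q", reverse_complement(refs[0].residues))
        out, _ = orient([rc], refs)
        assert out[0].residues == refs[0].residues
        twice, _ = orient(out, refs)
        assert twice[0].residues == refs[0].residues

    def test_zero_shared_kmers_unresolved(self):
        refs = self._refs()
        rec = SequenceRecord("q", "A" * 20)
        out, report = orient([rec], refs)
        assert report.excluded == [("q", "unresolved_orientation")]

    def test_content_only_changed_by_reverse_complement(self):
        refs = self._refs()
        recs = [SequenceRecord("a", refs[1].residues),
                SequenceRecord("b", reverse_complement(refs[2].residues))]
        out, _ = orient(recs, refs)
        for rec, o in zip(recs, out):
            assert o.residues in (rec.residues, reverse_complement(rec.residues))

    def test_empty_reference_pool_rejected(self):
        with pytest.raises(InvalidInputError):
            orient([SequenceRecord("q", "ACGT")], [])

    def test_mis_oriented_references_self_correct(self, default_truth):
        """A pool containing reverse-complemented submissions converges to
        the consensus orientation (checked against simulator truth)."""
        refs = [r for r in default_truth.records if r.label != "environmental"]
        out, report = orient(default_truth.records, refs)
        kept = set(report.kept)
        for rec in out:
            flags = default_truth.artifact_table[rec.id]
            if rec.id not in kept or flags["truncated"] or flags["short"]:
                continue
            assert rec.residues == default_truth.pristine_residues[rec.id]


class TestFilterRecords:
    def _rec(self, rid, n, its2=True):
        rmap = RegionMap(its1=(0, n // 3), r58s=(n // 3, 2 * n // 3),
                         its2=(2 * n // 3, n) if its2 else None)
        return SequenceRecord(rid, "A" * n, region_map=rmap)

    def test_no_thresholds_keeps_all(self):
        recs = [self._rec("a", 30), self._rec("b", 9, its2=False)]
        report = filter_records(recs, min_length=0, require_its2=False)
        assert report.kept == ["a", "b"] and report.excluded == []

    def test_exact_min_length_kept(self):
        report = filter_records([self._rec("a", 200)], min_length=200)
        assert report.kept == ["a"]
        report = filter_records([self._rec("a", 199)], min_length=200)
        assert report.excluded == [("a", "too_short")]

    def test_truncated_records_flagged_missing_its2(self):
        from anchorlign.synthetic_data import SimConfig, simulate

        cfg = SimConfig(n_taxa=10, seed=13, n_queries=0,
                        artifact_fractions=(0.0, 0.3, 0.0))
        truth = simulate(cfg)
        report = filter_records(truth.records, min_length=0, require_its2=True)
        expected = {rid for rid, f in truth.artifact_table.items() if f["truncated"]}
        assert {rid for rid, reason in report.excluded
                if reason == "missing_its2"} == expected
        assert len(expected) == 3

    def test_partition_identity(self, default_truth):
        report = filter_records(default_truth.records, 200, True)
        ids = {r.id for r in default_truth.records}
        assert set(report.kept) | set(report.excluded_ids) == ids
        assert set(report.kept) & set(report.excluded_ids) == set()
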