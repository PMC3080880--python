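"""Data preparation: orientation correction, exclusion filters, and
Needle-style global pairwise similarity.

Similarity between two ITS sequences is defined as the number of
identically paired residues in one optimal end-to-end alignment divided by
the total alignment length, gaps included — the convention used when
screening candidate sequences with EMBOSS Needle.  Ambiguity codes only
count as matching when the two characters are literally identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _affine
from .records import (
    GAP,
    InvalidInputError,
    SequenceRecord,
    reverse_complement,
)

#: Needle-style DNA defaults: +5 match / -4 mismatch, gap open 10, extend 0.5.
DEFAULT_SCORING = {"match": 5.0, "mismatch": -4.0, "gap_open": 10.0, "gap_extend": 0.5}

DEFAULT_MIN_LENGTH = 200
DEFAULT_K = 8


@dataclass
class FilterReport:
    """Outcome of the exclusion filters: kept ids and (id, reason) pairs.

    Reasons: ``too_short``, ``missing_its2``, ``unresolved_orientation``.
    """

    kept: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [rid for rid, _ in self.excluded]

    def as_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "excluded": [{"id": rid, "reason": r} for rid, r in self.excluded],
        }


def _score_matrix(a: str, b: str, match: float, mismatch: float) -> np.ndarray:
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    eq = av[:, None] == bv[None, :]
    return np.where(eq, match, mismatch)


def global_alignment(a: str, b: str, scoring: dict | None = None) -> tuple[str, str, float]:
    """One canonical optimal global alignment of two DNA strings.

    Returns the two gapped rows and the alignment score.
    """
    if not a or not b:
        raise InvalidInputError("cannot align an empty sequence")
    sc = {**DEFAULT_SCORING, **(scoring or {})}
    S = _score_matrix(a, b, sc["match"], sc["mismatch"])
    score, ops = _affine.align_score_path(S, sc["gap_open"], sc["gap_extend"])
    ra, rb, i, j = [], [], 0, 0
    for op in ops:
        if op == _affine.DIAG:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == _affine.UP:
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb), score


def global_similarity(a: SequenceRecord | str, b: SequenceRecord | str,
                      scoring: dict | None = None) -> float:
    """Fraction of identical aligned pairs over total alignment length.

    Gap columns count toward the length but never as matches; ambiguity
    codes match only when literally identical.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    # canonical argument order: distinct optimal alignments can differ in
    # match count, so symmetry is guaranteed by fixing the orientation
    if sb < sa:
        sa, sb = sb, sa
    ra, rb, _ = global_alignment(sa, sb, scoring)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return matches / len(ra)


def similarity_matrix(records: Sequence[SequenceRecord],
                      scoring: dict | None = None) -> "pd.DataFrame":
    import pandas as pd

    ids = [r.id for r in records]
    mat = np.ones((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = global_similarity(records[i], records[j], scoring)
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Orientation correction
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def orient(records: Iterable[SequenceRecord],
           references: Sequence[SequenceRecord],
           k: int = DEFAULT_K) -> tuple[list[SequenceRecord], FilterReport]:
    """Flip records submitted in reverse-complement orientation.

    Each record is compared against the pooled reference k-mers in both
    orientations; the orientation sharing more k-mers wins.  Equal counts
    (including the zero/zero case) are unresolvable and reported.

    The reference pool may itself contain mis-oriented submissions, so the
    references are corrected first (each voting against the others, never
    against itself); all records are then judged against the corrected
    pool.
    """
    references = list(references)
    if not references:
        raise InvalidInputError("orientation vote needs at least one reference")

    # pass 1: self-consistent orientation of the reference pool.  A single
    # vote per reference is not enough — a record whose closest relatives
    # are themselves mis-oriented votes the wrong way — so orientations are
    # relaxed greedily: flip one reference at a time whenever the flip
    # strictly increases the total same-orientation k-mer sharing over all
    # reference pairs.  Every accepted flip increases that bounded total,
    # so the sweep terminates; as-submitted majority orientation is kept.
    ref_ids = [ref.id for ref in references]
    fwd_kmers = {ref.id: _kmers(ref.residues, k) for ref in references}
    rev_kmers = {ref.id: _kmers(reverse_complement(ref.residues), k)
                 for ref in references}
    # per pair: shared count with equal vs opposite orientation (flipping
    # both members of a pair leaves the shared count unchanged)
    same = {}
    opp = {}
    for i, a in enumerate(ref_ids):
        for b in ref_ids[i + 1:]:
            same[(a, b)] = same[(b, a)] = len(fwd_kmers[a] & fwd_kmers[b])
            opp[(a, b)] = opp[(b, a)] = len(fwd_kmers[a] & rev_kmers[b])
    flipped_refs: set[str] = set()
    changed = True
    while changed:
        changed = False
        for rid in ref_ids:
            gain = 0
            for other in ref_ids:
                if other == rid:
                    continue
                agree_now = (rid in flipped_refs) == (other in flipped_refs)
                cur = same[(rid, other)] if agree_now else opp[(rid, other)]
                alt = opp[(rid, other)] if agree_now else same[(rid, other)]
                gain += alt - cur
            if gain > 0:
                flipped_refs.symmetric_difference_update({rid})
                changed = True
    corrected_pool: set[str] = set()
    for rid in ref_ids:
        corrected_pool |= rev_kmers[rid] if rid in flipped_refs else fwd_kmers[rid]

    out: list[SequenceRecord] = []
    report = FilterReport()
    for rec in records:
        fwd = len(_kmers(rec.residues, k) & corrected_pool)
        rc_seq = reverse_complement(rec.residues)
        rev = len(_kmers(rc_seq, k) & corrected_pool)
        if fwd > rev:
            out.append(rec)
            report.kept.append(rec.id)
        elif rev > fwd:
            # flipping invalidates any forward-coordinate region annotation
            out.append(rec.with_residues(rc_seq, region_map=None))
            report.kept.append(rec.id)
        else:
            out.append(rec)
            report.excluded.append((rec.id, "unresolved_orientation"))
    return out, report


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------

def filter_records(records: Iterable[SequenceRecord],
                   min_length: int = DEFAULT_MIN_LENGTH,
                   require_its2: bool = False) -> FilterReport:
    """Exclude records strictly shorter than ``min_length`` and, optionally,
    records whose region map lacks an ITS2 interval.  Order-preserving."""
    report = FilterReport()
    for rec in records:
        if len(rec) < min_length:
            report.excluded.append((rec.id, "too_short"))
        elif require_its2 and (rec.region_map is None or rec.region_map.its2 is None):
            report.excluded.append((rec.id, "missing_its2"))
        else:
            report.kept.append(rec.id)
    return report


def apply_filter(records: Sequence[SequenceRecord], report: FilterReport) -> list[SequenceRecord]:
    kept = set(report.kept)
    return [r for r in records if r.id in kept]
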