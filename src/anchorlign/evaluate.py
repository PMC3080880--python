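"""Alignment and tree quality metrics.

Column classification follows the parsimony bookkeeping conventional in
alignment summaries: over the unambiguous, non-gap residues of a column,
a column is *constant* when exactly one state is present (in at least two
sequences), *parsimony-informative* when at least two states are each
present in at least two sequences, *parsimony-uninformative* when variable
but not informative, and *other* when fewer than two scorable residues
remain.  Gaps and ambiguity codes are treated as missing throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

from . import trees
from .coestimate import encode_msa
from .records import GAP, InvalidInputError, Msa

DEFAULT_LONG_BRANCH_FACTOR = 5.0


@dataclass(frozen=True)
class ColumnClasses:
    n_total: int
    n_constant: int
    n_pars_uninformative: int
    n_pars_informative: int
    n_other: int

    def __post_init__(self) -> None:
        parts = (self.n_constant + self.n_pars_uninformative
                 + self.n_pars_informative + self.n_other)
        if parts != self.n_total:
            raise AssertionError("column classes do not partition the columns")

    @property
    def informative_percent(self) -> int:
        """Percentage of informative columns, rounded half away from zero."""
        if self.n_total == 0:
            return 0
        return int(math.floor(100.0 * self.n_pars_informative / self.n_total + 0.5))

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_constant": self.n_constant,
            "n_pars_uninformative": self.n_pars_uninformative,
            "n_pars_informative": self.n_pars_informative,
            "n_other": self.n_other,
            "informative_percent": self.informative_percent,
        }


def classify_columns(msa: Msa) -> ColumnClasses:
    if len(msa) == 0 or msa.ncol == 0:
        raise InvalidInputError("empty alignment")
    arr = encode_msa(msa)  # -1 for gap/ambiguity
    n_constant = n_uninf = n_inf = n_other = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        col = col[col >= 0]
        if col.size < 2:
            n_other += 1
            continue
        counts = np.bincount(col, minlength=4)
        states = int((counts > 0).sum())
        if states == 1:
            n_constant += 1
        elif int((counts >= 2).sum()) >= 2:
            n_inf += 1
        else:
            n_uninf += 1
    return ColumnClasses(arr.shape[1], n_constant, n_uninf, n_inf, n_other)


# ---------------------------------------------------------------------------
# Tree metrics
# ---------------------------------------------------------------------------

def monophyly(tree: dendropy.Tree, group: Iterable[str]) -> tuple[bool, float | None]:
    """Is the group one side of some edge's bipartition (unrooted sense)?

    Returns the defining edge's support when the group is monophyletic and
    the edge carries one.  Singleton groups and complements of clades are
    monophyletic by convention.
    """
    group = frozenset(group)
    all_leaves = frozenset(trees.leaf_ids(tree))
    if not group <= all_leaves:
        raise InvalidInputError("group is not a subset of the tree leaves")
    if not (1 <= len(group) < len(all_leaves)):
        raise InvalidInputError("group must be a proper non-empty leaf subset")
    if len(group) == 1 or len(group) == len(all_leaves) - 1:
        return True, None  # terminal edge bipartition
    bips = trees.bipartitions(tree)
    key = trees.canonical_side(group, all_leaves)
    if key in bips:
        return True, bips[key]
    return False, None


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Robinson-Foulds: symmetric difference of internal bipartition sets,
    and its normalisation by 2(n-3)."""
    l1, l2 = set(trees.leaf_ids(t1)), set(trees.leaf_ids(t2))
    if l1 != l2:
        raise InvalidInputError("trees have different leaf sets")
    b1 = set(trees.bipartitions(t1))
    b2 = set(trees.bipartitions(t2))
    count = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    return count, (count / denom if denom > 0 else 0.0)


def long_branches(tree: dendropy.Tree,
                  factor: float = DEFAULT_LONG_BRANCH_FACTOR) -> list[str]:
    """Leaves whose terminal branch is strictly longer than
    ``factor`` x the median terminal branch length."""
    lengths = {}
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise InvalidInputError("tree lacks branch lengths")
        lengths[leaf.taxon.label] = leaf.edge.length
    med = float(np.median(list(lengths.values())))
    return sorted(rid for rid, ln in lengths.items() if ln > factor * med)


def supported_fraction(tree: dendropy.Tree, threshold: float) -> float:
    """Proportion of internal edges with support strictly above threshold."""
    bips = trees.bipartitions(tree)
    if not bips:
        return 0.0
    good = sum(1 for s in bips.values() if s is not None and s > threshold)
    return good / len(bips)


# ---------------------------------------------------------------------------
# Alignment accuracy against simulated truth
# ---------------------------------------------------------------------------

def _residue_columns(msa: Msa) -> dict[str, np.ndarray]:
    """Per row: array mapping residue index -> alignment column."""
    out = {}
    for rid, row in msa.rows.items():
        out[rid] = np.flatnonzero(np.frombuffer(row.encode(), np.uint8) != ord(GAP))
    return out


def alignment_accuracy(estimated: Msa, truth: Msa) -> tuple[float, float]:
    """(sum-of-pairs score, column score) of an estimate against the truth.

    sp_score: fraction of the truth's homologous residue pairs that the
    estimate reproduces.  column_score: fraction of truth columns whose
    full residue content is reproduced as an identical estimate column.
    """
    if set(estimated.rows) != set(truth.rows):
        raise InvalidInputError("alignments have different row sets")
    for rid in truth.rows:
        if estimated.degap(rid) != truth.degap(rid):
            raise InvalidInputError(f"row {rid!r} differs in ungapped content")

    ids = sorted(truth.rows)
    true_cols = _residue_columns(truth)
    est_cols = _residue_columns(estimated)

    # residue-index occupancy per truth column: pos[i][j] = residue index of
    # row i at truth column j, or -1
    def occupancy(msa: Msa, cols: Mapping[str, np.ndarray]) -> np.ndarray:
        occ = np.full((len(ids), msa.ncol), -1, dtype=np.int64)
        for i, rid in enumerate(ids):
            occ[i, cols[rid]] = np.arange(cols[rid].size)
        return occ

    occ_t = occupancy(truth, true_cols)

    total_pairs = reproduced = 0
    for i in range(len(ids)):
        for k in range(i + 1, len(ids)):
            both = (occ_t[i] >= 0) & (occ_t[k] >= 0)
            ri, rk = occ_t[i][both], occ_t[k][both]
            total_pairs += int(both.sum())
            # a pair is reproduced when the two residues share a column in
            # the estimate as well
            same = est_cols[ids[i]][ri] == est_cols[ids[k]][rk]
            reproduced += int(same.sum())
    sp = reproduced / total_pairs if total_pairs else 1.0

    # column score via signatures: residue index per row, -1 for gap
    occ_e = occupancy(estimated, est_cols)
    est_signatures = {tuple(occ_e[:, j]) for j in range(estimated.ncol)}
    hit = sum(1 for j in range(truth.ncol) if tuple(occ_t[:, j]) in est_signatures)
    cs = hit / truth.ncol if truth.ncol else 1.0
    return sp, cs
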