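"""Iterative alignment/tree co-estimation.

The loop alternates guide-tree construction, progressive profile
alignment, distance-based tree re-estimation and likelihood scoring,
keeping the best-scored (alignment, tree) pair across independent runs.
This is a desk-scale analogue of simultaneous alignment and tree
estimation: the iteration feeds each new tree back in as the next guide,
but there is no divide-and-conquer decomposition — the previous alignment
influences the next one only through the re-estimated tree.

Components
----------
* ``kmer_distance_matrix`` — alignment-free starting distances;
* ``nj`` — neighbor-joining with a deterministic tie rule;
* ``progressive_align`` — guide-tree progressive profile-profile
  alignment under affine gap penalties ("once a gap, always a gap");
* ``score_alignment_tree`` — Felsenstein pruning log-likelihood under
  Jukes-Cantor with gaps as missing data (the selection criterion);
* ``coestimate`` — the multi-run loop with a full score trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import _affine, trees
from .records import GAP, InvalidInputError, Msa, SequenceRecord
from .seqprep import DEFAULT_SCORING

logger = logging.getLogger(__name__)

DEFAULT_K = 8
#: saturation guard for the Jukes-Cantor distance transform
DEFAULT_D_MAX = 5.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def kmer_distance_matrix(records: Sequence[SequenceRecord],
                         k: int = DEFAULT_K) -> pd.DataFrame:
    """1 - shared-kmer fraction, normalised by the smaller k-mer set."""
    if len(records) < 3:
        raise InvalidInputError("need >= 3 records for a distance matrix")
    sets = []
    for rec in records:
        if len(rec.residues) < k:
            logger.warning("sequence %s shorter than k=%d", rec.id, k)
            sets.append(set())
        else:
            sets.append({rec.residues[i:i + k] for i in range(len(rec.residues) - k + 1)})
    ids = [r.id for r in records]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            if denom == 0:
                d = 1.0
            else:
                d = 1.0 - len(sets[i] & sets[j]) / denom
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def encode_msa(msa: Msa) -> np.ndarray:
    """Alignment as int8 matrix: A..T -> 0..3, gap/ambiguity -> -1."""
    arr = np.full((len(msa), msa.ncol), -1, dtype=np.int8)
    for i, row in enumerate(msa.rows.values()):
        codes = np.frombuffer(row.encode(), dtype=np.uint8)
        for base, idx in _BASE_INDEX.items():
            arr[i][codes == ord(base)] = idx
    return arr


def jc_distance_matrix(msa: Msa, d_max: float = DEFAULT_D_MAX) -> pd.DataFrame:
    """Jukes-Cantor distances with pairwise gap deletion.

    d = -(3/4) ln(1 - (4/3) p) with p the proportion of differing
    ungapped pairs; saturated pairs (p >= 0.75) are capped at ``d_max``.
    """
    arr = encode_msa(msa)
    ids = msa.ids
    n = len(ids)
    valid = arr >= 0
    mat = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (arr[i] != arr[i + 1:]) & both
        counts = both.sum(axis=1)
        p = np.where(counts > 0, diff.sum(axis=1) / np.maximum(counts, 1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        d = np.where((p >= 0.75) | ~np.isfinite(d) | (counts == 0), d_max, d)
        mat[i, i + 1:] = mat[i + 1:, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj(matrix: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining with deterministic tie-breaking.

    On Q-score ties the join with the lexicographically smallest (sorted)
    id pair is taken; negative branch lengths are clamped to zero.
    """
    if not np.allclose(matrix.values, matrix.values.T):
        raise InvalidInputError("distance matrix must be symmetric")
    ids = list(matrix.index)
    if len(ids) < 3:
        raise InvalidInputError("neighbor joining needs >= 3 taxa")

    D = matrix.values.astype(float).copy()
    taxon_ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    names: list[str] = []
    for rid in ids:
        taxon = taxon_ns.new_taxon(rid)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
        names.append(rid)

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (n - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # all index pairs achieving the minimum (tolerance for float noise)
        cand = np.argwhere(Q <= qmin + 1e-12)
        pairs = sorted(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = pairs[0]
        vi = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = vi
        parent.add_child(nodes[j]); nodes[j].edge.length = vj
        new_name = min(names[i], names[j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [new_name]

    # the agglomeration always terminates with exactly three subtrees;
    # their pendant lengths follow the three-point formulas
    root = dendropy.Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = (
        max(0.0, 0.5 * (d01 + d02 - d12)),
        max(0.0, 0.5 * (d01 + d12 - d02)),
        max(0.0, 0.5 * (d02 + d12 - d01)),
    )
    for nd, ln in zip(nodes, lens):
        root.add_child(nd)
        nd.edge.length = ln

    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Progressive profile alignment
# ---------------------------------------------------------------------------

def _profile(sub: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base frequencies (over A,C,G,T) and non-gap weights."""
    arr = encode_msa(sub)
    ncol = arr.shape[1]
    freq = np.zeros((ncol, 4))
    for b in range(4):
        freq[:, b] = (arr == b).sum(axis=0)
    nres = freq.sum(axis=1)
    weight = nres / arr.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.where(nres[:, None] > 0, freq / np.maximum(nres, 1)[:, None], 0.0)
    return freq, weight


def _merge(a: Msa, b: Msa, sc: dict) -> Msa:
    fa, _ = _profile(a)
    fb, _ = _profile(b)
    M = np.full((4, 4), sc["mismatch"])
    np.fill_diagonal(M, sc["match"])
    # expected pair score over the residues present; gaps carry no mass, so
    # a conserved column keeps its full match reward however gappy the rows
    S = fa @ M @ fb.T
    _, ops = _affine.align_score_path(S, sc["gap_open"], sc["gap_extend"])
    rows_a = {rid: [] for rid in a.rows}
    rows_b = {rid: [] for rid in b.rows}
    i = j = 0
    for op in ops:
        if op == _affine.DIAG:
            for rid in rows_a:
                rows_a[rid].append(a.rows[rid][i])
            for rid in rows_b:
                rows_b[rid].append(b.rows[rid][j])
            i += 1; j += 1
        elif op == _affine.UP:
            for rid in rows_a:
                rows_a[rid].append(a.rows[rid][i])
            for rid in rows_b:
                rows_b[rid].append(GAP)
            i += 1
        else:
            for rid in rows_a:
                rows_a[rid].append(GAP)
            for rid in rows_b:
                rows_b[rid].append(b.rows[rid][j])
            j += 1
    merged = {rid: "".join(chars) for rid, chars in {**rows_a, **rows_b}.items()}
    return Msa(merged)


def progressive_align(records: Sequence[SequenceRecord],
                      guide: dendropy.Tree,
                      scoring: dict | None = None) -> Msa:
    """Align leaves pairwise then profile-profile up the guide topology.

    Gap characters are treated as absent mass during profile scoring, and
    gaps introduced at one merge are never removed later ("once a gap,
    always a gap").
    """
    sc = {**DEFAULT_SCORING, **(scoring or {})}
    by_id = {r.id: r for r in records}
    guide_ids = set(trees.leaf_ids(guide))
    if guide_ids != set(by_id):
        raise InvalidInputError("guide tree leaves do not match record ids")
    if len(records) == 1:
        rec = records[0]
        return Msa({rec.id: rec.residues})

    # merge in postorder over a (possibly multifurcating) rooted view
    def build(node) -> Msa:
        if node.is_leaf():
            rid = node.taxon.label
            return Msa({rid: by_id[rid].residues})
        children = [build(ch) for ch in node.child_nodes()]
        acc = children[0]
        for nxt in children[1:]:
            acc = _merge(acc, nxt, sc)
        return acc

    msa = build(guide.seed_node)
    # restore input record order
    order = [r.id for r in records]
    return Msa({rid: msa.rows[rid] for rid in order})


# ---------------------------------------------------------------------------
# Likelihood scoring
# ---------------------------------------------------------------------------

def score_alignment_tree(msa: Msa, tree: dendropy.Tree) -> float:
    """Felsenstein pruning log-likelihood under Jukes-Cantor.

    Columns are independent; gaps and ambiguity codes are missing data
    (partial likelihood 1 for every state); all-gap columns contribute 0.
    Root frequencies are the JC stationary 1/4.
    """
    tree_ids = set(trees.leaf_ids(tree))
    if tree_ids != set(msa.ids):
        raise InvalidInputError("tree leaves do not match alignment rows")
    arr = encode_msa(msa)
    row_of = {rid: k for k, rid in enumerate(msa.ids)}
    ncol = msa.ncol

    def transition(d: float) -> np.ndarray:
        if d is None:
            d = 0.0
        if d < 0:
            raise InvalidInputError("negative branch length")
        same = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
        diff = (1.0 - same) / 3.0
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P

    def partials(node) -> np.ndarray:
        if node.is_leaf():
            states = arr[row_of[node.taxon.label]]
            L = np.ones((ncol, 4))
            known = states >= 0
            L[known] = 0.0
            L[known, states[known]] = 1.0
            return L
        L = np.ones((ncol, 4))
        for child in node.child_nodes():
            P = transition(child.edge.length)
            L *= partials(child) @ P.T
        return L

    root_L = partials(tree.seed_node)
    site = 0.25 * root_L.sum(axis=1)
    with np.errstate(divide="ignore"):
        logs = np.log(site)
    # all-gap columns have site likelihood exactly 1 under missing-data
    # convention; guard anyway against degenerate zeros
    logs[~np.isfinite(logs)] = 0.0
    return float(logs.sum())


# ---------------------------------------------------------------------------
# The co-estimation loop
# ---------------------------------------------------------------------------

@dataclass
class CoestimationTrace:
    """Score trajectory plus the globally best-scored (alignment, tree)."""

    scores: list[tuple[int, int, float]] = field(default_factory=list)  # run, iter, score
    best_run: int = -1
    best_iteration: int = -1
    best_score: float = -math.inf
    best_msa: Msa | None = None
    best_tree: dendropy.Tree | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=["run", "iteration", "score"])


def coestimate(records: Sequence[SequenceRecord],
               runs: int = 6,
               iterations: int = 20,
               seed: int = 0,
               scoring: dict | None = None,
               k: int = DEFAULT_K,
               noise: float = 0.05,
               d_max: float = DEFAULT_D_MAX) -> CoestimationTrace:
    """Multi-run iterative co-estimation.

    Run 0 starts from the plain k-mer distance guide tree (so a single run
    of a single iteration reproduces the one-pass baseline); later runs
    perturb the starting distances with seeded multiplicative noise
    (+/- ``noise``) to emulate independent search trajectories.
    """
    if runs < 1 or iterations < 1:
        raise InvalidInputError("runs and iterations must be >= 1")
    base_dist = kmer_distance_matrix(records, k=k)
    trace = CoestimationTrace()
    for run in range(runs):
        dist = base_dist.copy()
        if run > 0:
            rng = np.random.default_rng(seed + 1000 * run)
            n = dist.shape[0]
            pert = rng.uniform(1.0 - noise, 1.0 + noise, size=(n, n))
            pert = np.triu(pert, 1)
            pert = pert + pert.T + np.eye(n)
            dist = dist * pert
        guide = nj(dist)
        for it in range(iterations):
            msa = progressive_align(records, guide, scoring)
            tree = nj(jc_distance_matrix(msa, d_max=d_max))
            score = score_alignment_tree(msa, tree)
            trace.scores.append((run, it, score))
            if score > trace.best_score:
                trace.best_score = score
                trace.best_run, trace.best_iteration = run, it
                trace.best_msa, trace.best_tree = msa, tree
            guide = tree
    logger.info("co-estimation best score %.3f at run %d iteration %d",
                trace.best_score, trace.best_run, trace.best_iteration)
    return trace
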