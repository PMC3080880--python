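"""Branch support by column bootstrap, and majority-rule consensus.

Support is the frequency of each internal bipartition of the point
estimate among trees rebuilt from column-resampled alignments (distance
trees under Jukes-Cantor).  The support slot and every decision rule
downstream are estimator-agnostic: the conventional "significantly
supported" threshold of 0.94 is carried in configuration and any other
clade-support estimator could fill the same slot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import trees
from .coestimate import jc_distance_matrix, nj
from .records import InvalidInputError, Msa

logger = logging.getLogger(__name__)

#: support above this is conventionally reported as significant
DEFAULT_SUPPORT_THRESHOLD = 0.94
STRICT_SUPPORT_THRESHOLD = 0.95


@dataclass
class BipartitionTable:
    """Canonical bipartition -> frequency among replicate trees."""

    frequencies: dict[frozenset, float] = field(default_factory=dict)
    n_replicates: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"bipartition": "|".join(sorted(side)), "frequency": f}
            for side, f in sorted(
                self.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["bipartition", "frequency"])


def _resample_columns(msa: Msa, rng: np.random.Generator) -> Msa:
    cols = rng.integers(0, msa.ncol, size=msa.ncol)
    rows = {}
    for rid, row in msa.rows.items():
        rows[rid] = "".join(row[j] for j in cols)
    return Msa(rows)


def bootstrap_support(msa: Msa, n_replicates: int = 100, seed: int = 0,
                      d_max: float | None = None) -> tuple[dendropy.Tree, BipartitionTable]:
    """Point-estimate distance tree with bootstrap bipartition support.

    Resamples alignment columns with replacement, rebuilds a tree per
    replicate, and writes each internal edge's replicate frequency onto
    the point-estimate tree.  Reproducible from the seed.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    kwargs = {} if d_max is None else {"d_max": d_max}
    point = nj(jc_distance_matrix(msa, **kwargs))
    if len(msa) < 4:
        logger.warning("fewer than 4 taxa: no internal edges to support")
        return point, BipartitionTable({}, n_replicates)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        rep = _resample_columns(msa, rng)
        # resampling may produce an all-gap row for sparse alignments; such
        # replicates still carry distance information for the other rows,
        # so gapped-out rows keep a saturated distance rather than failing
        try:
            rep_tree = nj(jc_distance_matrix(rep, **kwargs))
        except InvalidInputError:
            continue
        for side in trees.bipartitions(rep_tree):
            counts[side] = counts.get(side, 0) + 1

    table = BipartitionTable(
        {side: c / n_replicates for side, c in counts.items()}, n_replicates
    )
    point_bips = trees.bipartitions(point)
    trees.annotate_support(
        point, {side: table.frequencies.get(side, 0.0) for side in point_bips}
    )
    return point, table


def majority_consensus(tree_list: Sequence[dendropy.Tree],
                       threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: exactly the bipartitions with frequency
    strictly above ``threshold`` (>= 0.5, which guarantees compatibility).

    Internal node labels carry the bipartition frequencies; polytomies are
    left unresolved.
    """
    if not tree_list:
        raise InvalidInputError("need at least one tree")
    if threshold < 0.5:
        raise InvalidInputError("threshold below 0.5 may yield incompatible splits")
    leafsets = {frozenset(trees.leaf_ids(t)) for t in tree_list}
    if len(leafsets) != 1:
        raise InvalidInputError("trees have different leaf sets")
    all_leaves = leafsets.pop()

    counts: dict[frozenset, int] = {}
    for t in tree_list:
        for side in trees.bipartitions(t):
            counts[side] = counts.get(side, 0) + 1
    n = len(tree_list)
    majority = {
        side: c / n for side, c in counts.items() if c / n > threshold
    }

    # build by clade nesting: each retained bipartition, taken as the side
    # away from the anchor leaf, is a clade in the anchor-rooted view
    taxon_ns = dendropy.TaxonNamespace()
    node_of: dict[str, dendropy.Node] = {}
    root = dendropy.Node()
    for rid in sorted(all_leaves):
        taxon = taxon_ns.new_taxon(rid)
        node_of[rid] = dendropy.Node(taxon=taxon)
        root.add_child(node_of[rid])
        node_of[rid].edge.length = 1.0

    # insert largest first so smaller clades attach inside them
    for side, freq in sorted(majority.items(), key=lambda kv: -len(kv[0])):
        # find current parents of the clade members; all must share one parent
        # when processed largest-first (splits are mutually compatible)
        members = set(side)
        child_map: dict[dendropy.Node, list[dendropy.Node]] = {}
        for node in root.preorder_iter():
            inside = [
                ch for ch in node.child_nodes()
                if {lf.taxon.label for lf in ch.leaf_iter()} <= members
            ]
            covered = set()
            for ch in inside:
                covered |= {lf.taxon.label for lf in ch.leaf_iter()}
            if covered == members and len(inside) >= 2:
                child_map[node] = inside
                break
        if not child_map:
            continue  # nested inside an equal clade already present
        parent, children = next(iter(child_map.items()))
        clade = dendropy.Node()
        clade.label = f"{freq:.3f}"
        clade.edge.length = 1.0
        for ch in children:
            parent.remove_child(ch)
            clade.add_child(ch)
        parent.add_child(clade)

    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = False
    return tree
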