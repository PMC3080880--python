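"""Support-aware assignment of unlabeled query sequences to reference groups.

Each query leaf is walked from the tip toward the root of a midpoint-rooted
copy of the support-annotated tree.  The first enclosing clade whose
subtending edge is supported above the threshold and which contains at
least one labelled reference decides: if all its references carry one
label, the query is assigned that label; if labels are mixed, the walk
continues outward; if the walk ends without a uniformly labelled supported
clade, the query stays unassigned with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from . import trees
from .records import ENVIRONMENTAL, InvalidInputError
from .support import DEFAULT_SUPPORT_THRESHOLD

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Assignment:
    query_id: str
    group: str                      # group name or "unassigned"
    support: float | None           # support of the defining clade
    clade_size: int
    reference_ids: tuple[str, ...]  # references inside the defining clade
    reason: str | None = None       # set only when unassigned

    @property
    def assigned(self) -> bool:
        return self.group != UNASSIGNED


def assign_queries(tree: dendropy.Tree,
                   labels: Mapping[str, str],
                   threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                   outgroup: Sequence[str] | None = None) -> list[Assignment]:
    """Assign every query leaf (absent from ``labels`` or labelled
    environmental) to a reference group, walking tip-to-root.

    Rooting is at the midpoint by default; pass ``outgroup`` leaf ids to
    root on their stem instead.  Deterministic for a given tree.
    """
    leaf_set = set(trees.leaf_ids(tree))
    references = {
        rid: grp for rid, grp in labels.items()
        if grp != ENVIRONMENTAL and rid in leaf_set
    }
    if not references:
        raise InvalidInputError("need at least one labelled reference in the tree")
    queries = sorted(leaf_set - set(references))

    # support lives on unrooted bipartitions; capture it before rerooting
    bip_support = trees.bipartitions(tree)
    all_leaves = frozenset(leaf_set)

    if outgroup:
        rooted = tree.clone(depth=1)
        og = set(outgroup)
        if not og <= leaf_set:
            raise InvalidInputError("outgroup ids not in tree")
        mrca = rooted.mrca(taxon_labels=sorted(og))
        if mrca.edge.length is not None and mrca.parent_node is not None:
            rooted.reroot_at_edge(mrca.edge, update_bipartitions=False)
    else:
        rooted = trees.midpoint_rooted(tree)

    leaf_nodes = {lf.taxon.label: lf for lf in rooted.leaf_node_iter()}
    out: list[Assignment] = []
    for qid in queries:
        if qid not in leaf_nodes:
            raise InvalidInputError(f"query {qid!r} is not a tree leaf")
        node = leaf_nodes[qid].parent_node
        result: Assignment | None = None
        saw_supported = False
        while node is not None:
            clade = {lf.taxon.label for lf in node.leaf_iter()}
            if node.parent_node is None or len(clade) < 2 or len(all_leaves) - len(clade) < 2:
                sup = None  # root or trivial bipartition: no support defined
            else:
                sup = bip_support.get(trees.canonical_side(clade, all_leaves))
            if sup is not None and sup > threshold:
                refs_inside = sorted(r for r in clade if r in references)
                if refs_inside:
                    saw_supported = True
                    groups = {references[r] for r in refs_inside}
                    if len(groups) == 1:
                        result = Assignment(
                            qid, groups.pop(), sup, len(clade), tuple(refs_inside)
                        )
                        break
                    # mixed labels: keep walking outward
            node = node.parent_node
        if result is None:
            reason = "mixed labels at all levels" if saw_supported else "no supported clade"
            result = Assignment(qid, UNASSIGNED, None, 0, (), reason=reason)
        out.append(result)
    return out


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "group": a.group,
                "support": a.support,
                "clade_size": a.clade_size,
                "reference_ids": ",".join(a.reference_ids),
                "reason": a.reason or "",
            }
            for a in assignments
        ],
        columns=["query_id", "group", "support", "clade_size", "reference_ids", "reason"],
    )


def assignment_accuracy(assignments: Sequence[Assignment],
                        true_groups: Mapping[str, str]) -> float | None:
    """Fraction of assigned queries whose group matches the truth.

    Returns None when no query received an assignment.
    """
    assigned = [a for a in assignments if a.assigned]
    if not assigned:
        return None
    hits = sum(1 for a in assigned if true_groups.get(a.query_id) == a.group)
    return hits / len(assigned)
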