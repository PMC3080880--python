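"""Tree utilities shared across modules.

Trees are held as :class:`dendropy.Tree` objects.  Bipartitions are
represented as canonical frozensets of leaf ids: for an unrooted tree on
leaf set L, each internal edge splits L into two sides; the canonical side
is the one *not* containing the lexicographically smallest leaf id.  Only
non-trivial bipartitions (both sides of size >= 2) are reported.

Branch support values live in ``node.label`` (the conventional Newick slot
for support on the subtending edge of an internal node).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

Bipartition = frozenset


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def leaf_ids(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _clade_leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def canonical_side(side: Iterable[str], all_leaves: frozenset) -> Bipartition:
    side = frozenset(side)
    anchor = min(all_leaves)
    return frozenset(all_leaves - side) if anchor in side else side


def bipartitions(tree: dendropy.Tree) -> dict[Bipartition, float | None]:
    """Canonical non-trivial bipartitions -> support (None when absent).

    Works on the tree as an unrooted object: for a rooted binary tree the
    two root-child edges induce the same bipartition; the supported one
    (if any) wins.
    """
    all_leaves = frozenset(leaf_ids(tree))
    n = len(all_leaves)
    out: dict[Bipartition, float | None] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _clade_leafset(node)
        if len(side) < 2 or n - len(side) < 2:
            continue
        key = canonical_side(side, all_leaves)
        sup = None
        if node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        if key not in out or (out[key] is None and sup is not None):
            out[key] = sup
    return out


def annotate_support(tree: dendropy.Tree,
                     table: Mapping[Bipartition, float]) -> None:
    """Write support values from a bipartition table onto internal nodes."""
    all_leaves = frozenset(leaf_ids(tree))
    n = len(all_leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _clade_leafset(node)
        if len(side) < 2 or n - len(side) < 2:
            continue
        key = canonical_side(side, all_leaves)
        if key in table:
            node.label = f"{table[key]:.3f}"


def midpoint_rooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-leaf path.

    Implemented directly (double traversal for the diameter, then a walk to
    the midpoint) because the midpoint can fall exactly on an internal
    node, a case the library rerooting does not handle.
    """
    t = tree.clone(depth=1)
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda tx: tx.label)
    # diameter endpoints
    u = max(taxa, key=lambda tx: max(pdm.distance(tx, o) for o in taxa))
    v = max(taxa, key=lambda tx: pdm.distance(u, tx))
    diameter = pdm.distance(u, v)
    if diameter <= 1e-12:
        return t  # all distances vanish: any rooting is a midpoint rooting
    # walk from u's leaf up toward the root, then down to v, tracking the
    # path; simpler: collect the u->v path via node ancestors
    node_u = next(lf for lf in t.leaf_node_iter() if lf.taxon is u)
    node_v = next(lf for lf in t.leaf_node_iter() if lf.taxon is v)
    anc_u = []
    n = node_u
    while n is not None:
        anc_u.append(n)
        n = n.parent_node
    anc_v_set = set()
    n = node_v
    path_v = []
    while n is not None:
        path_v.append(n)
        anc_v_set.add(n)
        n = n.parent_node
    mrca = next(n for n in anc_u if n in anc_v_set)
    path = anc_u[: anc_u.index(mrca) + 1] + list(
        reversed(path_v[: path_v.index(mrca)])
    )
    # walk along the path from u, find where cumulative length passes D/2
    half = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        edge = a.edge if a.parent_node is b else b.edge
        ln = edge.length or 0.0
        if acc + ln >= half - 1e-12:
            into = half - acc  # distance from a along this edge
            if a.parent_node is b:  # walking rootward over a's edge
                child, dist_from_child = a, into
            else:  # walking tipward over b's edge
                child, dist_from_child = b, ln - into
            if dist_from_child <= 1e-12 and not child.is_leaf():
                # midpoint exactly on an internal node
                t.reroot_at_node(child, update_bipartitions=False)
            else:
                t.reroot_at_edge(
                    child.edge,
                    length1=max((child.edge.length or 0.0) - dist_from_child, 0.0),
                    length2=dist_from_child,
                    update_bipartitions=False,
                )
            return t
        acc += ln
    t.reroot_at_node(path[-1], update_bipartitions=False)
    return t


def restrict_to(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Copy of the tree pruned down to the given leaf ids."""
    keep = set(keep)
    t = tree.clone(depth=1)
    taxa = [tx for tx in t.taxon_namespace if tx.label in keep]
    t.retain_taxa(taxa)
    return t
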