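"""Synthetic ITS evolution: known tree, known alignment, known regions.

Generates datasets that mimic the statistical structure of fungal ITS
collections spanning several genera or classes: a slowly evolving ~160 nt
5.8S core flanked by fast-evolving, indel-rich ITS1 and ITS2 spacers, with
occasional database-style artifacts (reverse-complemented submissions,
records truncated before the ITS2, fragments below a usable length).

The generator is the truth source for every downstream benchmark: it
returns the true tree, the true (gap-propagated) alignment, per-record
region annotations, taxonomic group labels, and an artifact table.

Model summary
-------------
* topology: Yule (pure-birth) tree, rescaled so the root-to-tip height
  equals ``depth_scale`` expected substitutions/site at the 5.8S rate;
* substitutions: Jukes-Cantor per branch, with per-region rate
  multipliers (5.8S normalised to 1);
* indels: Poisson number of events per branch and region with rate
  ``indel_rate * region_length * branch_length``, geometric lengths,
  insertion/deletion equiprobable, no indels in the 5.8S by default;
* labels: leaves are partitioned into ``n_groups`` clade-defined groups
  ("genera"); ``n_queries`` leaves are masked as "environmental".

Default calibration targets the empirical regime of congeneric and
intergeneric ITS comparisons: whole-ITS pairwise similarity mostly in the
50-70% band between groups, i.e. generally below 70%.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
from dendropy.simulate import treesim

from . import trees
from .records import (
    ENVIRONMENTAL,
    InvalidInputError,
    Msa,
    RegionMap,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_msa_fasta,
    write_regions_tsv,
    dump_json,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults define the package's standard study.

    ``depth_scale`` is the tree height in expected substitutions/site at
    the 5.8S (slow) rate; flank regions evolve ``rate_multipliers`` times
    faster.  ``artifact_fractions`` are the fractions of records to
    reverse-complement, truncate (drop ITS2) and shorten below a usable
    length, in that order.
    """

    n_taxa: int = 32
    tree_model: str = "yule"
    birth_rate: float = 1.0
    depth_scale: float = 0.06
    region_lengths: tuple[int, int, int] = (180, 160, 180)  # ITS1, 5.8S, ITS2
    rate_multipliers: tuple[float, float, float] = (8.0, 1.0, 8.0)
    indel_rate: tuple[float, float, float] = (0.10, 0.0, 0.10)
    indel_length_mean: float = 3.0
    n_groups: int = 4
    n_queries: int = 8
    query_branch_multiplier: float = 1.0
    artifact_fractions: tuple[float, float, float] = (0.10, 0.05, 0.05)
    short_length: int = 150
    chimera_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise InvalidInputError("n_taxa must be >= 3")
        if self.tree_model != "yule":
            raise InvalidInputError(f"unknown tree model {self.tree_model!r}")
        if self.rate_multipliers[1] != 1.0 and any(self.rate_multipliers):
            # 5.8S is the unit rate; the all-zero vector is the no-change limit
            raise InvalidInputError("5.8S rate multiplier is the unit rate (must be 1)")
        for name in ("birth_rate", "depth_scale", "indel_length_mean",
                     "query_branch_multiplier", "chimera_fraction"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if any(v < 0 for v in self.rate_multipliers + self.indel_rate):
            raise InvalidInputError("rates must be >= 0")
        if any(v <= 0 for v in self.region_lengths):
            raise InvalidInputError("region lengths must be > 0")
        if any(not (0 <= f <= 1) for f in self.artifact_fractions):
            raise InvalidInputError("artifact fractions must be in [0, 1]")
        if not (0 <= self.n_queries <= self.n_taxa):
            raise InvalidInputError("n_queries must be in [0, n_taxa]")
        if self.n_groups < 1:
            raise InvalidInputError("n_groups must be >= 1")


@dataclass
class SimTruth:
    """Ground truth bundle for one simulated dataset."""

    config: SimConfig
    true_tree: dendropy.Tree
    true_alignment: Msa
    records: list[SequenceRecord]
    group_labels: dict[str, str]          # id -> true group (queries included)
    artifact_table: dict[str, dict[str, bool]]
    pristine_residues: dict[str, str] = field(default_factory=dict)
    pristine_region_maps: dict[str, RegionMap] = field(default_factory=dict)

    @property
    def query_ids(self) -> list[str]:
        return [r.id for r in self.records if r.label == ENVIRONMENTAL]

    @property
    def region_maps(self) -> dict[str, RegionMap]:
        return {r.id: r.region_map for r in self.records if r.region_map is not None}

    def serialize(self) -> str:
        """Deterministic text serialization (for reproducibility checks)."""
        payload = {
            "config": dataclasses.asdict(self.config),
            "tree": trees.to_newick(self.true_tree),
            "alignment": self.true_alignment.rows,
            "records": {r.id: [r.residues, r.label] for r in self.records},
            "groups": self.group_labels,
            "artifacts": self.artifact_table,
        }
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# Tree sampling
# ---------------------------------------------------------------------------

def sample_tree(cfg: SimConfig) -> dendropy.Tree:
    """Yule tree with ``n_taxa`` leaves, height rescaled to ``depth_scale``.

    Leaf ids are "t0001"... assigned in a fixed traversal order; strictly
    positive branch lengths; byte-identical Newick for identical config.
    """
    rng = random.Random(cfg.seed)
    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_taxa, rng=rng,
    )
    tree.seed_node.edge.length = 0.0
    height = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    scale = cfg.depth_scale / height if height > 0 else 1.0
    floor = 1e-6
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length * scale, floor if edge.head_node.parent_node else 0.0)
    # canonical leaf naming in postorder
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:04d}"
    return tree


def _assign_groups(tree: dendropy.Tree, n_groups: int) -> dict[str, str]:
    """Partition leaves into clade-defined groups by splitting the largest
    clade until ``n_groups`` blocks exist."""
    blocks = [tree.seed_node]
    while len(blocks) < n_groups:
        blocks.sort(key=lambda nd: (-len(nd.leaf_nodes()), min(
            lf.taxon.label for lf in nd.leaf_iter())))
        head = blocks.pop(0)
        if head.is_leaf():  # cannot split further
            blocks.append(head)
            break
        blocks = blocks + head.child_nodes()
    labels: dict[str, str] = {}
    blocks.sort(key=lambda nd: min(lf.taxon.label for lf in nd.leaf_iter()))
    for gi, block in enumerate(blocks, start=1):
        for lf in block.leaf_iter():
            labels[lf.taxon.label] = f"G{gi}"
    return labels


def _choose_queries(group_labels: Mapping[str, str], n_queries: int,
                    rng: random.Random) -> list[str]:
    """Mask leaves as environmental while keeping >=1 labelled reference
    per group."""
    ids = sorted(group_labels)
    rng.shuffle(ids)
    remaining = {}
    for rid in ids:
        remaining.setdefault(group_labels[rid], set()).add(rid)
    queries: list[str] = []
    for rid in ids:
        if len(queries) == n_queries:
            break
        grp = group_labels[rid]
        if len(remaining[grp]) > 1:
            queries.append(rid)
            remaining[grp].discard(rid)
    return sorted(queries)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

class _ColumnRegistry:
    """Global ordered registry of homology columns for the true alignment."""

    def __init__(self, region_lengths: tuple[int, int, int]):
        self.order: list[int] = []
        self.region: dict[int, int] = {}
        self._next = 0
        for ri, length in enumerate(region_lengths):
            for _ in range(length):
                self.order.append(self._next)
                self.region[self._next] = ri
                self._next += 1

    def root_ids(self) -> list[int]:
        return list(self.order)

    def insert_after(self, host: int, count: int, region: int) -> list[int]:
        idx = self.order.index(host)
        new = list(range(self._next, self._next + count))
        self._next += count
        self.order[idx + 1:idx + 1] = new
        for cid in new:
            self.region[cid] = region
        return new


def _jc_substitute(bases: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve bases along a branch of length d substitutions/site under JC."""
    if d <= 0 or bases.size == 0:
        return bases
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    mask = rng.random(bases.size) < p_change
    if mask.any():
        bases = bases.copy()
        shift = rng.integers(1, 4, size=int(mask.sum()))
        bases[mask] = (bases[mask] + shift) % 4
    return bases


def evolve_its(tree: dendropy.Tree, cfg: SimConfig) -> SimTruth:
    """Evolve ITS1/5.8S/ITS2 along the tree; record the true alignment.

    Residue coordinates are 0-based half-open on ungapped residues; the
    true alignment propagates every insertion column so that degapping a
    row reproduces the leaf's residues exactly.
    """
    if len(tree.leaf_nodes()) < 3:
        raise InvalidInputError("tree must have >= 3 leaves")
    rng = np.random.default_rng(cfg.seed + 1)
    sub_rng = random.Random(cfg.seed + 2)

    registry = _ColumnRegistry(cfg.region_lengths)
    root_ids = registry.root_ids()
    root_bases = rng.integers(0, 4, size=len(root_ids))

    group_labels = _assign_groups(tree, cfg.n_groups)
    queries = set(_choose_queries(group_labels, cfg.n_queries, sub_rng))

    p_geo = 1.0 / max(cfg.indel_length_mean, 1.0)
    leaf_tokens: dict[str, tuple[list[int], np.ndarray]] = {}

    def descend(node, ids: list[int], bases: np.ndarray) -> None:
        edge_len = node.edge.length or 0.0
        if node.is_leaf() and node.taxon.label in queries:
            edge_len *= cfg.query_branch_multiplier
        if edge_len > 0 and ids:
            regions = np.fromiter((registry.region[c] for c in ids), dtype=np.int64)
            # substitutions, per region rate class
            new_bases = bases.copy()
            for ri, mult in enumerate(cfg.rate_multipliers):
                sel = regions == ri
                if sel.any():
                    new_bases[sel] = _jc_substitute(bases[sel], edge_len * mult, rng)
            bases = new_bases
            # indels, per region
            for ri in range(3):
                positions = np.flatnonzero(regions == ri)
                if positions.size == 0 or cfg.indel_rate[ri] <= 0:
                    continue
                n_events = rng.poisson(cfg.indel_rate[ri] * positions.size * edge_len)
                for _ in range(n_events):
                    positions = np.flatnonzero(
                        np.fromiter((registry.region[c] for c in ids), dtype=np.int64) == ri
                    )
                    if positions.size == 0:
                        break
                    length = int(rng.geometric(p_geo))
                    pos = int(rng.choice(positions))
                    if rng.random() < 0.5:  # deletion from pos
                        stop = min(pos + length, positions[-1] + 1)
                        del_idx = [k for k in range(pos, stop)
                                   if registry.region[ids[k]] == ri]
                        keep = np.ones(len(ids), dtype=bool)
                        keep[del_idx] = False
                        ids = [c for c, k in zip(ids, keep) if k]
                        bases = bases[keep]
                    else:  # insertion after pos
                        host = ids[pos]
                        new_ids = registry.insert_after(host, length, ri)
                        new_bases = rng.integers(0, 4, size=length)
                        ids = ids[:pos + 1] + new_ids + ids[pos + 1:]
                        bases = np.concatenate([bases[:pos + 1], new_bases, bases[pos + 1:]])
        if node.is_leaf():
            leaf_tokens[node.taxon.label] = (ids, bases)
        else:
            for child in node.child_nodes():
                descend(child, list(ids), bases.copy())

    descend(tree.seed_node, root_ids, root_bases)

    # assemble records, region maps, true alignment
    present: set[int] = set()
    for ids, _ in leaf_tokens.values():
        present.update(ids)
    aln_columns = [c for c in registry.order if c in present]
    col_index = {c: j for j, c in enumerate(aln_columns)}

    records: list[SequenceRecord] = []
    rows: dict[str, str] = {}
    for label in sorted(leaf_tokens):
        ids, bases = leaf_tokens[label]
        residues = "".join(_BASES[b] for b in bases)
        row = ["-"] * len(aln_columns)
        for c, b in zip(ids, bases):
            row[col_index[c]] = _BASES[b]
        rows[label] = "".join(row)
        # contiguous region blocks on the ungapped residues
        counts = [0, 0, 0]
        for c in ids:
            counts[registry.region[c]] += 1
        b0, b1, b2 = counts
        rmap = RegionMap(
            its1=(0, b0) if b0 else None,
            r58s=(b0, b0 + b1) if b1 else None,
            its2=(b0 + b1, b0 + b1 + b2) if b2 else None,
        )
        rec_label = ENVIRONMENTAL if label in queries else group_labels[label]
        records.append(SequenceRecord(label, residues, label=rec_label, region_map=rmap))

    truth = SimTruth(
        config=cfg,
        true_tree=tree,
        true_alignment=Msa(rows),
        records=records,
        group_labels=group_labels,
        artifact_table={
            r.id: {"reverse_complemented": False, "truncated": False, "short": False}
            for r in records
        },
        pristine_residues={r.id: r.residues for r in records},
        pristine_region_maps={r.id: r.region_map for r in records},
    )
    return truth


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def _pick(ids: list[str], fraction: float, rng: random.Random) -> list[str]:
    count = int(round(fraction * len(ids)))
    return sorted(rng.sample(ids, count))


def inject_artifacts(truth: SimTruth, cfg: SimConfig | None = None) -> SimTruth:
    """Apply database-style artifacts to a seeded subset of records.

    Reverse-complemented records lose their region annotation (it no
    longer describes the stored orientation); truncated records lose the
    ITS2; short records are clipped below a usable length.  The artifact
    table records exactly which records were touched.
    """
    cfg = cfg or truth.config
    rng = random.Random(cfg.seed + 3)
    ids = sorted(r.id for r in truth.records)
    rc_ids = set(_pick(ids, cfg.artifact_fractions[0], rng))
    trunc_ids = set(_pick(ids, cfg.artifact_fractions[1], rng))
    short_ids = set(_pick(ids, cfg.artifact_fractions[2], rng))

    new_records: list[SequenceRecord] = []
    table: dict[str, dict[str, bool]] = {}
    for rec in truth.records:
        residues, rmap = rec.residues, rec.region_map
        flags = {"reverse_complemented": rec.id in rc_ids,
                 "truncated": rec.id in trunc_ids,
                 "short": rec.id in short_ids}
        if flags["truncated"] and rmap is not None and rmap.r58s is not None:
            residues = residues[: rmap.r58s[1]]
            rmap = RegionMap(its1=rmap.its1, r58s=rmap.r58s, its2=None)
        if flags["short"]:
            keep = min(cfg.short_length, len(residues))
            residues = residues[:keep]
            rmap = _clip_map(rmap, keep)
        if flags["reverse_complemented"]:
            residues = reverse_complement(residues)
            rmap = None
        new_records.append(SequenceRecord(rec.id, residues, label=rec.label,
                                          region_map=rmap))
        table[rec.id] = flags
    return SimTruth(
        config=truth.config,
        true_tree=truth.true_tree,
        true_alignment=truth.true_alignment,
        records=new_records,
        group_labels=truth.group_labels,
        artifact_table=table,
        pristine_residues=truth.pristine_residues,
        pristine_region_maps=truth.pristine_region_maps,
    )


def _clip_map(rmap: RegionMap | None, length: int) -> RegionMap | None:
    if rmap is None:
        return None

    def clip(iv):
        if iv is None or iv[0] >= length:
            return None
        return (iv[0], min(iv[1], length))

    return RegionMap(its1=clip(rmap.its1), r58s=clip(rmap.r58s), its2=clip(rmap.its2))


# ---------------------------------------------------------------------------
# Orchestration and output
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimTruth:
    """Full generator: tree -> evolution -> artifacts."""
    tree = sample_tree(cfg)
    truth = evolve_its(tree, cfg)
    return inject_artifacts(truth, cfg)


def write_dataset(truth: SimTruth, out_dir: str | Path) -> None:
    """Write records.fasta, true_alignment.fasta, true_tree.nwk,
    regions.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.records, out / "records.fasta")
    write_msa_fasta(truth.true_alignment, out / "true_alignment.fasta")
    trees.write_newick(truth.true_tree, out / "true_tree.nwk")
    write_regions_tsv(truth.region_maps, out / "regions.tsv")
    dump_json(
        {
            "group_labels": truth.group_labels,
            "query_ids": truth.query_ids,
            "artifact_table": truth.artifact_table,
            "observed_labels": {r.id: r.label for r in truth.records},
        },
        out / "truth.json",
    )
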