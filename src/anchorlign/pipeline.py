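"""End-to-end orchestration of the four alignment strategies.

Strategies
----------
1. ``baseline_whole``      one-pass progressive alignment of the whole ITS
                           (the traditional single-aligner control);
2. ``coest_whole``         iterative co-estimation on the whole ITS;
3. ``coest_anchored``      5.8S replaced by a 16-character constant anchor,
                           then co-estimation on ITS1 + anchor + ITS2;
4. ``coest_58s_reincluded``the anchored strategy's best alignment with the
                           true 5.8S block re-inserted, then tree + support
                           on the combined alignment.

Each strategy yields an alignment, a support-annotated tree, column
classes, tree metrics (against the simulator's truth when available) and
query assignments; a comparison table ranks the strategies.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from . import regions as regions_mod
from . import seqprep, trees
from .assign import Assignment, assign_queries, assignment_accuracy, assignments_frame
from .coestimate import (
    CoestimationTrace,
    coestimate,
    kmer_distance_matrix,
    nj,
    progressive_align,
)
from .evaluate import (
    ColumnClasses,
    alignment_accuracy,
    classify_columns,
    long_branches,
    monophyly,
    rf_distance,
    supported_fraction,
)
from .records import ENVIRONMENTAL, Msa, RegionMap, SequenceRecord, attach
from .support import DEFAULT_SUPPORT_THRESHOLD, bootstrap_support
from .synthetic_data import SimConfig, SimTruth, simulate

logger = logging.getLogger(__name__)

STRATEGIES = (
    "baseline_whole",
    "coest_whole",
    "coest_anchored",
    "coest_58s_reincluded",
)


@dataclass
class PipelineConfig:
    runs: int = 2
    iterations: int = 10
    bootstrap_replicates: int = 100
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
    min_length: int = seqprep.DEFAULT_MIN_LENGTH
    require_its2: bool = True
    anchor_length: int = regions_mod.DEFAULT_ANCHOR_LENGTH
    long_branch_factor: float = 5.0
    scoring: dict | None = None
    seed: int = 0


@dataclass
class TreeMetricsReport:
    monophyly: dict[str, tuple[bool, float | None]]
    supported_fraction: float
    long_branch_ids: list[str]
    n_long_branches: int
    rf: int | None = None
    rf_normalized: float | None = None
    sp_score: float | None = None
    column_score: float | None = None


@dataclass
class StrategyReport:
    strategy: str
    msa: Msa
    tree: dendropy.Tree
    column_classes: ColumnClasses
    metrics: TreeMetricsReport
    assignments: list[Assignment]
    trace: CoestimationTrace | None
    runtime_s: float
    seed: int
    error: str | None = None


@dataclass
class PipelineResult:
    reports: dict[str, StrategyReport]
    comparison: pd.DataFrame
    filter_report: seqprep.FilterReport
    truth: SimTruth | None = None


# ---------------------------------------------------------------------------

def _strategy_tree_metrics(msa: Msa, tree: dendropy.Tree, groups: Mapping[str, str],
                           cfg: PipelineConfig,
                           truth: SimTruth | None,
                           comparable_to_truth_alignment: bool) -> TreeMetricsReport:
    leaf_set = set(trees.leaf_ids(tree))
    by_group: dict[str, set[str]] = {}
    for rid, grp in groups.items():
        if grp != ENVIRONMENTAL and rid in leaf_set:
            by_group.setdefault(grp, set()).add(rid)
    mono = {}
    for grp, members in sorted(by_group.items()):
        if 1 <= len(members) < len(leaf_set):
            mono[grp] = monophyly(tree, members)
    lb = long_branches(tree, cfg.long_branch_factor)
    rep = TreeMetricsReport(
        monophyly=mono,
        supported_fraction=supported_fraction(tree, cfg.support_threshold),
        long_branch_ids=lb,
        n_long_branches=len(lb),
    )
    if truth is not None:
        true_restricted = trees.restrict_to(truth.true_tree, leaf_set)
        rep.rf, rep.rf_normalized = rf_distance(tree, true_restricted)
        if comparable_to_truth_alignment:
            truth_sub = truth.true_alignment.subset(sorted(leaf_set))
            try:
                rep.sp_score, rep.column_score = alignment_accuracy(
                    msa.subset(sorted(leaf_set)), truth_sub
                )
            except Exception:
                logger.exception("alignment accuracy unavailable")
    return rep


def run_strategies(records: Sequence[SequenceRecord],
                   region_maps: Mapping[str, RegionMap],
                   groups: Mapping[str, str],
                   cfg: PipelineConfig | None = None,
                   truth: SimTruth | None = None) -> PipelineResult:
    """Run the four strategies on prepared records and compare them.

    ``records`` should already be orientation-corrected; the exclusion
    filters are applied here.  Failures are isolated per strategy.
    """
    cfg = cfg or PipelineConfig()
    records = attach(records, region_maps=region_maps, labels=groups)

    filt = seqprep.filter_records(records, cfg.min_length, cfg.require_its2)
    kept = seqprep.apply_filter(records, filt)
    logger.info("filters kept %d/%d records", len(kept), len(records))

    labels = {r.id: r.label for r in kept}
    reports: dict[str, StrategyReport] = {}

    def finish(strategy: str, msa: Msa, tree: dendropy.Tree,
               trace: CoestimationTrace | None, t0: float,
               comparable: bool) -> StrategyReport:
        metrics = _strategy_tree_metrics(msa, tree, labels, cfg, truth, comparable)
        assignments = assign_queries(tree, labels, cfg.support_threshold)
        return StrategyReport(
            strategy=strategy,
            msa=msa,
            tree=tree,
            column_classes=classify_columns(msa),
            metrics=metrics,
            assignments=assignments,
            trace=trace,
            runtime_s=time.perf_counter() - t0,
            seed=cfg.seed,
        )

    def supported_tree(msa: Msa) -> dendropy.Tree:
        tree, _ = bootstrap_support(
            msa, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed
        )
        return tree

    # strategy 1: one-pass baseline -------------------------------------
    t0 = time.perf_counter()
    try:
        base_trace = coestimate(kept, runs=1, iterations=1, seed=cfg.seed,
                                scoring=cfg.scoring)
        msa1 = base_trace.best_msa
        tree1 = supported_tree(msa1)
        reports["baseline_whole"] = finish("baseline_whole", msa1, tree1,
                                           base_trace, t0, comparable=True)
    except Exception as exc:
        logger.exception("baseline_whole failed")
        reports["baseline_whole"] = _failed("baseline_whole", cfg.seed, t0, exc)

    # strategy 2: co-estimation on whole ITS ----------------------------
    t0 = time.perf_counter()
    try:
        trace2 = coestimate(kept, runs=cfg.runs, iterations=cfg.iterations,
                            seed=cfg.seed, scoring=cfg.scoring)
        msa2 = trace2.best_msa
        tree2 = supported_tree(msa2)
        reports["coest_whole"] = finish("coest_whole", msa2, tree2, trace2,
                                        t0, comparable=True)
    except Exception as exc:
        logger.exception("coest_whole failed")
        reports["coest_whole"] = _failed("coest_whole", cfg.seed, t0, exc)

    # strategy 3: anchored ----------------------------------------------
    anchored = None
    t0 = time.perf_counter()
    try:
        anchored = regions_mod.make_anchored(kept, cfg.anchor_length)
        if len(anchored.anchored_records) < 4:
            raise ValueError("too few anchorable records")
        trace3 = coestimate(anchored.anchored_records, runs=cfg.runs,
                            iterations=cfg.iterations, seed=cfg.seed,
                            scoring=cfg.scoring)
        msa3 = trace3.best_msa
        tree3 = supported_tree(msa3)
        reports["coest_anchored"] = finish("coest_anchored", msa3, tree3,
                                           trace3, t0, comparable=False)
    except Exception as exc:
        logger.exception("coest_anchored failed")
        reports["coest_anchored"] = _failed("coest_anchored", cfg.seed, t0, exc)

    # strategy 4: 5.8S re-included ---------------------------------------
    t0 = time.perf_counter()
    try:
        if anchored is None or "coest_anchored" not in reports or \
                reports["coest_anchored"].error:
            raise ValueError("anchored strategy unavailable")

        def block_aligner(seqs: Sequence[SequenceRecord]) -> Msa:
            guide = nj(kmer_distance_matrix(seqs))
            return progressive_align(seqs, guide, cfg.scoring)

        msa4 = regions_mod.reinsert_58s(
            reports["coest_anchored"].msa, anchored.excised, block_aligner,
            anchor=anchored.anchor,
        )
        tree4 = supported_tree(msa4)
        reports["coest_58s_reincluded"] = finish(
            "coest_58s_reincluded", msa4, tree4, None, t0, comparable=True
        )
    except Exception as exc:
        logger.exception("coest_58s_reincluded failed")
        reports["coest_58s_reincluded"] = _failed("coest_58s_reincluded",
                                                  cfg.seed, t0, exc)

    comparison = comparison_table(reports, truth, groups)
    return PipelineResult(reports=reports, comparison=comparison,
                          filter_report=filt, truth=truth)


def _failed(strategy: str, seed: int, t0: float, exc: Exception) -> StrategyReport:
    return StrategyReport(
        strategy=strategy, msa=None, tree=None, column_classes=None,
        metrics=None, assignments=[], trace=None,
        runtime_s=time.perf_counter() - t0, seed=seed, error=str(exc),
    )


def comparison_table(reports: Mapping[str, StrategyReport],
                     truth: SimTruth | None,
                     groups: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    true_groups = truth.group_labels if truth is not None else {}
    for name in STRATEGIES:
        rep = reports.get(name)
        if rep is None or rep.error:
            rows.append({"strategy": name, "error": rep.error if rep else "missing"})
            continue
        acc = assignment_accuracy(rep.assignments, true_groups) if truth else None
        rows.append({
            "strategy": name,
            "ncol": rep.msa.ncol,
            "n_taxa": len(rep.msa),
            "informative_percent": rep.column_classes.informative_percent,
            "supported_fraction": rep.metrics.supported_fraction,
            "n_long_branches": rep.metrics.n_long_branches,
            "rf": rep.metrics.rf,
            "rf_normalized": rep.metrics.rf_normalized,
            "sp_score": rep.metrics.sp_score,
            "column_score": rep.metrics.column_score,
            "n_assigned": sum(1 for a in rep.assignments if a.assigned),
            "assignment_accuracy": acc,
            "runtime_s": round(rep.runtime_s, 2),
            "error": None,
        })
    df = pd.DataFrame(rows)
    if "rf_normalized" in df.columns:
        df = df.sort_values(
            by=["rf_normalized", "supported_fraction"],
            ascending=[True, False],
            na_position="last",
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------

def simulate_and_run(sim_cfg: SimConfig | None = None,
                     pipe_cfg: PipelineConfig | None = None) -> PipelineResult:
    """Generate a synthetic dataset and push it through all strategies.

    Orientation correction runs first, using the labelled references as
    the k-mer pool; region annotations (simulator truth, forward strand)
    are re-attached afterwards.
    """
    sim_cfg = sim_cfg or SimConfig()
    pipe_cfg = pipe_cfg or PipelineConfig(seed=sim_cfg.seed)
    truth = simulate(sim_cfg)

    refs = [r for r in truth.records if r.label != ENVIRONMENTAL]
    oriented, orient_report = seqprep.orient(truth.records, refs)
    resolved = seqprep.apply_filter(
        oriented,
        seqprep.FilterReport(kept=orient_report.kept, excluded=orient_report.excluded),
    )
    region_maps = _forward_region_maps(truth)
    labels = {r.id: r.label for r in truth.records}
    return run_strategies(resolved, region_maps, labels, pipe_cfg, truth=truth)


def _forward_region_maps(truth: SimTruth) -> dict[str, RegionMap]:
    """Region maps in forward orientation for every record that has one.

    Reverse-complemented artifacts lose their map at injection; once the
    orientation is corrected the pre-artifact forward-strand coordinates
    apply again, unless the record was also truncated or shortened.
    """
    maps: dict[str, RegionMap] = {}
    for rec in truth.records:
        flags = truth.artifact_table[rec.id]
        if rec.region_map is not None:
            maps[rec.id] = rec.region_map
        elif flags["reverse_complemented"] and not (flags["truncated"] or flags["short"]):
            pristine = truth.pristine_region_maps.get(rec.id)
            if pristine is not None:
                maps[rec.id] = pristine
    return maps


# ---------------------------------------------------------------------------

def comparative_study(seeds: Sequence[int],
                      sim_kwargs: Mapping | None = None,
                      pipe_kwargs: Mapping | None = None) -> pd.DataFrame:
    """Replicate the four-strategy comparison over several seeded datasets.

    Returns one row per (seed, strategy) with normalised RF to the truth
    tree, supported-branch fraction, long-branch count, informative-column
    percentage, and query-assignment recovery (accuracy over assigned
    queries plus the assigned fraction).
    """
    rows = []
    for seed in seeds:
        sim_cfg = SimConfig(seed=seed, **(sim_kwargs or {}))
        pipe_cfg = PipelineConfig(seed=seed, **(pipe_kwargs or {}))
        result = simulate_and_run(sim_cfg, pipe_cfg)
        truth = result.truth
        for name in STRATEGIES:
            rep = result.reports[name]
            if rep.error:
                rows.append({"seed": seed, "strategy": name, "error": rep.error})
                continue
            acc = assignment_accuracy(rep.assignments, truth.group_labels)
            rows.append({
                "seed": seed,
                "strategy": name,
                "rf_normalized": rep.metrics.rf_normalized,
                "supported_fraction": rep.metrics.supported_fraction,
                "n_long_branches": rep.metrics.n_long_branches,
                "informative_percent": rep.column_classes.informative_percent,
                "ncol": rep.msa.ncol,
                "n_taxa": len(rep.msa),
                "n_queries": len(rep.assignments),
                "n_assigned": sum(1 for a in rep.assignments if a.assigned),
                "assignment_accuracy": acc,
                "error": None,
            })
    return pd.DataFrame(rows)


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    from .records import dump_json, write_msa_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    dump_json(result.filter_report.as_dict(), out / "filter_report.json")
    lines = ["# Strategy comparison", "", result.comparison.to_markdown(index=False), ""]
    for name, rep in result.reports.items():
        sub = out / name
        sub.mkdir(exist_ok=True)
        if rep.error:
            (sub / "error.txt").write_text(rep.error + "\n")
            continue
        write_msa_fasta(rep.msa, sub / "alignment.fasta")
        trees.write_newick(rep.tree, sub / "tree.nwk")
        assignments_frame(rep.assignments).to_csv(sub / "assignments.tsv",
                                                  sep="\t", index=False)
        dump_json(rep.column_classes.as_dict(), sub / "column_classes.json")
        if rep.trace is not None:
            rep.trace.as_frame().to_csv(sub / "trace.tsv", sep="\t", index=False)
    (out / "summary.md").write_text("\n".join(lines))
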