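"""End-to-end orchestration: expression filter -> scan -> features -> fusion.

The pipeline reads a YAML config naming the input files, selects
auxin-induced genes by fold change (optional: without an expression table
every FASTA gene is scanned), scans their upstream sequences for candidate
cores, trains the discriminant, builds and fuzzifies the three learning
graphs, fuses the per-graph masses for every candidate, and writes a
coordinate report with belief/plausibility/pignistic scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import ds_fusion, features, fuzzy_mass, learning_graphs, sequence_io
from .features import FeaturePoint, TrainingMotif
from .motif_scan import DEFAULT_MOTIF, MotifOccurrence, find_core_matches
from .sequence_io import OccurrenceReport, ReportRow, UpstreamSequence
from .synthetic_data import make_training_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's auxin-induction fold change (treated/mock signal ratio)."""

    gene_id: str
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(
                f"fold_change must be positive, got {self.fold_change} "
                f"for {self.gene_id}"
            )


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene_id, fold_change."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        ExpressionRecord(r.gene_id, float(r.fold_change))
        for r in df.itertuples(index=False)
    ]


def select_genes(
    records: Sequence[ExpressionRecord], threshold: float = 3.0
) -> list[str]:
    """Gene ids induced strictly more than ``threshold``-fold, input order kept.

    A gene at exactly the threshold is excluded; duplicate ids are an
    error because the selection would be ambiguous.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in expression table")
        seen.add(rec.gene_id)
    return [rec.gene_id for rec in records if rec.fold_change > threshold]


def read_training_tsv(path: str | Path) -> list[TrainingMotif]:
    """Read a training TSV with columns context, label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TrainingMotif(r.context, r.label) for r in df.itertuples(index=False)]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    fasta: Path
    training: Path | None = None
    expression: Path | None = None
    out: Path | None = None
    summary: Path | None = None
    table1_mode: bool = False
    motifs: list[str] = field(default_factory=lambda: [DEFAULT_MOTIF])
    scan_reverse: bool = False
    expression_threshold: float = 3.0
    lda_shrinkage: float = 0.1
    background_order: int = 0
    graph_bins: int = 4
    graph_pairs: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(learning_graphs.DEFAULT_GRAPH_PAIRS)
    )
    graph_thresholds: dict[str, float] | None = None
    fuzzy_alpha: float = fuzzy_mass.DEFAULT_ALPHA
    decision_threshold: float = 0.5
    seed_training: int = 1
    alias_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def _path(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        kwargs: dict = {"fasta": _path("fasta")}
        if kwargs["fasta"] is None:
            raise ValueError("config must name a fasta file")
        for key in ("training", "expression", "out", "summary"):
            kwargs[key] = _path(key)
        if "motifs" in raw:
            kwargs["motifs"] = list(raw["motifs"])
        for src, dst in [
            ("table1", "table1_mode"),
            ("scan_reverse", "scan_reverse"),
            ("alias_map", "alias_map"),
        ]:
            if src in raw:
                kwargs[dst] = raw[src]
        if "expression_threshold" in raw:
            kwargs["expression_threshold"] = float(raw["expression_threshold"])
        lda = raw.get("lda", {})
        if "shrinkage" in lda:
            kwargs["lda_shrinkage"] = float(lda["shrinkage"])
        bg = raw.get("background", {})
        if "order" in bg:
            kwargs["background_order"] = int(bg["order"])
        graphs = raw.get("graphs", {})
        if "bins" in graphs:
            kwargs["graph_bins"] = int(graphs["bins"])
        if "pairs" in graphs:
            kwargs["graph_pairs"] = {
                gid: tuple(pair) for gid, pair in graphs["pairs"].items()
            }
        if "thresholds" in graphs:
            kwargs["graph_thresholds"] = {
                k: float(v) for k, v in graphs["thresholds"].items()
            }
        fuzzy = raw.get("fuzzy", {})
        if "alpha" in fuzzy:
            kwargs["fuzzy_alpha"] = float(fuzzy["alpha"])
        decision = raw.get("decision", {})
        if "threshold" in decision:
            kwargs["decision_threshold"] = float(decision["threshold"])
        seed = raw.get("seed", {})
        if "training" in seed:
            kwargs["seed_training"] = int(seed["training"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Report plus per-stage bookkeeping of one run."""

    report: OccurrenceReport
    occurrences: list[MotifOccurrence]
    stage_counts: dict[str, int]
    graphs: list[learning_graphs.LearningGraph]


def _build_report(
    occurrences: Sequence[MotifOccurrence],
    scores: Sequence[tuple[float, float, float, str]] | None,
) -> OccurrenceReport:
    order = sorted(
        range(len(occurrences)),
        key=lambda k: (occurrences[k].gene_id, occurrences[k].start),
    )
    counts: dict[str, int] = {}
    for occ in occurrences:
        counts[occ.gene_id] = counts.get(occ.gene_id, 0) + 1
    rows = []
    for k in order:
        occ = occurrences[k]
        bel = pl = betp = label = None
        if scores is not None:
            bel, pl, betp, label = scores[k]
        rows.append(
            ReportRow(
                gene_id=occ.gene_id,
                repeats=counts[occ.gene_id],
                start=occ.start,
                end=occ.end,
                matching_seq=occ.context,
                bel=bel,
                pl=pl,
                betp=betp,
                label=label,
            )
        )
    return OccurrenceReport(rows)


def scan_only(
    promoters: Sequence[UpstreamSequence],
    motifs: Sequence[str] | None = None,
    scan_reverse: bool = False,
) -> OccurrenceReport:
    """Coordinate-only report (no evidence scores) for a promoter set."""
    occurrences: list[MotifOccurrence] = []
    for rec in promoters:
        occurrences.extend(
            find_core_matches(rec, set(motifs) if motifs else None, scan_reverse)
        )
    return _build_report(occurrences, None)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full prediction pipeline for one configuration."""
    all_promoters = sequence_io.read_fasta(config.fasta)
    by_id = {rec.gene_id: rec for rec in all_promoters}

    if config.expression is not None:
        records = read_expression_table(config.expression)
        selected = select_genes(records, config.expression_threshold)
        selected = [config.alias_map.get(g, g) for g in selected]
        logger.info(
            "expression filter: %d of %d genes above %.1f-fold",
            len(selected),
            len(records),
            config.expression_threshold,
        )
    else:
        selected = [rec.gene_id for rec in all_promoters]

    promoters = []
    for gene_id in selected:
        if gene_id not in by_id:
            logger.warning("selected gene %s missing from FASTA; skipped", gene_id)
            continue
        promoters.append(by_id[gene_id])
    if not promoters:
        raise ValueError("no selected gene has an upstream sequence in the FASTA")
    logger.info("scanning %d promoters", len(promoters))

    occurrences: list[MotifOccurrence] = []
    for rec in promoters:
        occurrences.extend(
            find_core_matches(rec, set(config.motifs), config.scan_reverse)
        )
    genes_with_hits = len({occ.gene_id for occ in occurrences})
    logger.info(
        "found %d candidate cores in %d genes", len(occurrences), genes_with_hits
    )

    if config.training is not None:
        training = read_training_tsv(config.training)
    else:
        logger.info(
            "no training TSV configured; generating a synthetic high-separation "
            "set (seed %d)",
            config.seed_training,
        )
        training = make_training_set(
            200, 200, separation="high", seed=config.seed_training
        )
    model = features.train_lda(training, shrinkage=config.lda_shrinkage)
    background = features.estimate_background(promoters, order=config.background_order)

    word_cache: dict[str, tuple[float, float]] = {}
    train_points: list[tuple[FeaturePoint, str]] = []
    for motif in training:
        core = motif.context[4:10].upper()
        train_points.append(
            (
                features.compute_features(
                    model, core, motif.context, promoters, background, word_cache
                ),
                motif.label,
            )
        )

    graphs = []
    for gid, (xf, yf) in config.graph_pairs.items():
        graph = learning_graphs.build_graph(
            gid,
            train_points,
            xf,
            yf,
            bins=config.graph_bins,
            thresholds=config.graph_thresholds,
        )
        fuzzy_mass.fuzzify_graph(graph, alpha=config.fuzzy_alpha)
        graphs.append(graph)
    if len(graphs) != 3:
        raise ValueError(f"expected 3 learning graphs, got {len(graphs)}")

    scores = []
    for occ in occurrences:
        fp = features.compute_features(
            model, occ.core, occ.context, promoters, background, word_cache
        )
        masses = [
            fuzzy_mass.fuzzy_graph_mass(g, (fp.get(g.x_feature), fp.get(g.y_feature)))
            for g in graphs
        ]
        fused = ds_fusion.fuse_graphs(masses)
        scores.append(ds_fusion.decision_scores(fused, config.decision_threshold))
        logger.debug(
            "%s %d..%d fused mass H1=%.4f H2=%.4f Theta=%.4f",
            occ.gene_id,
            occ.start,
            occ.end,
            fused.m_h1,
            fused.m_h2,
            fused.m_theta,
        )

    report = _build_report(occurrences, None if config.table1_mode else scores)
    stage_counts = {
        "genes_selected": len(selected),
        "genes_with_promoter": len(promoters),
        "genes_with_candidates": genes_with_hits,
        "candidates": len(occurrences),
        "called_auxre": sum(1 for s in scores if s[3] == "AuxRE"),
    }
    logger.info("stage counts: %s", stage_counts)

    if config.out is not None:
        sequence_io.write_report(report, config.out, table1_mode=config.table1_mode)
        logger.info("report written to %s", config.out)
    if config.summary is not None:
        with open(config.summary, "w") as fh:
            json.dump(stage_counts, fh, indent=2)
        logger.info("run summary written to %s", config.summary)
    return PipelineResult(
        report=report,
        occurrences=occurrences,
        stage_counts=stage_counts,
        graphs=graphs,
    )
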