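"""End-to-end orchestration of the ceRNA discovery pipeline.

Chains the stages in analysis order: back-splice circRNA detection from
reads, differential expression of mRNA and circRNA counts,
co-expression screening of DE circ-mRNA pairs, MRE prediction on the
detected circle and mRNA sequences, and triad assembly.  Each stage
logs its input/output cardinalities and every threshold it applies; a
stage failure aborts with the stage name and cause.  Fixed inputs and
a fixed config give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cerna, coexpr, diffexpr, mre
from .bsj import CircRNA, detect_circrnas, read_sam_linear_ids
from .config import PipelineConfig
from .io import (
    CountMatrix,
    ExonAnnotation,
    GenomeSequence,
    ReadRecord,
    write_json,
    write_tsv,
)

__all__ = ["PipelineInputs", "PipelineReport", "run_pipeline", "StageError"]

logger = logging.getLogger("circena")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineInputs:
    """In-memory inputs for a full pipeline run."""

    genome: list[GenomeSequence]
    annotations: list[ExonAnnotation]
    reads: list[ReadRecord]
    mirnas: dict[str, str]                  # id -> sequence (RNA or DNA alphabet)
    mrna_seqs: dict[str, str]               # gene id -> 3'UTR/transcript DNA
    circ_counts: CountMatrix | None = None
    mrna_counts: CountMatrix | None = None
    sam_path: str | None = None             # optional precomputed linear alignments
    mirna_counts: CountMatrix | None = None


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    circrnas: list[CircRNA] = field(default_factory=list)
    circ_de: pd.DataFrame | None = None
    mrna_de: pd.DataFrame | None = None
    mirna_de: pd.DataFrame | None = None
    network_edges: pd.DataFrame | None = None
    pair_correlations: pd.DataFrame | None = None
    mre_sites: pd.DataFrame | None = None
    circ_interactions: pd.DataFrame | None = None
    mrna_interactions: pd.DataFrame | None = None
    triads: list[cerna.CeRNATriad] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_circrnas": len(self.circrnas),
            "circ_ids": [c.id for c in self.circrnas],
            "n_de_circ": int(self.circ_de["called"].sum()) if self.circ_de is not None else 0,
            "n_de_mrna": int(self.mrna_de["called"].sum()) if self.mrna_de is not None else 0,
            "n_network_edges": len(self.network_edges) if self.network_edges is not None else 0,
            "n_correlated_pairs": len(self.pair_correlations) if self.pair_correlations is not None else 0,
            "n_mre_sites": len(self.mre_sites) if self.mre_sites is not None else 0,
            "n_triads": len(self.triads),
            "triads": [
                (t.circ_id, t.mirna_id, t.mrna_id, round(t.score, 4))
                for t in self.triads
            ],
            "skipped": self.skipped,
        }


def circrna_table(circrnas: Sequence[CircRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "chrom": c.candidate.chrom,
                "strand": c.candidate.strand,
                "acceptor": c.candidate.acceptor_pos,
                "donor": c.candidate.donor_pos,
                "splice_score": c.candidate.splice_score,
                "support": c.candidate.support,
                "junction_read_count": c.junction_read_count,
            }
            for c in circrnas
        ],
        columns=["id", "chrom", "strand", "acceptor", "donor", "splice_score",
                 "support", "junction_read_count"],
    )


def circrna_bed(circrnas: Sequence[CircRNA]) -> str:
    """BED (0-based half-open) export of detected circles, with a header."""
    lines = ["# BED: 0-based half-open intervals converted from 1-based inclusive"]
    for c in circrnas:
        lines.append(
            f"{c.candidate.chrom}\t{c.candidate.acceptor_pos - 1}"
            f"\t{c.candidate.donor_pos}\t{c.id}\t{c.junction_read_count}"
            f"\t{c.candidate.strand}"
        )
    return "\n".join(lines) + "\n"


def pair_correlations(
    circ_counts: CountMatrix,
    mrna_counts: CountMatrix,
    circ_ids: Sequence[str],
    mrna_ids: Sequence[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Significant circ-mRNA expression correlations over the full cohort."""
    circ_expr = coexpr.log_expression(circ_counts)
    mrna_expr = coexpr.log_expression(mrna_counts)
    rows = []
    for circ_id in circ_ids:
        if circ_id not in circ_expr.index:
            continue
        x = circ_expr.loc[circ_id].to_numpy()
        if np.std(x) == 0:
            continue
        for mrna_id in mrna_ids:
            if mrna_id not in mrna_expr.index:
                continue
            y = mrna_expr.loc[mrna_id].to_numpy()
            if np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            if p < config.correlation_p_threshold and abs(r) >= config.correlation_r_threshold:
                rows.append((circ_id, mrna_id, float(r), float(p)))
    return pd.DataFrame(rows, columns=["circ_id", "mrna_id", "r", "p"])


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run every stage in order and optionally write result tables.

    Written outputs: circrnas.tsv / circrnas.bed, circ_de.tsv,
    mrna_de.tsv, network_edges.tsv, pair_correlations.tsv,
    mre_sites.tsv, interactions_{circ,mrna}.tsv, triads.tsv (+ the
    mechanism text), report.json.
    """
    report = PipelineReport()

    # --- stage 1: circRNA detection ---------------------------------------
    try:
        linear_ids = (
            read_sam_linear_ids(inputs.sam_path) if inputs.sam_path else None
        )
        if inputs.reads:
            report.circrnas = detect_circrnas(
                inputs.reads,
                inputs.genome,
                inputs.annotations,
                config,
                linear_read_ids=linear_ids,
            )
        else:
            report.circrnas = []
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(f"stage detect-circ failed: {exc}") from exc
    logger.info(
        "detect-circ: %d reads in, %d circRNAs out (min_support=%d, "
        "min_splice_score=%.3g, max_span=%d, min_overhang=%d)",
        len(inputs.reads), len(report.circrnas), config.min_support_reads,
        config.min_splice_score, config.max_junction_span_bp, config.min_overhang_nt,
    )
    if not inputs.reads:
        report.skipped["detect-circ"] = "no reads supplied; zero circRNA calls"

    # --- stage 2: differential expression ----------------------------------
    try:
        if inputs.mrna_counts is not None:
            report.mrna_de = diffexpr.run_de(inputs.mrna_counts, config)
        if inputs.circ_counts is not None:
            report.circ_de = diffexpr.run_de(inputs.circ_counts, config)
        if inputs.mirna_counts is not None:
            report.mirna_de = diffexpr.run_de(inputs.mirna_counts, config)
    except Exception as exc:
        raise StageError(f"stage diffexp failed: {exc}") from exc
    for name, de in (("mrna", report.mrna_de), ("circ", report.circ_de)):
        if de is not None:
            logger.info(
                "diffexp[%s]: %d features, %d called (|FC|>%.3g, FDR<%.3g)",
                name, len(de), int(de["called"].sum()),
                config.fc_threshold, config.fdr_threshold,
            )

    # --- stage 3: co-expression -------------------------------------------
    detected_ids = [c.id for c in report.circrnas]
    if report.circ_de is None or report.mrna_de is None:
        report.skipped["coexpress"] = "circ or mRNA counts missing"
    elif not detected_ids:
        report.skipped["coexpress"] = "no circRNAs detected; nothing to correlate"
    else:
        try:
            network = coexpr.pearson_network(inputs.mrna_counts, config)
            report.network_edges = network.edge_table()
            de_circ_ids = sorted(
                set(report.circ_de.loc[report.circ_de["called"], "feature_id"])
                & set(detected_ids)
            )
            de_mrna_ids = sorted(
                report.mrna_de.loc[report.mrna_de["called"], "feature_id"]
            )
            report.pair_correlations = pair_correlations(
                inputs.circ_counts, inputs.mrna_counts,
                de_circ_ids, de_mrna_ids, config,
            )
        except Exception as exc:
            raise StageError(f"stage coexpress failed: {exc}") from exc
        logger.info(
            "coexpress: %d network edges, %d significant DE circ-mRNA pairs "
            "(p<%.3g, |r|>=%.3g)",
            len(report.network_edges), len(report.pair_correlations),
            config.correlation_p_threshold, config.correlation_r_threshold,
        )

    # --- stage 4: MRE prediction -------------------------------------------
    if not detected_ids:
        report.skipped["predict-mre"] = "no circRNAs detected"
    elif not inputs.mirnas:
        report.skipped["predict-mre"] = "no miRNA sequences supplied"
    else:
        try:
            mirna_objs = [mre.MiRNA(mid, seq) for mid, seq in inputs.mirnas.items()]
            circ_targets = {c.id: c.exonic_sequence for c in report.circrnas}
            circ_sites, circ_inter = mre.predict_targets(
                mirna_objs, circ_targets,
                min_seed_class=config.min_seed_class,
                min_duplex_score=config.min_duplex_score,
                circular_targets=set(circ_targets),
            )
            mrna_sites, mrna_inter = mre.predict_targets(
                mirna_objs, inputs.mrna_seqs,
                min_seed_class=config.min_seed_class,
                min_duplex_score=config.min_duplex_score,
            )
            report.mre_sites = pd.concat([circ_sites, mrna_sites], ignore_index=True)
            report.circ_interactions = circ_inter
            report.mrna_interactions = mrna_inter
        except Exception as exc:
            raise StageError(f"stage predict-mre failed: {exc}") from exc
        logger.info(
            "predict-mre: %d miRNAs x (%d circ + %d mRNA) targets -> %d sites, "
            "%d circ + %d mRNA interactions (class>=%s, score>=%.3g)",
            len(inputs.mirnas), len(circ_targets), len(inputs.mrna_seqs),
            len(report.mre_sites), len(circ_inter), len(mrna_inter),
            config.min_seed_class, config.min_duplex_score,
        )

    # --- stage 5: triad assembly -------------------------------------------
    ready = (
        report.circ_interactions is not None
        and report.mrna_interactions is not None
        and report.circ_de is not None
        and report.mrna_de is not None
        and report.pair_correlations is not None
    )
    if not ready:
        report.skipped["assemble-cerna"] = "upstream stage outputs missing"
    else:
        try:
            shared = cerna.shared_mirnas(
                report.circ_interactions, report.mrna_interactions
            )
            report.triads = cerna.assemble_triads(
                shared,
                report.circ_de,
                report.mrna_de,
                report.pair_correlations,
                report.circ_interactions,
                report.mrna_interactions,
                mirna_de=report.mirna_de,
            )
        except Exception as exc:
            raise StageError(f"stage assemble-cerna failed: {exc}") from exc
        logger.info(
            "assemble-cerna: %d circ-mRNA pairs share miRNAs -> %d triads",
            len(shared), len(report.triads),
        )

    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tsv(circrna_table(report.circrnas), out_dir / "circrnas.tsv")
    (out_dir / "circrnas.bed").write_text(circrna_bed(report.circrnas))
    for name, df in (
        ("circ_de", report.circ_de),
        ("mrna_de", report.mrna_de),
        ("network_edges", report.network_edges),
        ("pair_correlations", report.pair_correlations),
        ("mre_sites", report.mre_sites),
        ("interactions_circ", report.circ_interactions),
        ("interactions_mrna", report.mrna_interactions),
    ):
        if df is not None:
            write_tsv(df, out_dir / f"{name}.tsv")
    cerna.triad_report(report.triads, out_dir / "triads.tsv")
    write_json(report.summary(), out_dir / "report.json")
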