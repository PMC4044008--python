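"""End-to-end orchestration of the lncRNA identification cascade.

Stage order follows the screen's flowchart: differential-expression screen
-> coding-potential filter and length/ORF screen -> positional
classification -> miRNA-precursor detection -> exact small-RNA read matching
-> hierarchical precursor taxonomy -> antisense CDS pairing -> tissue
specificity.  Every stage writes its intermediate table under the configured
output directory, and the summary mirrors the two headline count matrices of
such screens: direction x positional class, and precursor class x positional
class.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cds as cds_mod
from . import coding, expression, genomic, precursor, tissue
from .config import PipelineConfig
from .errors import ValidationError
from .io_formats import (POSITIONAL_CLASSES, PRECURSOR_CLASSES, ClassificationResult,
                         classification_summary, read_counts, read_fasta, read_gff3,
                         read_srna_fasta, read_transcript_loci, read_transcripts_fasta,
                         write_classification_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "summarize_counts"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    expression: pd.DataFrame
    candidates: list[str]
    results: list[ClassificationResult]
    table4: pd.DataFrame
    tissue: pd.DataFrame | None
    summary_direction: pd.DataFrame
    summary_precursor: pd.DataFrame


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def summarize_counts(results: list[ClassificationResult]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two headline count matrices, each with marginal totals.

    Returns ``(direction x positional, precursor x positional)``; the grand
    totals of both equal the cohort size by construction.
    """
    direction = pd.DataFrame(0, index=["up", "down"], columns=list(POSITIONAL_CLASSES))
    for r in results:
        if r.direction in direction.index:
            direction.loc[r.direction, r.positional_class] += 1
    direction["Total"] = direction.sum(axis=1)
    direction.loc["Total"] = direction.sum(axis=0)
    direction.index.name = "direction"
    return direction, classification_summary(results)


def _load_coding_labels(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"])
    bad = set(df["label"]) - {"coding", "noncoding"}
    if bad:
        raise ValidationError(f"coding label table has labels {sorted(bad)}")
    return dict(zip(df["id"], df["label"]))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full cascade and write all intermediate and summary tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip_stages)

    for name in ("transcripts_fasta", "counts_tsv", "genes_gff3"):
        logger.info("input %s = %s (sha256 %s)", name, getattr(config, name),
                    _checksum(getattr(config, name)))

    loci = read_transcript_loci(config.transcripts_gff3)
    transcripts = read_transcripts_fasta(config.transcripts_fasta, loci)
    by_id = {t.id: t for t in transcripts}
    logger.info("loaded %d transcripts", len(transcripts))

    # -- stage 1: differential expression -----------------------------------
    counts = read_counts(config.counts_tsv)
    lengths = {t.id: t.length_nt for t in transcripts}
    records = expression.call_differential(
        counts, lengths,
        fold_threshold=config.fold_threshold,
        fdr_threshold=config.fdr_threshold,
        control=config.control_label,
        treatment=config.treatment_label,
    )
    expr = expression.expression_table(records)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    direction_of = dict(zip(expr.index, expr["direction"]))
    if "de" in skip:
        logger.info("stage de: SKIPPED; passing all %d transcripts on", len(transcripts))
        responsive = [t for t in transcripts if t.id in direction_of]
    else:
        responsive = [t for t in transcripts
                      if direction_of.get(t.id, "unchanged") != "unchanged"]
        logger.info("stage de: %d / %d transcripts responsive", len(responsive),
                    len(transcripts))

    # -- stage 2: coding filter ----------------------------------------------
    if "coding_filter" in skip:
        logger.info("stage coding_filter: SKIPPED")
        candidates = responsive
    else:
        labels = (_load_coding_labels(config.coding_labels_tsv)
                  if config.coding_labels_tsv else None)
        candidates = coding.filter_lncrna_candidates(
            responsive, min_length_nt=config.min_length_nt,
            max_orf_aa=config.max_orf_aa, labels=labels)
        logger.info("stage coding_filter: %d / %d candidates retained",
                    len(candidates), len(responsive))
    pd.Series([t.id for t in candidates], name="transcript_id").to_csv(
        outdir / "candidates.tsv", sep="\t", index=False)

    # -- stage 3: positional classes -----------------------------------------
    annotation = read_gff3(config.genes_gff3)
    positional: dict[str, genomic.PositionalClass] = {}
    for t in candidates:
        if t.locus is None:
            raise ValidationError(f"transcript {t.id} has no genomic locus")
        positional[t.id] = genomic.classify_position(
            t.locus, annotation, config.same_strand_precedence)
    logger.info("stage positional: %s",
                {c: sum(p.label == c for p in positional.values())
                 for c in POSITIONAL_CLASSES})

    # -- stage 4: miRNA precursors -------------------------------------------
    precursor_lib = read_fasta(config.precursors_fasta)
    mirna_calls = precursor.classify_mirna_precursor(
        candidates, precursor_lib,
        min_identity_pct=config.mirna_min_identity_pct,
        min_precursor_cov_pct=config.mirna_min_coverage_pct,
        both_strands=config.mirna_both_strands)
    logger.info("stage mirna: %d precursor hosts", len(mirna_calls))

    # -- stage 5: exact sRNA read matching -----------------------------------
    reads = (read_srna_fasta(config.shrna_fasta, "shRNA")
             + read_srna_fasta(config.sirna_fasta, "siRNA"))
    support = precursor.match_reads_exact(candidates, reads,
                                          both_strands=config.read_both_strands)

    # -- stage 6: hierarchy ----------------------------------------------------
    results: list[ClassificationResult] = []
    classes: dict[str, precursor.PrecursorClass] = {}
    for t in candidates:
        cls = precursor.hierarchical_classify(t.id, mirna_calls, support,
                                              min_reads=config.min_reads)
        classes[t.id] = cls
        bits = []
        if cls.mirna_hits:
            bits.append("precursors=" + ",".join(h.subject_id for h in cls.mirna_hits))
        for s in cls.read_support:
            bits.append(f"{s.library}_reads={s.distinct_reads}")
        if cls.shrna_only:
            bits.append("flag=shRNA_support_without_siRNA")
        results.append(ClassificationResult(
            t.id, positional[t.id].label, cls.label,
            direction_of.get(t.id, "unchanged"), ";".join(bits)))
    logger.info("stage hierarchy: %s",
                {c: sum(r.precursor_class == c for r in results)
                 for c in PRECURSOR_CLASSES})
    write_classification_table(results, outdir / "classification.tsv")

    # -- stage 7: CDS pairing of non-antisense "other" lncRNAs ----------------
    table4 = pd.DataFrame(columns=cds_mod.TABLE_COLUMNS)
    if "cds" not in skip:
        others = [by_id[r.id] for r in results
                  if r.precursor_class == "other" and r.positional_class != "antisense"]
        cds_set = read_fasta(config.cds_fasta)
        pairs = cds_mod.pair_with_cds(
            others, cds_set,
            min_identity_pct=config.cds_min_identity_pct,
            min_cov_pct=config.cds_min_coverage_pct,
            coverage_mode=config.cds_coverage_mode)
        table4 = cds_mod.table4_report(pairs, outdir / "cds_pairs.tsv")
        logger.info("stage cds: %d near-perfect pairs over %d lncRNAs",
                    len(table4), table4["Query_name"].nunique() if len(table4) else 0)

    # -- stage 8: tissue specificity -------------------------------------------
    tissue_df = None
    if config.tissue_tsv and "tissue" not in skip:
        matrix = pd.read_csv(config.tissue_tsv, sep="\t", index_col=0)
        other_ids = [r.id for r in results if r.precursor_class == "other"]
        present = [i for i in other_ids if i in matrix.index]
        tissue_df = tissue.tissue_profiles(matrix.loc[present], config.tau_threshold)
        tissue_df.to_csv(outdir / "tissue_tau.tsv", sep="\t")
        logger.info("stage tissue: %d / %d 'other' lncRNAs in matrix, %d specific",
                    len(present), len(other_ids), tissue_df["specific_tissue"].notna().sum())

    summary_direction, summary_precursor = summarize_counts(results)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("# direction x positional class\n")
        fh.write(summary_direction.to_string() + "\n\n")
        fh.write("# precursor class x positional class\n")
        fh.write(summary_precursor.to_string() + "\n")

    return PipelineResult(
        config=config,
        expression=expr,
        candidates=[t.id for t in candidates],
        results=results,
        table4=table4,
        tissue=tissue_df,
        summary_direction=summary_direction,
        summary_precursor=summary_precursor,
    )
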