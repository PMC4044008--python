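"""Positional classification of lncRNAs relative to annotated gene loci.

Each transcript gets exactly one of four labels:

* ``intergenic`` — shares no nucleotide with any gene span;
* ``antisense`` — overlaps only gene(s) on the opposite strand;
* ``intragenic`` — same-strand overlap, fully contained within one gene span;
* ``overlapping`` — same-strand overlap extending past a gene boundary.

Overlap is tested against gene *spans* (introns count as inside the gene),
and when both same- and opposite-strand overlaps exist the same-strand
relation wins by default.  Both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io_formats import GeneFeature, GenomeAnnotation, Locus

__all__ = ["PositionalClass", "classify_position"]


@dataclass(frozen=True)
class PositionalClass:
    label: str                      # intergenic / intragenic / antisense / overlapping
    supporting_gene: str | None     # gene with maximal overlap, None iff intergenic
    overlap_nt: int


def _overlap_nt(locus: Locus, gene: GeneFeature) -> int:
    return max(0, min(locus.end, gene.end) - max(locus.start, gene.start))


def _best_gene(locus: Locus, genes: list[GeneFeature]) -> tuple[GeneFeature, int]:
    # maximal overlap; ties broken by smaller gene start
    return max(
        ((g, _overlap_nt(locus, g)) for g in genes),
        key=lambda pair: (pair[1], -pair[0].start),
    )


def classify_position(
    locus: Locus,
    annotation: GenomeAnnotation,
    same_strand_precedence: bool = True,
) -> PositionalClass:
    """Assign the positional class of a transcript locus.

    Decision cascade: no gene overlap -> intergenic; otherwise same-strand
    overlaps take precedence (configurable) — containment in one gene span
    gives intragenic, crossing a boundary gives overlapping; overlaps
    restricted to the opposite strand give antisense.
    """
    if locus.end <= locus.start:
        raise ValidationError(f"degenerate transcript interval [{locus.start}, {locus.end})")
    hits = annotation.overlapping(locus.chrom, locus.start, locus.end)
    if not hits:
        return PositionalClass("intergenic", None, 0)

    same = [g for g in hits if g.strand == locus.strand]
    opposite = [g for g in hits if g.strand != locus.strand]
    if same and (same_strand_precedence or not opposite):
        contained = [g for g in same if g.start <= locus.start and locus.end <= g.end]
        if contained:
            gene, nt = _best_gene(locus, contained)
            return PositionalClass("intragenic", gene.gene_id, nt)
        gene, nt = _best_gene(locus, same)
        return PositionalClass("overlapping", gene.gene_id, nt)
    gene, nt = _best_gene(locus, opposite)
    return PositionalClass("antisense", gene.gene_id, nt)
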