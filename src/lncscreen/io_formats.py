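"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: everything in memory is 0-based, half-open ``[start,
end)``.  GFF3 files are 1-based inclusive, so the conversion happens here at
the I/O boundary and nowhere else.

Sequence alphabet is restricted to ``{A, C, G, T, N}``; anything else is
rejected rather than silently remapped, because downstream small-RNA matching
is exact and a silently converted base would change its results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .errors import DuplicateRecordError, FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(
            f"{label}: sequence contains characters outside A/C/G/T/N: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Locus:
    """A genomic interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"locus end {self.end} < start {self.start}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript isoform: sequence plus optional genomic locus."""

    id: str
    sequence: str
    locus: Locus | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.id))

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene span (not an exon model)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"gene {self.gene_id}: end < start")
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SmallRNARead:
    """A small-RNA read from one of the shRNA / siRNA / miRNA libraries."""

    read_id: str
    sequence: str
    library: str
    min_len: int = 18
    max_len: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.read_id))
        if not (self.min_len <= len(self.sequence) <= self.max_len):
            raise ValidationError(
                f"read {self.read_id}: length {len(self.sequence)} outside "
                f"[{self.min_len}, {self.max_len}]"
            )


@dataclass(frozen=True)
class ClassificationResult:
    """Flat per-transcript record written to the classification table."""

    id: str
    positional_class: str
    precursor_class: str
    direction: str
    evidence: str = ""


class GenomeAnnotation:
    """Strand-aware gene intervals with fast overlap queries per chromosome."""

    def __init__(self, genes: Iterable[GeneFeature]):
        self.genes: list[GeneFeature] = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            if g.end > g.start:  # zero-length spans cannot be indexed
                self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        """Genes sharing >= 1 nt with [start, end); absent chromosomes are gene-free."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, on_duplicate: str = "error") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Ids are taken up to the first whitespace; sequences are uppercased.
    ``on_duplicate`` is ``"error"`` (default) or ``"warn"``.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            msg = f"{path}: duplicate FASTA id {rec.id!r}"
            if on_duplicate == "warn":
                warnings.warn(msg)
            else:
                raise DuplicateRecordError(msg)
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_transcripts_fasta(path: str | Path,
                           loci: Mapping[str, Locus] | None = None) -> list[Transcript]:
    """Read transcripts, attaching genomic loci by id when provided."""
    loci = loci or {}
    return [Transcript(name, seq, loci.get(name)) for name, seq in read_fasta(path)]


def read_srna_fasta(path: str | Path, library: str,
                    min_len: int = 18, max_len: int = 30) -> list[SmallRNARead]:
    return [
        SmallRNARead(name, seq, library, min_len, max_len)
        for name, seq in read_fasta(path, on_duplicate="warn")
    ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_rows(path: Path):
    """Yield validated 9-column rows from a GFF3 file (comments skipped)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            yield cols


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Extract gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    Only features of type ``gene`` enter the gene index; GFF3 1-based
    inclusive coordinates become 0-based half-open internally.
    """
    path = Path(path)
    genes = []
    for cols in _gff3_rows(path):
        if cols[2] != "gene":
            continue
        if cols[6] not in STRANDS:
            raise FormatError(f"{path}: gene feature with strand {cols[6]!r}")
        attrs = _parse_attributes(cols[8])
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if not gene_id:
            raise FormatError(f"{path}: gene feature without ID attribute")
        biotype = attrs.get("biotype", "other")
        if biotype != "protein_coding":
            biotype = "other"
        genes.append(GeneFeature(gene_id, cols[0], int(cols[3]) - 1, int(cols[4]),
                                 cols[6], biotype))
    return GenomeAnnotation(genes)


def read_transcript_loci(path: str | Path) -> dict[str, Locus]:
    """Read ``transcript`` features from a GFF3 file as an id -> locus map."""
    path = Path(path)
    loci: dict[str, Locus] = {}
    for cols in _gff3_rows(path):
        if cols[2] != "transcript":
            continue
        attrs = _parse_attributes(cols[8])
        tid = attrs.get("ID")
        if not tid:
            raise FormatError(f"{path}: transcript feature without ID attribute")
        if tid in loci:
            raise DuplicateRecordError(f"{path}: duplicate transcript id {tid!r}")
        loci[tid] = Locus(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
    return loci


def write_gff3(path: str | Path,
               genes: Iterable[GeneFeature] = (),
               transcript_loci: Mapping[str, Locus] | None = None,
               source: str = "lncscreen") -> None:
    """Write genes and/or transcript loci back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.start + 1), str(g.end), ".",
                g.strand, ".", f"ID={g.gene_id};biotype={g.biotype}",
            ]) + "\n")
        for tid, loc in (transcript_loci or {}).items():
            fh.write("\t".join([
                loc.chrom, source, "transcript", str(loc.start + 1), str(loc.end),
                ".", loc.strand, ".", f"ID={tid}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-transcript count table.

    The header names replicate columns as ``<condition>_<replicate>``
    (e.g. ``control_r1``).  Returns a DataFrame indexed by transcript id with
    MultiIndex columns ``(condition, replicate)``.  Transcripts absent from
    the file stay absent (no zero-filling).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        logger.warning("%s: count table has no data rows", path)
    cols = []
    for c in df.columns:
        if "_" not in c:
            raise FormatError(f"{path}: column {c!r} not of the form condition_replicate")
        cond, rep = c.rsplit("_", 1)
        cols.append((cond, rep))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
    values = df.to_numpy()
    if df.size and not ((values == values.astype(int)) & (values >= 0)).all():
        raise ValidationError(f"{path}: counts must be non-negative integers")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    flat = df.copy()
    flat.columns = [f"{cond}_{rep}" for cond, rep in df.columns]
    flat.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Classification table
# ---------------------------------------------------------------------------

def write_classification_table(results: Sequence[ClassificationResult],
                               path: str | Path) -> None:
    """Write the per-transcript classification TSV plus a count-summary block.

    The summary block (precursor class x positional class, with margins) is
    appended as ``#``-prefixed lines so the main table stays machine-readable.
    """
    path = Path(path)
    rows = pd.DataFrame(
        [(r.id, r.positional_class, r.precursor_class, r.direction, r.evidence)
         for r in results],
        columns=["id", "positional_class", "precursor_class", "direction", "evidence"],
    )
    with open(path, "w") as fh:
        rows.to_csv(fh, sep="\t", index=False)
        fh.write("#\n# summary: precursor class x positional class\n")
        summary = classification_summary(results)
        for line in summary.to_csv(sep="\t").splitlines():
            fh.write(f"# {line}\n")


POSITIONAL_CLASSES = ("intergenic", "intragenic", "antisense", "overlapping")
PRECURSOR_CLASSES = ("miRNA_precursor", "shRNA_siRNA_precursor", "siRNA_precursor", "other")


def classification_summary(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Precursor x positional count matrix with row/column totals."""
    mat = pd.DataFrame(0, index=list(PRECURSOR_CLASSES), columns=list(POSITIONAL_CLASSES))
    for r in results:
        mat.loc[r.precursor_class, r.positional_class] += 1
    mat["Total"] = mat.sum(axis=1)
    mat.loc["Total"] = mat.sum(axis=0)
    mat.index.name = "precursor_class"
    return mat
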