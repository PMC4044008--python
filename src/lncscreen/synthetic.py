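"""Seeded synthetic dataset with planted ground truth for every pipeline stage.

The generator emulates the inputs of a drought-response lncRNA screen on a
toy genome: annotated genes on both strands separated by >= 1 kb of
intergenic space; candidate lncRNAs planted in each positional class
(intergenic / intragenic / antisense / overlapping); hosts carrying verbatim
miRNA hairpin precursors; hosts from which 21-24 nt small-RNA reads are
sliced into the shRNA and/or siRNA libraries; "other" lncRNAs, some with a
CDS constructed as the reverse complement of one of their subsequences;
count tables with planted fold changes under Poisson noise; and a
nine-tissue expression matrix with planted tissue-specific and ubiquitous
profiles.  Decoy transcripts (too short, long-ORF, high coding potential,
not differentially expressed) exercise every filter.

Background sequence is i.i.d. uniform over {A,C,G,T}, so at the pipeline's
identity/coverage thresholds spurious alignments and spurious exact 21-mer
matches are vanishingly rare and the planted truth stays clean.  All
randomness flows from a single :class:`numpy.random.Generator`; the same
seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .coding import find_longest_orf
from .errors import GenerationError
from .io_formats import (GeneFeature, Locus, write_counts, write_fasta, write_gff3)

__all__ = ["DatasetSpec", "SyntheticDataset", "generate_dataset"]

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TISSUES = (
    "10DAP_Whole_Seed", "R1_Anthers", "R1_Innermost_Husk",
    "R1_Pre-pollination_Cob", "R1_Silks", "V1_GH_Primary_Root",
    "V1_Pooled_Leaves", "V3_Topmost_Leaf", "V4_Stem_and_SAM",
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DatasetSpec:
    """Cohort composition and noise parameters of the synthetic study.

    The default cohort of 60 lncRNAs follows the shape of the real screen's
    taxonomy (miRNA precursors rarest, then shRNA/siRNA, then siRNA, "other"
    largest) and leans intergenic in its positional mix.  Planted expression
    changes are 4-fold with Poisson replicate noise at means of roughly
    100-400 pooled reads, comfortably above the screen's 2-fold gate.
    """

    # cohort sizes per precursor class
    n_mirna_hosts: int = 4
    n_shsi_hosts: int = 10
    n_sirna_hosts: int = 20
    n_other: int = 26
    # decoys exercising the filters
    n_decoy_short: int = 4
    n_decoy_long_orf: int = 4
    n_decoy_coding: int = 4
    n_background: int = 250
    # libraries
    n_decoy_precursors: int = 6
    n_decoy_reads: int = 30          # unmatched reads added to each sRNA library
    n_decoy_cds: int = 20
    n_cds_hosts: int = 4             # "other" lncRNAs given antisense CDS partners
    n_shrna_only: int = 1            # "other" lncRNAs with shRNA-only read support
    # expression model
    true_fold: float = 4.0
    n_replicates: int = 2
    # genome layout
    n_chromosomes: int = 2
    genes_per_chromosome: int = 14
    min_gap: int = 1500
    # tissue matrix
    tissues: tuple[str, ...] = TISSUES
    n_tissue_background: int = 30

    @property
    def n_cohort(self) -> int:
        return self.n_mirna_hosts + self.n_shsi_hosts + self.n_sirna_hosts + self.n_other


@dataclass
class SyntheticDataset:
    """File paths plus the per-transcript truth table of one generated dataset."""

    outdir: Path
    genome_fasta: Path
    genes_gff3: Path
    transcripts_fasta: Path
    transcripts_gff3: Path
    counts_tsv: Path
    precursors_fasta: Path
    shrna_fasta: Path
    sirna_fasta: Path
    cds_fasta: Path
    tissue_tsv: Path
    truth_tsv: Path
    truth: pd.DataFrame
    spec: DatasetSpec


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _orf_nt(rng: np.random.Generator, aa: int) -> str:
    """An ORF of exactly ``aa`` amino acids: ATG, aa-1 non-stop codons, stop."""
    codons = ["".join(BASES[rng.integers(0, 4, 3)]) for _ in range(4 * aa)]
    codons = [c for c in codons if c not in ("TAA", "TAG", "TGA")][: aa - 1]
    if len(codons) < aa - 1:
        raise GenerationError("could not sample enough non-stop codons")
    return "ATG" + "".join(codons) + "TAA"


def _noncoding_seq(rng: np.random.Generator, n: int, max_aa: int = 60,
                   max_fraction: float = 0.45, tries: int = 500) -> str:
    """Random sequence whose longest ORF is short in both AA and span terms,
    so it survives the coding-potential heuristic and the ORF gate with margin."""
    for _ in range(tries):
        s = _random_seq(rng, n)
        orf = find_longest_orf(s)
        if orf is None:
            return s
        if orf.aa_length <= max_aa and (3 * orf.aa_length + 3) / n <= max_fraction:
            return s
    raise GenerationError(f"no ORF-poor sequence of length {n} after {tries} tries")


def _seq_with_orf(rng: np.random.Generator, n: int, lo_aa: int, hi_aa: int,
                  max_fraction: float = 1.0, tries: int = 500) -> str:
    """Random sequence whose longest ORF lands in [lo_aa, hi_aa] amino acids."""
    target = (lo_aa + hi_aa) // 2
    for _ in range(tries):
        orf = _orf_nt(rng, target)
        pad = n - len(orf)
        left = rng.integers(0, pad + 1)
        s = _random_seq(rng, int(left)) + orf + _random_seq(rng, int(pad - left))
        call = find_longest_orf(s)
        if (call is not None and lo_aa <= call.aa_length <= hi_aa
                and (3 * call.aa_length + 3) / n <= max_fraction):
            return s
    raise GenerationError(f"no sequence with ORF in [{lo_aa},{hi_aa}] AA after {tries} tries")


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

class _Layout:
    """Gene and gap coordinates of the toy genome, plus placement helpers."""

    def __init__(self, rng: np.random.Generator, spec: DatasetSpec):
        self.rng = rng
        self.genes: list[GeneFeature] = []
        self.gaps: list[tuple[str, int, int]] = []   # (chrom, start, end)
        self.chrom_len: dict[str, int] = {}
        for c in range(spec.n_chromosomes):
            chrom = f"chr{c + 1}"
            pos = 0
            for g in range(spec.genes_per_chromosome):
                gap = int(rng.integers(spec.min_gap, spec.min_gap + 1200))
                self.gaps.append((chrom, pos, pos + gap))
                pos += gap
                glen = int(rng.integers(1500, 3000))
                strand = "+" if rng.random() < 0.5 else "-"
                self.genes.append(GeneFeature(
                    f"gene_{chrom}_{g + 1:03d}", chrom, pos, pos + glen, strand))
                pos += glen
            tail = int(rng.integers(spec.min_gap, spec.min_gap + 1200))
            self.gaps.append((chrom, pos, pos + tail))
            self.chrom_len[chrom] = pos + tail
        self._gap_cursor = 0
        self._gene_cursor = 0

    def _next_gap(self, need: int) -> tuple[str, int, int]:
        for _ in range(len(self.gaps)):
            gap = self.gaps[self._gap_cursor % len(self.gaps)]
            self._gap_cursor += 1
            if gap[2] - gap[1] >= need:
                return gap
        raise GenerationError(f"no intergenic gap can hold {need} nt")

    def _next_gene(self, need: int) -> GeneFeature:
        for _ in range(len(self.genes)):
            gene = self.genes[self._gene_cursor % len(self.genes)]
            self._gene_cursor += 1
            if gene.end - gene.start >= need:
                return gene
        raise GenerationError(f"no gene span can hold {need} nt")

    def place(self, positional: str, tlen: int) -> Locus:
        rng = self.rng
        if positional == "intergenic":
            chrom, gs, ge = self._next_gap(tlen + 40)
            start = gs + 20 + int(rng.integers(0, ge - gs - tlen - 40 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            return Locus(chrom, start, start + tlen, strand)
        if positional in ("intragenic", "antisense"):
            gene = self._next_gene(tlen + 20)
            start = gene.start + 10 + int(rng.integers(0, gene.end - gene.start - tlen - 20 + 1))
            strand = gene.strand if positional == "intragenic" else (
                "-" if gene.strand == "+" else "+")
            return Locus(gene.chrom, start, start + tlen, strand)
        if positional == "overlapping":
            # cross the gene's 3' boundary into the following gap
            gene = self._next_gene(200)
            inside = int(rng.integers(60, min(tlen - 60, gene.end - gene.start) + 1))
            start = gene.end - inside
            return Locus(gene.chrom, start, start + tlen, gene.strand)
        raise GenerationError(f"unknown positional class {positional!r}")


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _positional_pattern(spec: DatasetSpec) -> list[str]:
    """Fixed per-group positional assignments, every class represented."""
    def spread(n: int, inter: int, intra: int, anti: int, over: int) -> list[str]:
        out = (["intergenic"] * inter + ["intragenic"] * intra
               + ["antisense"] * anti + ["overlapping"] * over)
        if len(out) < n:
            out += ["intergenic"] * (n - len(out))
        return out[:n]

    return (
        spread(spec.n_mirna_hosts, spec.n_mirna_hosts - 2, 1, 0, 1)
        + spread(spec.n_shsi_hosts, spec.n_shsi_hosts - 4, 2, 1, 1)
        + spread(spec.n_sirna_hosts, spec.n_sirna_hosts - 8, 5, 1, 2)
        + spread(spec.n_other, spec.n_other - 11, 7, 2, 2)
    )


def _slice_reads(rng: np.random.Generator, seq: str, n_reads: int,
                 prefix: str, start_index: int) -> list[tuple[str, str]]:
    """21-24 nt sub-reads of ``seq``, random offset, both polarities."""
    reads = []
    for k in range(n_reads):
        length = int(rng.integers(21, 25))
        off = int(rng.integers(0, len(seq) - length + 1))
        piece = seq[off:off + length]
        if rng.random() < 0.5:
            piece = _revcomp(piece)
        reads.append((f"{prefix}_{start_index + k:05d}", piece))
    return reads


def generate_dataset(seed: int, outdir: str | Path,
                     spec: DatasetSpec | None = None) -> SyntheticDataset:
    """Generate the complete toy input set plus its truth table under ``outdir``."""
    spec = spec or DatasetSpec()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    layout = _Layout(rng, spec)

    transcripts: list[tuple[str, str]] = []        # (id, sequence)
    loci: dict[str, Locus] = {}
    truth_rows: list[dict] = []
    shrna_reads: list[tuple[str, str]] = []
    sirna_reads: list[tuple[str, str]] = []
    precursors: list[tuple[str, str]] = []
    cds_records: list[tuple[str, str]] = []

    positional = _positional_pattern(spec)
    groups = (["miRNA_precursor"] * spec.n_mirna_hosts
              + ["shRNA_siRNA_precursor"] * spec.n_shsi_hosts
              + ["siRNA_precursor"] * spec.n_sirna_hosts
              + ["other"] * spec.n_other)
    down_every = 5   # every 5th cohort member is planted down-regulated

    # -- miRNA hairpin precursors: one shared between the last two hosts ----
    n_prec = max(1, spec.n_mirna_hosts - 1)
    prec_seqs = [_random_seq(rng, int(rng.integers(100, 141))) for _ in range(n_prec)]
    for i, s in enumerate(prec_seqs):
        precursors.append((f"zma-MIR{9001 + i} MI{7000001 + i} Zea mays stem-loop", s))

    other_ids: list[str] = []
    cohort_meta: list[dict] = []
    for i, (pclass, pos) in enumerate(zip(groups, positional)):
        tid = f"TCONS_{10000 + i:08d}"
        if pclass == "miRNA_precursor":
            prec = prec_seqs[min(i, n_prec - 1)]
            total = int(rng.integers(max(320, len(prec) + 80), 601))
            for _ in range(500):
                pad = total - len(prec)
                left = int(rng.integers(0, pad + 1))
                seq = _random_seq(rng, left) + prec + _random_seq(rng, pad - left)
                orf = find_longest_orf(seq)
                if orf is None or (orf.aa_length <= 60
                                   and (3 * orf.aa_length + 3) / total <= 0.45):
                    break
            else:
                raise GenerationError("could not embed precursor in an ORF-poor host")
            # half the hosts also shed siRNA reads: the hierarchy must still
            # put them in the miRNA class
            if i % 2 == 0:
                sirna_reads += _slice_reads(rng, seq, int(rng.integers(5, 12)),
                                            "si", len(sirna_reads))
        else:
            seq = _noncoding_seq(rng, int(rng.integers(280, 601)))
            if pclass == "shRNA_siRNA_precursor":
                shrna_reads += _slice_reads(rng, seq, int(rng.integers(4, 10)),
                                            "sh", len(shrna_reads))
                sirna_reads += _slice_reads(rng, seq, int(rng.integers(4, 10)),
                                            "si", len(sirna_reads))
            elif pclass == "siRNA_precursor":
                sirna_reads += _slice_reads(rng, seq, int(rng.integers(8, 20)),
                                            "si", len(sirna_reads))
        transcripts.append((tid, seq))
        loci[tid] = layout.place(pos, len(seq))
        direction = "down" if (i + 1) % down_every == 0 else "up"
        meta = dict(transcript_id=tid, role="lncrna", positional_class=pos,
                    precursor_class=pclass, direction=direction,
                    true_fold=spec.true_fold, cds_partners="", tissue_class="",
                    specific_tissue="", shrna_only=False)
        cohort_meta.append(meta)
        if pclass == "other":
            other_ids.append(tid)

    # -- shRNA-only support: stays "other" in the taxonomy, but flagged -----
    eligible_flag = [m for m in cohort_meta
                     if m["precursor_class"] == "other"][-spec.n_shrna_only:]
    for meta in eligible_flag if spec.n_shrna_only else []:
        seq = dict(transcripts)[meta["transcript_id"]]
        shrna_reads += _slice_reads(rng, seq, int(rng.integers(3, 7)),
                                    "sh", len(shrna_reads))
        meta["shrna_only"] = True

    # -- CDS partners for non-antisense "other" lncRNAs ---------------------
    seq_by_id = dict(transcripts)
    candidates = [m for m in cohort_meta
                  if m["precursor_class"] == "other"
                  and m["positional_class"] != "antisense"
                  and not m["shrna_only"]
                  and len(seq_by_id[m["transcript_id"]]) >= 360]
    if len(candidates) < spec.n_cds_hosts:
        raise GenerationError("not enough long non-antisense 'other' lncRNAs for CDS pairing")
    for j, meta in enumerate(candidates[: spec.n_cds_hosts]):
        seq = seq_by_id[meta["transcript_id"]]
        n_partners = 2 if j == 0 else 1      # one host pairs with two CDSs
        names = []
        for k in range(n_partners):
            cds_len = 3 * int(rng.integers(80, min(110, (len(seq) - 20) // 3) + 1))
            off = int(rng.integers(0, len(seq) - cds_len + 1))
            cds_id = f"GRMZM2G{700000 + 10 * j + k}_T01"
            cds_records.append((cds_id, _revcomp(seq[off:off + cds_len])))
            names.append(cds_id)
        meta["cds_partners"] = ";".join(names)

    # -- planted tissue profiles for the "other" class ----------------------
    n_specific = (len(other_ids) * 3) // 5
    for k, meta in enumerate(m for m in cohort_meta if m["precursor_class"] == "other"):
        if k < n_specific:
            meta["tissue_class"] = "specific"
            meta["specific_tissue"] = spec.tissues[k % len(spec.tissues)]
        else:
            meta["tissue_class"] = "ubiquitous"
    truth_rows.extend(cohort_meta)

    # -- decoys --------------------------------------------------------------
    def add_decoy(tid: str, seq: str, role: str, direction: str) -> None:
        transcripts.append((tid, seq))
        loci[tid] = layout.place("intergenic", len(seq))
        truth_rows.append(dict(transcript_id=tid, role=role, positional_class="",
                               precursor_class="", direction=direction,
                               true_fold=spec.true_fold if direction != "unchanged" else 1.0,
                               cds_partners="", tissue_class="", specific_tissue="",
                               shrna_only=False))

    for d in range(spec.n_decoy_short):
        add_decoy(f"DECOY_SHORT_{d:03d}",
                  _noncoding_seq(rng, int(rng.integers(120, 191)), max_fraction=0.4),
                  "decoy_short", "up" if d % 4 else "down")
    for d in range(spec.n_decoy_long_orf):
        add_decoy(f"DECOY_ORF_{d:03d}",
                  _seq_with_orf(rng, 620, 82, 98, max_fraction=0.5),
                  "decoy_long_orf", "up")
    for d in range(spec.n_decoy_coding):
        add_decoy(f"DECOY_CODING_{d:03d}", _seq_with_orf(rng, 520, 105, 140),
                  "decoy_coding", "up")
    for b in range(spec.n_background):
        add_decoy(f"BG_{b:05d}", _random_seq(rng, int(rng.integers(250, 601))),
                  "background", "unchanged")

    # -- decoy library entries ----------------------------------------------
    for d in range(spec.n_decoy_precursors):
        precursors.append((f"zma-MIR{8001 + d} MI{7100001 + d} Zea mays stem-loop",
                           _random_seq(rng, int(rng.integers(100, 141)))))
    for d in range(spec.n_decoy_reads):
        shrna_reads.append((f"sh_decoy_{d:04d}", _random_seq(rng, int(rng.integers(21, 25)))))
        sirna_reads.append((f"si_decoy_{d:04d}", _random_seq(rng, int(rng.integers(21, 25)))))
    for d in range(spec.n_decoy_cds):
        cds_records.append((f"GRMZM2G{800000 + d}_T01",
                            _random_seq(rng, 3 * int(rng.integers(100, 250)))))

    # -- counts with planted fold changes ------------------------------------
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    count_rows = {}
    for tid, _seq in transcripts:
        direction = truth.loc[tid, "direction"]
        if direction == "up":
            mu_c = rng.uniform(80, 250)
            mu_t = mu_c * spec.true_fold
        elif direction == "down":
            mu_c = rng.uniform(150, 400)
            mu_t = mu_c / spec.true_fold
        else:
            # stable transcripts carry the bulk of sequencing depth, as in a
            # real transcriptome; log-uniform spans lowly to highly expressed
            mu_c = mu_t = float(np.exp(rng.uniform(np.log(100), np.log(3000))))
        count_rows[tid] = np.concatenate([
            rng.poisson(mu_c, spec.n_replicates), rng.poisson(mu_t, spec.n_replicates)])
    columns = pd.MultiIndex.from_tuples(
        [("control", f"r{r + 1}") for r in range(spec.n_replicates)]
        + [("treatment", f"r{r + 1}") for r in range(spec.n_replicates)],
        names=["condition", "replicate"])
    counts = pd.DataFrame.from_dict(count_rows, orient="index", dtype=int)
    counts.columns = columns
    counts.index.name = "transcript_id"

    # -- tissue matrix --------------------------------------------------------
    tissue_ids = other_ids + [f"BG_{b:05d}" for b in range(spec.n_tissue_background)]
    tissue_rows = []
    for tid in tissue_ids:
        tclass = truth.loc[tid, "tissue_class"] if tid in truth.index else ""
        if tclass == "specific":
            target = truth.loc[tid, "specific_tissue"]
            row = [rng.uniform(50, 200) if t == target else rng.uniform(0, 3)
                   for t in spec.tissues]
        else:
            base = rng.uniform(30, 60)
            row = [base * rng.uniform(0.8, 1.25) for _ in spec.tissues]
        tissue_rows.append([tid] + [round(v, 3) for v in row])
    tissue_df = pd.DataFrame(tissue_rows,
                             columns=["transcript_id"] + list(spec.tissues)
                             ).set_index("transcript_id")

    # -- genome sequence ------------------------------------------------------
    genome = [(chrom, _random_seq(rng, length))
              for chrom, length in layout.chrom_len.items()]

    # -- write everything ------------------------------------------------------
    paths = SyntheticDataset(
        outdir=outdir,
        genome_fasta=outdir / "genome.fasta",
        genes_gff3=outdir / "genes.gff3",
        transcripts_fasta=outdir / "transcripts.fasta",
        transcripts_gff3=outdir / "transcripts.gff3",
        counts_tsv=outdir / "counts.tsv",
        precursors_fasta=outdir / "mirna_precursors.fasta",
        shrna_fasta=outdir / "shrna_reads.fasta",
        sirna_fasta=outdir / "sirna_reads.fasta",
        cds_fasta=outdir / "cds.fasta",
        tissue_tsv=outdir / "tissue_matrix.tsv",
        truth_tsv=outdir / "truth.tsv",
        truth=truth,
        spec=spec,
    )
    write_fasta(genome, paths.genome_fasta)
    write_gff3(paths.genes_gff3, genes=layout.genes)
    write_fasta(transcripts, paths.transcripts_fasta)
    write_gff3(paths.transcripts_gff3, transcript_loci=loci)
    write_counts(counts, paths.counts_tsv)
    write_fasta(precursors, paths.precursors_fasta)
    write_fasta(shrna_reads, paths.shrna_fasta)
    write_fasta(sirna_reads, paths.sirna_fasta)
    write_fasta(cds_records, paths.cds_fasta)
    tissue_df.to_csv(paths.tissue_tsv, sep="\t")
    truth.to_csv(paths.truth_tsv, sep="\t")
    return paths
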