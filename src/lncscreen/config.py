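"""Pipeline configuration: every threshold and switch in one round-trippable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Inputs, output directory, thresholds and mode switches of one run.

    Defaults encode the screen's canonical gates: 2-fold change at FDR <
    0.001; candidates >200 nt with ORF <80 AA; miRNA precursors at >99%
    identity and >90% precursor coverage; CDS pairing at >90% identity and
    >90% coverage; >=1 distinct read per small-RNA library; tau >= 0.8 for a
    tissue-specific call.
    """

    # input files
    transcripts_fasta: str = "transcripts.fasta"
    transcripts_gff3: str = "transcripts.gff3"
    genes_gff3: str = "genes.gff3"
    counts_tsv: str = "counts.tsv"
    precursors_fasta: str = "mirna_precursors.fasta"
    shrna_fasta: str = "shrna_reads.fasta"
    sirna_fasta: str = "sirna_reads.fasta"
    cds_fasta: str = "cds.fasta"
    tissue_tsv: str = ""                 # optional
    coding_labels_tsv: str = ""          # optional external coding/noncoding labels
    outdir: str = "lncscreen_out"

    # thresholds
    fold_threshold: float = 2.0
    fdr_threshold: float = 0.001
    min_length_nt: int = 201
    max_orf_aa: int = 79
    mirna_min_identity_pct: float = 99.0
    mirna_min_coverage_pct: float = 90.0
    cds_min_identity_pct: float = 90.0
    cds_min_coverage_pct: float = 90.0
    min_reads: int = 1
    tau_threshold: float = 0.8

    # switches
    control_label: str = "control"
    treatment_label: str = "treatment"
    same_strand_precedence: bool = True
    read_both_strands: bool = True
    mirna_both_strands: bool = True
    cds_coverage_mode: str = "max"       # max / both / query
    qpcr_flip_sign: bool = False
    skip_stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.fold_threshold >= 1):
            raise ValidationError("fold_threshold must be >= 1")
        if not (0 < self.fdr_threshold <= 1):
            raise ValidationError("fdr_threshold must be in (0, 1]")
        for name in ("mirna_min_identity_pct", "mirna_min_coverage_pct",
                     "cds_min_identity_pct", "cds_min_coverage_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name} must be a percentage in [0, 100]")
        if not (0 <= self.tau_threshold <= 1):
            raise ValidationError("tau_threshold must be in [0, 1]")
        if self.cds_coverage_mode not in ("max", "both", "query"):
            raise ValidationError(f"bad cds_coverage_mode {self.cds_coverage_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
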