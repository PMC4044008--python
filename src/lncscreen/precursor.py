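"""Local alignment and the hierarchical small-RNA precursor taxonomy.

A drought-responsive lncRNA is classified, in order of precedence, as

1. ``miRNA_precursor`` — some precursor from the hairpin library aligns with
   identity above 99% and precursor coverage above 90%;
2. ``shRNA_siRNA_precursor`` — exact-match read support in *both* the shRNA
   and the siRNA library;
3. ``siRNA_precursor`` — exact-match read support in the siRNA library only;
4. ``other`` — none of the above; candidates to act as long molecules.

Alignment uses affine-gap Smith-Waterman (match +2, mismatch -3, gap open
-5, gap extend -2) via Biopython's :class:`Bio.Align.PairwiseAligner`; hit
length counts every alignment column including gap columns, which is why a
coverage can exceed 100%.  Zero-mismatch short-read mapping is semantically
exact substring occurrence, and is implemented as such over both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Seq import reverse_complement

from .errors import ValidationError
from .io_formats import SmallRNARead, Transcript

__all__ = [
    "Scoring",
    "AlignmentHit",
    "ReadSupport",
    "PrecursorClass",
    "align_local",
    "coverage_stats",
    "classify_mirna_precursor",
    "match_reads_exact",
    "hierarchical_classify",
]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; the first gap position costs ``gap_open``,
    each further position ``gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    score: float
    hit_len: int            # alignment columns, gap columns included
    matches: int            # identical columns
    query_len: int
    subject_len: int
    orientation: str        # "plus/plus" or "plus/minus"

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.hit_len

    @property
    def query_cov_pct(self) -> float:
        return 100.0 * self.hit_len / self.query_len

    @property
    def subject_cov_pct(self) -> float:
        return 100.0 * self.hit_len / self.subject_len


@dataclass(frozen=True)
class ReadSupport:
    """Exact-match small-RNA read evidence on one lncRNA from one library."""

    lncrna_id: str
    library: str
    distinct_reads: int
    positions: tuple[tuple[int, str], ...]  # (offset in lncRNA, strand)


@dataclass(frozen=True)
class PrecursorClass:
    label: str   # miRNA_precursor / shRNA_siRNA_precursor / siRNA_precursor / other
    mirna_hits: tuple[AlignmentHit, ...] = ()
    read_support: tuple[ReadSupport, ...] = ()
    shrna_only: bool = False    # flagged: shRNA support without siRNA support


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_local(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    orientation: str = "plus/plus",
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 0.0,
) -> AlignmentHit | None:
    """Best Smith-Waterman local alignment, or ``None`` when no positive-score
    alignment exists.

    ``plus/minus`` aligns the query against the reverse complement of the
    subject.  When several alignments are co-optimal the first one in
    Biopython's deterministic traceback order is reported.  ``min_score``
    skips the (expensive) traceback when the optimal score falls below it.
    """
    if not query or not subject:
        raise ValidationError("cannot align an empty sequence")
    if orientation not in ("plus/plus", "plus/minus"):
        raise ValidationError(f"bad orientation {orientation!r}")
    oriented = reverse_complement(subject) if orientation == "plus/minus" else subject
    aligner = _aligner(scoring)
    score = aligner.score(query, oriented)
    if score <= 0 or score < min_score:
        return None
    best = aligner.align(query, oriented)[0]
    counts = best.counts()
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        hit_len=int(best.length),
        matches=int(counts.identities),
        query_len=len(query),
        subject_len=len(subject),
        orientation=orientation,
    )


def coverage_stats(query_len: int, subject_len: int, hit_len: int) -> tuple[float, float]:
    """Per-side alignment coverage, percent, rounded to 2 decimals.

    Returns ``(100*hit_len/query_len, 100*hit_len/subject_len)``.  Values can
    exceed 100 because gap columns inflate the hit length.
    """
    if query_len <= 0 or subject_len <= 0:
        raise ValidationError("sequence lengths must be positive")
    return (round(100.0 * hit_len / query_len, 2),
            round(100.0 * hit_len / subject_len, 2))


def classify_mirna_precursor(
    lncrnas: Iterable[Transcript],
    precursor_library: Sequence[tuple[str, str]],
    min_identity_pct: float = 99.0,
    min_precursor_cov_pct: float = 90.0,
    both_strands: bool = True,
    scoring: Scoring = DEFAULT_SCORING,
) -> dict[str, list[AlignmentHit]]:
    """Identify lncRNAs hosting known miRNA hairpin precursors.

    Each lncRNA (query) is aligned against each precursor (subject); a
    precursor qualifies when identity exceeds ``min_identity_pct`` and its
    own coverage exceeds ``min_precursor_cov_pct`` (both strict).  All
    qualifying precursors are reported — one lncRNA can host several hairpins
    and one hairpin can appear in several lncRNAs.
    """
    calls: dict[str, list[AlignmentHit]] = {}
    orientations = ("plus/plus", "plus/minus") if both_strands else ("plus/plus",)
    # a qualifying hit has >= min_identity matches over >= min_cov of the
    # precursor, so its score is bounded below; skip tracebacks under the
    # bound (0.8 safety factor for gap columns)
    f, c = min_identity_pct / 100.0, min_precursor_cov_pct / 100.0
    per_column = scoring.match * f + min(scoring.mismatch, scoring.gap_open) * (1 - f)
    for lnc in lncrnas:
        for prec_id, prec_seq in precursor_library:
            floor = max(0.0, 0.8 * per_column * c * len(prec_seq))
            best: AlignmentHit | None = None
            for orientation in orientations:
                hit = align_local(lnc.sequence, prec_seq, lnc.id, prec_id,
                                  orientation, scoring, min_score=floor)
                if hit and (best is None or hit.score > best.score):
                    best = hit
            if (best is not None
                    and best.identity_pct > min_identity_pct
                    and best.subject_cov_pct > min_precursor_cov_pct):
                calls.setdefault(lnc.id, []).append(best)
    return calls


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def match_reads_exact(
    lncrnas: Iterable[Transcript],
    reads: Sequence[SmallRNARead],
    both_strands: bool = True,
) -> dict[tuple[str, str], ReadSupport]:
    """Zero-mismatch mapping of small-RNA reads onto lncRNAs.

    A read supports an lncRNA when its sequence occurs verbatim in the
    lncRNA, or (with ``both_strands``) when its reverse complement does —
    siRNA duplexes yield reads of both polarities.  Returns one
    :class:`ReadSupport` per (lncRNA, library) with every occurrence offset;
    ``distinct_reads`` counts unique supporting read sequences.
    """
    support: dict[tuple[str, str], ReadSupport] = {}
    by_library: dict[str, list[SmallRNARead]] = {}
    for r in reads:
        by_library.setdefault(r.library, []).append(r)
    for lnc in lncrnas:
        for library, lib_reads in by_library.items():
            positions: list[tuple[int, str]] = []
            distinct: set[str] = set()
            for read in lib_reads:
                sense = _occurrences(lnc.sequence, read.sequence)
                anti = (_occurrences(lnc.sequence, reverse_complement(read.sequence))
                        if both_strands else [])
                if sense or anti:
                    distinct.add(read.sequence)
                positions.extend((off, "+") for off in sense)
                positions.extend((off, "-") for off in anti)
            if positions:
                support[(lnc.id, library)] = ReadSupport(
                    lnc.id, library, len(distinct), tuple(sorted(positions)))
    return support


def hierarchical_classify(
    lncrna_id: str,
    mirna_calls: Mapping[str, Sequence[AlignmentHit]],
    read_support: Mapping[tuple[str, str], ReadSupport],
    min_reads: int = 1,
    shrna_library: str = "shRNA",
    sirna_library: str = "siRNA",
) -> PrecursorClass:
    """Assign the precursor class of one lncRNA; the first matching rule wins.

    shRNA support without siRNA support has no class of its own in this
    taxonomy; such transcripts fall through to ``other`` and are flagged via
    ``shrna_only``.
    """
    sh = read_support.get((lncrna_id, shrna_library))
    si = read_support.get((lncrna_id, sirna_library))
    sh_ok = sh is not None and sh.distinct_reads >= min_reads
    si_ok = si is not None and si.distinct_reads >= min_reads
    evidence = tuple(s for s in (sh, si) if s is not None)
    if lncrna_id in mirna_calls:
        return PrecursorClass("miRNA_precursor",
                              mirna_hits=tuple(mirna_calls[lncrna_id]),
                              read_support=evidence)
    if sh_ok and si_ok:
        return PrecursorClass("shRNA_siRNA_precursor", read_support=evidence)
    if si_ok:
        return PrecursorClass("siRNA_precursor", read_support=evidence)
    return PrecursorClass("other", read_support=evidence, shrna_only=sh_ok)
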