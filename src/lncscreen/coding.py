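"""The non-coding screen: ORF finding, a coding-potential stage, and the
length / ORF filter that defines a lncRNA candidate.

A transcript is kept as a lncRNA candidate when it is labelled non-coding by
the coding-potential stage, is longer than 200 nt, and its longest open
reading frame is shorter than 80 amino acids.  The coding-potential stage is
pluggable: the built-in heuristic can be replaced verbatim by a label table
produced by an external classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import Transcript

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfCall:
    """The longest open reading frame of a transcript.

    ``aa_length`` counts the initiating Met and excludes the stop codon;
    ``start_nt`` is the 0-based offset of the A of ATG, so
    ``start_nt % 3 == frame``.
    """

    frame: int
    start_nt: int
    aa_length: int
    has_stop: bool = True


def find_longest_orf(sequence: str, require_stop: bool = True) -> OrfCall | None:
    """Longest ATG..stop ORF over the three forward frames, or ``None``.

    Transcripts are orientation-resolved upstream, so reverse frames are not
    scanned.  Codons containing N never match ATG or a stop codon.  Ties on
    length go to the smallest start offset, then the smallest frame.  With
    ``require_stop=False`` an ATG running off the 3' end also counts, using
    the remaining full codons.
    """
    seq = sequence.upper()
    best: OrfCall | None = None
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                call = OrfCall(frame, start, (pos - start) // 3, True)
                best = _better(best, call)
                start = None
        if start is not None and not require_stop:
            aa = (len(seq) - start) // 3
            if aa >= 1:
                best = _better(best, OrfCall(frame, start, aa, False))
    return best


def _better(current: OrfCall | None, candidate: OrfCall) -> OrfCall:
    if current is None:
        return candidate
    key = lambda c: (-c.aa_length, c.start_nt, c.frame)
    return min(current, candidate, key=key)


def coding_potential_score(
    sequence: str,
    orf_fraction_threshold: float = 0.5,
    coding_orf_aa: int = 100,
    labels: Mapping[str, str] | None = None,
    transcript_id: str | None = None,
) -> tuple[str, float]:
    """Label a transcript ``coding`` or ``noncoding`` with a supporting score.

    The built-in heuristic calls a transcript coding when the longest ORF
    spans more than ``orf_fraction_threshold`` of its length or reaches
    ``coding_orf_aa`` amino acids; the score is the ORF span fraction.  When
    an external label table is supplied (id -> ``coding``/``noncoding``,
    e.g. exported from a dedicated coding-potential classifier), its label is
    passed through verbatim for transcripts it covers.
    """
    if not sequence:
        raise ValueError("empty sequence")
    orf = find_longest_orf(sequence)
    span_fraction = 0.0 if orf is None else (3 * orf.aa_length + 3) / len(sequence)
    if labels is not None and transcript_id is not None and transcript_id in labels:
        return labels[transcript_id], span_fraction
    if orf is not None and (span_fraction > orf_fraction_threshold
                            or orf.aa_length >= coding_orf_aa):
        return "coding", span_fraction
    return "noncoding", span_fraction


def filter_lncrna_candidates(
    transcripts: Iterable[Transcript],
    min_length_nt: int = 201,
    max_orf_aa: int = 79,
    labels: Mapping[str, str] | None = None,
    skip_coding_stage: bool = False,
) -> list[Transcript]:
    """Apply the full non-coding screen and return the retained transcripts.

    Retains transcripts that (1) are labelled noncoding by
    :func:`coding_potential_score` (or by the supplied external label table),
    (2) have ``length_nt >= min_length_nt`` (default 201, i.e. >200 nt), and
    (3) have no ORF or a longest ORF of at most ``max_orf_aa`` amino acids
    (default 79, i.e. <80 AA).
    """
    kept = []
    for t in transcripts:
        if not skip_coding_stage:
            label, _ = coding_potential_score(t.sequence, labels=labels,
                                              transcript_id=t.id)
            if label != "noncoding":
                continue
        if t.length_nt < min_length_nt:
            continue
        orf = find_longest_orf(t.sequence)
        if orf is not None and orf.aa_length > max_orf_aa:
            continue
        kept.append(t)
    return kept
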