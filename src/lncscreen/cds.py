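"""Antisense pairing of residual lncRNAs with coding sequences.

lncRNAs left in the ``other`` class (excluding positionally antisense ones,
which already sit opposite a gene) are searched against a CDS set in
plus/minus orientation: a near-perfect antisense match marks the lncRNA as a
candidate regulator of that CDS through transcriptional or
post-transcriptional silencing.

A pair passes when identity exceeds the identity threshold and the *larger*
of the two per-side coverages exceeds the coverage threshold.  A short CDS
fully covered by a long lncRNA should pass even though it covers little of
the lncRNA, and vice versa; the per-side mode is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import Transcript
from .precursor import DEFAULT_SCORING, AlignmentHit, Scoring, align_local, coverage_stats

__all__ = ["CdsPair", "pair_with_cds", "table4_report"]

TABLE_COLUMNS = [
    "Query_name", "Hit_name", "Query_len", "Sbject_len", "Hit_len",
    "Percent_identity", "Percent_query_aligned", "Percent_Sbject_aligned",
]


@dataclass(frozen=True)
class CdsPair:
    lncrna_id: str
    cds_id: str
    hit: AlignmentHit
    passes_threshold: bool


def _coverage_gate(hit: AlignmentHit, min_cov_pct: float, mode: str) -> bool:
    q, s = hit.query_cov_pct, hit.subject_cov_pct
    if mode == "max":
        return max(q, s) > min_cov_pct
    if mode == "both":
        return q > min_cov_pct and s > min_cov_pct
    if mode == "query":
        return q > min_cov_pct
    raise ValidationError(f"unknown coverage mode {mode!r}")


def pair_with_cds(
    other_lncrnas: Iterable[Transcript],
    cds_set: Sequence[tuple[str, str]],
    min_identity_pct: float = 90.0,
    min_cov_pct: float = 90.0,
    coverage_mode: str = "max",
    orientations: Sequence[str] = ("plus/minus",),
    scoring: Scoring = DEFAULT_SCORING,
) -> list[CdsPair]:
    """Align every lncRNA against every CDS and flag near-perfect pairs.

    Thresholds are strict; classification uses the unrounded percentages.
    One lncRNA may pair with many CDS and one CDS with many lncRNAs.
    Only pairs with some positive-score alignment are returned.
    """
    if not cds_set:
        raise ValidationError("CDS set is empty")
    pairs = []
    for lnc in other_lncrnas:
        for cds_id, cds_seq in cds_set:
            best: AlignmentHit | None = None
            for orientation in orientations:
                hit = align_local(lnc.sequence, cds_seq, lnc.id, cds_id,
                                  orientation, scoring)
                if hit and (best is None or hit.score > best.score):
                    best = hit
            if best is None:
                continue
            passes = (best.identity_pct > min_identity_pct
                      and _coverage_gate(best, min_cov_pct, coverage_mode))
            pairs.append(CdsPair(lnc.id, cds_id, best, passes))
    return pairs


def table4_report(pairs: Sequence[CdsPair], path: str | Path | None = None,
                  only_passing: bool = True) -> pd.DataFrame:
    """Tabulate pairs with the standard alignment-statistics columns.

    One row per pair: query/subject names and lengths, alignment column
    count, percent identity and both per-side coverages, percentages rounded
    to 2 decimals.  Optionally written as TSV.
    """
    rows = []
    for p in pairs:
        if only_passing and not p.passes_threshold:
            continue
        h = p.hit
        qcov, scov = coverage_stats(h.query_len, h.subject_len, h.hit_len)
        rows.append((p.lncrna_id, p.cds_id, h.query_len, h.subject_len,
                     h.hit_len, round(h.identity_pct, 2), qcov, scov))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
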