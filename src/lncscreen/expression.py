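"""RPKM quantification and the fold-change / FDR differential-expression screen.

A transcript counts as stress-responsive when its expression changes at least
``fold_threshold``-fold between conditions *and* the change survives
Benjamini-Hochberg correction at ``fdr_threshold``.  Both gates are required:
a large fold change at low counts, or a significant but small change, is
called ``unchanged``.

The per-transcript count test is pluggable.  The default is a two-sided
exact binomial test of the pooled treatment count against the pooled total,
with success probability equal to the treatment library's share of the
combined sequencing depth — the classic test for pooled digital expression
counts.  Replicates are summed before testing; the raw per-replicate table is
available to alternative tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ExpressionRecord",
    "compute_rpkm",
    "benjamini_hochberg",
    "binomial_count_test",
    "call_differential",
]


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    rpkm_control: float
    rpkm_treatment: float
    fold_change: float      # treatment / control, on pseudocounted RPKM
    p_value: float
    fdr: float
    direction: str          # up / down / unchanged


def compute_rpkm(count: int, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = 10^9 * count / (total_mapped * length_nt).
    """
    if length_nt <= 0:
        raise ValidationError("transcript length must be positive")
    if total_mapped <= 0:
        raise ValidationError("total mapped reads must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return 1e9 * count / (total_mapped * length_nt)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def binomial_count_test(control_count: int, treatment_count: int,
                        control_total: int, treatment_total: int) -> float:
    """Two-sided exact binomial p-value for a pooled count pair.

    Under no differential expression, each of the ``control + treatment``
    reads of a transcript falls in the treatment library with probability
    ``treatment_total / (control_total + treatment_total)``.
    """
    n = control_count + treatment_count
    if n == 0:
        return 1.0
    p0 = treatment_total / (control_total + treatment_total)
    return stats.binomtest(treatment_count, n, p0, alternative="two-sided").pvalue


def call_differential(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.001,
    control: str = "control",
    treatment: str = "treatment",
    test: Callable[[int, int, int, int], float] = binomial_count_test,
) -> list[ExpressionRecord]:
    """Screen every transcript in ``counts`` for differential expression.

    ``counts`` uses the MultiIndex column layout of
    :func:`lncscreen.io_formats.read_counts`.  Library sizes are the pooled
    column sums.  Fold change is computed on RPKM after adding one pseudo-read
    to each condition, so transcripts expressed in only one condition get a
    finite fold change.
    """
    for cond in (control, treatment):
        if cond not in counts.columns.get_level_values("condition"):
            raise ValidationError(f"count table has no {cond!r} columns")
    missing = [t for t in counts.index if t not in lengths]
    if missing:
        raise ValidationError(f"no length known for transcripts: {missing[:5]}...")

    c_pooled = counts[control].sum(axis=1).astype(int)
    t_pooled = counts[treatment].sum(axis=1).astype(int)
    n_control = int(c_pooled.sum())
    n_treatment = int(t_pooled.sum())
    if n_control == 0 or n_treatment == 0:
        raise ValidationError("a condition has zero total mapped reads")

    p_values = np.array([
        test(int(c_pooled[t]), int(t_pooled[t]), n_control, n_treatment)
        for t in counts.index
    ])
    fdrs = benjamini_hochberg(p_values)

    records = []
    for tid, p, fdr in zip(counts.index, p_values, fdrs):
        length = lengths[tid]
        rpkm_c = compute_rpkm(int(c_pooled[tid]), length, n_control)
        rpkm_t = compute_rpkm(int(t_pooled[tid]), length, n_treatment)
        fold = (
            compute_rpkm(int(t_pooled[tid]) + 1, length, n_treatment)
            / compute_rpkm(int(c_pooled[tid]) + 1, length, n_control)
        )
        if fdr < fdr_threshold and fold >= fold_threshold:
            direction = "up"
        elif fdr < fdr_threshold and fold <= 1.0 / fold_threshold:
            direction = "down"
        else:
            direction = "unchanged"
        records.append(ExpressionRecord(tid, rpkm_c, rpkm_t, float(fold),
                                        float(p), float(fdr), direction))
    return records


def expression_table(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.rpkm_control, r.rpkm_treatment, r.fold_change,
          r.p_value, r.fdr, r.direction) for r in records],
        columns=["transcript_id", "rpkm_control", "rpkm_treatment",
                 "fold_change", "p_value", "fdr", "direction"],
    ).set_index("transcript_id")
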