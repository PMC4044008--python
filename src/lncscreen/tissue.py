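"""Tissue-specificity scoring (tau) and Pfaffl relative quantification.

Tau (Yanai's index) summarises a multi-tissue expression profile in [0, 1]:
0 for perfectly ubiquitous expression, 1 for expression confined to a single
tissue::

    tau = sum_i (1 - x_i / x_max) / (n - 1)

The Pfaffl ratio is the efficiency-corrected relative expression used for
RT-qPCR validation::

    ratio = E_target ** dCp_target / E_ref ** dCp_ref

with dCp = Cp(control) - Cp(treatment) for both the target and the reference
gene, and E the amplification efficiency (2 for perfect doubling).  Note the
control-minus-treatment orientation: with it, a target *accumulating* under
treatment has a positive dCp_target and a ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["TissueProfile", "QpcrMeasurement", "tau_specificity",
           "tissue_profiles", "pfaffl_ratio"]


@dataclass(frozen=True)
class TissueProfile:
    transcript_id: str
    values: tuple[float, ...]
    tau: float
    specific_tissue: str | None


@dataclass(frozen=True)
class QpcrMeasurement:
    efficiency_target: float
    efficiency_ref: float
    delta_cp_target: float   # Cp control - Cp treatment, target gene
    delta_cp_ref: float      # Cp control - Cp treatment, reference gene

    def __post_init__(self) -> None:
        if self.efficiency_target < 1 or self.efficiency_ref < 1:
            raise ValidationError("amplification efficiencies must be >= 1")


def tau_specificity(values: Sequence[float],
                    tissues: Sequence[str] | None = None,
                    threshold: float = 0.8) -> tuple[float, str | int | None]:
    """Tau index of a per-tissue expression vector.

    Returns ``(tau, specific_tissue)`` where the tissue (label if ``tissues``
    is given, else index) is the argmax when ``tau >= threshold`` and ``None``
    otherwise.  All-zero profiles are undefined.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("tau needs at least two tissues")
    if np.any(v < 0):
        raise ValidationError("expression values must be non-negative")
    vmax = v.max()
    if vmax == 0:
        raise ValidationError("all-zero expression profile has no tau")
    tau = float(np.sum(1.0 - v / vmax) / (v.size - 1))
    if tau >= threshold:
        idx = int(np.argmax(v))
        return tau, (tissues[idx] if tissues is not None else idx)
    return tau, None


def tissue_profiles(matrix: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Tau and specific tissue for every row of a transcripts x tissues table.

    All-zero rows get ``tau = NaN`` rather than an error, so one silent
    transcript does not abort a whole matrix.
    """
    records = []
    tissues = list(matrix.columns)
    for tid, row in matrix.iterrows():
        if row.max() == 0:
            records.append((tid, np.nan, None))
            continue
        tau, tissue = tau_specificity(row.to_numpy(), tissues, threshold)
        records.append((tid, tau, tissue))
    return pd.DataFrame(records, columns=["transcript_id", "tau", "specific_tissue"]
                        ).set_index("transcript_id")


def pfaffl_ratio(m: QpcrMeasurement) -> float:
    """Efficiency-corrected expression ratio of target vs reference gene."""
    return (m.efficiency_target ** m.delta_cp_target
            / m.efficiency_ref ** m.delta_cp_ref)
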