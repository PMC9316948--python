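"""Categorical comparative-risk metrics.

Population attributable fraction (counterfactual: everyone at the
theoretical-minimum-risk exposure level), attributable burden, the summary
exposure value in [0, 1], and the annualised (log) rate of change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class RiskSpec:
    """Exposure-category prevalences and relative risks for one risk-outcome pair."""

    categories: list[str]
    prevalence: np.ndarray
    rr: np.ndarray
    tmrel_index: int = 0

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, float)
        self.rr = np.asarray(self.rr, float)
        k = len(self.categories)
        if self.prevalence.shape != (k,) or self.rr.shape != (k,):
            raise ValueError("prevalence and rr must have one entry per category")
        if np.any(self.prevalence < 0) or abs(self.prevalence.sum() - 1.0) > 1e-9:
            raise ValueError("prevalences must be non-negative and sum to 1 (within 1e-9)")
        if np.any(self.rr <= 0):
            raise ValueError("relative risks must be strictly positive")
        if not 0 <= self.tmrel_index < k:
            raise ValueError(f"tmrel_index {self.tmrel_index} out of range")
        if not math.isclose(self.rr[self.tmrel_index], 1.0):
            raise ValueError("relative risk at the TMREL category must equal 1")


def paf(spec: RiskSpec) -> float:
    """Population attributable fraction: (sum p_i rr_i - 1) / (sum p_i rr_i)."""
    mean_rr = float(spec.prevalence @ spec.rr)
    return (mean_rr - 1.0) / mean_rr


def attributable_burden(paf_value: float, outcome_burden: float) -> float:
    """Burden attributable to the risk: PAF times the outcome's burden."""
    if outcome_burden < 0:
        raise ValueError(f"outcome_burden must be non-negative, got {outcome_burden}")
    return paf_value * outcome_burden


def sev(spec: RiskSpec) -> float:
    """Summary exposure value: risk-weighted prevalence scaled to [0, 1].

    SEV = sum_i p_i (rr_i - 1) / (rr_max - 1); 0 when all exposure sits at
    the TMREL category, 1 when all sits at the maximum-risk category.
    """
    rr_max = float(spec.rr.max())
    if math.isclose(rr_max, 1.0):
        raise ValueError("SEV undefined for null risk (all relative risks equal 1)")
    return float(spec.prevalence @ (spec.rr - 1.0)) / (rr_max - 1.0)


def annualized_rate_of_change(initial: float, final: float, n_years: float) -> float:
    """ln(final / initial) / n_years."""
    if initial <= 0:
        raise ValueError(f"initial must be positive, got {initial}")
    if final <= 0:
        raise ValueError(f"final must be positive, got {final}")
    if n_years <= 0:
        raise ValueError(f"n_years must be positive, got {n_years}")
    return math.log(final / initial) / n_years
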