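"""Comorbidity-adjusted YLDs, YLLs, DALYs, Sullivan HALE and the
ill-health fraction of remaining life at a given age.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .lifetable import LifeTable, life_expectancy_at

MAX_ANALYTIC_SEQUELAE = 20


@dataclass
class HealthspanResult:
    le70: float
    hale70: float
    pyih70: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.hale70 <= self.le70):
            raise ValueError(f"need 0 <= hale70 <= le70, got {self.hale70} vs {self.le70}")
        expected = (self.le70 - self.hale70) / self.le70
        if abs(self.pyih70 - expected) > 1e-12:
            raise ValueError("pyih70 must equal (le70 - hale70) / le70")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.285 -> 0.29), as used for reporting."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def comorbidity_adjust(
    prevalence: np.ndarray,
    disability_weight: np.ndarray,
    mode: str = "analytic",
    n_sim: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Comorbidity-adjusted per-condition YLD rate per capita.

    Conditions co-occur independently.  A person with condition set S has
    combined disability ``1 - prod_{i in S} (1 - dw_i)``, which is attributed
    to the member conditions proportionally to their disability weights.
    The returned vector is the expected attributed disability per person for
    each condition; its sum is the expected combined disability
    ``1 - prod_i (1 - p_i * dw_i)``.

    ``mode='analytic'`` enumerates all 2^k condition sets exactly (k <= 20);
    ``mode='microsim'`` simulates ``n_sim`` independent persons.
    """
    p = np.atleast_1d(np.asarray(prevalence, float))
    dw = np.atleast_1d(np.asarray(disability_weight, float))
    if p.shape != dw.shape or p.ndim != 1:
        raise ValueError("prevalence and disability_weight must be 1-D and aligned")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalences must lie in [0, 1]")
    if np.any((dw < 0) | (dw > 1)):
        raise ValueError("disability weights must lie in [0, 1]")
    k = p.size

    if mode == "analytic":
        if k > MAX_ANALYTIC_SEQUELAE:
            raise ValueError(
                f"analytic enumeration supports at most {MAX_ANALYTIC_SEQUELAE} "
                f"sequelae (got {k}); use mode='microsim'"
            )
        masks = np.arange(2**k)
        has = ((masks[:, None] >> np.arange(k)) & 1).astype(bool)  # (2^k, k)
        prob = np.prod(np.where(has, p, 1.0 - p), axis=1)
        return _attribute(has, dw, weights=prob)

    if mode == "microsim":
        rng = np.random.default_rng(seed)
        has = rng.random((n_sim, k)) < p
        return _attribute(has, dw, weights=np.full(n_sim, 1.0 / n_sim))

    raise ValueError(f"mode must be 'analytic' or 'microsim', got {mode!r}")


def _attribute(has: np.ndarray, dw: np.ndarray, weights: np.ndarray) -> np.ndarray:
    combined = 1.0 - np.prod(np.where(has, 1.0 - dw, 1.0), axis=1)
    dw_sum = has @ dw
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(dw_sum > 0, combined / np.where(dw_sum > 0, dw_sum, 1.0), 0.0)
    return (has * dw).T @ (weights * scale)


def yll(deaths: np.ndarray, standard_le: np.ndarray) -> np.ndarray:
    """Years of life lost: deaths times remaining standard life expectancy.

    ``deaths`` is (n_causes, n_ages) or (n_ages,); ``standard_le`` is
    (n_ages,) on the same grid.  Additive over causes by construction.
    """
    deaths = np.asarray(deaths, float)
    standard_le = np.asarray(standard_le, float)
    if deaths.shape[-1] != standard_le.shape[0]:
        raise ValueError(
            f"age-grid mismatch: deaths has {deaths.shape[-1]} age groups, "
            f"standard_le has {standard_le.shape[0]}"
        )
    if np.any(deaths < 0) or np.any(standard_le < 0):
        raise ValueError("deaths and standard_le must be non-negative")
    return deaths * standard_le


def hale_sullivan(lt: LifeTable, yld_rate_by_age: np.ndarray) -> np.ndarray:
    """Sullivan-method health expectancy at every grid age.

    HALE(x) = sum_{a >= x} L_a * (1 - yld_a) / l_x, with yld_a the per-capita
    comorbidity-adjusted YLD rate in age group a.
    """
    yld = np.asarray(yld_rate_by_age, float)
    if yld.shape != lt.age_start.shape:
        raise ValueError("yld_rate_by_age must align with the life-table grid")
    if np.any((yld < 0) | (yld > 1)):
        raise ValueError("yld rates must lie in [0, 1]")
    healthy_L = lt.Lx * (1.0 - yld)
    tail = np.cumsum(healthy_L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(lt.lx > 0, tail / lt.lx, 0.0)


def pyih(le70: float, hale70: float) -> float:
    """Fraction of remaining life expectancy expected in ill health."""
    if le70 <= 0:
        raise ValueError(f"le70 must be positive, got {le70}")
    if hale70 < 0 or hale70 > le70:
        raise ValueError(f"need 0 <= hale70 <= le70, got hale70={hale70}, le70={le70}")
    return (le70 - hale70) / le70


def healthspan_at(
    lt: LifeTable, yld_rate_by_age: np.ndarray, age: float = 70.0
) -> HealthspanResult:
    """LE, HALE and ill-health fraction at one grid age."""
    le = life_expectancy_at(lt, age)
    hale = float(hale_sullivan(lt, yld_rate_by_age)[lt.row_index(age)])
    return HealthspanResult(le70=le, hale70=hale, pyih70=pyih(le, hale))


def daly(yll_table: np.ndarray, yld_table: np.ndarray) -> np.ndarray:
    """Disability-adjusted life years: cellwise YLL + YLD."""
    yll_table = np.asarray(yll_table, float)
    yld_table = np.asarray(yld_table, float)
    if yll_table.shape != yld_table.shape:
        raise ValueError("yll and yld tables must share a grid")
    if np.any(yll_table < 0) or np.any(yld_table < 0):
        raise ValueError("burden tables must be non-negative")
    return yll_table + yld_table
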