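"""Abridged period life tables.

Columns follow the classical demographic notation: ``mx`` (central death
rate), ``ax`` (mean person-years lived in the interval by those dying in
it), ``qx`` (conditional death probability), ``lx`` (survivors at interval
start), ``dx`` (deaths), ``Lx`` (person-years in interval), ``Tx``
(person-years above interval start) and ``ex`` (remaining life expectancy).

Two ``ax`` rules are provided:

``midpoint``
    ax = n/2 for closed intervals (graduation-free default).
``exponential``
    ax implied by a constant hazard within each interval, which makes the
    table exact for piecewise-constant-hazard populations and lets
    constant-hazard closed forms (e = 1/mu) hold to machine precision.

The final open interval always uses qx = 1 and Lx = lx / mx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_RADIX = 100_000.0

AX_RULES = ("midpoint", "exponential")


@dataclass
class LifeTable:
    age_start: np.ndarray
    n: np.ndarray  # interval widths; inf for open interval
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": self.age_start,
                "n": self.n,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )

    def row_index(self, age: float) -> int:
        hits = np.nonzero(np.isclose(self.age_start, age))[0]
        if hits.size == 0:
            raise ValueError(
                f"age {age} is not a grid point of this life table "
                f"(grid starts: {self.age_start.tolist()})"
            )
        return int(hits[0])


def build_lifetable(
    age_start: np.ndarray,
    mx: np.ndarray,
    ax_rule: str = "midpoint",
    radix: float = DEFAULT_RADIX,
) -> LifeTable:
    """Build an abridged life table from an age schedule of death rates.

    Parameters
    ----------
    age_start : ascending interval lower bounds; the last interval is open.
    mx : central death rates (per person-year), strictly positive.
    ax_rule : 'midpoint' or 'exponential' (see module docstring).
    radix : l0 scale; results are invariant to it.
    """
    age_start = np.asarray(age_start, float)
    mx = np.asarray(mx, float)
    if age_start.ndim != 1 or mx.shape != age_start.shape:
        raise ValueError("age_start and mx must be 1-D arrays of equal length")
    if age_start.size < 2:
        raise ValueError("need at least two age intervals")
    if np.any(np.diff(age_start) <= 0):
        raise ValueError("age_start must be strictly increasing")
    bad = np.nonzero(~(mx > 0) | ~np.isfinite(mx))[0]
    if bad.size:
        raise ValueError(
            f"mx must be positive and finite; offending age group starts at "
            f"{age_start[bad[0]]}"
        )
    if ax_rule not in AX_RULES:
        raise ValueError(f"ax_rule must be one of {AX_RULES}, got {ax_rule!r}")

    k = age_start.size
    n = np.empty(k)
    n[:-1] = np.diff(age_start)
    n[-1] = math.inf

    ax = np.empty(k)
    nc, mc = n[:-1], mx[:-1]
    if ax_rule == "midpoint":
        ax[:-1] = nc / 2.0
    else:  # constant hazard within interval
        z = nc * mc
        ax[:-1] = 1.0 / mc - nc * np.exp(-z) / (-np.expm1(-z))
    ax[-1] = 1.0 / mx[-1]

    qx = np.empty(k)
    qx[:-1] = nc * mc / (1.0 + (nc - ax[:-1]) * mc)
    qx[-1] = 1.0
    qx = np.clip(qx, 0.0, 1.0)

    lx = np.empty(k)
    lx[0] = radix
    lx[1:] = radix * np.cumprod(1.0 - qx[:-1])
    dx = lx * qx

    Lx = np.empty(k)
    Lx[:-1] = nc * lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    return LifeTable(age_start, n, mx, ax, qx, lx, dx, Lx, Tx, ex)


def life_expectancy_at(lt: LifeTable, age: float) -> float:
    """Remaining life expectancy at an exact grid age (no interpolation)."""
    return float(lt.ex[lt.row_index(age)])


def prob_death_window(lt: LifeTable, start: float = 70.0, span: float = 20.0) -> float:
    """Probability of dying between exact ages ``start`` and ``start + span``.

    Equals 1 - l(start+span) / l(start); both ages must be grid points.
    """
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    i = lt.row_index(start)
    j = lt.row_index(start + span)
    if lt.lx[i] <= 0:
        return 1.0
    return float(1.0 - lt.lx[j] / lt.lx[i])
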