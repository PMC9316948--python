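"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: the cohort
microsimulation samples death ages agent by agent from a piecewise-constant
hazard, the comorbidity oracle enumerates joint condition states with plain
Python floats, and the survival window uses the closed-form exponential
formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def simulate_cohort(
    age_start: np.ndarray,
    mx: np.ndarray,
    entry_age: float,
    n_agents: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Death ages for a cohort entering at ``entry_age`` under a
    piecewise-constant hazard schedule (last interval open)."""
    age_start = np.asarray(age_start, float)
    mx = np.asarray(mx, float)
    i0 = int(np.searchsorted(age_start, entry_age))
    if not math.isclose(age_start[i0], entry_age):
        raise ValueError("entry_age must be a grid point")
    bounds = age_start[i0:]
    rates = mx[i0:]
    widths = np.append(np.diff(bounds), np.inf)

    # cumulative hazard at the start of each interval (from entry)
    closed = rates[:-1] * widths[:-1]
    cum = np.concatenate([[0.0], np.cumsum(closed)])

    e = rng.exponential(1.0, n_agents)
    idx = np.searchsorted(cum, e, side="right") - 1
    idx = np.clip(idx, 0, len(rates) - 1)
    death = bounds[idx] + (e - cum[idx]) / rates[idx]
    return death


def window_death_prob_closed_form(
    age_start: np.ndarray, mx: np.ndarray, start: float, span: float
) -> float:
    """1 - exp(-integral of the piecewise-constant hazard over [start, start+span))."""
    total = 0.0
    end = start + span
    for i, a in enumerate(age_start):
        b = age_start[i + 1] if i + 1 < len(age_start) else math.inf
        lo, hi = max(a, start), min(b, end)
        if hi > lo:
            total += mx[i] * (hi - lo)
    return 1.0 - math.exp(-total)


def comorbidity_oracle(p: list[float], dw: list[float]) -> list[float]:
    """Expected attributed disability per condition by exhaustive enumeration
    of the 2^k independent joint states (pure Python)."""
    k = len(p)
    out = [0.0] * k
    for state in itertools.product((0, 1), repeat=k):
        prob = 1.0
        for i, s in enumerate(state):
            prob *= p[i] if s else (1.0 - p[i])
        members = [i for i, s in enumerate(state) if s]
        if not members or prob == 0.0:
            continue
        combined = 1.0
        for i in members:
            combined *= 1.0 - dw[i]
        combined = 1.0 - combined
        dw_sum = sum(dw[i] for i in members)
        if dw_sum == 0.0:
            continue
        for i in members:
            out[i] += prob * combined * dw[i] / dw_sum
    return out


def comorbidity_microsim_oracle(
    p: list[float], dw: list[float], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(mean, standard error) of per-condition attributed disability over
    ``n`` simulated persons with independent conditions."""
    k = len(p)
    has = rng.random((n, k)) < np.asarray(p)
    combined = 1.0 - np.prod(np.where(has, 1.0 - np.asarray(dw), 1.0), axis=1)
    dw_sum = has @ np.asarray(dw)
    safe = np.where(dw_sum > 0, dw_sum, 1.0)
    per_person = has * np.asarray(dw) * (combined / safe)[:, None]
    return per_person.mean(axis=0), per_person.std(axis=0, ddof=1) / math.sqrt(n)


def two_cause_replacement_oracle(
    age_start: np.ndarray,
    mx1: np.ndarray,  # (2, n_ages) at time 1
    mx2: np.ndarray,  # (2, n_ages) at time 2
    start: float,
    span: float,
) -> list[float]:
    """Average-of-both-orderings contributions for a two-cause world, written
    out explicitly against the closed-form window probability."""

    def f(rows) -> float:
        return window_death_prob_closed_form(age_start, rows[0] + rows[1], start, span)

    a1, b1 = mx1[0], mx1[1]
    a2, b2 = mx2[0], mx2[1]
    # ordering A: switch cause 0 then cause 1
    ca_first = f((a2, b1)) - f((a1, b1))
    cb_second = f((a2, b2)) - f((a2, b1))
    # ordering B: switch cause 1 then cause 0
    cb_first = f((a1, b2)) - f((a1, b1))
    ca_second = f((a2, b2)) - f((a1, b2))
    return [(ca_first + ca_second) / 2.0, (cb_first + cb_second) / 2.0]
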