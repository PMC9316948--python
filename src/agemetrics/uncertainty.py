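"""Draw-level uncertainty propagation and 95% percentile intervals.

Quantities are carried as ensembles of posterior draws (1000 by default);
any deterministic pipeline stage is applied draw-wise — never to the draw
means first — and intervals are empirical 2.5th/97.5th percentiles with
linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

DEFAULT_N_DRAWS = 1000
MIN_DRAWS_FOR_UI = 40


@dataclass
class DrawSet:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a DrawSet needs a 1-D array of at least 2 draws")

    @property
    def n_draws(self) -> int:
        return self.values.size

    @property
    def point(self) -> float:
        """Point estimate: mean of draws."""
        return float(self.values.mean())


def propagate(fn: Callable[..., float], *inputs: DrawSet) -> DrawSet:
    """Apply a deterministic stage function draw-wise across aligned DrawSets."""
    if not inputs:
        raise ValueError("propagate needs at least one DrawSet input")
    n = inputs[0].n_draws
    for d in inputs[1:]:
        if d.n_draws != n:
            raise ValueError(f"mismatched draw counts: {n} vs {d.n_draws}")
    try:  # vectorised fast path when fn is array-safe
        out = np.asarray(fn(*(d.values for d in inputs)), float)
        if out.shape != (n,):
            raise TypeError
    except Exception:
        out = np.array([fn(*(d.values[i] for d in inputs)) for i in range(n)], float)
    return DrawSet(out)


def ui95(d: DrawSet) -> tuple[float, float]:
    """Empirical 95% uncertainty interval (2.5th, 97.5th percentiles)."""
    if d.n_draws < MIN_DRAWS_FOR_UI:
        raise ValueError(
            f"need at least {MIN_DRAWS_FOR_UI} draws for a 95% interval, got {d.n_draws}"
        )
    lo, hi = np.percentile(d.values, [2.5, 97.5])
    return float(lo), float(hi)
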