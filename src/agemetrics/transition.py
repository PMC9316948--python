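"""Expected-value curves of an ageing metric against a development covariate.

A cubic regression spline (intercept implicit in the B-spline basis) is fit
by least squares to log(metric + offset) against SDI or HAQ, pooling all
location-years.  The fitted curve is the "expected" level; per-observation
observed/expected ratios quantify departures from the historical average
relation.  Interior knots sit at covariate quantiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEFAULT_OFFSET = 1e-7
SPLINE_DEGREE = 3


class ExtrapolationWarning(UserWarning):
    """Covariate value outside the fitted range; prediction is extrapolated."""


@dataclass
class TransitionModel:
    covariate: str  # 'sdi' or 'haq'
    knots: np.ndarray  # full knot vector incl. boundary repeats
    coefficients: np.ndarray
    offset: float = DEFAULT_OFFSET
    cov_range: tuple[float, float] = (0.0, 1.0)
    fitted: np.ndarray | None = field(default=None, repr=False)  # in-sample expected

    def _spline(self) -> BSpline:
        return BSpline(self.knots, self.coefficients, SPLINE_DEGREE, extrapolate=True)

    def predict(self, covariate_value: np.ndarray | float) -> np.ndarray | float:
        """Expected metric value(s); warns and extrapolates outside the fit range."""
        x = np.asarray(covariate_value, float)
        lo, hi = self.cov_range
        if np.any((x < lo) | (x > hi)):
            warnings.warn(
                f"covariate value outside fitted range [{lo:g}, {hi:g}]; extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        expected = np.maximum(np.exp(self._spline()(x)) - self.offset, 0.0)
        return float(expected) if np.isscalar(covariate_value) else expected

    def to_json(self, path: str) -> None:
        payload = {
            "covariate": self.covariate,
            "knots": self.knots.tolist(),
            "coefficients": self.coefficients.tolist(),
            "offset": self.offset,
            "cov_range": list(self.cov_range),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "TransitionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            covariate=payload["covariate"],
            knots=np.asarray(payload["knots"], float),
            coefficients=np.asarray(payload["coefficients"], float),
            offset=payload["offset"],
            cov_range=tuple(payload["cov_range"]),
        )


def _design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, SPLINE_DEGREE, extrapolate=True).toarray()


def fit_expected_curve(
    covariate_values: np.ndarray,
    metric_values: np.ndarray,
    covariate: str = "sdi",
    n_knots: int = 4,
    offset: float = DEFAULT_OFFSET,
) -> TransitionModel:
    """Least-squares cubic regression spline on log(metric + offset).

    ``n_knots`` interior knots are placed at equally spaced covariate
    quantiles.  Requires at least ``n_knots + 4`` observations (the basis
    size) and a non-degenerate covariate.
    """
    x = np.asarray(covariate_values, float)
    y = np.asarray(metric_values, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("covariate and metric arrays must be 1-D and aligned")
    if np.any(y < 0):
        raise ValueError("metric values must be non-negative")
    n_params = n_knots + SPLINE_DEGREE + 1
    if x.size < n_params:
        raise ValueError(
            f"need at least {n_params} observations for {n_knots} interior knots, "
            f"got {x.size}"
        )
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        raise ValueError("degenerate covariate: zero variance")

    if n_knots > 0:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    knots = np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), interior, [hi] * (SPLINE_DEGREE + 1)]
    )

    design = _design_matrix(x, knots)
    coef, *_ = np.linalg.lstsq(design, np.log(y + offset), rcond=None)

    model = TransitionModel(
        covariate=covariate,
        knots=knots,
        coefficients=coef,
        offset=offset,
        cov_range=(lo, hi),
    )
    model.fitted = np.maximum(np.exp(design @ coef) - offset, 0.0)
    return model


def observed_expected_ratio(
    observed: np.ndarray | float,
    model: TransitionModel,
    covariate_value: np.ndarray | float,
) -> np.ndarray | float:
    """(observed + offset) / (expected + offset); > 1 iff observed exceeds expected."""
    obs = np.asarray(observed, float)
    if np.any(obs < 0):
        raise ValueError("observed metric values must be non-negative")
    expected = np.asarray(model.predict(covariate_value), float)
    ratio = (obs + model.offset) / (expected + model.offset)
    return float(ratio) if np.isscalar(observed) else ratio
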