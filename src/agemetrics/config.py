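"""Simulation configuration for the synthetic burden-of-disease generator.

The configuration fully determines every generated artefact: one root seed
is expanded into independent per-stream child seeds via
``numpy.random.SeedSequence(seed, spawn_key=...)`` so that adding a stratum
never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: stream codes for the child-seed scheme (documented, stable)
STREAM_SDI = 0
STREAM_CAUSE_FRACTIONS = 1
STREAM_COVERAGE = 2
STREAM_HAQ = 3


def default_age_groups() -> list[tuple[float, float]]:
    """Five-year abridged age bands 0-4 ... 90-94 plus an open 95+ band."""
    groups = [(float(a), float(a + 5)) for a in range(0, 95, 5)]
    groups.append((95.0, math.inf))
    return groups


@dataclass
class DisabilityParams:
    """Linear-in-age prevalence model for one cause plus its disability weight.

    prevalence(age) = clip(intercept + age_slope * age, 0, 1)
    """

    intercept: float
    age_slope: float
    disability_weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.disability_weight <= 1.0):
            raise ValueError(
                f"disability_weight must lie in [0, 1], got {self.disability_weight}"
            )

    def prevalence(self, age: np.ndarray | float) -> np.ndarray:
        return np.clip(self.intercept + self.age_slope * np.asarray(age, float), 0.0, 1.0)


@dataclass
class RiskParams:
    """Categorical exposure prevalences and relative risks for one risk factor."""

    categories: list[str]
    prevalence: list[float]
    relative_risk: list[float]
    tmrel_index: int = 0

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.prevalence) or len(self.categories) != len(
            self.relative_risk
        ):
            raise ValueError("categories, prevalence and relative_risk must align")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("category prevalences must sum to 1")
        if any(r <= 0 for r in self.relative_risk):
            raise ValueError("relative risks must be positive")


@dataclass
class SdiLink:
    """Monotone, invertible map from SDI in [0, 1] to a mortality multiplier.

    multiplier(sdi) = exp(scale * (center - sdi)); higher SDI means lower
    mortality whenever scale > 0.  Stored so downstream recovery experiments
    can invert it.
    """

    scale: float = 1.2
    center: float = 0.5

    def multiplier(self, sdi: np.ndarray | float) -> np.ndarray:
        return np.exp(self.scale * (self.center - np.asarray(sdi, float)))

    def inverse(self, multiplier: np.ndarray | float) -> np.ndarray:
        return self.center - np.log(np.asarray(multiplier, float)) / self.scale


@dataclass
class SimConfig:
    n_locations: int = 8
    years: list[int] = field(default_factory=lambda: [1990, 2005, 2019])
    age_groups: list[tuple[float, float]] = field(default_factory=default_age_groups)
    causes: list[str] = field(
        default_factory=lambda: ["cardio_like", "cancer_like", "neuro_like", "injury_like"]
    )
    gompertz_alpha: float = 5e-5
    gompertz_beta: float = 0.09
    cause_dirichlet: list[float] = field(default_factory=lambda: [8.0, 5.0, 3.0, 2.0])
    disability_params: dict[str, DisabilityParams] = field(default_factory=dict)
    risk_params: dict[str, RiskParams] = field(default_factory=dict)
    sdi_link: SdiLink = field(default_factory=SdiLink)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.gompertz_alpha <= 0:
            raise ValueError(f"gompertz_alpha must be positive, got {self.gompertz_alpha}")
        if self.gompertz_beta < 0:
            raise ValueError(f"gompertz_beta must be non-negative, got {self.gompertz_beta}")
        if len(self.cause_dirichlet) != len(self.causes):
            raise ValueError("cause_dirichlet must have one concentration per cause")
        if any(a <= 0 for a in self.cause_dirichlet):
            raise ValueError("cause_dirichlet concentrations must be positive")
        self._validate_age_groups()
        if not self.disability_params:
            self.disability_params = _default_disability(self.causes)
        unknown = set(self.disability_params) - set(self.causes)
        if unknown:
            raise ValueError(f"disability_params for unknown causes: {sorted(unknown)}")
        if not self.risk_params:
            self.risk_params = _default_risks()

    def _validate_age_groups(self) -> None:
        if not self.age_groups:
            raise ValueError("age_groups must be non-empty")
        for i, (lo, hi) in enumerate(self.age_groups):
            if hi <= lo:
                raise ValueError(f"age group {i} has non-positive width: ({lo}, {hi})")
            if i + 1 < len(self.age_groups):
                nxt = self.age_groups[i + 1][0]
                if not math.isclose(hi, nxt):
                    raise ValueError(
                        f"age groups must be contiguous; group {i} ends at {hi} "
                        f"but group {i + 1} starts at {nxt}"
                    )
        if not math.isinf(self.age_groups[-1][1]):
            raise ValueError("last age group must be open-ended (end = inf)")

    # -- seeding -----------------------------------------------------------
    def child_rng(self, stream: int, *indices: int) -> np.random.Generator:
        """Generator for one (stream, index...) cell of the seed tree."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream, *indices))
        return np.random.default_rng(ss)

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return _config_from_dict(raw)


def _default_disability(causes: list[str]) -> dict[str, DisabilityParams]:
    base = [
        DisabilityParams(intercept=0.02, age_slope=0.0030, disability_weight=0.25),
        DisabilityParams(intercept=0.01, age_slope=0.0015, disability_weight=0.35),
        DisabilityParams(intercept=0.00, age_slope=0.0040, disability_weight=0.45),
        DisabilityParams(intercept=0.03, age_slope=0.0005, disability_weight=0.10),
    ]
    return {c: base[i % len(base)] for i, c in enumerate(causes)}


def _default_risks() -> dict[str, RiskParams]:
    return {
        "smoking_like": RiskParams(
            categories=["never", "former", "current"],
            prevalence=[0.55, 0.25, 0.20],
            relative_risk=[1.0, 1.4, 2.5],
            tmrel_index=0,
        ),
        "bp_like": RiskParams(
            categories=["normal", "elevated", "high"],
            prevalence=[0.40, 0.35, 0.25],
            relative_risk=[1.0, 1.3, 2.0],
            tmrel_index=0,
        ),
    }


def _config_to_dict(cfg: SimConfig) -> dict:
    return {
        "n_locations": cfg.n_locations,
        "years": list(cfg.years),
        "age_groups": [[lo, "inf" if math.isinf(hi) else hi] for lo, hi in cfg.age_groups],
        "causes": list(cfg.causes),
        "gompertz_alpha": cfg.gompertz_alpha,
        "gompertz_beta": cfg.gompertz_beta,
        "cause_dirichlet": list(cfg.cause_dirichlet),
        "disability_params": {
            c: {
                "intercept": p.intercept,
                "age_slope": p.age_slope,
                "disability_weight": p.disability_weight,
            }
            for c, p in cfg.disability_params.items()
        },
        "risk_params": {
            r: {
                "categories": p.categories,
                "prevalence": p.prevalence,
                "relative_risk": p.relative_risk,
                "tmrel_index": p.tmrel_index,
            }
            for r, p in cfg.risk_params.items()
        },
        "sdi_link": {"scale": cfg.sdi_link.scale, "center": cfg.sdi_link.center},
        "seed": cfg.seed,
    }


def _config_from_dict(raw: dict) -> SimConfig:
    kwargs = dict(raw)
    if "age_groups" in kwargs:
        kwargs["age_groups"] = [
            (float(lo), math.inf if hi in ("inf", None) else float(hi))
            for lo, hi in kwargs["age_groups"]
        ]
    if "disability_params" in kwargs:
        kwargs["disability_params"] = {
            c: DisabilityParams(**p) for c, p in kwargs["disability_params"].items()
        }
    if "risk_params" in kwargs:
        kwargs["risk_params"] = {r: RiskParams(**p) for r, p in kwargs["risk_params"].items()}
    if "sdi_link" in kwargs:
        kwargs["sdi_link"] = SdiLink(**kwargs["sdi_link"])
    return SimConfig(**kwargs)
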