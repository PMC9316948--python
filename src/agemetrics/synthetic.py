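"""Synthetic long-format burden-of-disease inputs with known ground truth.

Every generator is deterministic given ``SimConfig.seed``: draws come from
per-stream child seeds (see :mod:`agemetrics.config`), so the output for one
stratum never depends on how many other strata were generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    STREAM_CAUSE_FRACTIONS,
    STREAM_COVERAGE,
    STREAM_HAQ,
    STREAM_SDI,
    SimConfig,
)

SEX_MALE = 1
SEX_FEMALE = 2
SEX_BOTH = 3

# fixed multiplicative sex contrast applied to the all-cause hazard
_SEX_FACTOR = {SEX_MALE: 1.2, SEX_FEMALE: 0.85}


@dataclass
class MortalitySurface:
    """Cause- and age-specific mortality rates for one location/sex/year."""

    location_id: int
    sex: int
    year: int
    age_start: np.ndarray  # interval lower bounds, years
    age_width: np.ndarray  # interval widths; inf for the open interval
    causes: list[str]
    mx: np.ndarray  # shape (n_causes, n_ages), deaths per person-year
    sdi: float = float("nan")

    def __post_init__(self) -> None:
        self.age_start = np.asarray(self.age_start, float)
        self.age_width = np.asarray(self.age_width, float)
        self.mx = np.asarray(self.mx, float)
        if self.mx.shape != (len(self.causes), len(self.age_start)):
            raise ValueError("mx must be (n_causes, n_ages)")

    @property
    def all_cause(self) -> np.ndarray:
        return self.mx.sum(axis=0)


@dataclass
class YldSurface:
    """Per-cause prevalence and (unadjusted) YLD rates on the same grid."""

    location_id: int
    sex: int
    year: int
    age_start: np.ndarray
    causes: list[str]
    prevalence: np.ndarray  # (n_causes, n_ages) in [0, 1]
    disability_weight: np.ndarray  # (n_causes,)
    yld_rate: np.ndarray = field(init=False)  # prevalence * dw, pre-comorbidity

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, float)
        self.disability_weight = np.asarray(self.disability_weight, float)
        if np.any((self.prevalence < 0) | (self.prevalence > 1)):
            raise ValueError("prevalences must lie in [0, 1]")
        if np.any((self.disability_weight < 0) | (self.disability_weight > 1)):
            raise ValueError("disability weights must lie in [0, 1]")
        self.yld_rate = self.prevalence * self.disability_weight[:, None]


def generate_sdi_haq(config: SimConfig) -> pd.DataFrame:
    """Per location-year SDI in [0, 1] and HAQ in [0, 100].

    Each location gets a base SDI plus a small positive secular drift; HAQ is
    a noisy monotone transform of SDI.  The mortality multiplier implied by
    SDI is ``config.sdi_link.multiplier`` and is stored with the mortality
    surfaces, so the SDI->mortality link is recoverable downstream.
    """
    rows = []
    y0 = min(config.years)
    for loc in range(config.n_locations):
        rng = config.child_rng(STREAM_SDI, loc)
        base = rng.uniform(0.15, 0.85)
        drift = rng.uniform(0.001, 0.004)  # per year
        rng_haq = config.child_rng(STREAM_HAQ, loc)
        for year in config.years:
            sdi = float(np.clip(base + drift * (year - y0), 0.0, 1.0))
            haq = float(np.clip(100 * sdi + rng_haq.normal(0, 3.0), 0.0, 100.0))
            rows.append({"location_id": loc, "year": year, "sdi": sdi, "haq": haq})
    return pd.DataFrame(rows)


def generate_mortality(
    config: SimConfig, sdi_table: pd.DataFrame | None = None
) -> list[MortalitySurface]:
    """One :class:`MortalitySurface` per (location, sex, year).

    All-cause rate at age-group start ``a``:
    ``alpha * exp(beta * a) * sdi_multiplier(location, year) * sex_factor``.
    Cause-specific rates are Dirichlet fractions of the all-cause rate; the
    fraction vector is drawn once per (location, sex) so trends over time
    come only through SDI.
    """
    if config.gompertz_alpha <= 0:
        raise ValueError(f"gompertz_alpha must be positive, got {config.gompertz_alpha}")
    if sdi_table is None:
        sdi_table = generate_sdi_haq(config)
    sdi_lookup = sdi_table.set_index(["location_id", "year"])["sdi"]

    starts = np.array([lo for lo, _ in config.age_groups])
    widths = np.array(
        [math.inf if math.isinf(hi) else hi - lo for lo, hi in config.age_groups]
    )
    base_hazard = config.gompertz_alpha * np.exp(config.gompertz_beta * starts)

    surfaces = []
    for loc in range(config.n_locations):
        for sex in (SEX_MALE, SEX_FEMALE):
            rng = config.child_rng(STREAM_CAUSE_FRACTIONS, loc, sex)
            fractions = rng.dirichlet(config.cause_dirichlet)
            for year in config.years:
                sdi = float(sdi_lookup.loc[(loc, year)])
                mult = float(config.sdi_link.multiplier(sdi)) * _SEX_FACTOR[sex]
                all_cause = base_hazard * mult
                surfaces.append(
                    MortalitySurface(
                        location_id=loc,
                        sex=sex,
                        year=year,
                        age_start=starts,
                        age_width=widths,
                        causes=list(config.causes),
                        mx=fractions[:, None] * all_cause[None, :],
                        sdi=sdi,
                    )
                )
    return surfaces


def generate_ylds(config: SimConfig, mortality: MortalitySurface) -> YldSurface:
    """Per-cause prevalences and pre-comorbidity YLD rates for one stratum.

    Prevalence is linear in age (clipped to [0, 1]); the YLD rate is
    prevalence times the cause's disability weight.
    """
    prev = np.vstack(
        [config.disability_params[c].prevalence(mortality.age_start) for c in config.causes]
    )
    dw = np.array([config.disability_params[c].disability_weight for c in config.causes])
    return YldSurface(
        location_id=mortality.location_id,
        sex=mortality.sex,
        year=mortality.year,
        age_start=mortality.age_start,
        causes=list(config.causes),
        prevalence=prev,
        disability_weight=dw,
    )


def generate_coverage(
    config: SimConfig,
    sparsity: float,
    entities: list[str] | None = None,
    periods: tuple[str, ...] = ("1990-2005", "2005-2019"),
    age_flags: tuple[str, ...] = ("all-ages", "aged-70-plus"),
) -> pd.DataFrame:
    """Bernoulli(1 - sparsity) data-availability indicators, long format.

    Columns: country, entity, entity_type, period, age_flag, has_data.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError(f"sparsity must lie in [0, 1], got {sparsity}")
    if entities is None:
        entities = list(config.causes) + list(config.risk_params)
    cause_set = set(config.causes)
    rng = config.child_rng(STREAM_COVERAGE)
    rows = []
    for loc in range(config.n_locations):
        for ent in entities:
            for period in periods:
                for flag in age_flags:
                    rows.append(
                        {
                            "country": f"loc_{loc}",
                            "entity": ent,
                            "entity_type": "cause" if ent in cause_set else "risk",
                            "period": period,
                            "age_flag": flag,
                            "has_data": int(rng.random() >= sparsity),
                        }
                    )
    return pd.DataFrame(rows)


def mortality_to_frame(surfaces: list[MortalitySurface]) -> pd.DataFrame:
    """Long-format rows (measure = 'mx') incl. the all-cause aggregate '_all'."""
    recs = []
    for s in surfaces:
        ends = s.age_start + s.age_width
        for ci, cause in enumerate(s.causes):
            for ai in range(len(s.age_start)):
                recs.append(
                    (s.location_id, s.year, s.sex, s.age_start[ai], ends[ai], cause, "mx",
                     s.mx[ci, ai])
                )
        allc = s.all_cause
        for ai in range(len(s.age_start)):
            recs.append(
                (s.location_id, s.year, s.sex, s.age_start[ai], ends[ai], "_all", "mx",
                 allc[ai])
            )
    return pd.DataFrame(
        recs,
        columns=["location_id", "year", "sex", "age_group_start", "age_group_end",
                 "label", "measure", "value"],
    )
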