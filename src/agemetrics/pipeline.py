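"""End-to-end driver: synthetic inputs -> life tables -> healthspan ->
decomposition -> risks -> transition ratios -> coverage indices.

Every stage logs one structured line (stage, rows in/out, seed) and all
outputs are plain CSV/JSON, deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import healthspan as hs
from . import io as aio
from .config import SimConfig
from .decomposition import decompose_window_prob, direction_split
from .lifetable import build_lifetable, life_expectancy_at, prob_death_window
from .riskburden import RiskSpec, annualized_rate_of_change, attributable_burden, paf, sev
from .synthetic import (
    MortalitySurface,
    generate_coverage,
    generate_mortality,
    generate_sdi_haq,
    generate_ylds,
    mortality_to_frame,
)
from .transition import fit_expected_curve, observed_expected_ratio

log = logging.getLogger("agemetrics.pipeline")

#: reference hazard schedule used for the bundled standard life expectancy
_STANDARD_ALPHA = 2e-5
_STANDARD_BETA = 0.095


def standard_life_expectancy(age_start: np.ndarray) -> np.ndarray:
    """Synthetic standard remaining life expectancy per age group.

    Built once from a fixed low-mortality reference schedule; stands in for
    an external standard table when computing years of life lost.
    """
    age_start = np.asarray(age_start, float)
    mx = _STANDARD_ALPHA * np.exp(_STANDARD_BETA * age_start)
    return build_lifetable(age_start, mx, ax_rule="exponential").ex


def _stage(name: str, rows_in: int, rows_out: int, seed: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d seed=%d", name, rows_in, rows_out, seed)


def _shifted_risk(spec: RiskSpec, shift: float) -> RiskSpec:
    """Move a fraction of the top-risk category's mass to TMREL (exposure improvement)."""
    prev = spec.prevalence.copy()
    top = int(np.argmax(spec.rr))
    moved = prev[top] * shift
    prev[top] -= moved
    prev[spec.tmrel_index] += moved
    return RiskSpec(spec.categories, prev, spec.rr.copy(), spec.tmrel_index)


def run_pipeline(
    config: SimConfig,
    outdir: str,
    sparsity: float = 0.3,
    ax_rule: str = "midpoint",
    exposure_improvement: float = 0.15,
) -> dict[str, str]:
    """Run all stages on a synthetic scenario; returns output paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # -- stage 1: simulate -------------------------------------------------
    sdi_haq = generate_sdi_haq(config)
    surfaces = generate_mortality(config, sdi_haq)
    est = mortality_to_frame(surfaces)
    sdi_rows = pd.DataFrame(
        {
            "location_id": sdi_haq["location_id"],
            "year": sdi_haq["year"],
            "sex": 3,
            "age_group_start": 0.0,
            "age_group_end": math.inf,
            "label": "_all",
            "measure": "sdi",
            "value": sdi_haq["sdi"],
        }
    )
    haq_rows = sdi_rows.assign(measure="haq", value=sdi_haq["haq"].to_numpy())
    est = pd.concat([est, sdi_rows, haq_rows], ignore_index=True)
    paths["estimates"] = str(out / "estimates.csv")
    aio.write_estimates(est, paths["estimates"])
    _stage("simulate", 0, len(est), config.seed)

    # -- stage 2+3: life tables, HALE, ill-health fraction -----------------
    std_le = standard_life_expectancy(surfaces[0].age_start)
    metric_rows = []
    for s in surfaces:
        lt = build_lifetable(s.age_start, s.all_cause, ax_rule=ax_rule)
        ylds = generate_ylds(config, s)
        yld_rate = np.zeros(len(s.age_start))
        for ai in range(len(s.age_start)):
            adj = hs.comorbidity_adjust(ylds.prevalence[:, ai], ylds.disability_weight)
            yld_rate[ai] = adj.sum()
        res = hs.healthspan_at(lt, yld_rate, age=70.0)
        i70 = lt.row_index(70.0)
        deaths = s.mx * (lt.Lx[None, :] / lt.lx[0])  # per-capita death counts
        yll_70plus = float(hs.yll(deaths, std_le)[:, i70:].sum())
        metric_rows.append(
            {
                "location_id": s.location_id,
                "year": s.year,
                "sex": s.sex,
                "sdi": s.sdi,
                "le70": res.le70,
                "hale70": res.hale70,
                "pyih70": res.pyih70,
                "q20_70": prob_death_window(lt, 70.0, 20.0),
                "yll70plus_per_capita": yll_70plus,
            }
        )
    metrics = pd.DataFrame(metric_rows)
    paths["metrics"] = str(out / "metrics.csv")
    metrics.to_csv(paths["metrics"], index=False)
    _stage("healthspan", len(est), len(metrics), config.seed)

    # -- stage 4: decomposition first vs last year -------------------------
    y1, y2 = min(config.years), max(config.years)
    by_key: dict[tuple[int, int, int], MortalitySurface] = {
        (s.location_id, s.sex, s.year): s for s in surfaces
    }
    decomp_rows = []
    for loc in range(config.n_locations):
        for sex in (1, 2):
            res = decompose_window_prob(by_key[(loc, sex, y1)], by_key[(loc, sex, y2)],
                                        ax_rule=ax_rule)
            neg, pos = direction_split(res)
            for cause, contrib in res.as_dict().items():
                share = contrib / res.total_change if res.total_change != 0 else math.nan
                decomp_rows.append(
                    {
                        "location_id": loc,
                        "sex": sex,
                        "year_from": y1,
                        "year_to": y2,
                        "cause": cause,
                        "contribution": contrib,
                        "share_of_change": share,
                        "total_change": res.total_change,
                        "negative_sum": neg,
                        "positive_sum": pos,
                    }
                )
    decomp = pd.DataFrame(decomp_rows)
    paths["decomposition"] = str(out / "decomposition.csv")
    decomp.to_csv(paths["decomposition"], index=False)
    _stage("decomposition", len(metrics), len(decomp), config.seed)

    # -- stage 5: risk attribution ----------------------------------------
    daly_70plus = metrics.groupby("year")["yll70plus_per_capita"].mean().to_dict()
    risk_rows = []
    for name in sorted(config.risk_params):
        rp = config.risk_params[name]
        spec1 = RiskSpec(rp.categories, np.array(rp.prevalence), np.array(rp.relative_risk),
                         rp.tmrel_index)
        spec2 = _shifted_risk(spec1, exposure_improvement)
        p2 = paf(spec2)
        arc = annualized_rate_of_change(sev(spec1), sev(spec2), y2 - y1)
        risk_rows.append(
            {
                "risk": name,
                "paf": p2,
                "sev_initial": sev(spec1),
                "sev_final": sev(spec2),
                "arc_sev": arc,
                "attrib_burden_70plus": attributable_burden(p2, daly_70plus[y2]),
            }
        )
    risks = pd.DataFrame(risk_rows)
    paths["risks"] = str(out / "risks.csv")
    risks.to_csv(paths["risks"], index=False)
    _stage("risks", len(metrics), len(risks), config.seed)

    # -- stage 6: transition (one model per sex) ---------------------------
    ratio_frames = []
    for sex, grp in metrics.groupby("sex"):
        n_knots = max(0, min(2, len(grp) - 4))  # cubic basis needs n_knots + 4 points
        model = fit_expected_curve(grp["sdi"].to_numpy(), grp["le70"].to_numpy(),
                                   covariate="sdi", n_knots=n_knots)
        model.to_json(str(out / f"transition_le70_sdi_sex{sex}.json"))
        ratio = observed_expected_ratio(grp["le70"].to_numpy(), model, grp["sdi"].to_numpy())
        ratio_frames.append(
            grp[["location_id", "year", "sex", "sdi", "le70"]].assign(
                expected_le70=model.predict(grp["sdi"].to_numpy()),
                obs_exp_ratio=ratio,
            )
        )
    ratios = pd.concat(ratio_frames, ignore_index=True)
    paths["transition"] = str(out / "transition_ratios.csv")
    ratios.to_csv(paths["transition"], index=False)
    _stage("transition", len(metrics), len(ratios), config.seed)

    # -- stage 7: coverage -------------------------------------------------
    cov_frame = generate_coverage(config, sparsity)
    paths["coverage"] = str(out / "coverage.csv")
    cov_frame.to_csv(paths["coverage"], index=False)
    matrix = cov.CoverageMatrix(cov_frame)
    dci_frames = {"dci_by_cause": [], "dci_by_country": [], "dci_gap": []}
    for period in matrix.periods:
        for flag in matrix.age_flags:
            dci_frames["dci_by_cause"].append(
                cov.dci_by_cause(matrix, period, flag).rename_axis("entity").reset_index()
                .assign(period=period, age_flag=flag)
            )
            dci_frames["dci_by_country"].append(
                cov.dci_by_country(matrix, period, flag).rename_axis("country").reset_index()
                .assign(period=period, age_flag=flag)
            )
        dci_frames["dci_gap"].append(
            cov.dci_gap(matrix, period, by="entity").rename_axis("entity").reset_index()
            .assign(period=period)
        )
    for key, frames in dci_frames.items():
        paths[key] = str(out / f"{key}.csv")
        pd.concat(frames, ignore_index=True).to_csv(paths[key], index=False)
    _stage("coverage", len(cov_frame), sum(len(f) for f in dci_frames.values()), config.seed)

    # -- summary -----------------------------------------------------------
    summary = {
        "seed": config.seed,
        "n_locations": config.n_locations,
        "years": list(config.years),
        "causes": list(config.causes),
        "outputs": {k: Path(v).name for k, v in sorted(paths.items())},
        "n_strata": len(surfaces),
    }
    paths["summary"] = str(out / "summary.json")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _stage("summary", len(metrics), 1, config.seed)
    return paths
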