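import math

import numpy as np
import pytest

from agemetrics import SimConfig, generate_coverage, generate_mortality, generate_sdi_haq
from agemetrics.synthetic import generate_ylds, mortality_to_frame


def test_closed_form_hazard():
    """alpha=0.005, beta=0.09, multiplier forced to 1: rate at 70 = 0.005 e^6.3."""
    cfg = SimConfig(n_locations=1, years=[2000], gompertz_alpha=0.005, gompertz_beta=0.09,
                    seed=5)
    cfg.sdi_link.scale = 0.0  # multiplier identically 1
    surfaces = generate_mortality(cfg)
    male = next(s for s in surfaces if s.sex == 1)
    i70 = int(np.searchsorted(male.age_start, 70.0))
    # male sex factor 1.2 is a fixed contrast; divide it out
    assert male.all_cause[i70] / 1.2 == pytest.approx(0.005 * math.exp(6.3), rel=1e-12)


def test_zero_slope_constant_rate():
    cfg = SimConfig(n_locations=1, years=[2000], gompertz_beta=0.0, seed=5)
    s = generate_mortality(cfg)[0]
    assert np.ptp(s.all_cause) == pytest.approx(0.0, abs=0.0)


def test_concentrated_dirichlet():
    cfg = SimConfig(
        n_locations=1, years=[2000],
        causes=["a", "b"], cause_dirichlet=[1e9, 1e-9], seed=5,
        disability_params={},
    )
    s = generate_mortality(cfg)[0]
    np.testing.assert_allclose(s.mx[0], s.all_cause, rtol=1e-6)
    assert np.all(s.mx[1] <= 1e-6 * s.all_cause)


def test_cause_closure_and_monotone_ageing(small_config):
    for s in generate_mortality(small_config):
        np.testing.assert_allclose(s.mx.sum(axis=0), s.all_cause, atol=1e-12)
        assert np.all(np.diff(s.all_cause) > 0)  # beta > 0


def test_determinism(small_config):
    a = mortality_to_frame(generate_mortality(small_config))
    b = mortality_to_frame(generate_mortality(small_config))
    assert a.equals(b)
    other = SimConfig(n_locations=3, years=[1990, 2019], seed=8)
    c = mortality_to_frame(generate_mortality(other))
    assert not a["value"].equals(c["value"])


def test_adding_location_does_not_perturb_existing(small_config):
    bigger = SimConfig(n_locations=small_config.n_locations + 2,
                       years=small_config.years, seed=small_config.seed)
    small = generate_sdi_haq(small_config)
    big = generate_sdi_haq(bigger)
    merged = small.merge(big, on=["location_id", "year"], suffixes=("_s", "_b"))
    np.testing.assert_allclose(merged["sdi_s"], merged["sdi_b"])


def test_sdi_haq_ranges(default_config):
    tab = generate_sdi_haq(default_config)
    assert tab["sdi"].between(0, 1).all()
    assert tab["haq"].between(0, 100).all()
    assert len(tab) == default_config.n_locations * len(default_config.years)


def test_sdi_link_invertible(default_config):
    sdi = np.linspace(0.05, 0.95, 7)
    mult = default_config.sdi_link.multiplier(sdi)
    np.testing.assert_allclose(default_config.sdi_link.inverse(mult), sdi, atol=1e-12)
    assert np.all(np.diff(mult) < 0)  # higher SDI -> lower mortality


def test_mortality_multiplier_applied(small_config):
    surfaces = generate_mortality(small_config)
    s = surfaces[0]
    base = small_config.gompertz_alpha * np.exp(small_config.gompertz_beta * s.age_start)
    expected = base * small_config.sdi_link.multiplier(s.sdi) * 1.2  # male factor
    np.testing.assert_allclose(s.all_cause, expected, rtol=1e-12)


def test_ylds_linear_model():
    """intercept 0.1, slope 0.004/yr at age 75 -> prevalence 0.4; dw 0.2 -> rate 0.08."""
    from agemetrics import DisabilityParams

    cfg = SimConfig(
        n_locations=1, years=[2000], causes=["only"], cause_dirichlet=[1.0], seed=5,
        disability_params={
            "only": DisabilityParams(intercept=0.1, age_slope=0.004, disability_weight=0.2)
        },
    )
    s = generate_mortality(cfg)[0]
    y = generate_ylds(cfg, s)
    i75 = int(np.searchsorted(s.age_start, 75.0))
    assert y.prevalence[0, i75] == pytest.approx(0.4, rel=1e-12)
    assert y.yld_rate[0, i75] == pytest.approx(0.08, rel=1e-12)


def test_ylds_zero_prevalence(small_config):
    from agemetrics import DisabilityParams

    cfg = SimConfig(
        n_locations=1, years=[2000], causes=["only"], cause_dirichlet=[1.0], seed=5,
        disability_params={"only": DisabilityParams(0.0, 0.0, 0.5)},
    )
    y = generate_ylds(cfg, generate_mortality(cfg)[0])
    assert np.all(y.yld_rate == 0)


def test_disability_weight_validation():
    from agemetrics import DisabilityParams

    with pytest.raises(ValueError, match="disability_weight"):
        DisabilityParams(0.1, 0.0, 1.5)


@pytest.mark.parametrize("sparsity,expect", [(0.0, 1), (1.0, 0)])
def test_coverage_extremes(small_config, sparsity, expect):
    frame = generate_coverage(small_config, sparsity)
    assert (frame["has_data"] == expect).all()


def test_coverage_seed_replay(small_config):
    """Row sums reproduce under an independent replay of the same child seed."""
    frame = generate_coverage(small_config, 0.5)
    rng = np.random.default_rng(np.random.SeedSequence(small_config.seed, spawn_key=(2,)))
    replay = (rng.random(len(frame)) >= 0.5).astype(int)
    np.testing.assert_array_equal(frame["has_data"].to_numpy(), replay)


def test_config_validation():
    with pytest.raises(ValueError, match="gompertz_alpha"):
        SimConfig(gompertz_alpha=-1.0)
    with pytest.raises(ValueError, match="contiguous"):
        SimConfig(age_groups=[(0.0, 5.0), (10.0, math.inf)])
    with pytest.raises(ValueError, match="open-ended"):
        SimConfig(age_groups=[(0.0, 5.0), (5.0, 10.0)])


def test_config_yaml_roundtrip(tmp_path, small_config):
    path = tmp_path / "cfg.yaml"
    small_config.to_yaml(str(path))
    loaded = SimConfig.from_yaml(str(path))
    assert loaded == small_config
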