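import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agemetrics import (
    HealthspanResult,
    build_lifetable,
    comorbidity_adjust,
    daly,
    hale_sullivan,
    healthspan_at,
    life_expectancy_at,
    pyih,
    round_half_up,
    yll,
)

from oracles import comorbidity_microsim_oracle, comorbidity_oracle


class TestComorbidity:
    def test_single_condition_unchanged(self):
        np.testing.assert_allclose(comorbidity_adjust([1.0], [0.3]), [0.3])
        np.testing.assert_allclose(comorbidity_adjust([0.4], [0.3]), [0.12])

    def test_two_condition_worked_case(self):
        adj = comorbidity_adjust([1.0, 1.0], [0.2, 0.3])
        assert adj.sum() == pytest.approx(0.44, rel=1e-12)
        np.testing.assert_allclose(adj, [0.176, 0.264], rtol=1e-12)

    def test_zero_weight_condition_inert(self):
        base = comorbidity_adjust([0.5, 0.7], [0.2, 0.3])
        with_null = comorbidity_adjust([0.5, 0.7, 0.9], [0.2, 0.3, 0.0])
        assert with_null[2] == 0.0
        np.testing.assert_allclose(with_null[:2], base, rtol=1e-12)

    def test_total_matches_independence_product(self):
        p = np.array([0.3, 0.5, 0.2, 0.8])
        dw = np.array([0.1, 0.45, 0.3, 0.05])
        adj = comorbidity_adjust(p, dw)
        assert adj.sum() == pytest.approx(1 - np.prod(1 - p * dw), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.uniform(0, 1, 5).tolist()
            dw = rng.uniform(0, 1, 5).tolist()
            np.testing.assert_allclose(
                comorbidity_adjust(p, dw), comorbidity_oracle(p, dw), rtol=1e-10
            )

    def test_microsim_agrees_with_analytic(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, 5)
        dw = rng.uniform(0.05, 0.6, 5)
        analytic = comorbidity_adjust(p, dw)
        micro = comorbidity_adjust(p, dw, mode="microsim", n_sim=100_000, seed=12)
        _, se = comorbidity_microsim_oracle(p.tolist(), dw.tolist(), 100_000,
                                            np.random.default_rng(99))
        np.testing.assert_array_less(np.abs(micro - analytic), 3 * se + 1e-12)

    def test_too_many_sequelae(self):
        with pytest.raises(ValueError, match="microsim"):
            comorbidity_adjust(np.full(21, 0.1), np.full(21, 0.1))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="disability weights"):
            comorbidity_adjust([0.5], [1.5])
        with pytest.raises(ValueError, match="prevalences"):
            comorbidity_adjust([-0.1], [0.5])


class TestYll:
    def test_products(self):
        assert yll(np.array([0.0]), np.array([14.6])) == pytest.approx(0.0)
        assert yll(np.array([10.0]), np.array([14.6])) == pytest.approx(146.0)

    def test_additive_over_causes(self):
        rng = np.random.default_rng(1)
        deaths = rng.uniform(0, 100, (4, 6))
        std = rng.uniform(1, 30, 6)
        total = yll(deaths.sum(axis=0), std)
        np.testing.assert_allclose(yll(deaths, std).sum(axis=0), total, rtol=1e-9)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            yll(np.zeros((2, 5)), np.zeros(4))


class TestSullivan:
    def test_zero_yld_gives_le(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        hale = hale_sullivan(lt, np.zeros(age_grid.size))
        np.testing.assert_allclose(hale, lt.ex, rtol=1e-12)

    def test_constant_yld_scales_le(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        d = 0.25
        hale = hale_sullivan(lt, np.full(age_grid.size, d))
        i70 = lt.row_index(70.0)
        assert hale[i70] == pytest.approx((1 - d) * lt.ex[i70], rel=1e-12)

    def test_total_disability_gives_zero(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        assert np.all(hale_sullivan(lt, np.ones(age_grid.size)) == 0)

    def test_monotone_harm(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        rng = np.random.default_rng(4)
        yld = rng.uniform(0, 0.5, age_grid.size)
        base = hale_sullivan(lt, yld)[lt.row_index(70.0)]
        bumped = yld.copy()
        bumped[-3] += 0.2
        assert hale_sullivan(lt, bumped)[lt.row_index(70.0)] < base

    def test_validation(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        with pytest.raises(ValueError, match="yld"):
            hale_sullivan(lt, np.full(age_grid.size, 1.2))


class TestPyih:
    @pytest.mark.parametrize(
        "le,hale,expected",
        [
            (11.8, 8.48, 0.28),
            (16.0, 10.5, 0.34),
            (12.0, 12.0, 0.0),
        ],
    )
    def test_values(self, le, hale, expected):
        assert round_half_up(pyih(le, hale), 2) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError, match="le70"):
            pyih(0.0, 0.0)
        with pytest.raises(ValueError, match="hale70"):
            pyih(10.0, 11.0)

    def test_result_type_consistency(self):
        res = HealthspanResult(le70=12.0, hale70=9.0, pyih70=0.25)
        assert res.pyih70 == 0.25
        with pytest.raises(ValueError):
            HealthspanResult(le70=12.0, hale70=9.0, pyih70=0.3)

    def test_healthspan_at_dominance(self, age_grid, gompertz_mx):
        lt = build_lifetable(age_grid, gompertz_mx)
        rng = np.random.default_rng(5)
        res = healthspan_at(lt, rng.uniform(0, 0.4, age_grid.size))
        assert 0 < res.hale70 < res.le70
        assert res.le70 == pytest.approx(life_expectancy_at(lt, 70.0))


def test_round_half_up():
    assert round_half_up(0.285, 2) == 0.29
    assert round_half_up(0.2849999, 2) == 0.28
    assert round_half_up(2.5, 0) == 3.0


@settings(max_examples=50, deadline=None)
@given(
    yll_vals=st.lists(st.floats(0, 1e6), min_size=3, max_size=3),
    yld_vals=st.lists(st.floats(0, 1e6), min_size=3, max_size=3),
)
def test_daly_is_exact_sum(yll_vals, yld_vals):
    a, b = np.array(yll_vals), np.array(yld_vals)
    np.testing.assert_array_equal(daly(a, b), a + b)


def test_daly_validation():
    with pytest.raises(ValueError, match="non-negative"):
        daly(np.array([-1.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="grid"):
        daly(np.zeros(3), np.zeros(4))
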