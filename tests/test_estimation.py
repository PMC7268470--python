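import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colddeck import (
    SimulationSpec,
    cmh_rr,
    correct_rr,
    crude_rr,
    forward_attenuation,
    generate_correlated_pairs,
    simulate_survival,
)


def _vectors(n_exp, d_exp, n_unexp, d_unexp):
    e = np.array([1] * n_exp + [0] * n_unexp)
    d = np.array([1] * d_exp + [0] * (n_exp - d_exp)
                 + [1] * d_unexp + [0] * (n_unexp - d_unexp))
    return e, d


class TestCrudeRR:
    def test_two_by_two(self):
        e, d = _vectors(20, 10, 20, 5)
        assert crude_rr(e, d) == pytest.approx(2.0)

    def test_identical_risks_give_one(self):
        e, d = _vectors(30, 6, 60, 12)
        assert crude_rr(e, d) == pytest.approx(1.0)

    def test_matches_hand_counted_contingency(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            e = (rng.random(n) < 0.4).astype(int)
            d = (rng.random(n) < 0.5).astype(int)
            a = sum(1 for x, y in zip(e, d) if x and y)
            b = sum(1 for x, y in zip(e, d) if not x and y)
            n1, n0 = int(e.sum()), int(n - e.sum())
            if n1 == 0 or n0 == 0 or b == 0:
                assert math.isnan(crude_rr(e, d))
                continue
            assert crude_rr(e, d) == pytest.approx((a / n1) / (b / n0))

    def test_undefined_cases_are_nan(self):
        e, d = _vectors(20, 5, 20, 0)
        assert math.isnan(crude_rr(e, d))  # no unexposed deaths
        assert math.isnan(crude_rr(np.ones(10), np.ones(10)))  # empty group


class TestCMH:
    def test_single_stratum_collapses_to_crude(self):
        e, d = _vectors(20, 10, 20, 5)
        s = np.repeat("60-64", 40)
        assert cmh_rr(e, d, s) == pytest.approx(crude_rr(e, d))

    def test_simpson_reversal_fixture(self):
        # young stratum: mostly exposed, low risk; old: mostly unexposed,
        # high risk. Within both strata RR > 1 but the crude RR < 1; the
        # pooled estimate must restore the within-stratum direction.
        e1, d1 = _vectors(100, 20, 20, 2)    # RR = 2.0
        e2, d2 = _vectors(20, 10, 100, 40)   # RR = 1.25
        e = np.concatenate([e1, e2])
        d = np.concatenate([d1, d2])
        s = np.array(["young"] * 120 + ["old"] * 120)
        assert crude_rr(e, d) < 1.0
        # hand summation: (20*20/120 + 10*100/120) / (2*100/120 + 40*20/120)
        assert cmh_rr(e, d, s) == pytest.approx(1.4)

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(23)
        for _ in range(20):
            e = (rng.random(300) < 0.5).astype(int)
            s = rng.choice(["a", "b", "c"], 300)
            d = (rng.random(300) < 0.3 + 0.2 * e).astype(int)
            tables = []
            for k in ("a", "b", "c"):
                m = s == k
                a = np.sum((e == 1) & (d == 1) & m)
                bq = np.sum((e == 1) & (d == 0) & m)
                c = np.sum((e == 0) & (d == 1) & m)
                dd = np.sum((e == 0) & (d == 0) & m)
                tables.append(np.array([[a, bq], [c, dd]]))
            expected = StratifiedTable(tables).riskratio_pooled
            assert cmh_rr(e, d, s) == pytest.approx(expected, rel=1e-10)

    def test_no_unexposed_deaths_anywhere_is_nan(self):
        e, d = _vectors(20, 5, 20, 0)
        s = np.array(["a"] * 20 + ["b"] * 20)
        assert math.isnan(cmh_rr(e, d, s))

    def test_equals_crude_under_independence_and_homogeneity(self):
        rng = np.random.default_rng(29)
        n = 200_000
        e = (rng.random(n) < 0.4).astype(int)
        s = rng.choice(["a", "b"], n)  # independent of exposure
        d = (rng.random(n) < 0.2 + 0.1 * e).astype(int)
        assert cmh_rr(e, d, s) == pytest.approx(crude_rr(e, d), rel=0.01)


class TestCorrection:
    def test_null_preserved(self):
        val, imp = correct_rr(1.0, 0.3, 0.05)
        assert val == pytest.approx(1.0)
        assert not imp

    def test_table_anchor_value(self):
        val, imp = correct_rr(1.064, 0.159, 0.071)
        assert val == pytest.approx(2.04, abs=0.01)
        assert not imp

    def test_zero_rho_yields_impossible(self):
        val, imp = correct_rr(1.05, 0.2, 0.0)
        assert val == pytest.approx(1 - 1 / 0.2)  # = -4
        assert imp

    def test_nan_input_is_invalid_not_impossible(self):
        val, imp = correct_rr(float("nan"), 0.2, 0.05)
        assert math.isnan(val) and not imp


class TestForwardAttenuation:
    def test_anchor_value(self):
        assert forward_attenuation(2.0, 0.159, 0.071) == pytest.approx(1.062, abs=0.001)

    def test_null_maps_to_null(self):
        assert forward_attenuation(1.0, 0.3, 0.1) == 1.0

    def test_perfect_measurement_limit(self):
        assert forward_attenuation(1.7, 0.0, 1.0) == pytest.approx(1.7)

    @settings(max_examples=300, derandomize=True)
    @given(
        x=st.floats(0.25, 4.0),
        p=st.floats(0.01, 0.99),
        rho=st.floats(0.001, 0.5),
    )
    def test_round_trip_identity(self, x, p, rho):
        rr_i = forward_attenuation(x, p, rho)
        back, imp = correct_rr(rr_i, p, rho)
        assert back == pytest.approx(x, rel=1e-9, abs=1e-9)
        assert not imp

    @settings(max_examples=300, derandomize=True)
    @given(
        x=st.floats(0.25, 4.0),
        p=st.floats(0.01, 0.99),
        rho=st.floats(0.0, 1.0),
    )
    def test_attenuation_toward_null(self, x, p, rho):
        rr_i = forward_attenuation(x, p, rho)
        assert abs(rr_i - 1) <= abs(x - 1) + 1e-12


class TestMonteCarloOracle:
    @pytest.mark.parametrize("d", [0.3, 0.54])
    def test_imputed_rr_converges_to_forward_attenuation(self, d):
        # imputed exposure pair-correlated with truth at (p, rho); survival
        # at target RR; the crude RR on the imputed exposure converges to
        # the closed-form attenuated value, independent of the death rate
        n, p, rho, target = 400_000, 0.159, 0.071, 2.0
        truth, imputed = generate_correlated_pairs(n, p, rho, seed=31)
        spec = SimulationSpec(target_rr=target, death_rate=d, prevalence=p,
                              n=n, seed=32)
        death = simulate_survival(truth, spec)
        expected = forward_attenuation(target, p, rho)
        assert crude_rr(imputed, death) == pytest.approx(expected, abs=0.01)
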