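"""Unit and property tests of the circular-statistics estimators."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibsync import circstat

from _tolerances import ORACLE_ATOL, ROTATION_ATOL
from oracles import (
    oracle_ccorr_adjusted,
    oracle_ccorr_standard,
    oracle_circ_mean,
    oracle_hodges_ajne_m,
    oracle_hodges_ajne_m_exact,
    oracle_hodges_ajne_pvalue,
    oracle_plv,
)


class TestWrap:
    def test_range(self, rng):
        x = rng.uniform(-50, 50, 1000)
        w = circstat.wrap_angle(x)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)

    def test_boundary_maps_to_plus_pi(self):
        assert circstat.wrap_angle(-np.pi) == pytest.approx(np.pi)
        assert circstat.wrap_angle(np.pi) == pytest.approx(np.pi)

    def test_equivalence_mod_2pi(self, rng):
        x = rng.uniform(-np.pi, np.pi, 100)
        np.testing.assert_allclose(
            circstat.wrap_angle(x + 6 * np.pi), x, atol=1e-12
        )


class TestCircMean:
    def test_concentrated(self):
        md = circstat.circ_mean([np.pi / 4] * 10)
        assert md.mu == pytest.approx(np.pi / 4)
        assert md.rbar == pytest.approx(1.0)
        assert md.defined

    def test_symmetric_cancellation(self):
        md = circstat.circ_mean([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert md.rbar == pytest.approx(0.0, abs=1e-12)
        assert not md.defined
        assert md.mu == 0.0

    def test_two_point(self):
        md = circstat.circ_mean([0, np.pi / 2])
        assert md.mu == pytest.approx(np.pi / 4)
        assert md.rbar == pytest.approx(np.sqrt(2) / 2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            circstat.circ_mean([])

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            circstat.circ_mean([0.0, np.nan])

    def test_matches_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(-np.pi, np.pi, rng.integers(2, 30))
            mu, rbar = oracle_circ_mean(a)
            md = circstat.circ_mean(a)
            assert md.mu == pytest.approx(mu, abs=ORACLE_ATOL)
            assert md.rbar == pytest.approx(rbar, abs=ORACLE_ATOL)


class TestCcorrStandard:
    def test_identical_concentrated_is_one(self, rng):
        a = 0.3 + 0.2 * rng.standard_normal(50)  # von Mises-like cluster
        est = circstat.ccorr_standard(a, a)
        assert est.value == pytest.approx(1.0, abs=1e-12)
        assert est.method == "standard"
        assert not est.mean_warning

    def test_sign_flip_is_minus_one(self, rng):
        a = 0.2 * rng.standard_normal(50)
        est = circstat.ccorr_standard(a, -a)
        assert est.value == pytest.approx(-1.0, abs=1e-12)

    def test_fixed_pairs_match_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-np.pi, np.pi, 6)
        b = rng.uniform(-np.pi, np.pi, 6)
        assert circstat.ccorr_standard(a, b).value == pytest.approx(
            oracle_ccorr_standard(a, b), abs=ORACLE_ATOL
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths differ"):
            circstat.ccorr_standard([0.1, 0.2], [0.1, 0.2, 0.3])

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            circstat.ccorr_standard([0.5] * 10, [0.5] * 10)

    def test_undefined_mean_sets_warning(self):
        a = np.array([0, np.pi / 2, np.pi, -np.pi / 2] * 3)
        b = a + 0.1
        est = circstat.ccorr_standard(a, b)
        assert est.mean_warning
        assert -1.0 <= est.value <= 1.0


class TestCcorrAdjusted:
    def test_uniform_in_phase_is_exactly_one(self):
        n = 16
        a = circstat.wrap_angle(np.arange(n) * 2 * np.pi / n)
        est = circstat.ccorr_adjusted(a, a)
        assert est.value == pytest.approx(1.0, abs=1e-12)
        assert est.r_diff == pytest.approx(n, abs=1e-9)
        assert est.r_sum == pytest.approx(0.0, abs=1e-9)

    def test_uniform_anti_phase_is_minus_one(self):
        n = 16
        a = circstat.wrap_angle(np.arange(n) * 2 * np.pi / n)
        assert circstat.ccorr_adjusted(a, -a).value == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_fixed_pairs_match_oracle(self, uniform_pair):
        a, b = uniform_pair
        assert circstat.ccorr_adjusted(a, b).value == pytest.approx(
            oracle_ccorr_adjusted(a, b), abs=ORACLE_ATOL
        )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for n in (8, 32, 128):
            a = rng.uniform(-np.pi, np.pi, n)
            b = rng.uniform(-np.pi, np.pi, n)
            r_adj, _ = pingouin.circ_corrcc(a, b, correction_uniform=True)
            r_std, _ = pingouin.circ_corrcc(a, b)
            assert circstat.ccorr_adjusted(a, b).value == pytest.approx(
                r_adj, abs=1e-12
            )
            assert circstat.ccorr_standard(a, b).value == pytest.approx(
                r_std, abs=1e-12
            )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            circstat.ccorr_adjusted([0.1, 0.2, 0.3], [0.1])


class TestPLV:
    def test_constant_lag_is_one(self, rng):
        a = rng.uniform(-np.pi, np.pi, 64)
        assert circstat.plv(a, a + 0.7).value == pytest.approx(1.0, abs=1e-12)

    def test_balanced_differences_cancel(self):
        n = 12
        a = np.arange(n) * 2 * np.pi / n
        assert circstat.plv(a, np.zeros(n)).value == pytest.approx(
            0.0, abs=1e-12
        )

    def test_fixed_pairs_match_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-np.pi, np.pi, 8)
        b = rng.uniform(-np.pi, np.pi, 8)
        assert circstat.plv(a, b).value == pytest.approx(
            oracle_plv(a, b), abs=ORACLE_ATOL
        )


class TestHodgesAjne:
    def test_identical_angles_reject(self):
        res = circstat.hodges_ajne([1.0] * 20)
        assert res.m == 0
        assert res.pvalue < 1e-3
        assert res.reject

    def test_evenly_spaced_fail_to_reject(self):
        a = np.arange(20) * 2 * np.pi / 20
        res = circstat.hodges_ajne(a)
        assert res.m == 10
        assert res.pvalue == 1.0
        assert not res.reject

    def test_concentrated_sample_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        a = circstat.wrap_angle(0.8 * rng.standard_normal(100))
        res = circstat.hodges_ajne(a)
        m_oracle = oracle_hodges_ajne_m(list(a))
        assert res.m == m_oracle
        assert res.pvalue == pytest.approx(
            oracle_hodges_ajne_pvalue(100, m_oracle), rel=1e-12
        )

    def test_small_sample_exact_formula(self):
        rng = np.random.default_rng(4)
        a = circstat.wrap_angle(0.5 * rng.standard_normal(20))
        res = circstat.hodges_ajne(a)
        assert res.pvalue == pytest.approx(
            oracle_hodges_ajne_pvalue(20, res.m), rel=1e-12
        )

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError):
            circstat.hodges_ajne([0.1, 0.2, 0.3])

    def test_statistic_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 60))
            res = circstat.hodges_ajne(rng.uniform(-np.pi, np.pi, n))
            assert 0 <= res.m <= n // 2
            assert 0 < res.pvalue <= 1.0


angle_lists = st.lists(
    st.floats(-10.0, 10.0, allow_nan=False), min_size=4, max_size=32
)


class TestProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data(), c=st.floats(-6.0, 6.0))
    def test_rotation_invariance(self, data, c):
        """Adding a constant to either input leaves all estimators unchanged."""
        a = np.array(data.draw(angle_lists))
        b = np.array(data.draw(st.lists(
            st.floats(-10.0, 10.0, allow_nan=False),
            min_size=len(a), max_size=len(a),
        )))
        try:
            ref_adj = circstat.ccorr_adjusted(a, b)
            ref_std = circstat.ccorr_standard(a, b)
        except ValueError:
            return  # degenerate draw
        ref_plv = circstat.plv(a, b)
        for aa, bb in ((a + c, b), (a, b + c)):
            assert circstat.ccorr_adjusted(aa, bb).value == pytest.approx(
                ref_adj.value, abs=ROTATION_ATOL
            )
            assert circstat.ccorr_standard(aa, bb).value == pytest.approx(
                ref_std.value, abs=ROTATION_ATOL
            )
            assert circstat.plv(aa, bb).value == pytest.approx(
                ref_plv.value, abs=ROTATION_ATOL
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_adjusted_antisymmetry(self, data):
        """ccorr_adjusted(a, -b) == -ccorr_adjusted(a, b)."""
        a = np.array(data.draw(angle_lists))
        b = np.array(data.draw(st.lists(
            st.floats(-10.0, 10.0, allow_nan=False),
            min_size=len(a), max_size=len(a),
        )))
        try:
            ref = circstat.ccorr_adjusted(a, b).value
        except ValueError:
            return
        assert circstat.ccorr_adjusted(a, -b).value == pytest.approx(
            -ref, abs=ROTATION_ATOL
        )

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(200):
            a = rng.uniform(-np.pi, np.pi, 256)
            b = rng.uniform(-np.pi, np.pi, 256)
            assert -1.0 <= circstat.ccorr_standard(a, b).value <= 1.0
            assert -1.0 <= circstat.ccorr_adjusted(a, b).value <= 1.0
            assert 0.0 <= circstat.plv(a, b).value <= 1.0

    def test_oracle_equivalence_small_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 33))
            a = rng.uniform(-np.pi, np.pi, n)
            b = rng.uniform(-np.pi, np.pi, n)
            assert circstat.ccorr_standard(a, b).value == pytest.approx(
                oracle_ccorr_standard(a, b), abs=ORACLE_ATOL
            )
            assert circstat.ccorr_adjusted(a, b).value == pytest.approx(
                oracle_ccorr_adjusted(a, b), abs=ORACLE_ATOL
            )
            assert circstat.plv(a, b).value == pytest.approx(
                oracle_plv(a, b), abs=ORACLE_ATOL
            )
            assert circstat.hodges_ajne(a).m == oracle_hodges_ajne_m_exact(list(a))
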