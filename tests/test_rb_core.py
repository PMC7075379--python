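"""Unit and property tests for the dose-response core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radbioqa as rb
from radbioqa.rb_core import ValidationError, _log_response

from conftest import random_differential_dvh


class TestEqd2:
    @pytest.mark.parametrize(
        "dose,n_fx,ab,expected",
        [
            (60.0, 30, 10.0, 60.0),  # 2 Gy/fraction is the fixed point
            (0.0, 5, 3.0, 0.0),
            (30.0, 3, 3.0, 78.0),    # x=10: 30*(10+3)/(2+3)
        ],
    )
    def test_scalar_values(self, dose, n_fx, ab, expected):
        assert rb.eqd2(dose, rb.FractionSchedule(n_fx), ab) == pytest.approx(
            expected, abs=1e-12
        )

    def test_vectorised_matches_scalar(self, schedule):
        doses = np.array([0.0, 10.0, 45.0, 80.0])
        out = rb.eqd2(doses, schedule, 3.0)
        for d, o in zip(doses, out):
            assert o == rb.eqd2(float(d), schedule, 3.0)

    def test_rejects_invalid(self, schedule):
        with pytest.raises(ValidationError):
            rb.eqd2(-1.0, schedule, 3.0)
        with pytest.raises(ValidationError):
            rb.eqd2(10.0, schedule, 0.0)
        with pytest.raises(ValidationError):
            rb.FractionSchedule(0)


class TestVoxelResponse:
    def test_half_response_at_d50(self, tumor_params):
        assert rb.voxel_response(55.0, tumor_params) == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_is_numerically_zero(self, tumor_params):
        assert rb.voxel_response(0.0, tumor_params) < 1e-100

    def test_double_d50_matches_direct_evaluation(self):
        # independent scalar evaluation of the response formula, gamma=1
        params = rb.ResponseParams("x", "tumor", 50.0, 1.0, 10.0)
        inner = math.e * 1.0 - 2.0 * (math.e * 1.0 - math.log(math.log(2.0)))
        expected = math.exp(-math.exp(inner))
        assert rb.voxel_response(100.0, params) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.9687931564585915, rel=1e-12)

    def test_extreme_doses_do_not_overflow(self, tumor_params):
        assert rb.voxel_response(1e6, tumor_params) == 1.0
        assert np.isfinite(_log_response(np.array([0.0, 1e9]), tumor_params)).all()

    @given(st.floats(min_value=0.5, max_value=8.0))
    def test_monotone_in_dose(self, gamma_slope):
        params = rb.ResponseParams("x", "tumor", 50.0, gamma_slope, 10.0)
        p = rb.voxel_response(np.linspace(0.0, 200.0, 2000), params)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("gamma_slope", [1.0, 2.5, 5.0])
    def test_slope_parameter_is_the_normalized_gradient(self, gamma_slope):
        params = rb.ResponseParams("x", "tumor", 60.0, gamma_slope, 10.0)
        est = rb.max_normalized_gradient(params)
        assert est == pytest.approx(gamma_slope, rel=0.01)


class TestTcp:
    def test_single_bin_at_d50(self, schedule):
        params = rb.ResponseParams("PTV", "tumor", 50.0, 2.5, 10.0)
        d50_total = 50.0  # pick total dose whose EQD2 equals D50: x=2 fixed point
        dvh = rb.DVH("PTV", "differential", np.array([d50_total]), np.array([1.0]))
        assert rb.tcp(dvh, rb.FractionSchedule(25), params) == pytest.approx(0.5, abs=1e-12)

    def test_two_half_volumes_at_d50(self):
        params = rb.ResponseParams("PTV", "tumor", 50.0, 2.5, 10.0)
        dvh = rb.DVH(
            "PTV", "differential", np.array([50.0 - 1e-9, 50.0]), np.array([0.5, 0.5])
        )
        assert rb.tcp(dvh, rb.FractionSchedule(25), params) == pytest.approx(0.5, rel=1e-6)

    def test_matches_per_bin_brute_force(self, schedule, tumor_params):
        dvh = rb.DVH(
            "PTV", "differential",
            np.array([40.0, 55.0, 62.0]), np.array([0.2, 0.5, 0.3]),
        )
        product = 1.0
        for d, v in zip(dvh.bin_doses, dvh.volumes):
            d2 = rb.eqd2(float(d), schedule, tumor_params.alpha_beta)
            product *= rb.voxel_response(d2, tumor_params) ** v
        assert rb.tcp(dvh, schedule, tumor_params) == pytest.approx(product, rel=1e-12)

    def test_rejects_cumulative_and_wrong_tissue(self, schedule, tumor_params, normal_params):
        cum = rb.DVH("PTV", "cumulative", np.array([0.0, 50.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValidationError, match="convert"):
            rb.tcp(cum, schedule, tumor_params)
        dvh = rb.DVH("PTV", "differential", np.array([50.0]), np.array([1.0]))
        with pytest.raises(ValidationError):
            rb.tcp(dvh, schedule, normal_params)

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=30)
    def test_log_space_matches_naive_product(self, schedule, tumor_params, seed):
        rng = np.random.default_rng(seed)
        dvh = random_differential_dvh(rng, 50)
        d2 = rb.eqd2(dvh.bin_doses, schedule, tumor_params.alpha_beta)
        p = rb.voxel_response(d2, tumor_params)
        naive = np.prod(p**dvh.volumes)
        if naive > 1e-300:
            assert rb.tcp(dvh, schedule, tumor_params) == pytest.approx(naive, abs=1e-9)

    @given(seed=st.integers(0, 2**32 - 1), scale=st.floats(1.02, 1.3))
    @settings(max_examples=25)
    def test_dose_scaling_strictly_increases_tcp(self, schedule, tumor_params, seed, scale):
        rng = np.random.default_rng(seed)
        dvh = random_differential_dvh(rng, 12, d_lo=20.0, d_hi=70.0)
        scaled = rb.DVH("PTV", "differential", dvh.bin_doses * scale, dvh.volumes)
        low = rb.tcp(dvh, schedule, tumor_params)
        high = rb.tcp(scaled, schedule, tumor_params)
        assert high > low


class TestNtcp:
    @pytest.mark.parametrize("s", [0.01, 0.1, 1.0, 10.0])
    def test_uniform_whole_organ_equals_voxel_response(self, s, schedule):
        params = rb.ResponseParams("o", "normal", 50.0, 2.0, 3.0, seriality=s)
        for dose in (10.0, 30.0, 45.0, 60.0, 80.0):
            dvh = rb.DVH("o", "differential", np.array([dose]), np.array([1.0]))
            d2 = rb.eqd2(dose, schedule, 3.0)
            assert rb.ntcp(dvh, schedule, params) == pytest.approx(
                rb.voxel_response(d2, params), abs=1e-9
            )

    def test_s1_reduces_to_parallel_closed_form(self, schedule):
        params = rb.ResponseParams("o", "normal", 55.0, 2.2, 3.0, seriality=1.0)
        dvh = rb.DVH("o", "differential", np.array([30.0, 60.0]), np.array([0.4, 0.6]))
        d2 = rb.eqd2(dvh.bin_doses, schedule, 3.0)
        p = rb.voxel_response(d2, params)
        expected = 1.0 - (1.0 - p[0]) ** 0.4 * (1.0 - p[1]) ** 0.6
        assert rb.ntcp(dvh, schedule, params) == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=50)
    def test_s1_closed_form_on_random_dvhs(self, schedule, seed):
        rng = np.random.default_rng(seed)
        dvh = random_differential_dvh(rng, int(rng.integers(2, 40)))
        params = rb.ResponseParams("o", "normal", 60.0, 2.0, 3.0, seriality=1.0)
        d2 = rb.eqd2(dvh.bin_doses, schedule, 3.0)
        p = rb.voxel_response(d2, params)
        expected = 1.0 - np.prod((1.0 - p) ** dvh.volumes)
        assert rb.ntcp(dvh, schedule, params) == pytest.approx(expected, abs=1e-9)

    def test_zero_dose_gives_zero_ntcp(self, schedule, normal_params):
        dvh = rb.DVH("o", "differential", np.array([0.0]), np.array([1.0]))
        assert rb.ntcp(dvh, schedule, normal_params) < 1e-12

    def test_missing_or_invalid_seriality_rejected(self, schedule):
        dvh = rb.DVH("o", "differential", np.array([40.0]), np.array([1.0]))
        no_s = rb.ResponseParams("o", "normal", 50.0, 2.0, 3.0)
        with pytest.raises(ValidationError, match="seriality"):
            rb.ntcp(dvh, schedule, no_s)
        with pytest.raises(ValidationError):
            rb.ResponseParams("o", "normal", 50.0, 2.0, 3.0, seriality=-1.0)

    @given(seed=st.integers(0, 2**32 - 1), scale=st.floats(1.02, 1.3))
    @settings(max_examples=25)
    def test_dose_scaling_strictly_increases_ntcp(self, schedule, normal_params, seed, scale):
        rng = np.random.default_rng(seed)
        dvh = random_differential_dvh(rng, 12, d_lo=20.0, d_hi=70.0)
        scaled = rb.DVH("o", "differential", dvh.bin_doses * scale, dvh.volumes)
        assert rb.ntcp(scaled, schedule, normal_params) > rb.ntcp(
            dvh, schedule, normal_params
        )


class TestPlanLevelProbabilities:
    def test_probability_injury(self):
        assert rb.probability_injury([0.3]) == pytest.approx(0.3)
        assert rb.probability_injury([]) == 0.0
        assert rb.probability_injury([0.1, 0.2]) == pytest.approx(1 - 0.9 * 0.8)
        with pytest.raises(ValidationError):
            rb.probability_injury([1.2])

    def test_probability_benefit(self):
        assert rb.probability_benefit([0.8]) == pytest.approx(0.8)
        assert rb.probability_benefit([0.9, 0.9]) == pytest.approx(0.81)
        assert rb.probability_benefit([]) == 1.0
        with pytest.raises(ValidationError):
            rb.probability_benefit([-0.1])

    @pytest.mark.parametrize(
        "pb,pi,expected", [(0.8, 0.2, 0.6), (1.0, 0.0, 1.0), (0.5, 0.5, 0.0)]
    )
    def test_p_plus(self, pb, pi, expected):
        assert rb.p_plus(pb, pi) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_p_plus_identity(self, pb, pi):
        assert rb.p_plus(pb, pi) + pi - pb == pytest.approx(0.0, abs=1e-15)
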