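import numpy as np
import pytest
from hypothesis import given, strategies as st

from angioffr import (
    CenterlineProfile,
    FlowMeasurement,
    FluidProperties,
    HyperemiaModel,
    LossCoefficients,
    StenosisSegment,
    calibrate_kfold,
    compute_ffr,
    expansion_coefficient_k2,
    pressure_drop,
    vascular_resistance,
    viscous_coefficient_k1,
)
from angioffr.cohort import CohortConfig, generate_cohort
from angioffr.errors import ConfigurationError
from angioffr.pressure import PA_PER_MMHG


def poiseuille_k1_mmhg(d_mm: float, length_mm: float, mu: float = 0.0035) -> float:
    """Closed-form 128*mu*L/(pi*D^4) for a uniform tube, in mmHg s/mL."""
    k1_si = 128.0 * mu * (length_mm * 1e-3) / (np.pi * (d_mm * 1e-3) ** 4)
    return k1_si * 1e-6 / PA_PER_MMHG


FIFTY_PCT_LESION = StenosisSegment(s_start=40, s_end=60, s_mld=50, mld=1.5, d_ref=3.0)


class TestViscousCoefficient:
    def test_uniform_tube_matches_poiseuille(self, uniform_tube):
        k1 = viscous_coefficient_k1(uniform_tube(d=3.0, length=100.0))
        assert k1 == pytest.approx(1.3205, abs=2e-4)
        assert k1 * PA_PER_MMHG / 1e-6 * 1e-12 == pytest.approx(176.05e-6, rel=1e-3)

    def test_linearity_in_length(self, uniform_tube):
        k1 = viscous_coefficient_k1(uniform_tube(d=3.0, length=100.0))
        k2 = viscous_coefficient_k1(uniform_tube(d=3.0, length=200.0))
        assert k2 == pytest.approx(2 * k1, rel=1e-9)

    def test_inverse_fourth_power_in_diameter(self, uniform_tube):
        k1 = viscous_coefficient_k1(uniform_tube(d=3.0, length=100.0))
        k_half = viscous_coefficient_k1(uniform_tube(d=1.5, length=100.0))
        assert k_half == pytest.approx(16 * k1, rel=1e-9)


class TestExpansionCoefficient:
    def test_no_stenosis_gives_zero(self):
        seg = StenosisSegment(s_start=0, s_end=10, s_mld=5, mld=3.0, d_ref=3.0)
        assert expansion_coefficient_k2(seg) == 0.0

    def test_fifty_percent_reference_lesion(self):
        assert expansion_coefficient_k2(FIFTY_PCT_LESION) == pytest.approx(1.0782, abs=2e-4)

    def test_linear_in_kt(self):
        k2 = expansion_coefficient_k2(FIFTY_PCT_LESION, kt=1.52)
        assert expansion_coefficient_k2(FIFTY_PCT_LESION, kt=3.04) == pytest.approx(
            2 * k2, rel=1e-12
        )


class TestQuadraticLaw:
    def test_zero_flow_limit_is_k1(self):
        coeffs = LossCoefficients(k1=1.32, k2=1.08)
        assert vascular_resistance(coeffs, 0.0) == pytest.approx(1.32)

    def test_hand_values(self):
        coeffs = LossCoefficients(k1=1.32, k2=1.08)
        assert vascular_resistance(coeffs, 2.0) == pytest.approx(3.48)
        assert pressure_drop(coeffs, 2.0) == pytest.approx(6.96)
        assert pressure_drop(LossCoefficients(k1=1.3205, k2=0.0), 1.0) == pytest.approx(1.3205)

    @given(
        k1=st.floats(0, 5),
        k2=st.floats(0, 5),
        q=st.floats(0, 6),
    )
    def test_drop_equals_resistance_times_flow(self, k1, k2, q):
        coeffs = LossCoefficients(k1=k1, k2=k2)
        assert pressure_drop(coeffs, q) == pytest.approx(
            vascular_resistance(coeffs, q) * q, rel=1e-12, abs=1e-12
        )

    @given(q=st.floats(0, 5), dq=st.floats(0.01, 2))
    def test_resistance_monotone_in_flow(self, q, dq):
        coeffs = LossCoefficients(k1=1.0, k2=0.5)
        assert vascular_resistance(coeffs, q + dq) >= vascular_resistance(coeffs, q)


def _flow(q_rest: float) -> FlowMeasurement:
    return FlowMeasurement(frame_count=10, fps=15, path_length=100.0, q_rest=q_rest)


class TestComputeFFR:
    def test_zero_loss_limit(self, uniform_tube):
        sol = compute_ffr(uniform_tube(), [], _flow(1e-9), 93.9)
        assert sol.ffr == pytest.approx(1.0, abs=1e-6)

    def test_worked_tube(self, uniform_tube):
        sol = compute_ffr(uniform_tube(d=3.0, length=100.0), [], _flow(0.83), 93.9)
        assert sol.pa_hyp == pytest.approx(84.51)
        assert sol.q_hyp == pytest.approx(1.66)
        assert sol.dp_total == pytest.approx(2.192, abs=2e-3)
        assert sol.ffr == pytest.approx(0.9741, abs=1e-4)

    def test_worked_tube_with_lesion(self, uniform_tube):
        sol = compute_ffr(
            uniform_tube(d=3.0, length=100.0), [FIFTY_PCT_LESION], _flow(0.83), 93.9
        )
        assert sol.dp_expansion == pytest.approx(2.971, abs=2e-3)
        assert sol.ffr == pytest.approx(0.9389, abs=1e-4)
        assert sol.dp_total == pytest.approx(sol.dp_viscous + sol.dp_expansion, rel=1e-9)
        assert sol.pd == pytest.approx(sol.pa_hyp - sol.dp_total, rel=1e-12)
        assert len(sol.per_lesion) == 1

    def test_supra_physiologic_loss_reports_undefined(self, uniform_tube):
        extreme = StenosisSegment(s_start=40, s_end=60, s_mld=50, mld=0.35, d_ref=3.5)
        sol = compute_ffr(
            uniform_tube(d=3.5, length=100.0), [extreme], _flow(3.0), 93.9
        )
        assert np.isnan(sol.ffr)
        assert any("supra-physiologic" in w for w in sol.warnings)

    def test_poiseuille_equivalence_grid(self, uniform_tube):
        # lesion-free uniform tubes must match the closed form to 1e-6 relative
        for d in (2.0, 3.0, 4.0, 5.0):
            for length in (20.0, 80.0, 150.0):
                prof = uniform_tube(d=d, length=length, step=0.1)
                k1 = poiseuille_k1_mmhg(d, length)
                for q in (0.2, 1.0, 4.0):
                    sol = compute_ffr(
                        prof, [], _flow(q), 90.0,
                        hyperemia=HyperemiaModel(pa_slope=1.0, flow_factor=1.0),
                    )
                    assert sol.dp_total == pytest.approx(k1 * q, rel=1e-6)

    def test_ffr_strictly_decreasing_in_severity(self, uniform_tube):
        prof = uniform_tube(d=3.0, length=100.0)
        ffrs = []
        for ds in np.arange(10.0, 86.0, 5.0):
            seg = StenosisSegment(
                s_start=40, s_end=60, s_mld=50, mld=3.0 * (1 - ds / 100), d_ref=3.0
            )
            ffrs.append(compute_ffr(prof, [seg], _flow(0.25), 93.9).ffr)
        assert np.all(np.isfinite(ffrs))
        assert np.all(np.diff(ffrs) < 0)

    def test_ffr_strictly_decreasing_in_flow(self, uniform_tube):
        prof = uniform_tube(d=3.0, length=100.0)
        hyp = HyperemiaModel(flow_factor=1.0)
        ffrs = [
            compute_ffr(prof, [FIFTY_PCT_LESION], _flow(q), 93.9, hyperemia=hyp).ffr
            for q in np.arange(0.5, 4.01, 0.25)
        ]
        assert np.all(np.diff(ffrs) < 0)

    def test_ffr_bounds(self, uniform_tube):
        sol = compute_ffr(uniform_tube(), [FIFTY_PCT_LESION], _flow(1.0), 93.9)
        assert 0 < sol.ffr < 1

    def test_tandem_expansion_additivity(self, uniform_tube):
        prof = uniform_tube(d=3.0, length=100.0)
        a = StenosisSegment(s_start=20, s_end=35, s_mld=27, mld=1.8, d_ref=3.0)
        b = StenosisSegment(s_start=60, s_end=75, s_mld=68, mld=2.1, d_ref=3.0)
        both = compute_ffr(prof, [a, b], _flow(0.9), 93.9)
        only_a = compute_ffr(prof, [a], _flow(0.9), 93.9)
        only_b = compute_ffr(prof, [b], _flow(0.9), 93.9)
        assert both.dp_expansion == pytest.approx(
            only_a.dp_expansion + only_b.dp_expansion, rel=1e-9
        )

    def test_viscous_additive_over_partition(self, gaussian_lesion_profile):
        prof = gaussian_lesion_profile([(40.0, 50.0, 10.0)], length=80.0)
        fluid = FluidProperties()
        whole = viscous_coefficient_k1(prof, fluid, resample_step=None)
        parts = 0.0
        for a, b in ((0.0, 23.0), (23.0, 41.5), (41.5, 80.0)):
            parts += viscous_coefficient_k1(prof.subprofile(a, b), fluid, resample_step=None)
        assert parts == pytest.approx(whole, rel=1e-9)


@pytest.fixture(scope="module")
def cohort22():
    cfg = CohortConfig(n_cases=100, seed=11, wire_noise_sd=0.03)
    hyp = HyperemiaModel(flow_factor=2.2)
    return [c.to_case_data() for c in generate_cohort(cfg, hyperemia=hyp)]


class TestCalibration:
    def test_self_consistent_cohort_recovers_exactly(self):
        cfg = CohortConfig(n_cases=30, seed=2, wire_noise_sd=0.0)
        cases = [c.to_case_data() for c in generate_cohort(cfg)]
        res = calibrate_kfold(cases, tunable=("flow_factor",), k=5, seed=0)
        assert res.params["flow_factor"] == pytest.approx(2.0)
        assert res.cv_rmse < 1e-9

    def test_noisy_recovery_within_tolerance(self, cohort22):
        res = calibrate_kfold(cohort22, tunable=("flow_factor",), k=5, seed=1)
        assert abs(res.params["flow_factor"] - 2.2) <= 0.15
        assert len(res.fold_bias) == 5

    def test_permuted_wire_labels_break_calibration(self, cohort22):
        rng = np.random.default_rng(3)
        wires = np.array([c.wire_ffr for c in cohort22])
        permuted = rng.permutation(wires)
        shuffled = [
            type(c)(
                profile=c.profile, lesions=c.lesions, flow=c.flow,
                map_rest=c.map_rest, wire_ffr=w, case_id=c.case_id,
            )
            for c, w in zip(cohort22, permuted)
        ]
        res = calibrate_kfold(shuffled, tunable=("flow_factor",), k=5, seed=1)
        # the null: held-out error cannot beat the cohort's own spread
        assert res.cv_rmse >= 0.9 * np.std(permuted)

    def test_deterministic_given_seed(self, cohort22):
        r1 = calibrate_kfold(cohort22, k=5, seed=7)
        r2 = calibrate_kfold(cohort22, k=5, seed=7)
        assert r1.params == r2.params
        np.testing.assert_array_equal(r1.fold_rmse, r2.fold_rmse)

    def test_k_exceeding_n_rejected(self, cohort22):
        with pytest.raises(ConfigurationError):
            calibrate_kfold(cohort22[:4], k=5)
        with pytest.raises(ConfigurationError):
            calibrate_kfold(cohort22, tunable=())
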