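import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fetalpbk as fp
from fetalpbk.errors import CalibrationError, ConfigurationError
from fetalpbk.scenarios import ExposureEstimate, _steady_state_ratio


@pytest.fixture(scope="module")
def short_regimen():
    return fp.DosingRegimen(
        route="oral", dose=0.01, n_doses=6, interval=24.0, formulation_solubility=323.0
    )


class TestEstimateFetalBrain:
    def test_equal_plasma_levels_give_maternal_brain_value(self):
        assert fp.estimate_fetal_brain(2.0, 0.5, 2.0) == pytest.approx(0.5)

    def test_composition_of_data_driven_ratios(self):
        # fetal/maternal 0.2 and brain/plasma 0.06 compose to 0.012
        p = 3.7
        assert fp.estimate_fetal_brain(0.2 * p, 0.06 * p, p) == pytest.approx(0.012 * p)

    def test_zero_maternal_plasma_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            fp.estimate_fetal_brain(1.0, 1.0, 0.0)

    @given(
        st.floats(min_value=1e-9, max_value=1e3),
        st.floats(min_value=1e-9, max_value=1e3),
        st.floats(min_value=1e-9, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, fpl, mbr, mpl, c):
        a = fp.estimate_fetal_brain(fpl, mbr, mpl)
        b = fp.estimate_fetal_brain(c * fpl, c * mbr, c * mpl)
        assert b == pytest.approx(c * a, rel=1e-9)


class TestMarginOfSafety:
    def test_benchmark_over_exposure(self):
        assert fp.margin_of_safety(0.5, 0.5) == pytest.approx(1.0)
        assert fp.margin_of_safety_rounded(0.5, 5664e-6) == 88

    def test_rounding_direction_note(self):
        # 18e-6 µM is a rounded table entry: recomputing gives 27778, and the
        # consistency check runs in the benchmark/MoS direction instead
        assert fp.margin_of_safety_rounded(0.5, 18e-6) == 27778
        assert 0.5 / 28250 == pytest.approx(17.7e-6, rel=0.01)

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(ValueError):
            fp.margin_of_safety(0.5, 0.0)


class TestDoseToBenchmark:
    @pytest.mark.parametrize("mos,expected", [(100.0, 1.0), (1.0, 0.01)])
    def test_dose_proportional_extrapolation(self, mos, expected):
        assert fp.dose_to_benchmark(0.01, mos) == pytest.approx(expected)

    def test_nonlinearity_warning(self):
        with pytest.warns(UserWarning, match="Km"):
            fp.dose_to_benchmark(0.01, 1000.0, cmax_at_adi=0.01, km=1.0)

    def test_linear_regime_passes_silently(self, recwarn):
        fp.dose_to_benchmark(0.01, 100.0, cmax_at_adi=1e-4, km=1.0)
        assert not recwarn.list


class TestReadAcross:
    def test_packaged_analogue_median_rounds_to_two_tenths(self):
        entries = fp.load_read_across()
        assert len(entries) == 6
        med = fp.read_across_median(entries)
        assert med == pytest.approx(0.18)
        assert round(med, 1) == 0.2

    def test_range_collapses_to_midpoint(self):
        entries = fp.load_read_across()
        bup = next(e for e in entries if e.compound == "Buprenorphine")
        assert bup.collapsed_ratio() == pytest.approx(0.245)

    def test_single_and_degenerate_cases(self):
        e = fp.ReadAcrossEntry(compound="x", molecular_weight=500, logKow=4.0, ratio_low=0.3)
        assert fp.read_across_median([e]) == 0.3
        assert fp.read_across_median([e, e, e]) == 0.3

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fp.read_across_median([])


class TestScenarioFile:
    def test_packaged_grid_reproduces_the_seven_cases(self):
        specs = {s.case_id: s for s in fp.load_scenarios()}
        assert len(specs) == 7
        assert specs["case1"].brain_pc == 0.17 and specs["case1"].solubility == 2.7e-3
        assert specs["case2"].brain_pc == 0.17 and specs["case2"].solubility == 323.0
        assert specs["case3"].brain_ratio_target == 1.0
        assert specs["case4"].fetal_maternal_target == 1.0
        assert specs["case5"].brain_ratio_target == 1.0
        assert specs["case5"].fetal_maternal_target == 1.0
        assert specs["case6"].brain_ratio_target == 1.5
        assert specs["case6"].fetal_maternal_target == 1.2
        assert specs["case7"].gestational_age == 40
        assert all(s.dose == 0.01 and s.duration == 60.0 and s.n_individuals == 100
                   for s in specs.values())

    def test_barrier_setting_must_be_unambiguous(self):
        from pydantic import ValidationError

        with pytest.raises((ConfigurationError, ValidationError)):
            fp.ScenarioSpec(case_id="x", brain_pc=0.17, brain_ratio_target=1.0,
                            fetal_maternal_target=0.2, solubility=323.0)


class TestCalibrations:
    def test_brain_calibration_fixed_point(self, human20_phys, compound, human_met, short_regimen):
        achieved = _steady_state_ratio(
            human20_phys, compound, human_met, short_regimen, 6.0, "brain", "plasma"
        )
        cal = fp.calibrate_brain_partition(
            human20_phys, compound, human_met, short_regimen, achieved, duration_days=6.0
        )
        assert cal.value == pytest.approx(compound.partition_coefficients["brain"], rel=0.05)
        assert cal.n_simulations <= 2

    def test_brain_calibration_is_monotone_in_target(
        self, human20_phys, compound, human_met, short_regimen
    ):
        cal_lo = fp.calibrate_brain_partition(
            human20_phys, compound, human_met, short_regimen, 1.0, duration_days=6.0
        )
        cal_hi = fp.calibrate_brain_partition(
            human20_phys, compound, human_met, short_regimen, 1.5, duration_days=6.0
        )
        assert cal_lo.value < cal_hi.value
        for cal in (cal_lo, cal_hi):
            assert abs(cal.achieved_ratio / cal.target_ratio - 1) <= 0.01

    def test_placental_ratio_saturates_towards_equilibration(
        self, human20_phys, compound, human_met, short_regimen
    ):
        r_small = _steady_state_ratio(
            human20_phys, compound, human_met, short_regimen, 6.0,
            "fetal_plasma", "plasma", bpb_ps=1e-4,
        )
        r_large = _steady_state_ratio(
            human20_phys, compound, human_met, short_regimen, 6.0,
            "fetal_plasma", "plasma", bpb_ps=20.0,
        )
        assert r_small < 0.2
        assert 0.9 < r_large <= 1.001

    def test_placental_calibration_hits_read_across_target(
        self, human20_phys, compound, human_met, short_regimen
    ):
        cal = fp.calibrate_placental_permeability(
            human20_phys, compound, human_met, short_regimen, 0.2, duration_days=6.0
        )
        assert cal.parameter == "bpb_ps"
        assert abs(cal.achieved_ratio / 0.2 - 1) <= 0.01

    def test_unreachable_target_reports_calibration_error(
        self, human20_phys, compound, human_met, short_regimen
    ):
        with pytest.raises(CalibrationError):
            fp.calibrate_placental_permeability(
                human20_phys, compound, human_met, short_regimen, 1e-9, duration_days=6.0
            )


@pytest.fixture(scope="module")
def tiny_case():
    return fp.ScenarioSpec(
        case_id="tiny", label="tiny", brain_ratio_target=1.0,
        fetal_maternal_target=1.0, solubility=323.0, gestational_age=20,
        n_individuals=2, duration=8.0, seed=11,
    )


@pytest.fixture(scope="module")
def tiny_result(tiny_case, compound, human_met):
    # variability off: the ratio-algebra checks refer to the calibrated
    # median individual, not a random draw around it
    no_var = fp.VariabilityModel(cv_map={}, seed=0)
    return fp.run_case(tiny_case, None, compound, human_met, variability=no_var)


class TestRunCase:
    def test_unit_targets_collapse_the_ratio_algebra(self, tiny_result):
        # with brain/plasma = 1 and fetal/maternal = 1 the estimated fetal
        # brain, fetal plasma, and maternal plasma maxima coincide
        s = tiny_result.summary
        assert s["calc_cmax_fetal_brain_uM"] == pytest.approx(
            s["cmax_fetal_plasma_uM"], rel=0.05
        )
        assert s["cmax_fetal_plasma_uM"] == pytest.approx(
            s["cmax_maternal_plasma_uM"], rel=0.05
        )

    def test_summary_is_deterministic_for_a_seed(self, compound, human_met):
        spec = fp.ScenarioSpec(
            case_id="det", label="det", brain_pc=0.17, fetal_maternal_target=0.2,
            solubility=323.0, gestational_age=20, n_individuals=2, duration=5.0, seed=7,
        )
        a = fp.run_case(spec, None, compound, human_met)
        b = fp.run_case(spec, None, compound, human_met)
        assert a.summary == b.summary

    def test_population_and_trajectories_have_requested_shape(self, tiny_result):
        assert len(tiny_result.individuals) == 2
        tr = tiny_result.trajectories["plasma"]
        assert tr["mean"].shape == tr["time"].shape == tr["sd"].shape

    def test_conservative_range_is_reported_both_ways(self, tiny_result):
        # calculated fetal brain and simulated fetal tissue are both present,
        # and the calculated value is the conservative (larger) one
        s = tiny_result.summary
        assert s["sim_cmax_fetal_tissue_uM"] > 0
        assert s["calc_cmax_fetal_brain_uM"] > s["sim_cmax_fetal_tissue_uM"]

    def test_exposure_estimate_invariants(self):
        e = ExposureEstimate(
            cmax_maternal_plasma=1e-3, cmax_maternal_brain=2e-4,
            cmax_fetal_plasma=3e-4, cmax_fetal_tissue=5e-5,
        )
        assert e.calc_fetal_brain == pytest.approx(3e-4 * 2e-4 / 1e-3)
        assert e.mos_brain == pytest.approx(0.5 / e.calc_fetal_brain)
        assert e.mos_tissue == pytest.approx(0.5 / 5e-5)

    def test_gestational_age_mismatch_rejected(self, tiny_case, compound, human_met, human40_phys):
        with pytest.raises(ConfigurationError):
            fp.run_case(tiny_case, human40_phys, compound, human_met)


@pytest.fixture(scope="module")
def sens(human20_phys, compound, human_met):
    reg = fp.DosingRegimen(route="oral", dose=0.01, n_doses=4,
                           formulation_solubility=323.0)
    return fp.local_sensitivity(
        human20_phys, compound, human_met, reg,
        ["partition_coefficients.brain", "bpb_ps", "partition_coefficients.muscle"],
        delta=0.2, duration_days=4.0,
    )


class TestLocalSensitivity:
    def _s(self, df, param, output):
        row = df[(df.parameter == param) & (df.output == output)]
        return float(row.sensitivity.iloc[0])

    def test_brain_partition_drives_maternal_brain(self, sens):
        assert self._s(sens, "partition_coefficients.brain", "cmax_maternal_brain") > 0.5

    def test_placental_exchange_drives_fetal_plasma(self, sens):
        assert self._s(sens, "bpb_ps", "cmax_fetal_plasma") > 0.1

    def test_decoupled_parameter_has_negligible_sensitivity(self, sens):
        assert abs(self._s(sens, "partition_coefficients.muscle", "cmax_fetal_plasma")) < 0.1

    def test_invalid_delta(self, human20_phys, compound, human_met):
        reg = fp.DosingRegimen(route="oral", dose=0.01)
        with pytest.raises(ValueError):
            fp.local_sensitivity(human20_phys, compound, human_met, reg, ["bpb_ps"], delta=0.9)
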