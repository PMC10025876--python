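import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fetalpbk as fp
from fetalpbk.errors import ConfigurationError
from fetalpbk.pbk_core import SimulationResult


class TestWeibullDissolution:
    def test_nothing_dissolved_at_time_zero(self):
        assert fp.weibull_dissolved_fraction(0.0, 1000.0, 0.01) == 0.0

    def test_half_dissolved_at_characteristic_time(self):
        assert fp.weibull_dissolved_fraction(1000.0, 1000.0, 0.01) == pytest.approx(0.5)

    def test_shallow_shape_dissolves_half_almost_immediately(self):
        # the fitted shallow profile implies rapid partial dissolution
        assert fp.weibull_dissolved_fraction(1.0, 1000.0, 0.01) == pytest.approx(0.476, abs=1e-3)

    @given(st.floats(min_value=0.0, max_value=1e5), st.floats(min_value=1.0, max_value=1e4))
    def test_non_decreasing_in_time(self, t, t50):
        f1 = fp.weibull_dissolved_fraction(t, t50, 0.5)
        f2 = fp.weibull_dissolved_fraction(t * 1.5 + 1.0, t50, 0.5)
        assert 0.0 <= f1 <= f2 <= 1.0

    @pytest.mark.parametrize("t,t50,shape", [(-1.0, 100.0, 1.0), (1.0, 0.0, 1.0), (1.0, 100.0, 0.0)])
    def test_invalid_arguments(self, t, t50, shape):
        with pytest.raises(ValueError):
            fp.weibull_dissolved_fraction(t, t50, shape)


class TestBuildModel:
    def test_rat_model_carries_plasma_esterase_and_cyp(self, rat_phys, compound, rat_met):
        assert len(rat_met) == 4  # 3 CES1 locations + CYP1A2
        model = fp.build_model(rat_phys, compound, rat_met, fp.DosingRegimen(route="oral", dose=1.0))
        met_state_indices = {t[0] for t in model.met_terms}
        assert model.i_ven in met_state_indices  # plasma CES1 acts on blood

    def test_human_model_has_no_plasma_metabolism(self, human20_phys, compound, human_met):
        assert all(m.location != "plasma" and m.enzyme == "CES1" for m in human_met)
        model = fp.build_model(
            human20_phys, compound, human_met, fp.DosingRegimen(route="oral", dose=0.01)
        )
        liver_tis = model.tis_idx[model.organs.index("liver")]
        assert {t[0] for t in model.met_terms} == {liver_tis}

    def test_rat_metabolism_rejected_in_human_model(self, human20_phys, compound, rat_met):
        with pytest.raises(ConfigurationError):
            fp.build_model(human20_phys, compound, rat_met, fp.DosingRegimen(route="oral", dose=0.01))

    def test_missing_permeability_is_named_configuration_error(self, rat_phys, compound, rat_met):
        bad = compound.model_copy(
            update={"permeabilities": {k: v for k, v in compound.permeabilities.items() if k != "fat"}}
        )
        with pytest.raises(ConfigurationError, match="permeabilities.fat"):
            fp.build_model(rat_phys, bad, rat_met, fp.DosingRegimen(route="oral", dose=1.0))

    def test_zero_dose_zero_state_has_zero_derivatives(self, rat_phys, compound, rat_met):
        model = fp.build_model(rat_phys, compound, rat_met, fp.DosingRegimen(route="oral", dose=0.0))
        dy = model.rhs(5.0, np.zeros(model.n_states))
        assert np.all(dy == 0.0)


class TestSimulate:
    def test_iv_bolus_without_exchange_stays_in_blood(self, rat_phys, compound, rat_met):
        # with vanishing permeabilities and no metabolism the dose just mixes
        # through the circulating blood volume and stays constant
        sealed = compound.model_copy(
            update={"permeabilities": {k: 1e-12 for k in compound.permeabilities}}
        )
        model = fp.build_model(rat_phys, sealed, [], fp.DosingRegimen(route="iv", dose=0.5))
        res = fp.simulate(model, 1.0, points_per_interval=50)
        v_circ = model.V_art + model.V_ven + model.Vvas.sum()
        expected = model.dose_amount_umol() / v_circ
        late = res.concentrations["plasma"][res.time > 200]
        assert late == pytest.approx(expected, rel=1e-6)
        assert res.max_mass_balance_residual < 1e-9

    def test_mass_balance_oral_and_iv(self, rat_oral_sim, rat_iv_sim):
        assert rat_oral_sim.max_mass_balance_residual < 1e-6
        assert rat_iv_sim.max_mass_balance_residual < 1e-6

    def test_oral_absorption_respects_the_cap(self, rat_oral_sim):
        # at the end, absorbed fraction = 1 - unabsorbed/dosed must not exceed 75%
        absorbed = 1.0 - rat_oral_sim.amounts["unabsorbed"][-1] / rat_oral_sim.amounts["dosed"][-1]
        assert absorbed <= 0.75 + 1e-9

    def test_all_reported_concentrations_nonnegative(self, rat_oral_sim, human_ss_sim):
        for res in (rat_oral_sim, human_ss_sim):
            for series in res.concentrations.values():
                assert np.all(series >= 0.0)

    def test_accumulating_compartment_grows_between_first_and_last_interval(self, human_ss_sim):
        first = human_ss_sim.time < human_ss_sim.interval_min
        fat = human_ss_sim.concentrations["fat"]
        assert fp.extract_cmax(human_ss_sim, "fat", "last_interval") >= fat[first].max()

    def test_invalid_duration(self, rat_phys, compound, rat_met):
        model = fp.build_model(rat_phys, compound, rat_met, fp.DosingRegimen(route="oral", dose=1.0))
        with pytest.raises(ValueError):
            fp.simulate(model, 0.0)

    @settings(max_examples=10)
    @given(
        pc_fat=st.floats(min_value=1.0, max_value=1000.0),
        pc_brain=st.floats(min_value=0.01, max_value=10.0),
        perm_fat=st.floats(min_value=1e-4, max_value=1.0),
        dose=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_admissible_parameters_keep_ledger_sane(
        self, rat_phys, compound, rat_met, pc_fat, pc_brain, perm_fat, dose
    ):
        pcs = dict(compound.partition_coefficients, fat=pc_fat, brain=pc_brain)
        perms = dict(compound.permeabilities, fat=perm_fat)
        comp = compound.model_copy(
            update={"partition_coefficients": pcs, "permeabilities": perms}
        )
        model = fp.build_model(rat_phys, comp, rat_met, fp.DosingRegimen(route="oral", dose=dose))
        res = fp.simulate(model, 1.0, rtol=1e-6, atol=1e-10, points_per_interval=40)
        assert res.max_mass_balance_residual < 1e-6
        assert np.all(res.amounts["in_system"] >= 0.0)
        assert np.all(np.diff(res.amounts["metabolized"]) >= -1e-12)


class TestExtractCmax:
    def _result(self, series):
        t = np.arange(len(series), dtype=float)
        return SimulationResult(
            time=t,
            concentrations={"plasma": np.asarray(series, dtype=float)},
            amounts={k: np.zeros_like(t) for k in ("dosed", "in_system", "metabolized", "unabsorbed")},
            interval_min=1.0,
            last_dose_time=2.0,
        )

    def test_monotone_series_peaks_at_the_end(self):
        res = self._result([0.0, 1.0, 2.0, 3.0])
        assert fp.extract_cmax(res, "plasma", "whole") == 3.0

    def test_single_dose_peak_is_the_global_maximum(self, rat_oral_sim):
        assert fp.extract_cmax(rat_oral_sim, "plasma", "whole") == rat_oral_sim.cmax["plasma"]

    def test_window_restricts_to_last_interval(self):
        res = self._result([5.0, 1.0, 2.0, 3.0])
        assert fp.extract_cmax(res, "plasma", "last_interval") == 3.0

    def test_unknown_compartment(self, rat_oral_sim):
        with pytest.raises(ValueError):
            fp.extract_cmax(rat_oral_sim, "spleen")


def test_human_clint_scaling(human20_phys, human_met):
    scaled = fp.scale_human_clint(human_met, human20_phys, target_ml_per_min_per_g=646.0)
    v_liver_ml = human20_phys.organ("liver").volume * 0.95 * 1000.0
    clint = sum(m.vmax * m.correction_factor / m.km for m in scaled) * v_liver_ml
    assert clint / human20_phys.liver_mass == pytest.approx(646.0, rel=1e-9)
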