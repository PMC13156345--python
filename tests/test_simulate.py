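import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from crosspk import (
    CascadeParameters,
    Cyp2A6Activity,
    apply_loq,
    bateman_chain,
    nicotine_parameters,
    nicotine_study_design,
    letrozole_study_design,
    simulate_crossover_study,
    simulate_profile,
)
from crosspk.simulate import (
    DEFAULT_LOQ_NM,
    UNINHIBITED,
    _chain_matrix,
    _simulate_amounts_ode,
)
from crosspk.nca import nca_dataset

from conftest import make_profile, noise_free_design


def ode_chain_oracle(rates, amount0, times):
    """Independent adaptive-step ODE integration of the full-transfer chain."""
    m = _chain_matrix(np.asarray(rates, dtype=float))
    y0 = np.zeros(len(rates))
    y0[0] = amount0
    sol = solve_ivp(
        lambda t, y: m @ y, (0.0, float(max(times))), y0,
        t_eval=np.asarray(times, dtype=float), method="Radau",
        rtol=1e-10, atol=1e-12 * amount0,
    )
    assert sol.success
    return sol.y


class TestBatemanChain:
    def test_initial_condition(self):
        amounts = bateman_chain([6.0, 0.2, 0.04], 100.0, [0.0])
        assert amounts[0, 0] == pytest.approx(100.0)
        assert amounts[1:, 0] == pytest.approx([0.0, 0.0])

    def test_one_half_life_single_compartment(self):
        amounts = bateman_chain([math.log(2.0)], 100.0, [1.0])
        assert amounts[0, 0] == pytest.approx(50.0, rel=1e-12)

    def test_three_compartment_chain_matches_ode_oracle(self):
        rates = (6.0, 0.204, 0.0433)
        times = (0.5, 4.0, 12.0)
        got = bateman_chain(rates, 12328.0, times)
        want = ode_chain_oracle(rates, 12328.0, times)
        scale = np.maximum(np.abs(want), 1e-9 * 12328.0)
        assert np.max(np.abs(got - want) / scale) < 1e-6

    def test_random_chains_match_ode_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 5)
            rates = 10 ** rng.uniform(-1.5, 1.0, size=n)
            times = np.sort(rng.uniform(0.1, 24.0, size=5))
            got = bateman_chain(rates, 1000.0, times)
            want = ode_chain_oracle(rates, 1000.0, times)
            scale = np.maximum(np.abs(want), 1e-6 * 1000.0)
            assert np.max(np.abs(got - want) / scale) < 1e-6

    def test_repeated_root_limit_is_finite_and_correct(self):
        rates = (0.2, 0.2, 0.5)  # exactly equal: limit branch
        got = bateman_chain(rates, 100.0, [1.0, 5.0, 20.0])
        want = ode_chain_oracle((0.2, 0.2 + 1e-13, 0.5), 100.0, [1.0, 5.0, 20.0])
        assert np.all(np.isfinite(got))
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_near_equal_rates_never_nan(self):
        got = bateman_chain((0.3, 0.3 * (1 + 1e-12), 0.1), 50.0, [2.0])
        assert np.all(np.isfinite(got))

    @pytest.mark.parametrize("rates", [(0.0, 1.0), (-0.1,), ()])
    def test_invalid_rates_rejected(self, rates):
        with pytest.raises(ValueError):
            bateman_chain(rates, 1.0, [1.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        rates=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=4),
        t=st.floats(0.0, 48.0),
    )
    def test_amounts_nonnegative_and_mass_bounded(self, rates, t):
        amounts = bateman_chain(rates, 100.0, [t])
        assert np.all(amounts >= 0.0)
        assert amounts.sum() <= 100.0 * (1 + 1e-9)


class TestSimulateProfile:
    def test_uninhibited_equals_bateman_chain(self, nicotine_params, study_times):
        conc = simulate_profile(nicotine_params, UNINHIBITED, study_times)
        p = nicotine_params
        full = bateman_chain(
            [p.ka, p.k_parent, p.k_m1, p.k_m2], p.dose_nmol, study_times
        )
        parent = full[1] / p.v_f
        m1 = p.f_m1 * full[2] / (p.v_f * p.vol_ratio_m1)
        assert conc["nicotine"] == pytest.approx(parent, rel=1e-12)
        assert conc["cotinine"] == pytest.approx(m1, rel=1e-12)

    def test_blocked_pathway_gives_zero_metabolites(self, nicotine_params, study_times):
        conc = simulate_profile(
            nicotine_params, Cyp2A6Activity(phi0=0.0), study_times
        )
        assert np.all(conc["cotinine"] == 0.0)
        assert np.all(conc["3-hydroxycotinine"] == 0.0)
        assert conc["nicotine"].max() > 0

    def test_mass_balance_constant_activity(self, nicotine_params, study_times):
        _, amounts = simulate_profile(
            nicotine_params, Cyp2A6Activity(phi0=0.6), study_times, return_amounts=True
        )
        total = amounts.sum(axis=0)
        assert total == pytest.approx(nicotine_params.dose_nmol, rel=1e-6)

    def test_mass_balance_time_varying_activity(self, nicotine_params):
        times = np.array([1.0, 6.0, 12.0])
        _, amounts = simulate_profile(
            nicotine_params,
            Cyp2A6Activity(phi0=0.5, mode="progressive", k_change=0.3),
            times,
            return_amounts=True,
        )
        total = amounts.sum(axis=0)
        assert total == pytest.approx(nicotine_params.dose_nmol, rel=1e-6)

    def test_ode_path_matches_closed_form_for_constant_activity(
        self, nicotine_params, study_times
    ):
        conc_cf = simulate_profile(nicotine_params, Cyp2A6Activity(phi0=0.7), study_times)
        amounts = _simulate_amounts_ode(
            nicotine_params, Cyp2A6Activity(phi0=0.7), study_times
        )
        p = nicotine_params
        assert amounts[1] / p.v_f == pytest.approx(conc_cf["nicotine"], rel=1e-7)
        assert amounts[3] / (p.v_f * p.vol_ratio_m2) == pytest.approx(
            conc_cf["3-hydroxycotinine"], rel=1e-6, abs=1e-9
        )

    def test_recovering_mode_with_no_inhibition_equals_baseline(
        self, nicotine_params, study_times
    ):
        conc = simulate_profile(
            nicotine_params,
            Cyp2A6Activity(phi0=1.0, mode="recovering", k_change=1.0),
            study_times,
        )
        base = simulate_profile(nicotine_params, UNINHIBITED, study_times)
        for analyte in conc:
            assert conc[analyte] == pytest.approx(base[analyte], rel=1e-12)


class TestActivity:
    def test_constant(self):
        act = Cyp2A6Activity(phi0=0.4)
        assert np.all(act([0.0, 5.0, 12.0]) == 0.4)

    def test_recovering_rises_toward_one(self):
        act = Cyp2A6Activity(phi0=0.3, mode="recovering", k_change=0.5)
        vals = act([0.0, 2.0, 50.0])
        assert vals[0] == pytest.approx(0.3)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-6)

    def test_progressive_falls_toward_phi0(self):
        act = Cyp2A6Activity(phi0=0.3, mode="progressive", k_change=0.5)
        vals = act([0.0, 2.0, 50.0])
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] == pytest.approx(0.3, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            Cyp2A6Activity(phi0=1.5)
        with pytest.raises(ValueError):
            Cyp2A6Activity(phi0=0.5, mode="recovering", k_change=0.0)


class TestApplyLoq:
    def test_below_loq_censored(self):
        values, censored = apply_loq([0.5], 7.4)
        assert censored[0] and math.isnan(values[0])

    def test_boundary_value_retained(self):
        values, censored = apply_loq([7.4], 7.4)
        assert not censored[0] and values[0] == 7.4

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            apply_loq([-1.0], 7.4)

    def test_default_nicotine_loq_from_assay_limit(self):
        # 1.2 ng/mL lower calibration limit at 162.23 g/mol
        assert DEFAULT_LOQ_NM["nicotine"] == pytest.approx(7.397, abs=0.005)


class TestCrossoverStudy:
    def test_no_noise_no_effect_gives_unit_auc_ratio(self, nicotine_params):
        design = noise_free_design(nicotine_study_design, n_subjects=4, seed=3)
        ds = simulate_crossover_study(design, nicotine_params)
        table = nca_dataset(ds.records, {"nicotine": nicotine_params.dose_nmol})
        nic = table[table.analyte == "nicotine"]
        wide = nic.pivot_table(index="subject_id", columns="period", values="auc_inf_nMh")
        assert wide["exposure"].to_numpy() == pytest.approx(
            wide["baseline"].to_numpy(), rel=1e-12
        )

    def test_constant_inhibition_reduces_clearance_in_every_subject(
        self, nicotine_params
    ):
        design = noise_free_design(
            nicotine_study_design,
            n_subjects=6,
            seed=5,
            activity_exposure=Cyp2A6Activity(phi0=0.5),
        )
        ds = simulate_crossover_study(design, nicotine_params)
        table = nca_dataset(ds.records, {"nicotine": nicotine_params.dose_nmol})
        nic = table[table.analyte == "nicotine"]
        wide = nic.pivot_table(index="subject_id", columns="period", values="cl_f_Lh")
        assert np.all(wide["exposure"].to_numpy() < wide["baseline"].to_numpy())

    def test_intra_subject_cv_propagates_to_auc_log_ratios(self, nicotine_params):
        design = replace(
            nicotine_study_design(n_subjects=200, seed=11, prop_error_cv=0.0),
            loq_nM=0.0,
        )
        ds = simulate_crossover_study(design, nicotine_params)
        table = nca_dataset(ds.records, {"nicotine": nicotine_params.dose_nmol})
        nic = table[table.analyte == "nicotine"]
        wide = nic.pivot_table(index="subject_id", columns="period", values="auc_inf_nMh")
        log_ratios = np.log(wide["exposure"] / wide["baseline"]).to_numpy()
        # two independent log-normal period deviates at CV 0.26:
        # SD of the difference = sqrt(2 * ln(1 + 0.26^2))
        expected = math.sqrt(2.0 * math.log(1.0 + 0.26**2))
        assert log_ratios.std(ddof=1) == pytest.approx(expected, rel=0.15)

    def test_seed_reproducibility_is_exact(self, nicotine_params):
        design = nicotine_study_design(n_subjects=5, seed=99)
        a = simulate_crossover_study(design, nicotine_params)
        b = simulate_crossover_study(design, nicotine_params)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_records_realised_parameters(self, nicotine_params):
        design = nicotine_study_design(n_subjects=3, seed=1)
        ds = simulate_crossover_study(design, nicotine_params)
        assert len(ds.truth) == 6  # subject x period
        assert set(ds.truth.columns) >= {"subject_id", "period", "cl_f", "v_f", "phi0"}
        assert np.all(ds.truth.cl_f > 0)

    def test_single_subject_design_rejected(self):
        with pytest.raises(ValueError):
            nicotine_study_design(n_subjects=1)

    def test_letrozole_study_has_single_analyte_extended_grid(self, letrozole_params):
        design = letrozole_study_design(n_subjects=2, seed=0)
        ds = simulate_crossover_study(design, letrozole_params)
        assert ds.analytes == ["letrozole"]
        assert ds.records.time_h.max() == 240.0
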