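import numpy as np
import pytest

from fluvopbpk import engine, ivive, pkmetrics
from fluvopbpk.population import PopulationSpec, build_population

from conftest import toy_population


def one_compartment_oral(t, dose, f, v, ka, k):
    """Bateman closed form for a single oral dose (amount/volume units)."""
    t = np.asarray(t, dtype=float)
    return 1000.0 * f * dose * ka / (v * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))


def make_one_compartment(cl_plasma_l_h, weight=75.0, bp=1.0):
    """Toy subject in which the engine collapses to one compartment:
    negligible inter-compartmental clearance, full availability."""
    from fluvopbpk.compound import default_fluvoxamine

    compound = default_fluvoxamine().replace(bp_ratio=bp)
    compound = compound.replace(
        distribution=compound.distribution.__class__(
            vss_l_kg=21.0, q_inter_l_h=1e-9, vsac_l_kg=6.0
        )
    )
    pop, cs = toy_population([weight], cl_blood=cl_plasma_l_h / bp, fh=1.0)
    return pop, cs, compound


class TestLinearEngineOracles:
    def test_zero_dose_gives_zero_profile(self, model):
        pop, cs, compound = make_one_compartment(50.0)
        prof = engine.simulate_population(
            pop, compound, cs, engine.DoseRegimen(0.0, 24.0, 3)
        )
        assert np.all(prof.conc == 0.0)

    def test_profile_matches_bateman_closed_form(self):
        cl = 60.0
        pop, cs, compound = make_one_compartment(cl)
        v = 15.0 * 75.0
        ka = compound.absorption.ka_per_h
        k = cl / v
        reg = engine.DoseRegimen(100.0, 24.0, 1, duration_h=96.0)
        prof = engine.simulate_population(pop, compound, cs, reg)
        expected = one_compartment_oral(prof.times, 100.0, 1.0, v, ka, k)
        np.testing.assert_allclose(prof.conc[0], expected, rtol=1e-7, atol=1e-9)

    def test_single_dose_auc_inf_matches_dose_over_clearance(self):
        """AUC(0-inf) = Dose/CL within 0.5% (one-compartment limit)."""
        cl = 60.0
        pop, cs, compound = make_one_compartment(cl)
        reg = engine.DoseRegimen(100.0, 24.0, 1, duration_h=360.0)
        prof = engine.simulate_population(pop, compound, cs, reg)
        auc = pkmetrics.auc_to_infinity(prof)
        assert auc == pytest.approx(1000.0 * 100.0 / cl, rel=0.005)

    def test_accumulation_index_one_compartment(self):
        """Interval-AUC accumulation matches 1/(1 - exp(-k tau)) within 1%."""
        cl = 60.0
        pop, cs, compound = make_one_compartment(cl)
        # make absorption effectively instantaneous so the bolus closed
        # form applies
        compound = compound.replace(
            absorption=compound.absorption.__class__(ka_per_h=100.0)
        )
        v = 15.0 * 75.0
        k = cl / v
        tau = 24.0
        reg = engine.DoseRegimen(100.0, tau, 20)
        prof = engine.simulate_population(pop, compound, cs, reg)
        win = engine.steady_state_window(prof, tau)
        auc_ss = pkmetrics.auc_trapezoid(win, 0.0, tau)
        first = pkmetrics.auc_trapezoid(prof, 0.0, tau)
        expected = 1.0 / (1.0 - np.exp(-k * tau))
        assert auc_ss / first == pytest.approx(expected, rel=0.01)

    def test_dose_proportionality(self, model):
        """Doubling the dose doubles Cmax, Cmin and AUC within 2%."""
        spec = PopulationSpec(n_trials=1, subjects_per_trial=5, seed=23)
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        metrics = {}
        for dose in (100.0, 200.0):
            reg = engine.DoseRegimen(dose, 24.0, 14)
            prof = engine.simulate_population(
                pop, model.compound, cs, reg, model.settings
            )
            win = engine.steady_state_window(prof, 24.0)
            metrics[dose] = (
                win.conc.max(axis=1),
                win.conc[:, -1],
                pkmetrics.auc_trapezoid(win, 0.0, 24.0),
            )
        for a, b in zip(metrics[200.0], metrics[100.0]):
            np.testing.assert_allclose(a, 2.0 * b, rtol=0.02)

    def test_mass_balance_non_negative_elimination(self, model):
        spec = PopulationSpec(n_trials=1, subjects_per_trial=5, seed=29)
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        reg = engine.DoseRegimen(100.0, 24.0, 5)
        prof = engine.simulate_population(pop, model.compound, cs, reg, model.settings)
        in_system = prof.amounts.sum(axis=2)
        eliminated = prof.dosed_in - in_system
        assert np.all(eliminated >= -1e-9)
        assert np.all(np.diff(eliminated, axis=1) >= -1e-8)

    def test_profiles_non_negative_and_zero_at_start(self, model):
        spec = PopulationSpec(n_trials=1, subjects_per_trial=5, seed=31)
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        prof = engine.simulate_population(
            pop, model.compound, cs, engine.DoseRegimen(50.0, 24.0, 3), model.settings
        )
        assert np.all(prof.conc >= 0.0)
        assert np.all(prof.conc[:, 0] == 0.0)

    def test_seed_determinism_end_to_end(self, model):
        spec = PopulationSpec(n_trials=2, subjects_per_trial=5, seed=37)
        out = []
        for _ in range(2):
            pop = build_population(spec, model.config, model.aging)
            cs = ivive.clearances(pop, model.compound)
            prof = engine.simulate_population(
                pop, model.compound, cs, engine.DoseRegimen(50.0, 24.0, 3),
                model.settings,
            )
            out.append(prof.conc)
        np.testing.assert_array_equal(out[0], out[1])

    def test_single_subject_wrapper_matches_population_row(self, model):
        spec = PopulationSpec(n_trials=1, subjects_per_trial=4, seed=41)
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        reg = engine.DoseRegimen(50.0, 24.0, 2)
        prof_all = engine.simulate_population(
            pop, model.compound, cs, reg, model.settings
        )
        prof_one = engine.simulate_profile(
            pop, model.compound, cs, reg, model.settings, subject=2
        )
        np.testing.assert_allclose(prof_one.c_plasma, prof_all.conc[2])


class TestSaturableMode:
    def test_linear_and_saturable_agree_at_top_dose(self, model):
        """Michaelis-Menten vs linearized CYP2D6 diverge < 3% at 200 mg/day:
        therapeutic concentrations stay far below Km."""
        spec = PopulationSpec(
            n_trials=1, subjects_per_trial=4, age_min=65, age_max=98,
            geriatric_flag=True, phenotype_mode="uniform_EM", seed=43,
        )
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        reg = engine.daily_dose_regimen(200.0, n_days=14)
        out = {}
        for sat in (False, True):
            prof = engine.simulate_population(
                pop, model.compound, cs, reg, model.settings, saturable=sat
            )
            win = engine.steady_state_window(prof, reg.interval_h)
            out[sat] = pkmetrics.auc_trapezoid(win, 0.0, reg.interval_h)
        np.testing.assert_allclose(out[True], out[False], rtol=0.03)


class TestSteadyStateWindow:
    def test_rejects_fewer_than_two_intervals(self, model):
        pop, cs, compound = make_one_compartment(60.0)
        prof = engine.simulate_population(
            pop, compound, cs, engine.DoseRegimen(50.0, 24.0, 1)
        )
        with pytest.raises(engine.RegimenValidationError):
            engine.steady_state_window(prof, 24.0)

    def test_periodic_profile_returns_stable_window(self):
        cl = 60.0
        pop, cs, compound = make_one_compartment(cl)
        reg = engine.DoseRegimen(100.0, 24.0, 20)
        prof = engine.simulate_population(pop, compound, cs, reg)
        win = engine.steady_state_window(prof, 24.0)
        assert win.times[0] == 0.0 and win.times[-1] == 24.0
        # once periodic, consecutive interval AUCs agree
        last = pkmetrics.auc_trapezoid(win, 0.0, 24.0)
        prev = pkmetrics.auc_trapezoid(
            prof, prof.times[-1] - 48.0, prof.times[-1] - 24.0
        )
        assert last == pytest.approx(prev, rel=1e-3)

    def test_warns_when_not_converged(self):
        # two doses of a slowly cleared drug: far from steady state
        pop, cs, compound = make_one_compartment(5.0)
        prof = engine.simulate_population(
            pop, compound, cs, engine.DoseRegimen(100.0, 24.0, 2)
        )
        with pytest.warns(engine.SteadyStateWarning):
            engine.steady_state_window(prof, 24.0)

    def test_fourteen_days_reach_convergence_for_elderly(self, model):
        """14 days of daily dosing exceed 10 half-lives even for elderly
        poor metabolizers; no convergence warning is raised."""
        import warnings

        spec = PopulationSpec(
            n_trials=1, subjects_per_trial=5, age_min=65, age_max=98,
            geriatric_flag=True, phenotype_mode="uniform_PM", seed=47,
        )
        pop = build_population(spec, model.config, model.aging)
        cs = ivive.clearances(pop, model.compound)
        prof = engine.simulate_population(
            pop, model.compound, cs, engine.DoseRegimen(100.0, 24.0, 14),
            model.settings,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", engine.SteadyStateWarning)
            engine.steady_state_window(prof, 24.0)


class TestRegimenValidation:
    def test_invalid_regimens(self):
        with pytest.raises(engine.RegimenValidationError):
            engine.DoseRegimen(-1.0, 24.0, 1)
        with pytest.raises(engine.RegimenValidationError):
            engine.DoseRegimen(50.0, 0.0, 1)
        with pytest.raises(engine.RegimenValidationError):
            engine.DoseRegimen(50.0, 24.0, 1, route="iv")

    def test_bid_split_above_100mg(self):
        assert engine.daily_dose_regimen(50.0).interval_h == 24.0
        assert engine.daily_dose_regimen(100.0).interval_h == 24.0
        reg = engine.daily_dose_regimen(150.0)
        assert reg.interval_h == 12.0 and reg.dose_mg == 75.0
        reg = engine.daily_dose_regimen(200.0)
        assert reg.interval_h == 12.0 and reg.dose_mg == 100.0
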