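"""Langmuir simulation, Scatchard/kinetic Kd fitting, competition IC50s."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ppiscreen import spr

UM = 1e-6
NM = 1e-9
LADDER_UM = np.array(spr.FASTSTEP_LADDER_UM) * UM


def test_zero_concentration_gives_zero_response():
    program = spr.InjectionProgram.faststep([0.0] * 4)
    gram = spr.simulate_faststep(1e-6, 1e5, 100.0, program)
    np.testing.assert_allclose(gram.ru, 0.0, atol=1e-12)


def test_single_step_reaches_langmuir_steady_state():
    kd, kon, rmax, conc = 5e-6, 1e5, 80.0, 10e-6
    program = spr.InjectionProgram.faststep([conc], step_seconds=2000.0,
                                            dissociation_seconds=1.0)
    gram = spr.simulate_faststep(kd, kon, rmax, program)
    end = gram.ru[gram.time <= 2000.0][-1]
    assert end == pytest.approx(rmax * conc / (kd + conc), rel=1e-6)


def test_piecewise_solution_matches_independent_closed_form():
    """Recursive per-step exponential recursion, coded independently."""
    kd, kon, rmax = 2e-6, 1e5, 60.0
    koff = kon * kd
    program = spr.InjectionProgram.faststep(LADDER_UM, 25.0, 100.0)
    gram = spr.simulate_faststep(kd, kon, rmax, program)
    r0, t0 = 0.0, 0.0
    bounds = [(s, e, c) for s, e, c in program.steps]
    bounds.append((program.association_end, program.dissociation_end, 0.0))
    expected = np.empty_like(gram.time)
    for start, end, conc in bounds:
        kobs = kon * conc + koff
        req = kon * conc * rmax / kobs
        mask = (gram.time >= start) & (gram.time <= end)
        expected[mask] = req + (r0 - req) * np.exp(-kobs * (gram.time[mask] - start))
        r0 = req + (r0 - req) * np.exp(-kobs * (end - start))
    np.testing.assert_allclose(gram.ru, expected, atol=1e-6)


def test_program_validation():
    with pytest.raises(ValueError):
        spr.InjectionProgram(steps=((0, 25, 1e-6), (30, 50, 2e-6)),
                             dissociation_end=100.0)
    with pytest.raises(ValueError):
        spr.simulate_faststep(-1e-6, 1e5, 100.0,
                              spr.InjectionProgram.faststep([1e-6]))


# --- Scatchard ------------------------------------------------------------


def test_scatchard_noiseless_recovery_exact():
    for kd in (40 * NM, 80 * NM, 12 * UM, 42 * UM):
        concs = np.geomspace(kd / 10, kd * 10, 8)
        ru = spr.equilibrium_response(kd, 100.0, concs)
        fit = spr.scatchard_fit(concs, ru)
        assert fit.ok
        assert fit.kd == pytest.approx(kd, rel=1e-9)
        assert fit.rmax == pytest.approx(100.0, rel=1e-9)


def test_scatchard_invariant_under_ru_scaling():
    concs = LADDER_UM
    ru = spr.equilibrium_response(42 * UM, 50.0, concs)
    kd1 = spr.scatchard_fit(concs, ru).kd
    kd2 = spr.scatchard_fit(concs, ru * 7.5).kd
    assert kd1 == pytest.approx(kd2, rel=1e-12)


def test_scatchard_no_saturation_is_failure_not_exception():
    concs = LADDER_UM
    ru = concs * 1e6  # strictly linear in C: no saturation
    fit = spr.scatchard_fit(concs, ru)
    assert not fit.ok and fit.kd is None


def test_scatchard_and_kinetic_fit_agree_noiselessly():
    kd, kon, rmax = 42 * UM, 1e5, 50.0
    program = spr.InjectionProgram.faststep(LADDER_UM, 25.0, 300.0)
    gram = spr.simulate_faststep(kd, kon, rmax, program)
    concs, rus = spr.step_end_response(gram)
    scat = spr.scatchard_fit(concs, rus)
    kin = spr.kinetic_fit(gram)
    assert scat.ok and kin.ok
    assert kin.kd == pytest.approx(kd, rel=1e-6)
    # micromolar ladder equilibrates within each 25 s step
    assert scat.kd == pytest.approx(kd, rel=0.01)


def test_step_end_vs_true_equilibrium_bias_is_observable():
    """Nanomolar ladders do not equilibrate in 25 s: the step-end
    Scatchard is visibly biased while the kinetic fit is not."""
    kd, kon, rmax = 40 * NM, 1e6, 100.0
    ladder = np.array(spr.FASTSTEP_LADDER_UM) * NM
    program = spr.InjectionProgram.faststep(ladder, 25.0, 300.0)
    gram = spr.simulate_faststep(kd, kon, rmax, program)
    concs, rus = spr.step_end_response(gram)
    eq = spr.equilibrium_response(kd, rmax, concs)
    assert np.all(rus < eq)  # none of the steps has equilibrated
    kin = spr.kinetic_fit(gram)
    assert kin.kd == pytest.approx(kd, rel=1e-4)


def test_median_kd_recovery_under_noise():
    """|median(Kd_hat)/Kd - 1| < 0.1 at 1% Rmax noise over 100 seeds."""
    rmax = 100.0
    cases = [
        (40 * NM, "kinetic"),
        (80 * NM, "equilibrium"),
        (12 * UM, "faststep"),
        (42 * UM, "faststep"),
    ]
    for kd, mode in cases:
        estimates = []
        for seed in range(100):
            if mode == "kinetic":
                ladder = np.array(spr.FASTSTEP_LADDER_UM) * NM
                program = spr.InjectionProgram.faststep(ladder, 25.0, 300.0)
                gram = spr.simulate_faststep(kd, 1e6, rmax, program,
                                             noise_sd=0.01 * rmax, seed=seed)
                fit = spr.kinetic_fit(gram)
            elif mode == "equilibrium":
                concs = np.geomspace(10 * NM, 5 * UM, 9)
                ru = spr.simulate_equilibrium_titration(
                    kd, rmax, concs, noise_sd=0.01 * rmax, seed=seed)
                fit = spr.scatchard_fit(concs, ru)
            else:
                program = spr.InjectionProgram.faststep(LADDER_UM, 25.0, 300.0)
                gram = spr.simulate_faststep(kd, 1e5, rmax, program,
                                             noise_sd=0.01 * rmax, seed=seed)
                fit = spr.scatchard_fit(*spr.step_end_response(gram))
            if fit.ok:
                estimates.append(fit.kd)
        med = float(np.median(estimates))
        assert abs(med / kd - 1) < 0.1, (kd, mode, med)


# --- competition ----------------------------------------------------------


def test_infinite_ki_limit_equals_uninhibited_signal():
    concs = np.array([1, 10, 100]) * UM
    ru = spr.competition_response(80 * NM, 1 * UM, 1e6, concs, 100.0)
    ru0 = spr.equilibrium_response(80 * NM, 100.0, np.array([1 * UM]))[0]
    np.testing.assert_allclose(ru, ru0, rtol=1e-3)


def test_competition_monotone_nonincreasing():
    concs = np.geomspace(0.1 * UM, 300 * UM, 20)
    ru = spr.competition_response(80 * NM, 1 * UM, 1.5 * UM, concs, 100.0)
    assert np.all(np.diff(ru) <= 1e-12)


def test_cheng_prusoff_against_numerical_equilibrium():
    """IC50 = Ki (1 + [P]/Kd_P), cross-checked by root-finding the coupled
    equilibria at trace receptor concentration."""
    kd_p, p_conc, ki = 80 * NM, 1 * UM, 1.4815 * UM
    r_tot = 1 * NM  # immobilised receptor, far below [P]
    ru0 = spr.competition_response(kd_p, p_conc, ki, np.array([0.0]), 1.0)[0]

    def occupancy(i_tot):
        # coupled two-ligand/one-site equilibria with explicit depletion,
        # solved by fixed-point iteration on the free concentrations
        free_p, free_i = p_conc, i_tot
        theta_p = theta_i = 0.0
        for _ in range(200):
            denom = 1 + free_p / kd_p + free_i / ki
            theta_p, theta_i = (free_p / kd_p) / denom, (free_i / ki) / denom
            free_p = p_conc - theta_p * r_tot
            free_i = i_tot - theta_i * r_tot
        return theta_p

    ic50_numeric = brentq(
        lambda i: occupancy(i) - 0.5 * occupancy(0.0), 1e-8, 1e-2
    )
    ic50_analytic = spr.ki_to_ic50(ki, p_conc, kd_p)
    assert ic50_numeric == pytest.approx(ic50_analytic, rel=0.02)
    # and the simulated response halves at the analytic IC50
    half = spr.competition_response(kd_p, p_conc, ki,
                                    np.array([ic50_analytic]), 1.0)[0]
    assert half == pytest.approx(ru0 / 2, rel=1e-9)


def test_ic50_fit_noiseless_exact():
    ki = 20 * UM / (1 + 1 * UM / (80 * NM))
    concs = np.geomspace(1 * UM, 100 * UM, 8)
    ru = spr.competition_response(80 * NM, 1 * UM, ki, concs, 100.0)
    fit = spr.ic50_fit(concs, ru)
    assert not fit.non_competing
    assert fit.ic50 == pytest.approx(20 * UM, rel=1e-3)


def test_flat_profile_is_non_competing_verdict():
    concs = np.geomspace(1 * UM, 100 * UM, 6)
    ru = np.full_like(concs, 90.0)
    fit = spr.ic50_fit(concs, ru)
    assert fit.non_competing and fit.ic50 is None


def test_sensorgram_csv_roundtrip():
    program = spr.InjectionProgram.faststep(LADDER_UM, 25.0, 120.0)
    gram = spr.simulate_faststep(42 * UM, 1e5, 50.0, program,
                                 noise_sd=0.5, seed=4)
    back = spr.Sensorgram.from_csv(gram.to_csv())
    np.testing.assert_allclose(back.time, gram.time, atol=1e-5)
    np.testing.assert_allclose(back.ru, gram.ru, atol=1e-5)
    np.testing.assert_allclose(
        np.array(back.program.steps), np.array(program.steps), rtol=1e-7
    )
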