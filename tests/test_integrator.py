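"""Euler stepping: hand values, kernel/pure-Python equivalence, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from hlsim import (ModelParameters, SimulationDiverged, SimulationSettings,
                   StateVector, euler_step, simulate)

DT = 0.0078125
ALL_TEN = StateVector(10, 10, 10, 10, 10, 10)


def test_euler_step_hand_value(defaults):
    """One default step from the all-10 state: csc moves by dt*(prol-loss)."""
    new = euler_step(ALL_TEN, defaults, t=0.0, dt=DT)
    assert math.isclose(new.csc, 10 + DT * (0.0999999 - 0.11001),
                        rel_tol=1e-12)
    assert math.isclose(new.ctac, 10 + DT * (9.0199999 - 9.39001),
                        rel_tol=1e-12)


def test_euler_step_zero_fixed_point(defaults):
    zero = StateVector()
    assert euler_step(zero, defaults, t=0.0, dt=DT) == zero
    traj = simulate(defaults.with_overrides(
        {f"initial_{k}": 0 for k in
         ("csc", "ctac", "mtc", "helper", "killer", "regulator")}),
        SimulationSettings(final_time=100.0))
    assert np.all(traj.states == 0.0)


def test_adoptive_transfer_is_additive_killer_influx(defaults):
    """During the transfer pulse the killer stock gains dt * intensity on
    top of its ordinary net terms."""
    p = defaults.with_overrides({"immuno1_time": 300, "immuno1_intens": 1e6})
    state = ALL_TEN
    with_pulse = euler_step(state, p, t=300.5, dt=DT)
    without = euler_step(state, defaults, t=300.5, dt=DT)
    assert math.isclose(with_pulse.killer - without.killer, DT * 1e6)
    assert with_pulse.csc == without.csc  # other stocks see flows, not influx


def test_kernel_matches_pure_python_stepping(defaults):
    """The compiled simulate loop reproduces repeated euler_step exactly,
    across therapy-pulse boundaries and the adoptive-transfer influx."""
    p = defaults.with_overrides({
        "csc_thx_time": 1, "csc_thx_dur": 1, "csc_thx_intens": 0.5,
        "killer_thx_time": 2, "killer_thx_dur": 1, "killer_thx_intens": -0.4,
        "immuno1_time": 1, "immuno1_dur": 2, "immuno1_intens": 50.0,
    })
    settings = SimulationSettings(final_time=4.0, dt=DT, saveper=DT)
    traj = simulate(p, settings)
    state = StateVector(*(p.get(f"initial_{k}") for k in
                          ("csc", "ctac", "mtc", "helper", "killer",
                           "regulator")))
    for i in range(len(traj)):
        rec = traj.state_at(i)
        assert rec == state, f"divergence at step {i}"
        state = euler_step(state, p, t=i * DT, dt=DT)


def test_simulate_is_deterministic(defaults, short_settings):
    a = simulate(defaults, short_settings)
    b = simulate(defaults, short_settings)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.times, b.times)


def test_trajectory_invariants(defaults, short_settings):
    traj = simulate(defaults, short_settings)
    assert len(traj.times) == len(traj.states) == 51
    assert np.all(np.diff(traj.times) > 0)
    assert traj.state_at(0) == ALL_TEN
    assert np.all(traj.states >= 0.0)


def test_geometric_recurrence_limit(defaults):
    """Without bystander cells and pulses, the CSC stock follows the exact
    logistic-Euler recurrence; the other bystander stocks stay at zero."""
    p = defaults.with_overrides(
        {"initial_helper": 0, "initial_killer": 0, "initial_regulator": 0})
    settings = SimulationSettings(final_time=50.0, dt=DT)
    traj = simulate(p, settings)
    assert np.all(traj.states[:, 3:] == 0.0)
    # independent recurrence evaluation
    r = p.csc_growth - p.csc_death - p.csc_diff
    csc = p.initial_csc
    expected = [csc]
    steps_per_day = round(1 / DT)
    for day in range(50):
        for _ in range(steps_per_day):
            csc = csc + DT * r * csc - DT * p.csc_cap * csc * csc
        expected.append(csc)
    np.testing.assert_allclose(traj.states[:, 0], expected, rtol=1e-12)


def test_massive_growth_with_defaults(defaults, horizon2000):
    """Untreated defaults: the tumor grows by more than three orders of
    magnitude over the 2000-day horizon."""
    traj = simulate(defaults, horizon2000)
    burden = traj.states[:, :3].sum(axis=1)
    assert burden[-1] > 1000 * burden[0]


@pytest.mark.parametrize("override,comment", [
    ({"initial_csc": 0}, "no cancer stem cells"),
    ({"initial_helper": 0}, "no helper cells"),
    ({"kill_of_csc": 0.1}, "high cytotoxicity against CSC"),
])
def test_no_growth_without_key_ingredient(defaults, horizon2000, override,
                                          comment):
    """Growth requires stem cells, helper shielding, and weak CSC killing."""
    traj = simulate(defaults.with_overrides(override), horizon2000)
    burden = traj.states[:, :3].sum(axis=1)
    assert burden[-1] <= burden[0], comment


@given(st.integers(0, 10 ** 9))
@hsettings(max_examples=30, deadline=None, derandomize=True)
def test_nonnegativity_under_parameter_fuzzing(seed):
    """Stocks stay >= 0 under random perturbation of every rate constant."""
    rng = np.random.default_rng(seed)
    base = ModelParameters()
    overrides = {}
    for key in ("csc_growth", "csc_death", "csc_diff", "ctac_growth",
                "ctac_death", "ctac_diff", "mtc_death", "mtc_growth",
                "kill_of_csc", "kill_of_ctac", "kill_of_mtc",
                "help_for_csc", "help_for_ctac", "help_for_mtc",
                "regulation_of_killer", "regulation_of_helper"):
        overrides[key] = base.get(key) * rng.uniform(0.0, 5.0)
    overrides["csc_thx_intens"] = rng.uniform(0, 2)
    overrides["ctac_thx_intens"] = rng.uniform(0, 2)
    overrides["immuno1_intens"] = rng.uniform(0, 1e8)
    overrides["immuno1_time"] = rng.uniform(0, 150)
    traj = simulate(base.with_overrides(overrides),
                    SimulationSettings(final_time=200.0))
    assert np.all(traj.states >= 0.0)


def test_nonfinite_parameters_rejected():
    from hlsim import ParameterError
    with pytest.raises(ParameterError, match="initial_csc"):
        ModelParameters(initial_csc=float("inf"))
    with pytest.raises(ParameterError, match="csc_growth"):
        ModelParameters(csc_growth=float("nan"))


def test_divergence_check_reports_stock_and_time(monkeypatch, defaults):
    """A non-finite value appearing mid-run is reported with the stock
    name and the first affected save time."""
    import hlsim.integrator as integ

    def bad_kernel(p, t0, dt, save_steps):
        out = np.full((len(save_steps), 6), 1.0)
        out[3, 4] = float("nan")  # killer goes bad at the 4th save point
        return out

    monkeypatch.setattr(integ._kernel, "run_packed", bad_kernel)
    with pytest.raises(SimulationDiverged, match=r"killer.*t=3"):
        integ.simulate(defaults, SimulationSettings(final_time=10.0))


def test_euler_step_rejects_nonfinite_state(defaults):
    with pytest.raises(SimulationDiverged, match="killer"):
        euler_step(StateVector(killer=float("nan")), defaults, 0.0, DT)


def test_dt_refinement_converges_on_tumor_stocks(defaults, horizon2000):
    """Halving the step changes the tumor compartments by < 0.5% at every
    saved day.  (The killer compartment's proliferation switch-on time is
    step-sensitive and is pinned by label stability instead.)"""
    coarse = simulate(defaults, horizon2000)
    fine = simulate(defaults, SimulationSettings(final_time=2000.0, dt=2 ** -8))
    a, b = coarse.states[:, :3], fine.states[:, :3]
    rel = np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-30)
    assert rel.max() < 0.005
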