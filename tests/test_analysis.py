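"""Outcome classification and search operations."""

import numpy as np
import pytest

from hlsim import (ModelParameters, OutcomeCriteria, SimulationSettings,
                   StateVector, Trajectory, classify_outcome,
                   find_min_intensity, find_threshold_integer, scan_pulse_window,
                   simulate, tumor_burden)


def make_traj(burdens, csc=None):
    """Synthetic trajectory with the given total-burden profile (all tumor
    mass placed in the MTC column unless csc values are given)."""
    n = len(burdens)
    states = np.zeros((n, 6))
    states[:, 2] = burdens
    if csc is not None:
        states[:, 0] = csc
        states[:, 2] = np.asarray(burdens) - np.asarray(csc)
    return Trajectory(times=np.arange(n, dtype=float), states=states,
                      params_used=None,
                      settings=SimulationSettings(final_time=float(n - 1)))


def test_tumor_burden_sums_tumor_compartments():
    assert tumor_burden(StateVector(10, 10, 10, 10, 10, 10)) == 30
    assert tumor_burden(StateVector()) == 0
    assert tumor_burden(StateVector(csc=10)) == 10
    arr = np.array([[1, 2, 3, 100, 100, 100], [0, 0, 5, 1, 1, 1]])
    np.testing.assert_array_equal(tumor_burden(arr), [6, 5])


def test_classify_elimination_and_empty_error():
    rep = classify_outcome(make_traj([30.0] + [0.0] * 10))
    assert rep.label == "eliminated"
    assert classify_outcome(make_traj([0, 0, 0])).label == "eliminated"
    with pytest.raises(ValueError):
        classify_outcome(make_traj([]))


def test_classify_labels_on_synthetic_profiles():
    # grows monotonically: progression
    assert classify_outcome(make_traj([30, 60, 120, 3000])).label == "progression"
    # deep response then regrowth past 10x initial: relapse
    rep = classify_outcome(make_traj([30, 300, 1.0, 2.0, 400.0]))
    assert rep.label == "relapse"
    assert rep.regrowth_time == 4.0
    assert rep.min_burden == 1.0 and rep.t_min_burden == 2.0
    # deep response without regrowth, final below initial: suppressed
    assert classify_outcome(make_traj([30, 300, 1.0, 2.0, 5.0])).label == "suppressed"
    # shallow dip then growth is progression, not relapse
    assert classify_outcome(make_traj([30, 15, 3000])).label == "progression"


def test_classify_reports_csc_eradication():
    rep = classify_outcome(make_traj([30, 1e6, 1e6], csc=[10, 0.0, 0.0]))
    assert rep.label == "progression"
    assert rep.csc_eliminated and rep.controlled


def test_classify_stable_under_tail_and_resampling(defaults):
    """The label does not depend on duplicating the endpoint or sampling
    twice as often."""
    settings = SimulationSettings(final_time=300.0)
    traj = simulate(defaults, settings)
    fine = simulate(defaults, SimulationSettings(final_time=300.0, saveper=0.5))
    assert classify_outcome(traj).label == classify_outcome(fine).label
    extended = Trajectory(times=np.append(traj.times, traj.times[-1] + 1e-9),
                          states=np.vstack([traj.states, traj.states[-1]]),
                          params_used=traj.params_used, settings=settings)
    assert classify_outcome(extended).label == classify_outcome(traj).label


def test_scan_zero_intensity_equals_untreated(defaults):
    """A zero-dose pulse is a null treatment: every start day classifies
    exactly like the untreated run."""
    settings = SimulationSettings(final_time=400.0)
    untreated = classify_outcome(simulate(defaults, settings))
    res = scan_pulse_window(defaults, 0.0, (5, 8), settings=settings)
    assert res.labels == [untreated.label] * 4
    assert list(res.suppressed) == [untreated.suppressed] * 4
    assert res.windows == ([] if untreated.suppressed else [(5, 8)])


def test_scan_day_range_validated(defaults):
    with pytest.raises(ValueError, match="day_range"):
        scan_pulse_window(defaults, 1e6, (100, 3000),
                          settings=SimulationSettings(final_time=2000.0))


def test_escape_window_disappears_without_initial_mtc_ctac(defaults,
                                                           horizon2000):
    """Transfer pulses inside the escape window succeed when the initially
    shrinking mature/transit compartments are absent."""
    p = defaults.with_overrides({"initial_mtc": 0, "initial_ctac": 0})
    res = scan_pulse_window(p, 1e6, (210, 212), settings=horizon2000)
    assert res.windows == []
    assert res.suppressed.all()


def test_find_min_intensity_bracket_validation(defaults, horizon2000):
    with pytest.raises(ValueError, match="bracket"):
        # both ends suppress at an early start day
        find_min_intensity(defaults, 100.0, (1e10, 1e12),
                           settings=horizon2000)


def test_find_min_intensity_result_is_tight(defaults, horizon2000):
    """The reported dose suppresses while 5% less does not."""
    res = find_min_intensity(defaults, 300.0, (1e6, 1e14),
                             settings=horizon2000, rel_tol=0.01)

    def suppresses(x):
        p = defaults.with_overrides({"immuno1_time": 300.0,
                                     "immuno1_intens": x})
        return classify_outcome(simulate(p, horizon2000)).suppressed

    assert suppresses(res.intensity)
    assert not suppresses(res.intensity / 1.05)


def test_find_threshold_requires_candidates_and_known_field(defaults):
    with pytest.raises(ValueError, match="empty"):
        find_threshold_integer(defaults, "immuno2_csc_intens", [])
    with pytest.raises(Exception, match="unknown parameter"):
        find_threshold_integer(defaults, "immuno2_xyz_intens", [1])


def test_mtc_amplification_alone_never_controls(defaults, horizon4000):
    """Killing mature tumor cells without touching the stem compartment
    cannot control the tumor at any amplification."""
    res = find_threshold_integer(defaults, "immuno2_mtc_intens",
                                 [1, 10, 100], settings=horizon4000)
    assert res.threshold is None
    assert not any(res.controlled)


def test_outcome_criteria_validation():
    with pytest.raises(ValueError):
        OutcomeCriteria(elimination_threshold=0.0)
    with pytest.raises(ValueError):
        OutcomeCriteria(relapse_low=2.0)
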