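"""Simulation experiments: outcome classification and threshold searches.

The dynamics are strongly bistable: after an intervention the tumor
burden either collapses toward zero or regrows by orders of magnitude,
so outcome labels are insensitive to the exact thresholds.  One regime
is the exception: killing-amplification therapy can eradicate the
cancer stem cell compartment while a residual, helper-shielded pool of
mature tumor cells persists at the horizon.  "Control" there is the
eradication of the stem-cell compartment, which the report exposes
separately from the burden-based label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .integrator import Trajectory, simulate
from .model import StateVector
from .params import ModelParameters, SimulationSettings

__all__ = [
    "OutcomeCriteria",
    "OutcomeReport",
    "tumor_burden",
    "classify_outcome",
    "scan_pulse_window",
    "WindowScanResult",
    "find_min_intensity",
    "MinIntensityResult",
    "find_threshold_integer",
    "ThresholdScanResult",
]


@dataclass(frozen=True)
class OutcomeCriteria:
    """Thresholds turning a trajectory into an outcome label.

    elimination_threshold : cells
        Final burden below this counts as eliminated (default 0.5 — less
        than one cell).
    control_ratio : dimensionless
        Final burden <= control_ratio × initial burden counts as
        suppressed.
    relapse_low : dimensionless
        Remission means the burden fell below ``relapse_low`` × its
        running peak (a >=90% response at the default 0.1).
    relapse_high : dimensionless
        Regrowth beyond ``relapse_high`` × the initial burden after a
        remission marks a relapse.
    """

    elimination_threshold: float = 0.5
    control_ratio: float = 1.0
    relapse_low: float = 0.1
    relapse_high: float = 10.0

    def __post_init__(self) -> None:
        if not self.elimination_threshold > 0:
            raise ValueError("elimination_threshold must be > 0")
        if not (self.relapse_low < 1.0 < self.relapse_high):
            raise ValueError("need relapse_low < 1 < relapse_high")


@dataclass(frozen=True)
class OutcomeReport:
    """Classification of one trajectory.

    ``label`` is one of ``eliminated``, ``suppressed``, ``relapse``,
    ``progression``.  ``csc_eliminated`` flags eradication of the cancer
    stem cell compartment, which can hold even when a shielded mature
    tumor cell pool keeps the burden label at ``progression``;
    ``controlled`` is the tumor-control predicate used by the
    amplification-threshold experiments (burden suppressed/eliminated
    *or* CSC eradicated).
    """

    label: str
    initial_burden: float
    final_burden: float
    min_burden: float
    t_min_burden: float
    regrowth_time: float | None
    final_csc: float
    csc_eliminated: bool

    @property
    def suppressed(self) -> bool:
        return self.label in ("eliminated", "suppressed")

    @property
    def controlled(self) -> bool:
        return self.suppressed or self.csc_eliminated


def tumor_burden(state) -> float | np.ndarray:
    """Total tumor burden: CSC + CTAC + MTC.

    Accepts a :class:`StateVector` or a ``(..., 6)`` state array and
    returns a scalar or per-row array accordingly.
    """
    if isinstance(state, StateVector):
        return state.csc + state.ctac + state.mtc
    arr = np.asarray(state, dtype=float)
    return arr[..., 0] + arr[..., 1] + arr[..., 2]


def classify_outcome(traj: Trajectory,
                     criteria: OutcomeCriteria | None = None) -> OutcomeReport:
    """Label a trajectory as eliminated / suppressed / relapse / progression.

    Order of precedence: eliminated (final burden below the elimination
    threshold); relapse (the burden fell below ``relapse_low`` × its
    running peak — a deep remission — and later exceeded
    ``relapse_high`` × the initial burden); suppressed (final burden at
    most ``control_ratio`` × initial); otherwise progression.
    """
    if criteria is None:
        criteria = OutcomeCriteria()
    if len(traj) == 0:
        raise ValueError("cannot classify an empty trajectory")
    b = tumor_burden(traj.states)
    initial, final = float(b[0]), float(b[-1])
    i_min = int(np.argmin(b))
    min_burden = float(b[i_min])
    running_peak = np.maximum.accumulate(b)
    in_remission = b < criteria.relapse_low * running_peak
    regrowth_time: float | None = None
    label: str
    if final < criteria.elimination_threshold:
        label = "eliminated"
    else:
        relapse = False
        if in_remission.any():
            first_rem = int(np.argmax(in_remission))
            regrown = b[first_rem:] > criteria.relapse_high * initial
            if regrown.any():
                relapse = True
                regrowth_time = float(traj.times[first_rem + int(np.argmax(regrown))])
        if relapse:
            label = "relapse"
        elif final <= criteria.control_ratio * initial:
            label = "suppressed"
        else:
            label = "progression"
    final_csc = float(traj.states[-1, 0])
    return OutcomeReport(
        label=label,
        initial_burden=initial,
        final_burden=final,
        min_burden=min_burden,
        t_min_burden=float(traj.times[i_min]),
        regrowth_time=regrowth_time,
        final_csc=final_csc,
        csc_eliminated=final_csc < criteria.elimination_threshold,
    )


# ---------------------------------------------------------------------------
# adoptive-transfer timing scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowScanResult:
    """Per-start-day suppression map of a single-day adoptive-transfer pulse.

    ``windows`` lists the maximal contiguous runs of non-suppressed
    start days as inclusive ``(first, last)`` pairs — the immune-escape
    windows.
    """

    days: np.ndarray
    suppressed: np.ndarray          # bool, aligned with days
    final_burden: np.ndarray
    labels: list[str]
    intensity: float
    windows: list[tuple[int, int]] = field(default_factory=list)

    def suppression_map(self) -> dict[int, bool]:
        return {int(d): bool(s) for d, s in zip(self.days, self.suppressed)}


def _contiguous_false_runs(days: np.ndarray, ok: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    for d, s in zip(days, ok):
        if not s:
            start = d if start is None else start
            end = d
        elif start is not None:
            runs.append((int(start), int(end)))
            start = None
    if start is not None:
        runs.append((int(start), int(end)))
    return runs


def scan_pulse_window(base: ModelParameters, intensity: float,
                      day_range: tuple[int, int],
                      criteria: OutcomeCriteria | None = None,
                      settings: SimulationSettings | None = None) -> WindowScanResult:
    """Scan the start day of a single-day killer-cell transfer pulse.

    For each integer start day in ``day_range`` (inclusive) the model is
    run with an adoptive-transfer schedule ``(day, dur=1, intensity)``
    and the outcome recorded as suppressed (label eliminated or
    suppressed) or not.
    """
    if settings is None:
        settings = SimulationSettings(final_time=2000.0)
    first, last = int(day_range[0]), int(day_range[1])
    if not (settings.initial_time <= first <= last <= settings.final_time):
        raise ValueError(f"day_range {day_range} outside horizon "
                         f"[{settings.initial_time}, {settings.final_time}]")
    days = np.arange(first, last + 1)
    supp = np.zeros(len(days), dtype=bool)
    fburden = np.empty(len(days))
    labels: list[str] = []
    for i, day in enumerate(days):
        params = base.with_overrides({
            "immuno1_time": float(day), "immuno1_dur": 1.0,
            "immuno1_intens": intensity,
        })
        try:
            rep = classify_outcome(simulate(params, settings), criteria)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for start day {day}") from exc
        supp[i] = rep.suppressed
        fburden[i] = rep.final_burden
        labels.append(rep.label)
    return WindowScanResult(days=days, suppressed=supp, final_burden=fburden,
                            labels=labels, intensity=intensity,
                            windows=_contiguous_false_runs(days, supp))


# ---------------------------------------------------------------------------
# minimal-dose search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinIntensityResult:
    """Minimal suppressing adoptive-transfer intensity at a fixed start day.

    ``intensity`` suppresses; ``bracket_lo`` is the largest intensity
    found not to suppress (the bracketing evidence).
    """

    intensity: float
    bracket_lo: float
    start_day: float
    evaluations: list[tuple[float, bool]]


def find_min_intensity(base: ModelParameters, start_day: float,
                       search_range: tuple[float, float],
                       criteria: OutcomeCriteria | None = None,
                       settings: SimulationSettings | None = None,
                       rel_tol: float = 0.01) -> MinIntensityResult:
    """Minimal single-day transfer dose that suppresses the tumor.

    Decade scan upward from ``search_range[0]`` followed by geometric
    bisection to ~2 significant figures.  The outcome is assumed
    monotone in the dose within the bracket; the bracket endpoints are
    verified (non-suppressed at the low end, suppressed at the high
    end) and a violation raises ``ValueError`` with both
    classifications.
    """
    if settings is None:
        settings = SimulationSettings(final_time=2000.0)
    lo, hi = float(search_range[0]), float(search_range[1])
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got {search_range}")
    evals: list[tuple[float, bool]] = []

    def suppresses(intens: float) -> bool:
        params = base.with_overrides({
            "immuno1_time": float(start_day), "immuno1_dur": 1.0,
            "immuno1_intens": intens,
        })
        ok = classify_outcome(simulate(params, settings), criteria).suppressed
        evals.append((intens, ok))
        return ok

    lo_ok, hi_ok = suppresses(lo), suppresses(hi)
    if lo_ok or not hi_ok:
        raise ValueError(
            f"invalid bracket at day {start_day}: intensity {lo:g} "
            f"{'suppresses' if lo_ok else 'does not suppress'} and {hi:g} "
            f"{'suppresses' if hi_ok else 'does not suppress'}")
    # decade scan to tighten the bracket
    x = lo * 10.0
    while x < hi:
        if suppresses(x):
            hi = x
            break
        lo = x
        x *= 10.0
    # geometric bisection
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if suppresses(mid):
            hi = mid
        else:
            lo = mid
    return MinIntensityResult(intensity=hi, bracket_lo=lo,
                              start_day=float(start_day), evaluations=evals)


# ---------------------------------------------------------------------------
# integer threshold search (killing amplification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdScanResult:
    """Outcome of an ascending integer scan of one parameter."""

    field_key: str
    threshold: int | None
    candidates: list[int]
    controlled: list[bool]
    final_burden: list[float]


def find_threshold_integer(base: ModelParameters, target_field: str,
                           candidates, criteria: OutcomeCriteria | None = None,
                           settings: SimulationSettings | None = None,
                           stop_at_first: bool = True) -> ThresholdScanResult:
    """Smallest integer value of ``target_field`` achieving tumor control.

    Control means burden suppression/elimination *or* eradication of the
    cancer stem cell compartment (the signature of successful
    killing-amplification therapy, whose residual helper-shielded
    mature-cell pool keeps the total burden above its initial value).
    Returns ``threshold=None`` if no candidate controls the tumor.
    """
    if settings is None:
        settings = SimulationSettings(final_time=4000.0)
    cand = [int(c) for c in candidates]
    if not cand:
        raise ValueError("candidate range is empty")
    tried: list[int] = []
    ok: list[bool] = []
    fb: list[float] = []
    threshold: int | None = None
    for c in cand:
        params = base.with_overrides({target_field: float(c)})
        rep = classify_outcome(simulate(params, settings), criteria)
        tried.append(c)
        ok.append(rep.controlled)
        fb.append(rep.final_burden)
        if rep.controlled and threshold is None:
            threshold = c
            if stop_at_first:
                break
    return ThresholdScanResult(field_key=target_field, threshold=threshold,
                               candidates=tried, controlled=ok, final_burden=fb)
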