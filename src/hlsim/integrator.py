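"""Fixed-step Euler integration and trajectory recording.

Euler integration is part of the model's definition, not a numerical
convenience: the published dynamics (including the small residue left
by the non-negativity fallback) are specified in terms of the discrete
update rule.  All flows are evaluated from the pre-step state and the
six stocks advance simultaneously, so the result is independent of
compartment ordering.  States are recorded at every multiple of
``saveper``; with the default step of 2**-7 days every integer day is
hit exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import _kernel
from .model import STOCK_NAMES, StateVector, compute_flows, net_change
from .params import ModelParameters, SimulationSettings

__all__ = ["Trajectory", "euler_step", "simulate", "SimulationDiverged"]


class SimulationDiverged(RuntimeError):
    """A stock became non-finite during integration."""


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed record of the six stocks sampled at ``saveper``.

    ``states`` is an ``(n, 6)`` array with columns in
    :data:`hlsim.model.STOCK_NAMES` order, aligned with ``times``.
    """

    times: np.ndarray
    states: np.ndarray
    params_used: ModelParameters | None
    settings: SimulationSettings

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> StateVector:
        return StateVector.from_iterable(self.states[i])

    def stock(self, name: str) -> np.ndarray:
        return self.states[:, STOCK_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STOCK_NAMES))
        df.insert(0, "time", self.times)
        return df


def _check_finite_state(state: StateVector) -> None:
    for name in STOCK_NAMES:
        v = getattr(state, name)
        if not math.isfinite(v):
            raise SimulationDiverged(f"stock {name!r} is non-finite: {v!r}")


def euler_step(state: StateVector, params: ModelParameters, t: float,
               dt: float) -> StateVector:
    """Advance the state by one Euler step of length ``dt``.

    Flows are computed once from ``state`` at time ``t``; each stock is
    then updated as ``stock + dt * net_change(...)``.  The adoptive-
    transfer influx enters the killer-cell update as the additive term
    of its guard and rate.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be > 0, got {dt}")
    _check_finite_state(state)
    f = compute_flows(state, params, t)
    for fl in fields(f):
        if not math.isfinite(getattr(f, fl.name)):
            raise SimulationDiverged(
                f"flow {fl.name!r} is non-finite at t={t}")
    return StateVector(
        csc=state.csc + dt * net_change(state.csc, f.csc_prol, f.csc_loss),
        ctac=state.ctac + dt * net_change(state.ctac, f.ctac_incr, f.ctac_loss),
        mtc=state.mtc + dt * net_change(state.mtc, f.mtc_incr, f.mtc_loss),
        helper=state.helper + dt * net_change(state.helper, f.helper_prol,
                                              f.helper_loss),
        killer=state.killer + dt * net_change(state.killer, f.killer_prol,
                                              f.killer_loss,
                                              additive=f.immuno1_rate),
        regulator=state.regulator + dt * net_change(state.regulator,
                                                    f.regulator_prol,
                                                    f.regulator_loss),
    )


def _save_step_indices(settings: SimulationSettings) -> np.ndarray:
    """Step index recorded for each save point: nearest step from below."""
    n_save = int(math.floor((settings.final_time - settings.initial_time)
                            / settings.saveper + 1e-9)) + 1
    save_times = settings.initial_time + settings.saveper * np.arange(n_save)
    steps = np.floor((save_times - settings.initial_time) / settings.dt
                     + 1e-9).astype(np.int64)
    return steps


def simulate(params: ModelParameters,
             settings: SimulationSettings | None = None) -> Trajectory:
    """Run the model from its initial stocks to ``settings.final_time``.

    Deterministic: identical inputs give bit-identical trajectories.

    Raises
    ------
    SimulationDiverged
        If any stock becomes non-finite; the message reports the first
        affected save time and stock.
    """
    if settings is None:
        settings = SimulationSettings()
    params.validate()
    packed = _kernel.pack_params(params)
    save_steps = _save_step_indices(settings)
    states = _kernel.run_packed(packed, settings.initial_time, settings.dt,
                                save_steps)
    # nominal save times; the recorded state is the one at the step
    # closest to each save point from below (exact when saveper is a
    # multiple of dt, as with the defaults)
    times = settings.initial_time + settings.saveper * np.arange(len(save_steps))
    bad = ~np.isfinite(states)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SimulationDiverged(
            f"stock {STOCK_NAMES[j]!r} became non-finite by t={times[i]:g}")
    return Trajectory(times=times, states=states, params_used=params,
                      settings=settings)
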