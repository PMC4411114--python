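"""Core model equations: six cell stocks and their flow rates.

The model tracks six interacting cell populations of a Hodgkin's
lymphoma and its micro-environment: three tumor sub-compartments —
cancer stem cells (CSC), cancer transit amplifying cells (CTAC) and
mature tumor cells (MTC) — and three bystander compartments — helper,
killer and regulatory cells.  Tumor cells stimulate all three bystander
compartments; helper cells shield tumor cells from death and
co-stimulate killer cells; killer cells remove tumor cells at
compartment-specific kill rates; regulatory cells suppress helper and
killer proliferation.  Each stock follows a logistic-style balance of a
proliferation (or increase) flow and a loss flow, both clamped
non-negative, with rectangular therapy pulses adding to the losses.

This module evaluates every auxiliary flow at a single time point; the
production time-stepping lives in :mod:`hlsim.integrator`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParameters, PulseSchedule

__all__ = [
    "StateVector",
    "FlowRates",
    "pulse",
    "therapy_rate",
    "stimulus",
    "compute_flows",
    "net_change",
]

STOCK_NAMES = ("csc", "ctac", "mtc", "helper", "killer", "regulator")


@dataclass(frozen=True)
class StateVector:
    """The six stock values (cell counts) at one time point."""

    csc: float = 0.0
    ctac: float = 0.0
    mtc: float = 0.0
    helper: float = 0.0
    killer: float = 0.0
    regulator: float = 0.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.csc, self.ctac, self.mtc, self.helper, self.killer, self.regulator)

    @classmethod
    def from_iterable(cls, values) -> "StateVector":
        return cls(*map(float, values))


@dataclass(frozen=True)
class FlowRates:
    """Every auxiliary quantity of the model evaluated at one time point.

    ``*_prol`` / ``*_incr`` / ``*_loss`` are cells/day and are
    non-negative by construction (each is clamped or is a sum of
    non-negative terms).  ``*_stim_by_tumor`` and ``*_thx_rate`` are
    per-day rates; ``immuno1_rate`` is an additive killer influx in
    cells/day; the ``immuno2_*_factor`` fields are dimensionless killing
    amplifiers entering the loss terms as ``(1 + factor)``.
    """

    csc_prol: float
    csc_loss: float
    ctac_incr: float
    ctac_loss: float
    mtc_incr: float
    mtc_loss: float
    helper_prol: float
    helper_loss: float
    killer_prol: float
    killer_loss: float
    regulator_prol: float
    regulator_loss: float
    helper_stim_by_tumor: float
    killer_stim_by_tumor: float
    regulator_stim_by_tumor: float
    csc_thx_rate: float
    ctac_thx_rate: float
    mtc_thx_rate: float
    helper_thx_rate: float
    killer_thx_rate: float
    regulator_thx_rate: float
    immuno1_rate: float
    immuno2_csc_factor: float
    immuno2_ctac_factor: float
    immuno2_mtc_factor: float


def pulse(t: float, start: float, duration: float) -> float:
    """Rectangular pulse indicator: 1 on ``[start, start + duration)``, else 0.

    The left endpoint is inclusive and the right endpoint exclusive, so
    ``duration=1`` with daily stepping covers exactly one day and
    ``duration=0`` is never active.
    """
    return 1.0 if (start <= t < start + duration) else 0.0


def therapy_rate(t: float, schedule: PulseSchedule) -> float:
    """Per-day therapy rate at time ``t``: pulse indicator times intensity.

    Negative intensities pass through unchanged (a negative "toxicity"
    models a transient increase of the targeted compartment).
    """
    return pulse(t, schedule.start_time, schedule.duration) * schedule.intensity


def stimulus(state: StateVector, w_csc: float, w_ctac: float, w_mtc: float,
             clamp: bool = False) -> float:
    """Tumor-derived stimulation: weighted sum of the three tumor stocks.

    ``clamp=True`` applies an outer ``max(0, .)``; the model uses the
    clamped variant only for killer-cell stimulation.
    """
    s = state.csc * w_csc + w_ctac * state.ctac + state.mtc * w_mtc
    return max(0.0, s) if clamp else s


def compute_flows(state: StateVector, params: ModelParameters, t: float) -> FlowRates:
    """Evaluate every flow of the model at ``(state, t)``.

    Pure function of its arguments; time enters only through the pulse
    schedules.  The loss terms share a common shape: an inner
    ``max(0, death + killing - help)`` clamp (helper cells can cancel
    death and killing, but never turn a loss into a gain), plus
    differentiation outflow where applicable, plus the therapy term.
    Helper/killer/regulator proliferation is gated to zero when the
    stimulation product is non-positive.
    """
    p = params
    csc, ctac, mtc = state.csc, state.ctac, state.mtc
    helper, killer, regulator = state.helper, state.killer, state.regulator

    csc_thx = therapy_rate(t, p.csc_thx)
    ctac_thx = therapy_rate(t, p.ctac_thx)
    mtc_thx = therapy_rate(t, p.mtc_thx)
    helper_thx = therapy_rate(t, p.helper_thx)
    killer_thx = therapy_rate(t, p.killer_thx)
    regulator_thx = therapy_rate(t, p.regulator_thx)
    immuno1 = therapy_rate(t, p.immuno1)
    i2_csc = therapy_rate(t, p.immuno2_csc)
    i2_ctac = therapy_rate(t, p.immuno2_ctac)
    i2_mtc = therapy_rate(t, p.immuno2_mtc)

    # tumor compartments: logistic growth / differentiation chain
    csc_prol = max(0.0, p.csc_growth * csc - csc * csc * p.csc_cap)
    csc_loss = (
        max(0.0, csc * p.csc_death + (1.0 + i2_csc) * p.kill_of_csc * killer
            - helper * p.help_for_csc)
        + csc * p.csc_diff
        + csc * csc_thx
    )
    ctac_incr = max(0.0, p.csc_diff * csc + p.ctac_growth * ctac
                    - p.ctac_cap * ctac * ctac)
    ctac_loss = (
        max(0.0, killer * p.kill_of_ctac * (1.0 + i2_ctac) + p.ctac_death * ctac
            - helper * p.help_for_ctac)
        + p.ctac_diff * ctac
        + ctac_thx * ctac
    )
    mtc_incr = max(0.0, p.mtc_growth * mtc + p.ctac_diff * ctac
                   - p.mtc_cap * mtc * mtc)
    mtc_loss = (
        max(0.0, killer * p.kill_of_mtc * (1.0 + i2_mtc) + p.mtc_death * mtc
            - helper * p.help_for_mtc)
        + mtc_thx * mtc
    )

    # bystander compartments: tumor-stimulated proliferation under regulation
    helper_stim = stimulus(state, p.helper_stim_by_csc, p.helper_stim_by_ctac,
                           p.helper_stim_by_mtc)
    if helper * helper_stim > 0.0:
        helper_prol = max(0.0, helper_stim * helper - helper * helper * p.helper_cap
                          - p.regulation_of_helper * regulator)
    else:
        helper_prol = 0.0
    helper_loss = helper * p.helper_death + helper * helper_thx

    killer_stim = stimulus(state, p.killer_stim_by_csc, p.killer_stim_by_ctac,
                           p.killer_stim_by_mtc, clamp=True)
    if killer * killer_stim * p.help_for_killer * helper > 0.0:
        killer_prol = max(0.0, killer * killer_stim - p.regulation_of_killer * regulator
                          + helper * p.help_for_killer - killer * killer * p.killer_cap)
    else:
        killer_prol = 0.0
    killer_loss = killer * p.killer_death + killer_thx * killer

    regulator_stim = stimulus(state, p.regulator_stim_by_csc, p.regulator_stim_by_ctac,
                              p.regulator_stim_by_mtc)
    if regulator * regulator_stim > 0.0:
        regulator_prol = max(0.0, regulator * regulator_stim
                             - regulator * regulator * p.regulator_cap)
    else:
        regulator_prol = 0.0
    regulator_loss = regulator * p.regulator_death + regulator_thx * regulator

    return FlowRates(
        csc_prol=csc_prol, csc_loss=csc_loss,
        ctac_incr=ctac_incr, ctac_loss=ctac_loss,
        mtc_incr=mtc_incr, mtc_loss=mtc_loss,
        helper_prol=helper_prol, helper_loss=helper_loss,
        killer_prol=killer_prol, killer_loss=killer_loss,
        regulator_prol=regulator_prol, regulator_loss=regulator_loss,
        helper_stim_by_tumor=helper_stim,
        killer_stim_by_tumor=killer_stim,
        regulator_stim_by_tumor=regulator_stim,
        csc_thx_rate=csc_thx, ctac_thx_rate=ctac_thx, mtc_thx_rate=mtc_thx,
        helper_thx_rate=helper_thx, killer_thx_rate=killer_thx,
        regulator_thx_rate=regulator_thx,
        immuno1_rate=immuno1,
        immuno2_csc_factor=i2_csc, immuno2_ctac_factor=i2_ctac,
        immuno2_mtc_factor=i2_mtc,
    )


def net_change(stock: float, gain: float, loss: float, additive: float = 0.0) -> float:
    """Per-day net change of a stock under the non-negativity guard.

    With ``r = gain - loss + additive``: returns ``r`` if
    ``stock + r > 0``, else ``-stock`` (the stock is drained instead of
    going negative).  The guard compares the stock against the *per-day*
    rate, not the dt-scaled increment — this mirrors the published
    update rule literally, and with an Euler step ``stock + dt*(-stock)``
    a small positive residue remains after a fallback step.
    """
    r = gain - loss + additive
    return r if stock + r > 0.0 else -stock
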