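"""Compiled Euler integration kernel.

The public API lives in :mod:`hlsim.integrator`; this module holds the
packed parameter-vector layout and the numba-compiled stepping loop.
The kernel is a literal transcription of the flow equations in
:mod:`hlsim.model` operating on a flat float64 vector; an equivalence
test pins the two code paths together.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParameters

# --- packed parameter vector layout ---------------------------------------
# scalar rates
CSC_CAP, CSC_DEATH, CSC_DIFF, CSC_GROWTH = 0, 1, 2, 3
CTAC_CAP, CTAC_DEATH, CTAC_DIFF, CTAC_GROWTH = 4, 5, 6, 7
MTC_CAP, MTC_DEATH, MTC_GROWTH = 8, 9, 10
HELP_FOR_CSC, HELP_FOR_CTAC, HELP_FOR_MTC, HELP_FOR_KILLER = 11, 12, 13, 14
HELPER_CAP, HELPER_DEATH = 15, 16
H_STIM_CSC, H_STIM_CTAC, H_STIM_MTC = 17, 18, 19
KILLER_CAP, KILLER_DEATH = 20, 21
K_STIM_CSC, K_STIM_CTAC, K_STIM_MTC = 22, 23, 24
KILL_OF_CSC, KILL_OF_CTAC, KILL_OF_MTC = 25, 26, 27
REG_CAP, REG_DEATH = 28, 29
R_STIM_CSC, R_STIM_CTAC, R_STIM_MTC = 30, 31, 32
REG_OF_HELPER, REG_OF_KILLER = 33, 34
# pulse schedules, 3 slots each: time, duration, intensity
CSC_THX, CTAC_THX, MTC_THX = 35, 38, 41
HELPER_THX, KILLER_THX, REG_THX = 44, 47, 50
IMMUNO1, I2_CSC, I2_CTAC, I2_MTC = 53, 56, 59, 62
# initial stocks
INIT = 65
N_PARAMS = 71

_PULSE_SLOTS = (
    ("csc_thx", CSC_THX), ("ctac_thx", CTAC_THX), ("mtc_thx", MTC_THX),
    ("helper_thx", HELPER_THX), ("killer_thx", KILLER_THX),
    ("regulator_thx", REG_THX),
    ("immuno1", IMMUNO1), ("immuno2_csc", I2_CSC),
    ("immuno2_ctac", I2_CTAC), ("immuno2_mtc", I2_MTC),
)

_SCALAR_SLOTS = (
    ("csc_cap", CSC_CAP), ("csc_death", CSC_DEATH), ("csc_diff", CSC_DIFF),
    ("csc_growth", CSC_GROWTH),
    ("ctac_cap", CTAC_CAP), ("ctac_death", CTAC_DEATH),
    ("ctac_diff", CTAC_DIFF), ("ctac_growth", CTAC_GROWTH),
    ("mtc_cap", MTC_CAP), ("mtc_death", MTC_DEATH), ("mtc_growth", MTC_GROWTH),
    ("help_for_csc", HELP_FOR_CSC), ("help_for_ctac", HELP_FOR_CTAC),
    ("help_for_mtc", HELP_FOR_MTC), ("help_for_killer", HELP_FOR_KILLER),
    ("helper_cap", HELPER_CAP), ("helper_death", HELPER_DEATH),
    ("helper_stim_by_csc", H_STIM_CSC), ("helper_stim_by_ctac", H_STIM_CTAC),
    ("helper_stim_by_mtc", H_STIM_MTC),
    ("killer_cap", KILLER_CAP), ("killer_death", KILLER_DEATH),
    ("killer_stim_by_csc", K_STIM_CSC), ("killer_stim_by_ctac", K_STIM_CTAC),
    ("killer_stim_by_mtc", K_STIM_MTC),
    ("kill_of_csc", KILL_OF_CSC), ("kill_of_ctac", KILL_OF_CTAC),
    ("kill_of_mtc", KILL_OF_MTC),
    ("regulator_cap", REG_CAP), ("regulator_death", REG_DEATH),
    ("regulator_stim_by_csc", R_STIM_CSC),
    ("regulator_stim_by_ctac", R_STIM_CTAC),
    ("regulator_stim_by_mtc", R_STIM_MTC),
    ("regulation_of_helper", REG_OF_HELPER),
    ("regulation_of_killer", REG_OF_KILLER),
    ("initial_csc", INIT), ("initial_ctac", INIT + 1),
    ("initial_mtc", INIT + 2), ("initial_helper", INIT + 3),
    ("initial_killer", INIT + 4), ("initial_regulator", INIT + 5),
)


def pack_params(params: ModelParameters) -> np.ndarray:
    """Flatten a :class:`ModelParameters` into the kernel's float64 layout."""
    p = np.empty(N_PARAMS, dtype=np.float64)
    for name, slot in _SCALAR_SLOTS:
        p[slot] = getattr(params, name)
    for name, slot in _PULSE_SLOTS:
        sched = getattr(params, name)
        p[slot] = sched.start_time
        p[slot + 1] = sched.duration
        p[slot + 2] = sched.intensity
    return p


@njit(cache=True, inline="always")
def _pulse_rate(t, p, slot):
    if p[slot] <= t < p[slot] + p[slot + 1]:
        return p[slot + 2]
    return 0.0


@njit(cache=True)
def run_packed(p, t0, dt, save_steps):
    """Euler-integrate the packed model, recording at ``save_steps``.

    ``save_steps`` are step indices (state *before* taking step k is
    recorded when k appears in save_steps, so index 0 is the initial
    state).  All flows are evaluated from the pre-step state and all six
    stocks advance simultaneously.
    """
    n_save = save_steps.shape[0]
    out = np.empty((n_save, 6), dtype=np.float64)
    csc = p[INIT]
    ctac = p[INIT + 1]
    mtc = p[INIT + 2]
    helper = p[INIT + 3]
    killer = p[INIT + 4]
    regulator = p[INIT + 5]
    total_steps = save_steps[n_save - 1]
    j = 0
    for step in range(total_steps + 1):
        if j < n_save and step == save_steps[j]:
            out[j, 0] = csc
            out[j, 1] = ctac
            out[j, 2] = mtc
            out[j, 3] = helper
            out[j, 4] = killer
            out[j, 5] = regulator
            j += 1
        if step == total_steps:
            break
        t = t0 + step * dt

        csc_thx = _pulse_rate(t, p, CSC_THX)
        ctac_thx = _pulse_rate(t, p, CTAC_THX)
        mtc_thx = _pulse_rate(t, p, MTC_THX)
        helper_thx = _pulse_rate(t, p, HELPER_THX)
        killer_thx = _pulse_rate(t, p, KILLER_THX)
        reg_thx = _pulse_rate(t, p, REG_THX)
        immuno1 = _pulse_rate(t, p, IMMUNO1)
        i2_csc = _pulse_rate(t, p, I2_CSC)
        i2_ctac = _pulse_rate(t, p, I2_CTAC)
        i2_mtc = _pulse_rate(t, p, I2_MTC)

        csc_prol = max(0.0, p[CSC_GROWTH] * csc - csc * csc * p[CSC_CAP])
        csc_loss = (max(0.0, csc * p[CSC_DEATH]
                        + (1.0 + i2_csc) * p[KILL_OF_CSC] * killer
                        - helper * p[HELP_FOR_CSC])
                    + csc * p[CSC_DIFF] + csc * csc_thx)
        ctac_incr = max(0.0, p[CSC_DIFF] * csc + p[CTAC_GROWTH] * ctac
                        - p[CTAC_CAP] * ctac * ctac)
        ctac_loss = (max(0.0, killer * p[KILL_OF_CTAC] * (1.0 + i2_ctac)
                         + p[CTAC_DEATH] * ctac - helper * p[HELP_FOR_CTAC])
                     + p[CTAC_DIFF] * ctac + ctac_thx * ctac)
        mtc_incr = max(0.0, p[MTC_GROWTH] * mtc + p[CTAC_DIFF] * ctac
                       - p[MTC_CAP] * mtc * mtc)
        mtc_loss = (max(0.0, killer * p[KILL_OF_MTC] * (1.0 + i2_mtc)
                        + p[MTC_DEATH] * mtc - helper * p[HELP_FOR_MTC])
                    + mtc_thx * mtc)

        h_stim = (csc * p[H_STIM_CSC] + p[H_STIM_CTAC] * ctac
                  + mtc * p[H_STIM_MTC])
        if helper * h_stim > 0.0:
            helper_prol = max(0.0, h_stim * helper
                              - helper * helper * p[HELPER_CAP]
                              - p[REG_OF_HELPER] * regulator)
        else:
            helper_prol = 0.0
        helper_loss = helper * p[HELPER_DEATH] + helper * helper_thx

        k_stim = max(0.0, csc * p[K_STIM_CSC] + p[K_STIM_CTAC] * ctac
                     + mtc * p[K_STIM_MTC])
        if killer * k_stim * p[HELP_FOR_KILLER] * helper > 0.0:
            killer_prol = max(0.0, killer * k_stim
                              - p[REG_OF_KILLER] * regulator
                              + helper * p[HELP_FOR_KILLER]
                              - killer * killer * p[KILLER_CAP])
        else:
            killer_prol = 0.0
        killer_loss = killer * p[KILLER_DEATH] + killer_thx * killer

        r_stim = (csc * p[R_STIM_CSC] + ctac * p[R_STIM_CTAC]
                  + mtc * p[R_STIM_MTC])
        if regulator * r_stim > 0.0:
            reg_prol = max(0.0, regulator * r_stim
                           - regulator * regulator * p[REG_CAP])
        else:
            reg_prol = 0.0
        reg_loss = regulator * p[REG_DEATH] + reg_thx * regulator

        # non-negativity guard: compare stock + per-day rate, fall back
        # to draining the stock
        d = csc_prol - csc_loss
        d_csc = d if csc + d > 0.0 else -csc
        d = ctac_incr - ctac_loss
        d_ctac = d if ctac + d > 0.0 else -ctac
        d = mtc_incr - mtc_loss
        d_mtc = d if mtc + d > 0.0 else -mtc
        d = helper_prol - helper_loss
        d_helper = d if helper + d > 0.0 else -helper
        d = killer_prol - killer_loss + immuno1
        d_killer = d if killer + d > 0.0 else -killer
        d = reg_prol - reg_loss
        d_reg = d if regulator + d > 0.0 else -regulator

        csc += dt * d_csc
        ctac += dt * d_ctac
        mtc += dt * d_mtc
        helper += dt * d_helper
        killer += dt * d_killer
        regulator += dt * d_reg
    return out
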