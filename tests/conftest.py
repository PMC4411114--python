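"""Shared fixtures and the independent equation-table oracle."""

from __future__ import annotations

import numpy as np
import pytest

from hlsim import ModelParameters, SimulationSettings


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def short_settings() -> SimulationSettings:
    return SimulationSettings(final_time=50.0)


@pytest.fixture(scope="session")
def horizon2000() -> SimulationSettings:
    return SimulationSettings(final_time=2000.0)


@pytest.fixture(scope="session")
def horizon4000() -> SimulationSettings:
    return SimulationSettings(final_time=4000.0)


def random_states(n: int, seed: int = 20150427) -> np.ndarray:
    """Non-negative random states spanning 12 orders of magnitude."""
    rng = np.random.default_rng(seed)
    mag = rng.uniform(-2.0, 12.0, size=(n, 6))
    states = 10.0 ** mag
    states[rng.random((n, 6)) < 0.1] = 0.0  # exercise the guards
    return states


def table_oracle_flows(state, p: ModelParameters, t: float) -> dict[str, float]:
    """Line-by-line transcription of the published equation table.

    Deliberately kept as a separate, naively written code path
    (spelled-out stock names, no shared helpers) so it can serve as an
    independent oracle for :func:`hlsim.model.compute_flows`.
    """
    CSC, CTAC, MTC, Helper, Killer, Regul = state

    def PULSE(start, dur):
        return 1.0 if (t >= start and t < start + dur) else 0.0

    CSC_THx = PULSE(p.csc_thx.start_time, p.csc_thx.duration) * p.csc_thx.intensity
    CTAC_THx = PULSE(p.ctac_thx.start_time, p.ctac_thx.duration) * p.ctac_thx.intensity
    MTC_THx = PULSE(p.mtc_thx.start_time, p.mtc_thx.duration) * p.mtc_thx.intensity
    Helper_THx = PULSE(p.helper_thx.start_time, p.helper_thx.duration) * p.helper_thx.intensity
    Killer_THx = PULSE(p.killer_thx.start_time, p.killer_thx.duration) * p.killer_thx.intensity
    Regulator_THx = PULSE(p.regulator_thx.start_time, p.regulator_thx.duration) * p.regulator_thx.intensity
    ImmunoTHx1 = PULSE(p.immuno1.start_time, p.immuno1.duration) * p.immuno1.intensity
    ImmunoTHx2CSC = PULSE(p.immuno2_csc.start_time, p.immuno2_csc.duration) * p.immuno2_csc.intensity
    ImmunoTHx2CTAC = PULSE(p.immuno2_ctac.start_time, p.immuno2_ctac.duration) * p.immuno2_ctac.intensity
    ImmunoTHx2MTC = PULSE(p.immuno2_mtc.start_time, p.immuno2_mtc.duration) * p.immuno2_mtc.intensity

    CSC_prol = max(0.0, (p.csc_growth * CSC) - (CSC * CSC * p.csc_cap))
    CSC_loss = (max(0.0, (CSC * p.csc_death)
                    + ((1 + ImmunoTHx2CSC) * p.kill_of_csc * Killer)
                    - (Helper * p.help_for_csc))
                + (CSC * p.csc_diff)) + (CSC * CSC_THx)
    CTAC_incr = max(0.0, (p.csc_diff * CSC) + (p.ctac_growth * CTAC)
                    - (p.ctac_cap * CTAC * CTAC))
    CTAC_loss = (max(0.0, (Killer * p.kill_of_ctac * (1 + ImmunoTHx2CTAC))
                     + (p.ctac_death * CTAC) - (Helper * p.help_for_ctac))
                 + (p.ctac_diff * CTAC)) + (CTAC_THx * CTAC)
    MTC_incr = max(0.0, (p.mtc_growth * MTC) + (p.ctac_diff * CTAC)
                   - (p.mtc_cap * MTC * MTC))
    MTC_loss = (max(0.0, (Killer * p.kill_of_mtc * (1 + ImmunoTHx2MTC))
                    + (p.mtc_death * MTC) - (Helper * p.help_for_mtc))) \
        + (MTC_THx * MTC)

    Helper_stim_by_Tumor = ((CSC * p.helper_stim_by_csc)
                            + (p.helper_stim_by_ctac * CTAC)
                            + (MTC * p.helper_stim_by_mtc))
    if Helper * Helper_stim_by_Tumor > 0:
        Helper_prol = max(0.0, (Helper_stim_by_Tumor * Helper)
                          - (Helper * Helper * p.helper_cap)
                          - (p.regulation_of_helper * Regul))
    else:
        Helper_prol = 0.0
    Helper_loss = (Helper * p.helper_death) + (Helper * Helper_THx)

    Killer_stim_by_Tumor = max(0.0, ((CSC * p.killer_stim_by_csc)
                                     + (p.killer_stim_by_ctac * CTAC)
                                     + (MTC * p.killer_stim_by_mtc)))
    if Killer * Killer_stim_by_Tumor * p.help_for_killer * Helper > 0:
        Killer_prol = max(0.0, (Killer * Killer_stim_by_Tumor)
                          - (p.regulation_of_killer * Regul)
                          + (Helper * p.help_for_killer)
                          - (Killer * Killer * p.killer_cap))
    else:
        Killer_prol = 0.0
    Killer_loss = (Killer * p.killer_death) + (Killer_THx * Killer)

    Regulator_stim_by_Tumor = ((CSC * p.regulator_stim_by_csc)
                               + (CTAC * p.regulator_stim_by_ctac)
                               + (MTC * p.regulator_stim_by_mtc))
    if Regul * Regulator_stim_by_Tumor > 0:
        Regulator_prol = max(0.0, (Regul * Regulator_stim_by_Tumor)
                             - (Regul * Regul * p.regulator_cap))
    else:
        Regulator_prol = 0.0
    Regulator_loss = (Regul * p.regulator_death) + (Regulator_THx * Regul)

    return {
        "csc_prol": CSC_prol, "csc_loss": CSC_loss,
        "ctac_incr": CTAC_incr, "ctac_loss": CTAC_loss,
        "mtc_incr": MTC_incr, "mtc_loss": MTC_loss,
        "helper_prol": Helper_prol, "helper_loss": Helper_loss,
        "killer_prol": Killer_prol, "killer_loss": Killer_loss,
        "regulator_prol": Regulator_prol, "regulator_loss": Regulator_loss,
        "helper_stim_by_tumor": Helper_stim_by_Tumor,
        "killer_stim_by_tumor": Killer_stim_by_Tumor,
        "regulator_stim_by_tumor": Regulator_stim_by_Tumor,
        "csc_thx_rate": CSC_THx, "ctac_thx_rate": CTAC_THx,
        "mtc_thx_rate": MTC_THx, "helper_thx_rate": Helper_THx,
        "killer_thx_rate": Killer_THx, "regulator_thx_rate": Regulator_THx,
        "immuno1_rate": ImmunoTHx1,
        "immuno2_csc_factor": ImmunoTHx2CSC,
        "immuno2_ctac_factor": ImmunoTHx2CTAC,
        "immuno2_mtc_factor": ImmunoTHx2MTC,
    }
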