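"""Model parameters, therapy pulse schedules and simulation settings.

The model is parameterised by ~70 named scalars: per-compartment growth,
death, differentiation and capacity constants for the three tumor
sub-compartments (CSC, CTAC, MTC); stimulation, help, killing and
regulation couplings for the three bystander compartments (helper,
killer, regulatory cells); one cytotoxic-therapy pulse schedule per
compartment; and the two immunotherapy extensions (adoptive killer-cell
transfer and killing-amplification pulses).

Parameters can be addressed either by their canonical snake_case key
(``kill_of_csc``, ``csc_thx_intens`` ...) or by the spelled-out names
used in the published parameter table (``"Kill of CSC"``,
``"CSC THx intens"``); :func:`normalize_key` maps both onto the
canonical set.  The full name mapping ships in ``docs/parameters.md``.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "PulseSchedule",
    "ModelParameters",
    "SimulationSettings",
    "ParameterError",
    "normalize_key",
    "canonical_keys",
]


class ParameterError(ValueError):
    """Invalid parameter name or value."""


@dataclass(frozen=True)
class PulseSchedule:
    """A rectangular therapy pulse.

    The pulse is active on the half-open interval
    ``[start_time, start_time + duration)`` (so ``duration=1`` delivers
    exactly one day of effect) and contributes ``intensity`` while
    active, zero otherwise.  Negative intensities are legitimate: an
    *increase* of a compartment is simulated by a negative "toxicity".

    Parameters
    ----------
    start_time : float
        First day of the pulse.
    duration : float
        Length of the pulse window in days; must be >= 0.
    intensity : float
        Per-day rate multiplier (additive cells/day for adoptive
        transfer); unrestricted in sign.
    """

    start_time: float
    duration: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        for name in ("start_time", "duration", "intensity"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"PulseSchedule.{name} must be finite, got {v!r}")
        if self.duration < 0:
            raise ParameterError(f"PulseSchedule.duration must be >= 0, got {self.duration}")


def _thx(time: float, dur: float, intens: float = 0.0) -> PulseSchedule:
    return PulseSchedule(start_time=time, duration=dur, intensity=intens)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, capacities, schedules and initial stocks.

    Default construction reproduces the published default parameter set
    exactly.  Capacities, death/growth/differentiation rates and all
    stimulation/killing/regulation couplings must be non-negative; pulse
    intensities may take either sign.
    """

    # cancer stem cells
    csc_cap: float = 1e-9          # 1/cells/day, resource limit
    csc_death: float = 0.01        # 1/day
    csc_diff: float = 0.002        # 1/day, differentiation into CTAC
    csc_growth: float = 0.01       # 1/day
    csc_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # cancer transit amplifying cells
    ctac_cap: float = 1e-9
    ctac_death: float = 0.03
    ctac_diff: float = 0.91        # differentiation into MTC
    ctac_growth: float = 0.9
    ctac_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # mature tumor cells (no proliferation by default)
    mtc_cap: float = 1e-9
    mtc_death: float = 0.5
    mtc_growth: float = 0.0
    mtc_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # anti-apoptotic "help" couplings
    help_for_csc: float = 0.001    # 1/cells/day
    help_for_ctac: float = 0.001
    help_for_mtc: float = 0.001
    help_for_killer: float = 1e-5  # co-stimulation of killer proliferation

    # helper cells
    helper_cap: float = 1e-9
    helper_death: float = 1e-5
    helper_stim_by_csc: float = 0.001
    helper_stim_by_ctac: float = 0.001
    helper_stim_by_mtc: float = 0.001
    helper_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # killer cells
    killer_cap: float = 1e-9
    killer_death: float = 1e-5
    killer_stim_by_csc: float = 1e-4
    killer_stim_by_ctac: float = 1e-4
    killer_stim_by_mtc: float = 0.02
    kill_of_csc: float = 1e-6
    kill_of_ctac: float = 1e-6
    kill_of_mtc: float = 1e-6
    killer_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # regulatory cells
    regulator_cap: float = 1e-4
    regulator_death: float = 1e-5
    regulator_stim_by_csc: float = 0.001
    regulator_stim_by_ctac: float = 0.001
    regulator_stim_by_mtc: float = 1e-4
    regulation_of_helper: float = 1e-4
    regulation_of_killer: float = 0.5
    regulator_thx: PulseSchedule = field(default_factory=lambda: _thx(400, 100))

    # immunotherapy extensions
    immuno1: PulseSchedule = field(default_factory=lambda: _thx(300, 1))       # adoptive transfer, cells/day
    immuno2_csc: PulseSchedule = field(default_factory=lambda: _thx(1000, 3000))   # killing amplification
    immuno2_ctac: PulseSchedule = field(default_factory=lambda: _thx(1000, 3000))
    immuno2_mtc: PulseSchedule = field(default_factory=lambda: _thx(1000, 3000))

    # initial stocks
    initial_csc: float = 10.0
    initial_ctac: float = 10.0
    initial_mtc: float = 10.0
    initial_helper: float = 10.0
    initial_killer: float = 10.0
    initial_regulator: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Reject negative rates/capacities/couplings and non-finite values.

        Pulse intensities are deliberately exempt from the sign check.
        """
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, PulseSchedule):
                continue  # validated by PulseSchedule itself
            if not math.isfinite(v):
                raise ParameterError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ParameterError(f"parameter {f.name!r} must be >= 0, got {v}")

    # -- flat key access ------------------------------------------------

    def get(self, key: str) -> float:
        """Return the value of a parameter by (any accepted spelling of) its name."""
        attr, sub = _resolve(key)
        v = getattr(self, attr)
        return getattr(v, sub) if sub else v

    def with_overrides(self, overrides: dict[str, float]) -> "ModelParameters":
        """Return a copy with the named parameters replaced.

        Keys may use canonical snake_case or the published table
        spellings.  Unknown keys raise :class:`ParameterError` naming
        the nearest valid key.
        """
        changes: dict[str, object] = {}
        for key, value in overrides.items():
            attr, sub = _resolve(key)
            if sub:
                base = changes.get(attr, getattr(self, attr))
                changes[attr] = replace(base, **{sub: float(value)})
            else:
                changes[attr] = float(value)
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        """Flat canonical-key snapshot (for logging and serialization)."""
        out: dict[str, float] = {}
        for key in canonical_keys():
            out[key] = self.get(key)
        return out

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ModelParameters":
        return cls().with_overrides(values)


@dataclass(frozen=True)
class SimulationSettings:
    """Fixed-step Euler integration settings.

    The published runs use initial time 0, final time 2000 or 4000
    days, a time step of 2**-7 days (displayed as 0.007812) and daily
    sampling (``saveper`` = 1).
    """

    initial_time: float = 0.0
    final_time: float = 2000.0
    dt: float = 0.0078125
    saveper: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.saveper < self.dt:
            raise ParameterError(f"saveper ({self.saveper}) must be >= dt ({self.dt})")
        if not self.final_time > self.initial_time:
            raise ParameterError("final_time must exceed initial_time")


# ---------------------------------------------------------------------------
# key normalization
# ---------------------------------------------------------------------------

# pulse-schedule sub-keys: canonical "<block>_thx_{time,dur,intens}"
_PULSE_ATTRS = {
    "csc_thx": "csc_thx",
    "ctac_thx": "ctac_thx",
    "mtc_thx": "mtc_thx",
    "helper_thx": "helper_thx",
    "killer_thx": "killer_thx",
    "regulator_thx": "regulator_thx",
    "immuno1": "immuno1",
    "immuno2_csc": "immuno2_csc",
    "immuno2_ctac": "immuno2_ctac",
    "immuno2_mtc": "immuno2_mtc",
}
_PULSE_SUBS = {"time": "start_time", "dur": "duration", "intens": "intensity"}

# published-name aliases that do not reduce to a canonical key by
# lowercasing alone
_ALIASES = {
    "initial_helper_cells": "initial_helper",
    "initial_killer_cells": "initial_killer",
    "initial_regulatory_cells": "initial_regulator",
    "help_for_killer_cells": "help_for_killer",
    "regulation_of_helper_cells": "regulation_of_helper",
    "regulation_of_killer_cells": "regulation_of_killer",
}
for _sub in ("time", "dur", "intens"):
    _ALIASES[f"immunothx1_{_sub}"] = f"immuno1_{_sub}"
    for _tc in ("csc", "ctac", "mtc"):
        _ALIASES[f"immunothx2{_tc}_{_sub}"] = f"immuno2_{_tc}_{_sub}"


def canonical_keys() -> list[str]:
    """The full canonical flat key set, in declaration order."""
    keys: list[str] = []
    for f in fields(ModelParameters):
        if f.name in _PULSE_ATTRS.values():
            keys.extend(f"{f.name}_{s}" for s in ("time", "dur", "intens"))
        else:
            keys.append(f.name)
    return keys


def normalize_key(key: str) -> str:
    """Map any accepted spelling of a parameter name to its canonical key.

    Accepts canonical snake_case keys, the published table spellings
    (including the "Thx"/"THx" capitalization inconsistencies) and the
    common "duration"/"intensity" long forms.
    """
    k = "_".join(str(key).strip().lower().split()).replace("-", "_")
    k = k.replace("_duration", "_dur").replace("_intensity", "_intens")
    k = k.replace("_start_time", "_time")
    k = _ALIASES.get(k, k)
    return k


def _resolve(key: str) -> tuple[str, str | None]:
    """Resolve a key to (attribute, pulse-subfield-or-None)."""
    k = normalize_key(key)
    valid = canonical_keys()
    if k not in valid:
        hint = difflib.get_close_matches(k, valid, n=1)
        extra = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ParameterError(f"unknown parameter key {key!r}{extra}")
    for prefix, attr in _PULSE_ATTRS.items():
        for sub, subattr in _PULSE_SUBS.items():
            if k == f"{prefix}_{sub}":
                return attr, subattr
    return k, None
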