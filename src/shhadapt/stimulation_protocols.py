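"""Shh input signals and the pre-equilibration + stimulation protocol.

The neural-tube screen drives the pathway model with two linearly
increasing Shh concentrations: time courses measured at two ventral
positions are fitted by straight lines, extrapolated back to zero, and
normalized so that the stronger signal reaches 2.0 and the weaker 1.0
(arbitrary concentration units) at the end of a 70-h stimulation window.
The fibroblast contrast uses a fixed rectangular pulse instead.

Every simulation first relaxes the model to its Shh-free steady state
(default 300 h) and only then applies the input.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .pathway_models import SPECIES, SPECIES_INDEX, ModelVariant, ParameterSet, make_rhs

__all__ = [
    "SignalKind",
    "InputSignal",
    "SimulationResult",
    "SolverError",
    "build_ramp_inputs",
    "default_pulse",
    "run_protocol",
]

#: Relative steady-state criterion max |dS/dt| / (|S| + eps) applied at the
#: end of pre-equilibration, in 1/h.
STEADY_STATE_TOL = 1e-6
_SS_EPS = 1e-9


class SignalKind(str, enum.Enum):
    RAMP = "ramp"
    PULSE = "pulse"
    CONSTANT = "constant"


class SolverError(RuntimeError):
    """ODE integration failure; carries the offending parameter set."""

    def __init__(self, message: str, params: ParameterSet | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-defined nonnegative Shh concentration time course.

    RAMP: zero before ``onset_time``, then ``slope * (t - onset_time)``,
    capped at ``max_value`` if one is set.  PULSE: ``level`` on
    ``[onset_time, onset_time + duration]``, zero outside.  CONSTANT:
    ``level`` everywhere.
    """

    kind: SignalKind
    onset_time: float = 0.0
    slope: float = 0.0  # conc/h, RAMP only
    level: float = 0.0  # conc, PULSE and CONSTANT
    duration: float = np.inf  # h, PULSE only
    max_value: float = np.inf  # conc cap, RAMP only

    def __post_init__(self) -> None:
        if self.kind == SignalKind.RAMP and self.slope < 0:
            raise ValueError("ramp slope must be >= 0")
        if self.level < 0:
            raise ValueError("signal level must be >= 0")
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")

    def __call__(self, t: float) -> float:
        if self.kind == SignalKind.RAMP:
            v = self.slope * (t - self.onset_time)
            if v <= 0.0:
                return 0.0
            return v if v < self.max_value else self.max_value
        if self.kind == SignalKind.PULSE:
            if self.onset_time <= t <= self.onset_time + self.duration:
                return self.level
            return 0.0
        return self.level

    def to_dict(self) -> dict:
        # unbounded duration / cap serialize as null (strict JSON has no inf)
        return {
            "kind": self.kind.value,
            "onset_time": self.onset_time,
            "slope": self.slope,
            "level": self.level,
            "duration": None if np.isinf(self.duration) else self.duration,
            "max_value": None if np.isinf(self.max_value) else self.max_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputSignal":
        d = dict(d)
        d["kind"] = SignalKind(d["kind"])
        if d.get("duration") is None:
            d["duration"] = np.inf
        if d.get("max_value") is None:
            d["max_value"] = np.inf
        return cls(**d)


def build_ramp_inputs(
    fit_position_1,
    fit_position_2,
    t_stim: float = 70.0,
    max_1: float = 2.0,
    max_2: float = 1.0,
) -> tuple[InputSignal, InputSignal]:
    """Turn two stereotyped linear Shh time-course fits into model inputs.

    Each fit (anything exposing a ``slope`` attribute, or a bare number)
    must be increasing; its extrapolated zero-crossing defines the start of
    the stimulation window, so both ramps start at zero at t = 0 and are
    rescaled to reach exactly ``max_1`` (ventral-most band) and ``max_2``
    at t = ``t_stim``.
    """
    out = []
    for fit, target in ((fit_position_1, max_1), (fit_position_2, max_2)):
        slope = getattr(fit, "slope", fit)
        if not np.isfinite(slope) or slope <= 0:
            raise ValueError(
                f"stereotyped fit slope must be positive (got {slope}); "
                "a non-increasing Shh time course has no zero-crossing"
            )
        out.append(
            InputSignal(SignalKind.RAMP, onset_time=0.0, slope=target / t_stim)
        )
    return out[0], out[1]


def default_pulse(level: float = 1.0, duration: float = 48.0) -> InputSignal:
    """Rectangular Shh pulse used for the fibroblast (NIH3T3) contrast.

    Defaults: onset at 0 h, 48-h duration matching the experimental
    exposure window, amplitude 1.0 (normalized units).
    """
    return InputSignal(SignalKind.PULSE, onset_time=0.0, level=level, duration=duration)


@dataclass
class SimulationResult:
    """Trajectories over the stimulation window plus the pre-stimulus state."""

    times: np.ndarray  # h, stimulation window grid
    states: np.ndarray  # (n_times, n_species)
    pre_equilibration_state: np.ndarray  # (n_species,)
    steady_state_ok: bool
    variant: ModelVariant
    params: ParameterSet
    signal: InputSignal

    def series(self, species: str) -> np.ndarray:
        return self.states[:, SPECIES_INDEX[species]]

    def basal(self, species: str) -> float:
        return float(self.pre_equilibration_state[SPECIES_INDEX[species]])

    def to_frame(self):
        """Tidy long-format table: time_h, species, value."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, len(SPECIES)),
                "species": np.tile(SPECIES, n_t),
                "value": self.states.reshape(-1),
            }
        )


_ZERO = InputSignal(SignalKind.CONSTANT, level=0.0)


def pre_equilibrate(
    params: ParameterSet,
    variant: ModelVariant,
    t_pre: float = 300.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    y0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Relax the model to its Shh-free steady state.

    Returns the terminal state and whether it satisfies the relative
    steady-state criterion (max |dS/dt| / (|S| + 1e-9) < 1e-6 per hour).
    """
    f = make_rhs(params, variant, _ZERO)
    if y0 is None:
        y0 = np.zeros(len(SPECIES))
    sol = solve_ivp(
        f, (0.0, t_pre), y0, method="LSODA", rtol=rtol, atol=atol, dense_output=False
    )
    if not sol.success:
        raise SolverError(f"pre-equilibration failed: {sol.message}", params)
    y_eq = sol.y[:, -1]
    rate = np.abs(f(t_pre, y_eq)) / (np.abs(y_eq) + _SS_EPS)
    return y_eq, bool(np.max(rate) < STEADY_STATE_TOL)


def run_protocol(
    params: ParameterSet,
    variant: ModelVariant,
    signal: InputSignal,
    t_pre: float = 300.0,
    t_stim: float = 70.0,
    grid_dt: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    pre_state: np.ndarray | None = None,
    warn_on_no_steady_state: bool = True,
) -> SimulationResult:
    """Pre-equilibrate without ligand, then stimulate with ``signal``.

    ``pre_state`` allows reusing one equilibration across several inputs of
    the same parameter set.  Output is sampled on a fixed grid (default
    0.5 h) over [0, t_stim]; a stiff-capable integrator (LSODA) is used
    throughout.  Failure to meet the steady-state criterion at the end of
    pre-equilibration is flagged (``steady_state_ok``), not silenced.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(variant)
    if pre_state is not None:
        y_eq, ss_ok = np.asarray(pre_state, dtype=float), True
    else:
        y_eq, ss_ok = pre_equilibrate(params, variant, t_pre, rtol, atol)
        if not ss_ok and warn_on_no_steady_state:
            warnings.warn(
                "model did not reach steady state during pre-equilibration",
                RuntimeWarning,
                stacklevel=2,
            )
    t_eval = np.arange(0.0, t_stim + 0.5 * grid_dt, grid_dt)
    f = make_rhs(params, variant, signal)
    sol = solve_ivp(
        f, (0.0, t_stim), y_eq, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise SolverError(f"stimulation failed: {sol.message}", params)
    return SimulationResult(
        times=sol.t,
        states=sol.y.T,
        pre_equilibration_state=y_eq,
        steady_state_ok=ss_ok,
        variant=variant,
        params=params,
        signal=signal,
    )
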