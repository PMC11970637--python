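"""Stiff ODE integration and the sequential simulation session.

The session mimics an interactive workflow: repeated "simulate a segment"
calls continue from the previous end state, with parameter changes (stimulus
weights, knockouts) applied between segments and persisting until changed or
reset.  Integration uses a stiff-capable implicit method (scipy's BDF, the
counterpart of MATLAB's ode15s) with rtol 1e-6 / atol 1e-9; each segment is
sampled on a fixed 201-point grid so output is deterministic and
plot-quality regardless of internal solver stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import numpy.typing as npt
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import CompiledNetwork
from .model import NetworkModel, validation_errors

__all__ = [
    "DEFAULT_DURATION",
    "ProtocolStep",
    "SimulationError",
    "SimulationSession",
    "SteadyStateError",
    "Trajectory",
    "read_trajectory",
    "run_protocol",
    "simulate_segment",
    "steady_state",
    "write_trajectory",
]

DEFAULT_DURATION = 10.0
GRID_POINTS = 201
RTOL = 1e-6
ATOL = 1e-9


class SimulationError(RuntimeError):
    """Integration failed (non-finite state or solver breakdown)."""


class SteadyStateError(RuntimeError):
    """The system did not settle within the integration horizon."""


@dataclass
class ProtocolStep:
    """Parameter overrides to apply, then a time span to integrate.

    ``overrides`` maps ``"<target>.<param>"`` to a value, e.g.
    ``{"r1.weight": 1}`` or ``{"NKX25.ymax": 0}``.  Overrides persist into
    later steps until changed or the session is reset.
    """

    duration: float = DEFAULT_DURATION
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"step duration must be > 0 (got {self.duration})")


@dataclass
class Trajectory:
    """Time grid plus per-species activity matrix (rows = times)."""

    times: npt.NDArray[np.float64]
    activities: npt.NDArray[np.float64]
    species_ids: list[str]
    segment_marks: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def column(self, species_id: str) -> npt.NDArray[np.float64]:
        return self.activities[:, self.species_ids.index(species_id)]

    def final(self, species_id: str | None = None):
        """Final state: one activity, or a Series over all species."""
        if species_id is not None:
            return float(self.column(species_id)[-1])
        return pd.Series(self.activities[-1], index=self.species_ids)

    def at_time(self, t: float) -> pd.Series:
        """Activities at the grid point nearest *t*."""
        i = int(np.argmin(np.abs(self.times - t)))
        return pd.Series(self.activities[i], index=self.species_ids, name=self.times[i])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.activities, columns=self.species_ids)
        frame.insert(0, "time", self.times)
        return frame


class SimulationSession:
    """Mutable simulation state over one model.

    Holds the live parameter overlay, the current activity vector, and the
    accumulated trajectory.  ``simulate_segment`` extends the trajectory;
    ``reset`` restores pristine parameters and/or the initial state.
    """

    def __init__(self, model: NetworkModel):
        errors = validation_errors(model)
        if errors:
            raise ValueError("model failed validation: " + "; ".join(map(str, errors)))
        self.model = model
        self.overrides: dict[str, float] = {}
        self._start()

    def _start(self) -> None:
        net = CompiledNetwork(self.model, self.overrides)
        self.t = 0.0
        self.y = net.yinit.copy()
        self.trajectory = Trajectory(
            times=np.array([0.0]),
            activities=self.y.reshape(1, -1).copy(),
            species_ids=net.species_ids,
            segment_marks=[],
        )

    def reset(self, parameters: bool = True, simulation: bool = True) -> None:
        """Restore pristine parameters and/or restart time at yinit."""
        if parameters:
            self.overrides = {}
        if simulation:
            self._start()

    def simulate_segment(self, step: ProtocolStep) -> Trajectory:
        """Apply the step's overrides, integrate over its duration, append.

        A ``yinit`` override only matters at session start or after a reset;
        mid-session the state continues from where the last segment ended.
        """
        starting = len(self.trajectory.times) == 1 and self.t == 0.0
        self.overrides.update(step.overrides)
        net = CompiledNetwork(self.model, self.overrides)  # validates targets
        if starting and any(k.endswith(".yinit") for k in self.overrides):
            self.y = net.yinit.copy()
            self.trajectory.activities[0] = self.y

        t_eval = np.linspace(self.t, self.t + step.duration, GRID_POINTS)
        sol = solve_ivp(
            net.rhs,
            (self.t, self.t + step.duration),
            self.y,
            method="BDF",
            rtol=RTOL,
            atol=ATOL,
            t_eval=t_eval,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SimulationError(
                f"integration failed near t={sol.t[-1] if len(sol.t) else self.t}: "
                f"{sol.message}"
            )
        self.trajectory.segment_marks.append(self.t)
        # drop the first output point: it duplicates the current state
        self.trajectory.times = np.concatenate([self.trajectory.times, sol.t[1:]])
        self.trajectory.activities = np.vstack([self.trajectory.activities, sol.y.T[1:]])
        self.t = float(sol.t[-1])
        self.y = sol.y[:, -1].copy()
        return self.trajectory


def simulate_segment(session: SimulationSession, step: ProtocolStep) -> Trajectory:
    """Functional alias for :meth:`SimulationSession.simulate_segment`."""
    return session.simulate_segment(step)


def run_protocol(model: NetworkModel, steps: Sequence[ProtocolStep]) -> Trajectory:
    """Run *steps* in order on a fresh session; return the full trajectory."""
    if not steps:
        raise ValueError("protocol must contain at least one step")
    session = SimulationSession(model)
    for step in steps:
        session.simulate_segment(step)
    return session.trajectory


def steady_state(
    model: NetworkModel,
    overrides: dict[str, float] | None = None,
    tol: float = 1e-9,
    horizon: float = 1e5,
    chunk: float = 50.0,
) -> pd.Series:
    """Integrate until max|dy/dt| < *tol*; return the settled activities.

    Raises :class:`SteadyStateError` if the system has not settled within
    *horizon* time units (oscillatory models exist in principle).
    """
    net = CompiledNetwork(model, overrides)
    y = net.yinit.copy()
    t = 0.0
    while t < horizon:
        span = min(chunk, horizon - t)
        sol = solve_ivp(net.rhs, (t, t + span), y, method="BDF", rtol=RTOL, atol=ATOL)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"integration failed near t={t}: {sol.message}")
        t, y = float(sol.t[-1]), sol.y[:, -1]
        if np.max(np.abs(net.rhs(t, y))) < tol:
            return pd.Series(y, index=net.species_ids)
    raise SteadyStateError(
        f"no steady state within horizon {horizon} (max|dy/dt| still >= {tol})"
    )


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "csv") -> None:
    """Write the trajectory table (header: time + species ids) at full precision."""
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown trajectory format {format!r}")
    traj.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_trajectory(path: str | Path, format: str = "csv") -> Trajectory:
    """Read back a trajectory written by :func:`write_trajectory`."""
    sep = {"csv": ",", "tsv": "\t"}[format]
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return Trajectory(
        times=frame["time"].to_numpy(dtype=float),
        activities=frame.drop(columns="time").to_numpy(dtype=float),
        species_ids=[c for c in frame.columns if c != "time"],
    )
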