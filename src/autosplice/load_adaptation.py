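"""Steady-state and dynamic responses of the circuit to perturbations.

Quantifies the homeostatic claims of the autoregulatory architecture:

* **reservoir sweeps** — steady-state ectopic protein as a function of the
  competing substrate load R (load adaptation: more substrate dilutes the
  factor per transcript, weakening self-repression, raising output);
* **induction sweeps** — steady states across production rates, exhibiting
  the expression ceiling (sub-linear sensitivity) and the buffering drop in
  endogenous protein;
* **response times** — time to reach a fraction (default 90%) of the final
  level, which negative feedback shortens at matched steady state;
* **log-log sensitivity coefficients** — central finite differences with a
  1% step in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    Circuit,
    CircuitState,
    ModelParameters,
    SteadyStateError,
    Trajectory,
    productive_fraction,
    steady_state_feedback,
    steady_state_no_feedback,
)

__all__ = [
    "SweepResult",
    "sweep_reservoir",
    "sweep_induction",
    "response_time",
    "sensitivity",
]


class ResponseError(RuntimeError):
    """The trajectory never reaches the requested fraction of its final level."""


@dataclass(frozen=True)
class SweepResult:
    """Steady states along a swept variable, with derived observables."""

    variable: str
    grid: np.ndarray
    states: tuple  # CircuitState per grid point (None where failed)
    p_ec: np.ndarray
    p_en: np.ndarray
    p_total: np.ndarray
    productive_frac: np.ndarray
    failures: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.variable: self.grid})
        for col in ("u_ec", "m_ec", "p_ec", "u_en", "m_en", "p_en"):
            df[col] = [getattr(s, col) if s is not None else np.nan
                       for s in self.states]
        df["p_total"] = self.p_total
        df["productive_frac"] = self.productive_frac
        return df


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D strictly increasing")
    if np.any(grid < 0):
        raise ValueError("grid must be nonnegative")
    return grid


def sweep_reservoir(params: ModelParameters, alpha_ec: float,
                    R_grid) -> SweepResult:
    """Steady-state response to the competing substrate load R."""
    grid = _check_grid(R_grid)
    states, fails = [], []
    for R in grid:
        try:
            states.append(steady_state_feedback(params.replace(reservoir=float(R)),
                                                alpha_ec))
        except (SteadyStateError, ValueError) as exc:
            states.append(None)
            fails.append((float(R), repr(exc)))
    return _pack("reservoir", grid, states, params, fails)


def sweep_induction(params: ModelParameters, alpha_grid,
                    circuit: Circuit | str) -> SweepResult:
    """Steady states across ectopic production rates for either circuit."""
    circuit = Circuit(circuit)
    grid = _check_grid(alpha_grid)
    states, fails = [], []
    for a in grid:
        try:
            if circuit is Circuit.NO_FEEDBACK:
                states.append(steady_state_no_feedback(params, float(a)))
            else:
                states.append(steady_state_feedback(params, float(a)))
        except (SteadyStateError, ValueError) as exc:
            states.append(None)
            fails.append((float(a), repr(exc)))
    return _pack("alpha_ec", grid, states, params, fails,
                 feedback=circuit is Circuit.FEEDBACK)


def _pack(variable, grid, states, params, fails, feedback=True) -> SweepResult:
    def arr(attr):
        return np.array([getattr(s, attr) if s is not None else np.nan
                         for s in states])

    frac = np.full(len(states), np.nan)
    if feedback:
        for i, s in enumerate(states):
            if s is not None:
                p = params if variable != "reservoir" \
                    else params.replace(reservoir=float(grid[i]))
                frac[i] = productive_fraction(p, s, copy="ec") \
                    if s.u_ec > 0 else productive_fraction(p, s, copy="en")
    return SweepResult(variable=variable, grid=grid, states=tuple(states),
                       p_ec=arr("p_ec"), p_en=arr("p_en"),
                       p_total=arr("p_ec") + arr("p_en"),
                       productive_frac=frac, failures=tuple(fails))


def response_time(trajectory: Trajectory, fraction: float = 0.9, *,
                  final: float | None = None) -> float:
    """First time the observable crosses I0 + fraction*(final - I0).

    ``final`` defaults to the trajectory's last observable value; pass the
    model steady state for an exact target.  Linearly interpolated between
    samples.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = trajectory.observable
    t = trajectory.times
    i0 = float(y[0])
    f = float(y[-1]) if final is None else float(final)
    if f <= i0:
        raise ResponseError("trajectory does not rise above its initial level")
    thresh = i0 + fraction * (f - i0)
    above = np.nonzero(y >= thresh)[0]
    above = above[above > 0]
    if len(above) == 0:
        raise ResponseError(
            f"observable never reaches {fraction:.0%} of its final level")
    i = int(above[0])
    # linear interpolation on the crossing interval
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    w = (thresh - y0) / (y1 - y0)
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


def sensitivity(params: ModelParameters, variable: str, at: float, *,
                circuit: Circuit | str = Circuit.FEEDBACK,
                response: str = "p_ec", step: float = 0.01) -> float:
    """Dimensionless log-log derivative of the steady-state protein level.

    ``variable`` is "alpha_ec" or "reservoir"; ``response`` selects p_ec or
    p_total.  Central difference with a 1% step in log space.
    """
    circuit = Circuit(circuit)
    if at <= 0:
        raise ValueError("evaluation point must be > 0")
    if variable not in ("alpha_ec", "reservoir"):
        raise ValueError("variable must be 'alpha_ec' or 'reservoir'")
    if response not in ("p_ec", "p_total"):
        raise ValueError("response must be 'p_ec' or 'p_total'")

    def level(v: float) -> float:
        if variable == "alpha_ec":
            if circuit is Circuit.NO_FEEDBACK:
                s = steady_state_no_feedback(params, v)
            else:
                s = steady_state_feedback(params, v)
        else:
            if circuit is Circuit.NO_FEEDBACK:
                raise ValueError("reservoir sensitivity requires the feedback circuit")
            s = steady_state_feedback(params.replace(reservoir=v),
                                      params.alpha_ec_hi)
        p = s.p_ec if response == "p_ec" else s.p_ec + s.p_en
        if p <= 0:
            return -np.inf
        return float(np.log(p))

    hi = level(at * np.exp(step))
    lo = level(at * np.exp(-step))
    if not (np.isfinite(hi) and np.isfinite(lo)):
        return 0.0
    return (hi - lo) / (2.0 * step)
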