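"""Periodic pulsed sterile-male releases.

Every ``tau`` days, starting at ``tS``, a pulse of ``tau * LambdaPer`` sterile
males is added instantaneously; between pulses sterile males decay at rate
``muS``.  Because the wild compartments never feed back into ``MS``, the pulse
train has the closed form

    MS(t) = sum_{n : tS + n tau <= t}  tau*LambdaPer * exp(-muS (t - tS - n tau))

which converges to a tau-periodic sawtooth with extrema::

    M_lower = tau*LambdaPer * e^{-muS tau} / (1 - e^{-muS tau})
    M_upper = tau*LambdaPer / (1 - e^{-muS tau})

The impulsive system is integrated exactly as written: flow between release
instants, an MS jump of ``tau * LambdaPer`` at each instant (integrate-restart
semantics, first pulse at t = tS).  Freezing MS at either extremum yields the
monotone bounding systems whose trajectories sandwich the pulsed dynamics
after the MS transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    Trajectory,
    _integrate,
    rhs_full,
    rhs_reduced,
)
from .params import ModelParams
from .states import FULL9_FIELDS, Full9State, Reduced7State

__all__ = [
    "PulseTrain",
    "ms_exact",
    "ms_periodic_bounds",
    "release_times",
    "simulate_periodic",
    "bounding_system_simulate",
]


@dataclass(frozen=True)
class PulseTrain:
    """Periodic release schedule: pulses of size ``tau * LambdaPer`` every
    ``tau`` days, first one at ``tS``."""

    tau: float
    LambdaPer: float
    muS: float
    tS: float = 100.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.muS <= 0:
            raise ValueError("tau and muS must be > 0")
        if self.LambdaPer < 0:
            raise ValueError("LambdaPer must be >= 0")

    @property
    def pulse_size(self) -> float:
        return self.tau * self.LambdaPer


def ms_exact(train: PulseTrain, t) -> np.ndarray | float:
    """Sterile males at time(s) ``t`` from the closed-form geometric sum.

    Zero before ``tS``; right-continuous jumps of ``tau * LambdaPer`` at each
    release instant.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    active = t >= train.tS
    if np.any(active):
        s = t[active] - train.tS
        m = np.floor(s / train.tau)  # index of last pulse received
        q = np.exp(-train.muS * train.tau)  # per-period decay factor
        # sum_{n=0..m} e^{-muS (s - n tau)} = e^{-muS(s - m tau)} (1-q^{m+1})/(1-q)
        phase = s - m * train.tau
        out[active] = (
            train.pulse_size * np.exp(-train.muS * phase) * (1.0 - q ** (m + 1)) / (1.0 - q)
        )
    return out if out.ndim else float(out)


def ms_periodic_bounds(train: PulseTrain) -> tuple[float, float]:
    """(min, max) of the asymptotic tau-periodic sterile-male waveform."""
    q = np.exp(-train.muS * train.tau)
    upper = train.pulse_size / (1.0 - q)
    return upper * q, upper


def release_times(train: PulseTrain, horizon: float) -> np.ndarray:
    """Release instants ``tS + n tau`` up to (and including) ``horizon``."""
    if horizon < train.tS:
        return np.empty(0)
    n = int(np.floor((horizon - train.tS) / train.tau))
    return train.tS + train.tau * np.arange(n + 1)


def simulate_periodic(
    params: ModelParams,
    train: PulseTrain,
    init: Full9State,
    horizon: float,
    *,
    t0: float = 0.0,
    sample_dt: float | None = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dt_max: float | None = None,
    stop_when: Callable[[float, np.ndarray], bool] | None = None,
) -> Trajectory:
    """Integrate the full impulsive system.

    ``sample_dt`` sets the output grid (None records segment endpoints only,
    the cheap mode used by the elimination classifier).  ``stop_when(t, y)``
    is checked at every release instant and truncates the run early when it
    returns True; the trajectory then ends at that instant.
    """
    if horizon <= t0:
        raise ValueError("horizon must exceed t0")
    y = init.to_array()
    pulses = release_times(train, horizon)
    pulses = pulses[pulses >= t0]
    # segment boundaries: t0, each release instant, horizon
    bounds = np.unique(np.concatenate([[t0], pulses, [horizon]]))
    grid = None
    if sample_dt is not None:
        grid = np.arange(t0, horizon + 0.5 * sample_dt, sample_dt)

    fun = lambda t, s: rhs_full(s, t, params, 0.0)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    pulse_set = set(np.round(pulses, 9))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if round(a, 9) in pulse_set:
            y = y.copy()
            y[8] += train.pulse_size
            if stop_when is not None and stop_when(a, y):
                times_out.append(np.array([a]))
                states_out.append(y[None, :])
                break
        if sample_dt is not None:
            t_eval = np.unique(np.concatenate([grid[(grid > a) & (grid < b)], [a, b]]))
        else:
            t_eval = np.array([a, b])
        t_leg, y_leg = _integrate(fun, y, a, b, t_eval, rtol, atol, dt_max)
        times_out.append(t_leg)
        states_out.append(y_leg)
        y = y_leg[-1]

    times = np.concatenate(times_out)
    states = np.concatenate(states_out)
    # keep duplicate times at jumps (left/right limits of MS)
    return Trajectory(
        times=times,
        states=states,
        fields=FULL9_FIELDS,
        meta={"params": params, "train": train, "t0": t0, "horizon": horizon},
    )


def bounding_system_simulate(
    params: ModelParams,
    train: PulseTrain,
    which: str,
    init: Reduced7State,
    horizon: float,
    *,
    t0: float = 0.0,
    sample_dt: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the monotone bounding system (reduced flow with MS frozen).

    ``which='upper'`` freezes MS at the waveform maximum (most suppression,
    hence a lower bound on the wild compartments); ``which='lower'`` at the
    minimum (least suppression, an upper bound).
    """
    lo, hi = ms_periodic_bounds(train)
    try:
        MS = {"upper": hi, "lower": lo}[which]
    except KeyError:
        raise ValueError("which must be 'upper' or 'lower'") from None
    grid = np.arange(t0, horizon + 0.5 * sample_dt, sample_dt)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    fun = lambda t, s: rhs_reduced(s, t, params, MS)
    times, states = _integrate(fun, init.to_array(), t0, horizon, grid, rtol, atol, None)
    return Trajectory(
        times=times,
        states=states,
        fields=("A", "M", "FW", "FS", "FWW", "FWS", "FSW"),
        meta={"params": params, "train": train, "which": which, "MS": MS},
    )
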