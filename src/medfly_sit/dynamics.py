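"""Vector fields and time integration for continuous or zero releases.

Three nested systems share one bookkeeping convention (see ``states``):

* the full 9-state flow, with sterile males ``MS`` driven by a release rate
  ``u(t)``;
* the reduced 7-state flow, where ``MS`` is an exogenous constant (its own
  equation is autonomous and settles at ``Lambda/muS``) and the pure-sink
  ``FSS`` compartment is dropped;
* the wild-only 4-state flow obtained with no sterile males at all.

Integration uses an adaptive stiff-capable solver (LSODA) with output
clipping at zero; positivity and step-size convergence are asserted in the
test suite rather than guaranteed by a bespoke scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import LifeHistoryParams, ModelParams, ReleasePolicy
from .states import FULL9_FIELDS, Full9State, Reduced7State, Wild4State
from .thresholds import mating_fractions

__all__ = [
    "IntegrationError",
    "Trajectory",
    "rhs_full",
    "rhs_reduced",
    "rhs_wild",
    "simulate",
    "simulate_wild",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the solver fails or produces non-finite state."""


@dataclass
class Trajectory:
    """Sampled solution: ``times`` (days) against rows of ``states``."""

    times: np.ndarray
    states: np.ndarray
    fields: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.fields.index(name)]

    def final(self) -> np.ndarray:
        return self.states[-1]

    def wild_total(self) -> np.ndarray:
        """Total wild-origin population over time (all compartments but MS)."""
        cols = [i for i, f in enumerate(self.fields) if f != "MS"]
        return self.states[:, cols].sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(self.fields)).assign(t=self.times)[
            ["t", *self.fields]
        ]

    def to_csv(self, path: str | Path) -> None:
        """Write ``t,<fields...>`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str) + "\n")


def rhs_full(state: Sequence[float], t: float, params: ModelParams, u: float) -> np.ndarray:
    """Right-hand side of the full 9-state system with release rate ``u``."""
    A, M, FW, FS, FWW, FWS, FSW, FSS, MS = state
    life, rem, st = params.life, params.rem, params.sterile
    pW, pS = mating_fractions(max(M, 0.0), max(MS, 0.0), st.gamma, st.eps)
    births = (life.bW * FW + life.bWW * FWW + life.bSW * FSW + life.bWS * FWS) * (
        1.0 - A / life.K
    )
    rnuA_A = life.r * life.nuA * A
    return np.array(
        [
            births - (life.nuA + life.muA) * A,
            (1.0 - life.r) * life.nuA * A - life.muM * M,
            rnuA_A * pW - (rem.delta + life.muF) * FW,
            rnuA_A * pS - (rem.deltaS + life.muF) * FS,
            rem.delta * pW * FW - life.muFWW * FWW,
            rem.delta * pS * FW - life.muFWS * FWS,
            rem.deltaS * pW * FS - life.muFSW * FSW,
            rem.deltaS * pS * FS - life.muF * FSS,
            u - st.muS * MS,
        ]
    )


def rhs_reduced(state: Sequence[float], t: float, params: ModelParams, MSvalue: float) -> np.ndarray:
    """Right-hand side of the reduced 7-state system with exogenous ``MSvalue``."""
    A, M, FW, FS, FWW, FWS, FSW = state
    life, rem, st = params.life, params.rem, params.sterile
    pW, pS = mating_fractions(max(M, 0.0), max(MSvalue, 0.0), st.gamma, st.eps)
    births = (life.bW * FW + life.bWW * FWW + life.bSW * FSW + life.bWS * FWS) * (
        1.0 - A / life.K
    )
    rnuA_A = life.r * life.nuA * A
    return np.array(
        [
            births - (life.nuA + life.muA) * A,
            (1.0 - life.r) * life.nuA * A - life.muM * M,
            rnuA_A * pW - (rem.delta + life.muF) * FW,
            rnuA_A * pS - (rem.deltaS + life.muF) * FS,
            rem.delta * pW * FW - life.muFWW * FWW,
            rem.delta * pS * FW - life.muFWS * FWS,
            rem.deltaS * pW * FS - life.muFSW * FSW,
        ]
    )


def rhs_wild(state: Sequence[float], t: float, life: LifeHistoryParams, delta: float) -> np.ndarray:
    """Right-hand side of the wild-only 4-state system (no sterile males)."""
    A, M, FW, FWW = state
    births = (life.bW * FW + life.bWW * FWW) * (1.0 - A / life.K)
    return np.array(
        [
            births - (life.nuA + life.muA) * A,
            (1.0 - life.r) * life.nuA * A - life.muM * M,
            life.r * life.nuA * A - (delta + life.muF) * FW,
            delta * FW - life.muFWW * FWW,
        ]
    )


def _integrate(
    fun: Callable,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray | None,
    rtol: float,
    atol: float,
    max_step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One solve_ivp leg with clipping and failure diagnostics."""
    sol = solve_ivp(
        fun,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step if max_step is not None else np.inf,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed on [{t0}, {t1}]: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"non-finite state encountered on [{t0}, {t1}]")
    return sol.t, np.clip(sol.y.T, 0.0, None)


def _sample_grid(t0: float, horizon: float, sample_dt: float) -> np.ndarray:
    grid = np.arange(t0, horizon, sample_dt, dtype=float)
    if grid.size == 0 or grid[-1] < horizon:
        grid = np.append(grid, horizon)
    return grid


def simulate(
    params: ModelParams,
    policy: ReleasePolicy,
    init: Full9State,
    horizon: float,
    *,
    t0: float = 0.0,
    dt_max: float | None = None,
    sample_dt: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the full system under no release or a continuous release.

    A continuous release switches on at ``policy.tS`` (set ``tS=0`` for a
    release active from the start); periodic policies are handled by
    :func:`medfly_sit.impulsive.simulate_periodic`.  Output is sampled on a
    fixed ``sample_dt`` grid (1 day by default, matching the daily rates).
    """
    if horizon <= t0:
        raise ValueError("horizon must exceed t0")
    if policy.mode == "periodic":
        raise ValueError("use impulsive.simulate_periodic for periodic policies")
    y0 = init.to_array()
    grid = _sample_grid(t0, horizon, sample_dt)

    def leg(u: float, a: float, b: float, y: np.ndarray):
        # segment endpoints always evaluated so the last row seeds the next leg
        t_eval = np.unique(np.concatenate([grid[(grid >= a) & (grid <= b)], [a, b]]))
        fun = lambda t, s: rhs_full(s, t, params, u)
        return _integrate(fun, y, a, b, t_eval, rtol, atol, dt_max)

    pieces_t, pieces_y = [], []
    if policy.mode == "continuous" and t0 < policy.tS < horizon:
        t_a, y_a = leg(0.0, t0, policy.tS, y0)
        pieces_t.append(t_a)
        pieces_y.append(y_a)
        t_b, y_b = leg(policy.Lambda, policy.tS, horizon, y_a[-1])
        pieces_t.append(t_b)
        pieces_y.append(y_b)
    else:
        u = policy.Lambda if policy.mode == "continuous" and policy.tS <= t0 else 0.0
        t_a, y_a = leg(u, t0, horizon, y0)
        pieces_t.append(t_a)
        pieces_y.append(y_a)

    times = np.concatenate(pieces_t)
    states = np.concatenate(pieces_y)
    times, idx = np.unique(times, return_index=True)
    return Trajectory(
        times=times,
        states=states[idx],
        fields=FULL9_FIELDS,
        meta={"params": params, "policy": policy, "t0": t0, "horizon": horizon},
    )


def simulate_wild(
    life: LifeHistoryParams,
    delta: float,
    init: Wild4State,
    horizon: float,
    *,
    t0: float = 0.0,
    dt_max: float | None = None,
    sample_dt: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the wild-only 4-state system."""
    grid = _sample_grid(t0, horizon, sample_dt)
    fun = lambda t, s: rhs_wild(s, t, life, delta)
    times, states = _integrate(fun, init.to_array(), t0, horizon, grid, rtol, atol, dt_max)
    return Trajectory(times=times, states=states, fields=("A", "M", "FW", "FWW"),
                      meta={"life": life, "delta": delta})
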