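"""Critical sterile-male release rates.

Continuous releases: at steady state with ``MS* = Lambda/muS`` the reduced
system collapses, after eliminating every compartment in favour of the wild
males ``M``, to one scalar condition ``g(M) = 0`` (see
:func:`equilibrium_equation`).  Scanning ``g`` over the admissible range of
``M`` counts the positive equilibria; the fold pattern as the release rate
grows is 1 root (no release) -> 2 roots (bistable: Allee threshold below an
attracting persistence state) -> 0 roots (elimination), and the critical rate
``Lambda_cont`` is located by bisection on the 2 -> 0 transition.

Periodic releases: no scalar reduction exists, so the critical pulsed rate is
bracketed by the monotone-bounding inequality

    (1 - e^{-muS tau})/(tau muS) * Lambda_cont
        <= Lambda_per <= (e^{muS tau} - 1)/(tau muS) * Lambda_cont

and refined by bisection on elimination-vs-persistence of full impulsive
simulations started from the wild equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .impulsive import PulseTrain, simulate_periodic
from .params import EquilibriumSet, ModelParams
from .states import Reduced7State
from .thresholds import epsilon_max, mating_fractions, wild_equilibrium

__all__ = [
    "NoFiniteCriticalRate",
    "CriticalResult",
    "equilibrium_equation",
    "back_substitute",
    "count_positive_equilibria",
    "critical_release_continuous",
    "classify_outcome",
    "critical_release_periodic",
]

#: default settings of the elimination/persistence classifier
CLASSIFIER_DEFAULTS = dict(horizon=15000.0, elim_frac=1e-6, persist_frac=1e-2,
                           persist_rel_change=1e-3, persist_window=20)


class NoFiniteCriticalRate(RuntimeError):
    """Raised when eps >= eps_max: a positive steady state survives any
    release rate, so no finite critical rate exists."""


@dataclass
class CriticalResult:
    """Outcome of a critical-rate search.

    ``value`` is the release rate (individuals/day); ``ratio`` expresses it in
    the field's operational currency, sterile males per wild male at the
    pre-release equilibrium: ``Lambda/M0*`` for continuous releases and
    ``tau*LambdaPer/M0*`` (sterile males per pulse per wild male) for periodic
    ones.
    """

    mode: str
    value: float
    ratio: float
    bracket: tuple[float, float]
    M0star: float
    tau: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _m_max(params: ModelParams) -> float:
    life = params.life
    return (1.0 - life.r) * life.nuA * life.K / life.muM


def equilibrium_equation(M, params: ModelParams, Lambda: float):
    """Scalar equilibrium residual g(M) for the constant-release system.

    With ``MS* = Lambda/muS`` and mating fractions evaluated at ``M``, the
    per-immature offspring rate is::

        beta(M) = r nuA [ pW (bW + delta pW bWW/muFWW + delta pS bWS/muFWS)/(delta+muF)
                          + pS deltaS pW (bSW/muFSW)/(deltaS+muF) ]

    and ``g(M) = beta(M) (1 - A(M)/K) - (nuA + muA)`` with
    ``A(M) = muM M / ((1-r) nuA)``.  Roots of g on (0, Mmax) are exactly the
    wild-male components of the positive equilibria.  Accepts scalars or
    arrays.
    """
    life, rem, st = params.life, params.rem, params.sterile
    M_arr = np.asarray(M, dtype=float)
    scalar = M_arr.ndim == 0
    M_arr = np.atleast_1d(M_arr)
    Mmax = _m_max(params)
    if np.any((M_arr <= 0) | (M_arr >= Mmax)):
        raise ValueError(f"M must lie in (0, Mmax={Mmax:.6g})")
    MS = Lambda / st.muS
    denom = M_arr + st.gamma * MS
    pW = np.where(denom > 0, (M_arr + st.eps * st.gamma * MS) / denom, 0.0)
    pS = np.where(denom > 0, (1.0 - st.eps) * st.gamma * MS / denom, 0.0)
    beta = life.r * life.nuA * (
        pW
        * (life.bW + rem.delta * pW * life.bWW / life.muFWW
           + rem.delta * pS * life.bWS / life.muFWS)
        / (rem.delta + life.muF)
        + pS * rem.deltaS * pW * (life.bSW / life.muFSW) / (rem.deltaS + life.muF)
    )
    A = life.muM * M_arr / ((1.0 - life.r) * life.nuA)
    g = beta * (1.0 - A / life.K) - (life.nuA + life.muA)
    return float(g[0]) if scalar else g


def back_substitute(M: float, params: ModelParams, Lambda: float) -> Reduced7State:
    """Rebuild the full reduced state from the wild-male component of a root."""
    life, rem, st = params.life, params.rem, params.sterile
    MS = Lambda / st.muS
    pW, pS = mating_fractions(M, MS, st.gamma, st.eps)
    A = life.muM * M / ((1.0 - life.r) * life.nuA)
    FW = life.r * life.nuA * pW * A / (rem.delta + life.muF)
    FS = life.r * life.nuA * pS * A / (rem.deltaS + life.muF)
    FWW = rem.delta * pW * FW / life.muFWW
    FWS = rem.delta * pS * FW / life.muFWS
    FSW = rem.deltaS * pW * FS / life.muFSW
    return Reduced7State(A, M, FW, FS, FWW, FWS, FSW)


def count_positive_equilibria(
    params: ModelParams, Lambda: float, n_grid: int = 2000
) -> EquilibriumSet:
    """Count and locate the positive equilibria at release rate ``Lambda``.

    Dense sign scan of g on (0, Mmax) — log-spaced near zero (where the Allee
    threshold root lives) plus a uniform tail — with brentq polishing of every
    bracketed sign change.
    """
    Mmax = _m_max(params)
    n_log = n_grid // 2
    grid = np.unique(
        np.concatenate(
            [
                np.geomspace(Mmax * 1e-12, Mmax * 0.1, n_log),
                np.linspace(Mmax * 0.1, Mmax * (1.0 - 1e-9), n_grid - n_log),
            ]
        )
    )
    g = equilibrium_equation(grid, params, Lambda)
    roots: list[float] = []
    sign_change = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    for i in sign_change:
        roots.append(brentq(lambda m: equilibrium_equation(m, params, Lambda),
                            grid[i], grid[i + 1], xtol=1e-14 * Mmax, rtol=1e-14))
    # exact zeros on the grid (vanishingly rare, but keep the scan airtight)
    roots.extend(grid[g == 0.0].tolist())
    roots = sorted(roots)
    entries = []
    for j, m in enumerate(roots):
        label = "lower-unstable" if len(roots) == 2 and j == 0 else "upper-stable"
        entries.append((m, back_substitute(m, params, Lambda), label))
    return EquilibriumSet(roots=tuple(entries), count=len(entries))


def critical_release_continuous(
    params: ModelParams, tol: float = 1e-3, n_grid: int = 2000
) -> CriticalResult:
    """Critical continuous release rate, by bisection on the root count.

    Requires R(delta) > 1 (a wild population to fight) and eps < eps_max
    (raises :class:`NoFiniteCriticalRate` otherwise).  ``tol`` is relative on
    Lambda.
    """
    life, rem, st = params.life, params.rem, params.sterile
    eq0 = wild_equilibrium(life, rem.delta)  # raises if R <= 1
    if st.eps >= epsilon_max(params):
        raise NoFiniteCriticalRate(
            f"eps={st.eps} >= eps_max={epsilon_max(params):.6g}: a positive steady "
            "state persists for any release rate"
        )
    M0 = eq0.M
    probes: list[tuple[float, int]] = []

    def n_roots(lam: float) -> int:
        n = count_positive_equilibria(params, lam, n_grid=n_grid).count
        probes.append((lam, n))
        return n

    lo, hi = 0.0, st.muS * M0  # hi ~ release sustaining MS = M0*
    while n_roots(hi) > 0:
        lo = hi
        hi *= 2.0
        if hi > 1e12 * st.muS * M0:
            raise RuntimeError("failed to bracket the critical release rate")
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if n_roots(mid) > 0:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    return CriticalResult(
        mode="continuous",
        value=lam,
        ratio=lam / M0,
        bracket=(lo, hi),
        M0star=M0,
        diagnostics={"probes": probes},
    )


def classify_outcome(
    params: ModelParams,
    train: PulseTrain,
    *,
    horizon: float = CLASSIFIER_DEFAULTS["horizon"],
    elim_frac: float = CLASSIFIER_DEFAULTS["elim_frac"],
    persist_frac: float = CLASSIFIER_DEFAULTS["persist_frac"],
    persist_rel_change: float = CLASSIFIER_DEFAULTS["persist_rel_change"],
    persist_window: int = CLASSIFIER_DEFAULTS["persist_window"],
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> str:
    """Classify a pulsed-release programme as ``'elimination'``,
    ``'persistence'`` or ``'undecided'``.

    The run starts from the wild equilibrium with all sterile-related
    compartments empty (the pre-release burn-in pattern).  Elimination: total
    wild-origin population falls below ``elim_frac`` of its pre-release value.
    Persistence: the mean total over the last ``persist_window`` release
    periods exceeds ``persist_frac`` of pre-release and two consecutive such
    window means differ by less than ``persist_rel_change`` (convergence to a
    positive periodic orbit).
    """
    eq = wild_equilibrium(params.life, params.rem.delta)
    init = eq.to_full9()
    total0 = init.wild_total()
    window_totals: list[float] = []
    prev_mean = {"val": None}
    outcome = {"flag": None}

    def stop_when(t: float, y: np.ndarray) -> bool:
        if t <= train.tS:
            return False
        total = float(np.sum(y[:8]))
        if total < elim_frac * total0:
            outcome["flag"] = "elimination"
            return True
        window_totals.append(total)
        if len(window_totals) >= persist_window:
            mean = float(np.mean(window_totals[-persist_window:]))
            if len(window_totals) % persist_window == 0:
                if (
                    prev_mean["val"] is not None
                    and mean > persist_frac * total0
                    and abs(mean - prev_mean["val"]) < persist_rel_change * mean
                ):
                    outcome["flag"] = "persistence"
                    return True
                prev_mean["val"] = mean
        return False

    simulate_periodic(
        params, train, init, horizon,
        sample_dt=None, rtol=rtol, atol=atol, stop_when=stop_when,
    )
    return outcome["flag"] or "undecided"


def critical_release_periodic(
    params: ModelParams,
    tau: float,
    *,
    tol_ratio: float = 0.25,
    tS: float = 100.0,
    horizon: float = CLASSIFIER_DEFAULTS["horizon"],
    classifier_kwargs: dict | None = None,
    continuous_result: CriticalResult | None = None,
) -> CriticalResult:
    """Critical pulsed release rate for period ``tau``.

    Bisects the pulse ratio ``tau*LambdaPer/M0*`` between the monotone-system
    brackets derived from the continuous critical rate, classifying each probe
    by simulation.  ``tol_ratio`` is absolute on the pulse ratio (0.25 by
    default, about the integer resolution at which release programmes are
    planned).  An undecided probe retries once with a doubled horizon, then
    fails loudly.
    """
    st = params.sterile
    cont = continuous_result or critical_release_continuous(params)
    M0 = cont.M0star
    x = st.muS * tau
    lam_lo = (1.0 - np.exp(-x)) / x * cont.value
    lam_hi = (np.exp(x) - 1.0) / x * cont.value
    r_lo = tau * lam_lo / M0
    r_hi = tau * lam_hi / M0
    kwargs = dict(classifier_kwargs or {})
    kwargs.setdefault("horizon", horizon)
    probes: list[tuple[float, str]] = []

    def classify(ratio: float) -> str:
        train = PulseTrain(tau=tau, LambdaPer=ratio * M0 / tau, muS=st.muS, tS=tS)
        res = classify_outcome(params, train, **kwargs)
        if res == "undecided":
            retry = dict(kwargs)
            retry["horizon"] = 2.0 * kwargs["horizon"]
            res = classify_outcome(params, train, **retry)
            if res == "undecided":
                raise RuntimeError(
                    f"classifier undecided at ratio={ratio:.3f} even with extended horizon"
                )
        probes.append((ratio, res))
        return res

    # Prop-2 guarantees persistence below r_lo and elimination above r_hi;
    # bisect the bracket (already narrower than tol_ratio for tiny tau).
    while r_hi - r_lo > tol_ratio:
        mid = 0.5 * (r_lo + r_hi)
        if classify(mid) == "elimination":
            r_hi = mid
        else:
            r_lo = mid
    ratio = 0.5 * (r_lo + r_hi)
    return CriticalResult(
        mode="periodic",
        value=ratio * M0 / tau,
        ratio=ratio,
        bracket=(r_lo, r_hi),
        M0star=M0,
        tau=tau,
        diagnostics={"probes": probes, "continuous": cont},
    )
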