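"""Closed-form quantities of the SIT model.

Basic offspring numbers, the re-mating trade-off term, the residual-fertility
ceiling ``eps_max`` below which massive sterile-male releases make the extinct
state locally stable (strong Allee effect), the wild-population equilibrium,
and the linearised per-immature offspring sum at the origin that ties them all
together.

Throughout, ``N(delta)`` is the expected lifetime female offspring of a
once-mated female and ``R(delta) >= N(delta)`` adds the contribution of the
double-wild-mated class ``FWW``::

    N(delta) = bW * r * nuA / ((nuA + muA) * (muF + delta))
    R(delta) = N(delta) * (1 + (bWW / bW) * (delta / muFWW))
"""

from __future__ import annotations

import math
import warnings

from .params import LifeHistoryParams, ModelParams
from .states import Wild4State

__all__ = [
    "NoPositiveEquilibrium",
    "mating_fractions",
    "basic_offspring_N",
    "basic_offspring_R",
    "remating_tradeoff_F",
    "offspring_sum",
    "origin_linearization",
    "epsilon_max",
    "wild_equilibrium",
]


class NoPositiveEquilibrium(ValueError):
    """Raised when R(delta) <= 1: the wild population cannot establish and
    the origin is globally stable without any releases."""


def mating_fractions(M: float, MS: float, gamma: float, eps: float) -> tuple[float, float]:
    """Fertilising and sterilising mating probabilities.

    A newly mature female mates a wild male with probability M/(M + gamma*MS)
    and a sterile male otherwise; a fraction ``eps`` of sterile males carries
    fertile sperm, so the female ends up fertilised with probability

        pW = (M + eps*gamma*MS) / (M + gamma*MS)

    and sterilised with probability ``pS = (1-eps)*gamma*MS / (M + gamma*MS)``.
    When no males of either kind are present there is no mating and (0, 0) is
    returned, which keeps the origin an equilibrium of the flow.
    """
    if M < 0 or MS < 0:
        raise ValueError("male counts must be nonnegative")
    denom = M + gamma * MS
    if denom == 0.0:
        return 0.0, 0.0
    pW = (M + eps * gamma * MS) / denom
    pS = (1.0 - eps) * gamma * MS / denom
    return pW, pS


def basic_offspring_N(life: LifeHistoryParams, delta: float) -> float:
    """Basic offspring number of a once-mated female, N(delta)."""
    return life.bW * life.r * life.nuA / ((life.nuA + life.muA) * (life.muF + delta))


def basic_offspring_R(life: LifeHistoryParams, delta: float) -> float:
    """Basic offspring number including the double-wild-mated class, R(delta)."""
    N = basic_offspring_N(life, delta)
    return N * (1.0 + (life.bWW / life.bW) * (delta / life.muFWW))


def remating_tradeoff_F(params: ModelParams) -> float:
    """Re-mating trade-off term F(delta, deltaS).

    Negative F means re-mating reduces the impact of SIT (the sterile-then-wild
    path outweighs the gain from double-wild matings); F >= 0 means re-mating
    is neutral or beneficial.  In particular F = 0 when there is no re-mating,
    and F < 0 in the worst case delta = 0 < deltaS where only females mated by
    a sterile male re-mate.
    """
    life, rem = params.life, params.rem
    return rem.delta * (life.bWW / life.muFWW - life.bWS / life.muFWS) - rem.deltaS * (
        life.bSW / life.muFSW
    ) * (rem.delta + life.muF) / (rem.deltaS + life.muF)


def offspring_sum(params: ModelParams, eps: float) -> float:
    """Linearised per-immature offspring sum E(eps) at the origin under
    sterile-male saturation.

    With the wild population near zero and sterile males maintained at any
    positive level, the mating fractions degenerate to pW = eps, pS = 1 - eps
    and the next-generation offspring of one immature individual is::

        E(eps) = r*nuA/(nuA+muA) * {
            eps*[bW + delta*eps*bWW/muFWW + delta*(1-eps)*bWS/muFWS]/(delta+muF)
            + (1-eps)*deltaS*eps*(bSW/muFSW)/(deltaS+muF) }

    The origin is locally asymptotically stable iff E(eps) < 1, and
    ``epsilon_max`` is exactly the root of E(eps) = 1 in (0, 1].
    """
    life, rem = params.life, params.rem
    c = life.r * life.nuA / (life.nuA + life.muA)
    fertile_path = (
        eps
        * (
            life.bW
            + rem.delta * eps * life.bWW / life.muFWW
            + rem.delta * (1.0 - eps) * life.bWS / life.muFWS
        )
        / (rem.delta + life.muF)
    )
    sterile_then_wild = (
        (1.0 - eps) * rem.deltaS * eps * (life.bSW / life.muFSW) / (rem.deltaS + life.muF)
    )
    return c * (fertile_path + sterile_then_wild)


def origin_linearization(params: ModelParams, MSbar: float) -> tuple[float, bool]:
    """Stability of the extinct state under a constant sterile-male level.

    Returns ``(E, stable)`` where E is the offspring sum of
    :func:`offspring_sum` and ``stable`` is ``E < 1``.  ``MSbar`` must be
    positive — with no sterile males at all the origin's stability is governed
    by R(delta) instead (Theorem-1 regime).
    """
    if MSbar <= 0:
        raise ValueError("MSbar must be > 0 (sterile-male saturation at the origin)")
    E = offspring_sum(params, params.sterile.eps)
    return E, E < 1.0


def epsilon_max(params: ModelParams) -> float:
    """Residual-fertility ceiling: the largest eps for which massive releases
    stabilise the extinct state.

    Solves the origin-linearisation quadratic ``N*Fhat*eps^2 + N*(1+a)*eps - 1
    = 0`` for its root in (0, 1], where ``N = N(delta)``, ``Fhat = F/bW`` is
    the normalised re-mating trade-off and ``a`` collects the sterilised
    re-mating paths.  Without re-mating this collapses to ``1/R(0)``.  When
    even eps = 1 leaves E(eps) < 1 (a population too weak to rebound), the
    ceiling is capped at 1 with a warning.
    """
    life, rem = params.life, params.rem
    N = basic_offspring_N(life, rem.delta)
    a = (rem.deltaS / life.muFSW) * (life.bSW / life.bW) * (
        (rem.delta + life.muF) / (rem.deltaS + life.muF)
    ) + (rem.delta / life.muFWS) * (life.bWS / life.bW)
    Fhat = remating_tradeoff_F(params) / life.bW
    b = N * (1.0 + a)  # linear coefficient; also E'(0)
    disc = b * b + 4.0 * N * Fhat
    if disc < 0.0:
        warnings.warn(
            "epsilon_max quadratic has no real root (strongly negative trade-off); "
            "capping at 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    if N * Fhat == 0.0:
        eps = 1.0 / b if b > 0 else math.inf
    else:
        # smaller positive root, written in cancellation-safe form
        eps = 2.0 / (b + math.sqrt(disc))
    if eps > 1.0:
        warnings.warn(
            "offspring sum stays below 1 on (0, 1]: origin stable for any residual "
            "fertility; epsilon_max capped at 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    return eps


def wild_equilibrium(life: LifeHistoryParams, delta: float) -> Wild4State:
    """Positive equilibrium of the wild-only system.

    Exists iff R(delta) > 1 and is then globally attracting away from the
    female-free axis::

        A*   = (1 - 1/R) K
        M*   = (1-r) nuA / muM * A*
        FW*  = r nuA / (delta + muF) * A*
        FWW* = delta / muFWW * FW*

    Raises :class:`NoPositiveEquilibrium` when R(delta) <= 1.
    """
    R = basic_offspring_R(life, delta)
    if R <= 1.0:
        raise NoPositiveEquilibrium(
            f"R(delta)={R:.4g} <= 1: no positive wild equilibrium; origin globally stable"
        )
    A = (1.0 - 1.0 / R) * life.K
    M = (1.0 - life.r) * life.nuA / life.muM * A
    FW = life.r * life.nuA / (delta + life.muF) * A
    FWW = delta / life.muFWW * FW
    return Wild4State(A, M, FW, FWW)
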