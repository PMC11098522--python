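"""Parameter containers for the medfly SIT model.

All rates are per day and all population quantities are head counts.  The
containers are plain frozen dataclasses with validation on construction and a
flat JSON round-trip (see :func:`params_to_json` / :func:`params_from_json`);
a machine-readable schema ships with the package (``params_schema.json``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

__all__ = [
    "LifeHistoryParams",
    "RematingParams",
    "SterileParams",
    "ReleasePolicy",
    "ModelParams",
    "EquilibriumSet",
    "params_to_json",
    "params_from_json",
]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Wild-population life-history rates.

    Parameters
    ----------
    bW, bWW, bWS, bSW
        Viable (hatched) eggs laid per female per day for once-mated females
        (``bW``) and for the three fertile double-mated classes: twice by a
        wild male (``bWW``), wild-then-sterile (``bWS``), sterile-then-wild
        (``bSW``).
    nuA
        Maturation rate out of the non-flying stage (larvae + pupae).
    muA
        Mortality of the non-flying stage.
    r
        Female fraction at emergence, in (0, 1).
    muM
        Wild-male mortality.
    muF
        Mortality of once-mated females and of females mated twice by sterile
        males.
    muFWW, muFWS, muFSW
        Mortality of the respective fertile double-mated female classes.
    K
        Carrying capacity of the non-flying stage (larvae/pupae supported by
        the host fruits).
    """

    bW: float
    bWW: float
    bWS: float
    bSW: float
    nuA: float
    muA: float
    r: float
    muM: float
    muF: float
    muFWW: float
    muFWS: float
    muFSW: float
    K: float = 1.0e4

    def __post_init__(self) -> None:
        for name in ("bW", "nuA", "muA", "muM", "muF", "muFWW", "muFWS", "muFSW", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("bWW", "bWS", "bSW"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"r must lie in (0, 1), got {self.r}")


@dataclass(frozen=True)
class RematingParams:
    """Female re-mating rates.

    ``1/delta`` and ``1/deltaS`` are the mean refractory periods after mating
    a wild and a sterile male.  Females mated with a sterile male tend to
    re-mate faster, so ``deltaS >= delta`` is the standing assumption; other
    orderings are accepted with a warning.
    """

    delta: float = 0.0
    deltaS: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.deltaS < 0:
            raise ValueError("re-mating rates must be nonnegative")
        if self.deltaS < self.delta:
            warnings.warn(
                "deltaS < delta violates the standing assumption deltaS >= delta >= 0",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SterileParams:
    """Sterile-male quality parameters.

    ``gamma`` is the mating competitiveness of a sterile male relative to a
    wild one (derived from the Relative Sterility Index as RSI/(1-RSI));
    ``eps`` is the residual fertility, the fraction of fertile sperm among
    released males.
    """

    muS: float
    gamma: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.muS <= 0:
            raise ValueError("muS must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.eps < 1.0:
            raise ValueError("eps must lie in [0, 1)")


@dataclass(frozen=True)
class ReleasePolicy:
    """Sterile-male release programme.

    ``continuous`` supplies ``Lambda`` males per day; ``periodic`` adds
    ``tau * LambdaPer`` males instantaneously every ``tau`` days starting at
    ``tS``; ``none`` releases nothing.
    """

    mode: Literal["continuous", "periodic", "none"] = "none"
    Lambda: float = 0.0
    tau: float = 7.0
    LambdaPer: float = 0.0
    tS: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "periodic", "none"):
            raise ValueError(f"unknown release mode {self.mode!r}")
        if self.Lambda < 0 or self.LambdaPer < 0:
            raise ValueError("release rates must be >= 0")
        if self.mode == "periodic" and self.tau <= 0:
            raise ValueError("tau must be > 0 in periodic mode")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation: life history + re-mating + sterile-male quality."""

    life: LifeHistoryParams
    rem: RematingParams = field(default_factory=RematingParams)
    sterile: SterileParams = field(default_factory=lambda: SterileParams(muS=0.2310, gamma=0.6129))

    def with_eps(self, eps: float) -> "ModelParams":
        """Copy with a different residual fertility."""
        return replace(self, sterile=replace(self.sterile, eps=eps))

    def with_K(self, K: float) -> "ModelParams":
        """Copy with a different carrying capacity."""
        return replace(self, life=replace(self.life, K=K))


@dataclass(frozen=True)
class EquilibriumSet:
    """Positive equilibria of the constant-release system at a given Lambda.

    ``roots`` holds ``(M, state, classification)`` triples sorted by ascending
    wild-male count M; classification is ``"lower-unstable"`` or
    ``"upper-stable"`` following the fold structure (the smaller equilibrium
    is the Allee threshold, the larger one attracts).
    """

    roots: tuple
    count: int

    def __post_init__(self) -> None:
        if self.count != len(self.roots):
            raise ValueError("count must match number of roots")
        Ms = [r[0] for r in self.roots]
        if Ms != sorted(Ms):
            raise ValueError("roots must be sorted ascending in M")


def params_to_json(params: ModelParams, path: str | Path | None = None) -> str:
    """Serialise ``ModelParams`` to the canonical JSON layout."""
    obj = {
        "life": asdict(params.life),
        "rem": asdict(params.rem),
        "sterile": asdict(params.sterile),
    }
    text = json.dumps(obj, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def params_from_json(source: str | Path) -> ModelParams:
    """Load ``ModelParams`` from a JSON string or file path."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
        obj = json.loads(Path(source).read_text())
    else:
        obj = json.loads(source)
    return ModelParams(
        life=LifeHistoryParams(**obj["life"]),
        rem=RematingParams(**obj["rem"]),
        sterile=SterileParams(**obj["sterile"]),
    )
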