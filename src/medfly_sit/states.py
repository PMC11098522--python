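"""State vectors for the full, reduced and wild-only systems.

Component order is fixed and shared with the trajectory CSV export:

* ``Full9State``:   (A, M, FW, FS, FWW, FWS, FSW, FSS, MS)
* ``Reduced7State``: (A, M, FW, FS, FWW, FWS, FSW) — sterile males held at an
  exogenous level, the pure-sink FSS compartment dropped
* ``Wild4State``:   (A, M, FW, FWW) — no sterile males at all
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["Full9State", "Reduced7State", "Wild4State", "FULL9_FIELDS"]

FULL9_FIELDS = ("A", "M", "FW", "FS", "FWW", "FWS", "FSW", "FSS", "MS")


class Full9State(NamedTuple):
    A: float
    M: float
    FW: float
    FS: float
    FWW: float
    FWS: float
    FSW: float
    FSS: float
    MS: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Full9State":
        return cls(*map(float, arr))

    def wild_total(self) -> float:
        """Total wild-origin population (everything except released males)."""
        return float(sum(self[:8]))


class Reduced7State(NamedTuple):
    A: float
    M: float
    FW: float
    FS: float
    FWW: float
    FWS: float
    FSW: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Reduced7State":
        return cls(*map(float, arr))


class Wild4State(NamedTuple):
    A: float
    M: float
    FW: float
    FWW: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Wild4State":
        return cls(*map(float, arr))

    def to_full9(self) -> Full9State:
        """Embed as a full state with every sterile-related compartment at 0."""
        return Full9State(self.A, self.M, self.FW, 0.0, self.FWW, 0.0, 0.0, 0.0, 0.0)
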