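"""Shared fixtures: scenario presets and randomized-parameter draws."""

from __future__ import annotations

import numpy as np
import pytest

from medfly_sit import (
    LifeHistoryParams,
    ModelParams,
    RematingParams,
    ScenarioSpec,
    SterileParams,
    build_preset,
)


@pytest.fixture(scope="session")
def peach_case1():
    """Case-1 preset, differential re-mating, no GRO."""
    return build_preset(ScenarioSpec(case_id=1, remating_mode="differential", gro=False))


@pytest.fixture(scope="session")
def peach_case2():
    """Case-2 preset, differential re-mating, no GRO (the reference scenario
    for periodic-release simulations)."""
    return build_preset(ScenarioSpec(case_id=2, remating_mode="differential", gro=False))


@pytest.fixture(scope="session")
def peach_case2_gro():
    return build_preset(ScenarioSpec(case_id=2, remating_mode="differential", gro=True))


def random_params(rng: np.random.Generator, K: float = 1.0e4) -> ModelParams:
    """A biologically plausible random parameter draw (rates in day^-1)."""
    muF = 1.0 / rng.uniform(20.0, 60.0)
    bW = rng.uniform(2.0, 15.0)
    delta = rng.uniform(0.0, 0.3)
    life = LifeHistoryParams(
        bW=bW,
        bWW=bW * rng.uniform(0.8, 1.5),
        bWS=bW * rng.uniform(0.0, 1.0),
        bSW=bW * rng.uniform(0.0, 1.0),
        nuA=rng.uniform(0.02, 0.08),
        muA=rng.uniform(0.01, 0.05),
        r=rng.uniform(0.4, 0.6),
        muM=1.0 / rng.uniform(20.0, 60.0),
        muF=muF,
        muFWW=muF * rng.uniform(0.5, 1.5),
        muFWS=muF * rng.uniform(0.5, 1.5),
        muFSW=muF * rng.uniform(0.5, 1.5),
        K=K,
    )
    rem = RematingParams(delta=delta, deltaS=delta + rng.uniform(0.0, 0.3))
    sterile = SterileParams(
        muS=rng.uniform(0.1, 0.5), gamma=rng.uniform(0.3, 2.5), eps=rng.uniform(0.0, 0.01)
    )
    return ModelParams(life=life, rem=rem, sterile=sterile)
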