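"""Closed-form thresholds: mating probabilities, offspring numbers, the
re-mating trade-off, eps_max and the wild equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medfly_sit import (
    NoPositiveEquilibrium,
    ScenarioSpec,
    basic_offspring_N,
    basic_offspring_R,
    build_preset,
    epsilon_max,
    mating_fractions,
    offspring_sum,
    origin_linearization,
    remating_tradeoff_F,
    wild_equilibrium,
)
from medfly_sit.dynamics import rhs_wild

from conftest import random_params


class TestMatingFractions:
    @pytest.mark.parametrize(
        "M, MS, gamma, eps, expected",
        [
            (5.0, 0.0, 0.6129, 0.01, (1.0, 0.0)),  # no sterile males
            (0.0, 7.0, 0.6129, 0.0, (0.0, 1.0)),  # fully sterile saturation
            (0.0, 0.0, 0.6129, 0.0, (0.0, 0.0)),  # nobody to mate
            # direct arithmetic: pW = (M + eps*gamma*MS)/(M + gamma*MS)
            (1.0, 1.0, 0.6129, 0.01, ((1.0 + 0.01 * 0.6129) / 1.6129, None)),
        ],
    )
    def test_examples(self, M, MS, gamma, eps, expected):
        pW, pS = mating_fractions(M, MS, gamma, eps)
        assert pW == pytest.approx(expected[0], abs=1e-12)
        if expected[1] is None:
            assert pS == pytest.approx(1.0 - pW, abs=1e-12)
        else:
            assert pS == pytest.approx(expected[1], abs=1e-12)

    @given(
        M=st.floats(0.0, 1e6),
        MS=st.floats(0.0, 1e6),
        gamma=st.floats(0.01, 5.0),
        eps=st.floats(0.0, 0.99),
    )
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unity(self, M, MS, gamma, eps):
        pW, pS = mating_fractions(M, MS, gamma, eps)
        assert 0.0 <= pW <= 1.0 and 0.0 <= pS <= 1.0
        if M + gamma * MS > 0:
            assert pW + pS == pytest.approx(1.0, abs=1e-12)


class TestOffspringNumbers:
    def test_peach_no_remating_matches_reference(self, peach_case1):
        # Table-4 anchor, exact to all printed digits
        assert basic_offspring_N(peach_case1.life, 0.0) == pytest.approx(181.4221, abs=5e-5)
        assert basic_offspring_R(peach_case1.life, 0.0) == pytest.approx(181.4221, abs=5e-5)

    def test_peach_with_remating_matches_reference(self, peach_case1):
        assert basic_offspring_R(peach_case1.life, 0.16) == pytest.approx(228.4270, abs=5e-5)
        assert basic_offspring_N(peach_case1.life, 0.16) == pytest.approx(23.183, abs=5e-4)

    def test_N_decreasing_in_delta_and_R_dominates(self, peach_case1):
        deltas = np.linspace(0.0, 0.5, 20)
        Ns = [basic_offspring_N(peach_case1.life, d) for d in deltas]
        assert all(a > b for a, b in zip(Ns, Ns[1:]))
        for d in deltas:
            assert basic_offspring_R(peach_case1.life, d) >= basic_offspring_N(peach_case1.life, d)

    def test_R_equals_N_iff_no_double_wild_path(self, peach_case1):
        assert basic_offspring_R(peach_case1.life, 0.0) == basic_offspring_N(peach_case1.life, 0.0)
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_params(rng)
            d = p.rem.delta
            gap = basic_offspring_R(p.life, d) - basic_offspring_N(p.life, d)
            if d * p.life.bWW > 0:
                assert gap > 0
            else:
                assert gap == 0


class TestRematingTradeoff:
    def test_zero_without_remating(self):
        p = build_preset(ScenarioSpec(case_id=1, remating_mode="none"))
        assert remating_tradeoff_F(p) == 0.0

    def test_zero_when_fecundities_balance(self, peach_case1):
        # delta = deltaS, all female death rates equal, bWW = bWS + bSW
        from dataclasses import replace

        life = replace(
            peach_case1.life,
            bWS=0.4 * peach_case1.life.bWW,
            bSW=0.6 * peach_case1.life.bWW,
            muFWW=peach_case1.life.muF,
        )
        from medfly_sit import ModelParams, RematingParams

        p = ModelParams(life=life, rem=RematingParams(0.2, 0.2), sterile=peach_case1.sterile)
        assert remating_tradeoff_F(p) == pytest.approx(0.0, abs=1e-12)

    def test_sterile_only_remating_is_detrimental(self):
        p = build_preset(ScenarioSpec(case_id=1, remating_mode="sterile_only"))
        F = remating_tradeoff_F(p)
        life, dS = p.life, p.rem.deltaS
        closed_form = -dS * (life.bSW / life.muFSW) * life.muF / (dS + life.muF)
        assert F < 0
        assert F == pytest.approx(closed_form, rel=1e-12)


class TestEpsilonMax:
    @pytest.mark.parametrize(
        "mode, expected, rel",
        [
            ("none", 0.00551, 2e-3),  # = 1/R(0), matches printed digits
            ("sterile_only", 0.00376, 2e-3),
            ("equal", 0.00549, 1.5e-2),
            ("differential", 0.00534, 1.5e-2),
        ],
    )
    def test_reference_table_case1(self, mode, expected, rel):
        p = build_preset(ScenarioSpec(case_id=1, remating_mode=mode, gro=False))
        assert epsilon_max(p) == pytest.approx(expected, rel=rel)

    def test_no_remating_is_reciprocal_R0(self, peach_case1):
        p = build_preset(ScenarioSpec(case_id=1, remating_mode="none"))
        assert epsilon_max(p) * basic_offspring_R(p.life, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_root_satisfies_offspring_sum(self):
        # eps_max is by construction the root of E(eps) = 1
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = random_params(rng)
            em = epsilon_max(p)
            if em < 1.0:
                assert offspring_sum(p, em) == pytest.approx(1.0, abs=1e-10)

    def test_monotone_decreasing_in_sterile_only_pressure(self, peach_case1):
        from dataclasses import replace

        from medfly_sit import ModelParams, RematingParams

        base = build_preset(ScenarioSpec(case_id=1, remating_mode="sterile_only"))
        # increasing bSW with delta = 0 strictly lowers the ceiling
        vals_b = [
            epsilon_max(ModelParams(life=replace(base.life, bSW=f * base.life.bW),
                                    rem=base.rem, sterile=base.sterile))
            for f in (0.2, 0.5, 0.8, 1.1)
        ]
        assert all(a > b for a, b in zip(vals_b, vals_b[1:]))
        # and so does increasing deltaS
        vals_d = [
            epsilon_max(ModelParams(life=base.life, rem=RematingParams(0.0, dS),
                                    sterile=base.sterile))
            for dS in (0.05, 0.2, 0.4, 0.8)
        ]
        assert all(a > b for a, b in zip(vals_d, vals_d[1:]))

    def test_cap_when_population_cannot_rebound(self):
        from medfly_sit import LifeHistoryParams, ModelParams, RematingParams, SterileParams

        weak = LifeHistoryParams(
            bW=0.05, bWW=0.05, bWS=0.0, bSW=0.0, nuA=0.03, muA=0.03, r=0.5,
            muM=0.05, muF=0.05, muFWW=0.05, muFWS=0.05, muFSW=0.05, K=1e4,
        )
        p = ModelParams(life=weak, rem=RematingParams(0.0, 0.0),
                        sterile=SterileParams(muS=0.231, gamma=1.0))
        with pytest.warns(UserWarning):
            assert epsilon_max(p) == 1.0


class TestOriginLinearization:
    def test_fully_sterile_release_stabilizes(self, peach_case1):
        E, stable = origin_linearization(peach_case1.with_eps(0.0), MSbar=1e4)
        assert E == 0.0 and stable

    def test_flip_exactly_at_ceiling(self, peach_case1):
        em = epsilon_max(peach_case1)
        _, below = origin_linearization(peach_case1.with_eps(em * 0.999), MSbar=1.0)
        _, above = origin_linearization(peach_case1.with_eps(min(em * 1.001, 0.999)), MSbar=1.0)
        assert below and not above

    def test_fully_fertile_release_recovers_R0(self):
        p = build_preset(ScenarioSpec(case_id=1, remating_mode="none"))
        E = offspring_sum(p, 1.0)
        assert E == pytest.approx(basic_offspring_R(p.life, 0.0), rel=1e-12)
        assert E > 1

    def test_requires_sterile_saturation(self, peach_case1):
        with pytest.raises(ValueError):
            origin_linearization(peach_case1, MSbar=0.0)


class TestWildEquilibrium:
    def test_no_equilibrium_when_R_below_one(self):
        from medfly_sit import LifeHistoryParams

        weak = LifeHistoryParams(
            bW=0.01, bWW=0.01, bWS=0.0, bSW=0.0, nuA=0.03, muA=0.03, r=0.5,
            muM=0.05, muF=0.05, muFWW=0.05, muFWS=0.05, muFSW=0.05, K=1e4,
        )
        with pytest.raises(NoPositiveEquilibrium):
            wild_equilibrium(weak, 0.0)

    def test_vector_field_vanishes_at_equilibrium(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_params(rng)
            try:
                eq = wild_equilibrium(p.life, p.rem.delta)
            except NoPositiveEquilibrium:
                continue
            res = rhs_wild(eq.to_array(), 0.0, p.life, p.rem.delta)
            assert np.max(np.abs(res)) < 1e-9 * p.life.K

    def test_components_follow_closed_form(self, peach_case2):
        life, delta = peach_case2.life, peach_case2.rem.delta
        R = basic_offspring_R(life, delta)
        eq = wild_equilibrium(life, delta)
        A = (1 - 1 / R) * life.K
        assert eq.A == pytest.approx(A, rel=1e-12)
        assert eq.M == pytest.approx((1 - life.r) * life.nuA / life.muM * A, rel=1e-12)
        assert eq.FW == pytest.approx(life.r * life.nuA / (delta + life.muF) * A, rel=1e-12)
        assert eq.FWW == pytest.approx(delta / life.muFWW * eq.FW, rel=1e-12)
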