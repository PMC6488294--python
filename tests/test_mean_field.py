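"""Mean-field reputation dynamics: update maps, fixed points, payoffs.

The per-norm update equations are transcribed literally here as independent
oracles and compared against the package's single matrix-driven
implementation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from empathynorms.mean_field import (
    ReputationState,
    cooperation_rate,
    reputation_update_map,
    solve_reputation_fixed_point,
    strategy_payoffs,
)
from empathynorms.norms import GameParams, StrategyMix

ALL_DISC = StrategyMix(0.0, 0.0, 1.0)
ALL_ALLD = StrategyMix(0.0, 1.0, 0.0)
ALL_ALLC = StrategyMix(1.0, 0.0, 0.0)


def _literal_update(norm, params, E, mix, gX, gY, gZ):
    """The published norm-specific update equations, transcribed term by term."""
    e1, e2, eps = params.e1, params.e2, params.epsilon
    g = mix.fX * gX + mix.fY * gY + mix.fZ * gZ
    g2 = mix.fX * gX**2 + mix.fY * gY**2 + mix.fZ * gZ**2
    d2 = g - g2
    b2 = 1 - 2 * g + g2
    if norm == "SJ":
        nX = g * eps + (1 - g) * (1 - eps)
        nY = g * e2 + (1 - g) * (1 - e2)
        nZ = E * (g * eps + (1 - g) * (1 - e2)) + (1 - E) * (
            g2 * eps + d2 * (e2 + 1 - eps) + b2 * (1 - e2)
        )
    elif norm == "SH":
        nX = g * eps + (1 - g) * e2
        nY = e2
        nZ = E * (g * eps + (1 - g) * e2) + (1 - E) * (g2 * eps + 2 * d2 * e2 + b2 * e2)
    elif norm == "SS":
        nX = g * eps + (1 - g) * (1 - e2)
        nY = g * e2 + (1 - g) * (1 - e2)
        nZ = E * (g * eps + (1 - g) * (1 - e2)) + (1 - E) * (
            g2 * eps + d2 + b2 * (1 - e2)
        )
    else:  # SC: empathy is irrelevant
        nX = eps
        nY = e2
        nZ = g * eps + (1 - g) * e2
    return nX, nY, nZ


@pytest.mark.parametrize("norm", ["SJ", "SS", "SC", "SH"])
def test_update_map_matches_literal_norm_equations(norm, rng):
    """The generic matrix-driven map reproduces each norm's printed equations."""
    for _ in range(50):
        params = GameParams(e1=rng.uniform(0, 0.4), e2=rng.uniform(0, 0.4))
        E = rng.uniform()
        f = rng.dirichlet([1, 1, 1])
        mix = StrategyMix(*f)
        gs = rng.uniform(0, 1, 3)
        state = ReputationState(*gs, mix)
        got = reputation_update_map(norm, params, E, mix, state)
        want = _literal_update(norm, params, E, mix, *gs)
        np.testing.assert_allclose(
            [got.gX, got.gY, got.gZ], want, rtol=0, atol=1e-14
        )


class TestFixedPoints:
    def test_scoring_fixed_point_closed_form(self, standard_params):
        """All-DISC Scoring equilibrium g = e2/(1 - eps + e2) ~ 0.33784, any E."""
        p = standard_params
        expected = p.e2 / (1 - p.epsilon + p.e2)
        assert expected == pytest.approx(0.337837838, abs=1e-8)
        for E in (0.0, 0.37, 1.0):
            st_ = solve_reputation_fixed_point("SC", p, E, ALL_DISC)
            assert st_.g == pytest.approx(expected, abs=1e-10)
        # mixed population: class reputations are eps / e2 / self-consistent
        mix = StrategyMix(0.2, 0.3, 0.5)
        st_ = solve_reputation_fixed_point("SC", p, 0.37, mix)
        assert st_.gX == pytest.approx(p.epsilon, abs=1e-10)
        assert st_.gY == pytest.approx(p.e2, abs=1e-10)
        assert st_.gZ == pytest.approx(st_.g * p.epsilon + (1 - st_.g) * p.e2, abs=1e-10)

    def test_error_free_agreeing_discriminators_stay_good(self):
        p = GameParams(e1=0.0, e2=0.0)
        st_ = ReputationState(1.0, 1.0, 1.0, ALL_DISC)
        new = reputation_update_map("SJ", p, 0.7, ALL_DISC, st_)
        assert new.gZ == pytest.approx(1.0, abs=1e-15)

    def test_sj_full_empathy_discriminator_line(self, standard_params):
        """At E=1 the DISC update is g*eps + (1-g)(1-e2) (the donor-view branch)."""
        p = standard_params
        st_ = solve_reputation_fixed_point("SJ", p, 1.0, ALL_DISC)
        g = st_.g
        assert st_.gZ == pytest.approx(g * p.epsilon + (1 - g) * (1 - p.e2), abs=1e-10)

    @pytest.mark.parametrize(
        "norm,expected_gy",
        [("SH", lambda p, g: p.e2), ("SJ", lambda p, g: g * p.e2 + (1 - g) * (1 - p.e2))],
    )
    def test_all_alld_defector_reputation(self, standard_params, norm, expected_gy):
        st_ = solve_reputation_fixed_point(norm, standard_params, 0.5, ALL_ALLD)
        assert st_.gY == pytest.approx(expected_gy(standard_params, st_.g), abs=1e-10)

    def test_fixed_point_independent_of_start(self, standard_params):
        for norm in ("SJ", "SS", "SC", "SH"):
            a = solve_reputation_fixed_point(
                norm, standard_params, 0.4, StrategyMix(0.1, 0.4, 0.5), start=0.01
            )
            b = solve_reputation_fixed_point(
                norm, standard_params, 0.4, StrategyMix(0.1, 0.4, 0.5), start=0.99
            )
            np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-9)

    def test_residual_below_tolerance(self, standard_params):
        mix = StrategyMix(0.3, 0.3, 0.4)
        st_ = solve_reputation_fixed_point("SJ", standard_params, 0.5, mix, tol=1e-12)
        new = reputation_update_map("SJ", standard_params, 0.5, mix, st_)
        assert np.abs(new.as_array() - st_.as_array()).max() < 1e-11

    @pytest.mark.parametrize("norm", ["SJ", "SS", "SH"])
    def test_equilibrium_good_standing_nondecreasing_in_empathy(self, standard_params, norm):
        """More empathy never hurts the discriminators' standing (all-DISC)."""
        gs = [
            solve_reputation_fixed_point(norm, standard_params, E, ALL_DISC).g
            for E in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(gs) >= -1e-10)

    def test_scoring_bitwise_empathy_invariance(self, standard_params):
        mix = StrategyMix(0.25, 0.25, 0.5)
        a = solve_reputation_fixed_point("SC", standard_params, 0.0, mix)
        b = solve_reputation_fixed_point("SC", standard_params, 1.0, mix)
        assert a.as_array().tobytes() == b.as_array().tobytes()

    @given(
        e=st.floats(0.0, 0.4),
        E=st.floats(0.0, 1.0),
        raw=st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
    )
    def test_fixed_point_stays_in_unit_cube(self, e, E, raw):
        f = np.array(raw) / sum(raw)
        mix = StrategyMix(*f)
        st_ = solve_reputation_fixed_point("SJ", GameParams(e1=e, e2=e), E, mix)
        assert np.all(st_.as_array() >= -1e-12)
        assert np.all(st_.as_array() <= 1 + 1e-12)
        assert st_.g2 <= st_.g + 1e-12
        assert 0 <= st_.d2 <= 1 and 0 <= st_.b2 <= 1


class TestPayoffs:
    def test_all_alld_population_earns_nothing(self, standard_params):
        st_ = solve_reputation_fixed_point("SJ", standard_params, 0.5, ALL_ALLD)
        pay = strategy_payoffs(standard_params, ALL_ALLD, st_)
        assert pay.pY == pytest.approx(0.0, abs=1e-14)

    def test_all_allc_cooperator_payoff(self, standard_params):
        p = standard_params
        st_ = solve_reputation_fixed_point("SJ", p, 0.5, ALL_ALLC)
        pay = strategy_payoffs(p, ALL_ALLC, st_)
        assert pay.pX == pytest.approx((p.b - p.c) * (1 - p.e1), abs=1e-12)

    def test_mean_payoff_is_mix_weighted_average(self, standard_params, rng):
        f = rng.dirichlet([1, 1, 1])
        mix = StrategyMix(*f)
        st_ = solve_reputation_fixed_point("SS", standard_params, 0.3, mix)
        pay = strategy_payoffs(standard_params, mix, st_)
        assert pay.mean == pytest.approx(
            mix.fX * pay.pX + mix.fY * pay.pY + mix.fZ * pay.pZ, abs=1e-14
        )


def test_fixed_point_record_is_flat_and_complete(standard_params):
    from empathynorms.mean_field import fixed_point_record

    rec = fixed_point_record("sj", standard_params, 0.5, ALL_DISC)
    assert rec["norm"] == "SJ"
    assert set(rec) == {"norm", "E", "b", "c", "e1", "e2", "fX", "fY", "fZ",
                        "gX", "gY", "gZ", "coop_rate"}
    assert rec["coop_rate"] == pytest.approx((1 - 0.02) * rec["gZ"], abs=1e-12)


class TestCooperationRate:
    def test_all_alld_rate_zero(self, standard_params):
        st_ = solve_reputation_fixed_point("SJ", standard_params, 0.5, ALL_ALLD)
        assert cooperation_rate(ALL_ALLD, st_, standard_params) == 0.0

    def test_all_allc_errorfree_rate_one(self):
        p = GameParams(e1=0.0, e2=0.02)
        st_ = solve_reputation_fixed_point("SJ", p, 0.5, ALL_ALLC)
        assert cooperation_rate(ALL_ALLC, st_, p) == pytest.approx(1.0)

    def test_all_disc_scoring_rate(self, standard_params):
        st_ = solve_reputation_fixed_point("SC", standard_params, 0.0, ALL_DISC)
        rate = cooperation_rate(ALL_DISC, st_, standard_params)
        assert rate == pytest.approx((1 - 0.02) * 0.337837838, abs=1e-4)
        assert rate == pytest.approx(0.3311, abs=1e-4)
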