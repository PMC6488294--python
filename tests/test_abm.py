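"""Agent-based model: initialization, the four generation phases, engines."""

import numpy as np
import pytest
from scipy import stats

from empathynorms.abm import (
    SimulationConfig,
    exploration_step,
    fermi_probability,
    imitation_step,
    init_population,
    observe_and_update,
    play_generation_games,
    run_generation,
    run_simulation,
)
from empathynorms.mean_field import solve_reputation_fixed_point
from empathynorms.norms import GameParams, StrategyMix


def _cfg(**kw):
    base = dict(norm="SJ", E=0.5, N=20, generations=10, replicates=1, seed=42, burn_in=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestInitPopulation:
    def test_deterministic_given_seed(self):
        a = init_population(_cfg(), np.random.default_rng(7))
        b = init_population(_cfg(), np.random.default_rng(7))
        assert (a.image == b.image).all()
        assert (a.p == b.p).all() and (a.q == b.q).all()

    def test_discrete_mode_never_draws_antidiscriminators(self, rng):
        st = init_population(_cfg(N=500), rng)
        assert not np.any((st.p == 1.0) & (st.q == 0.0))
        fx, fy, fz = st.strategy_counts()
        assert fx + fy + fz == pytest.approx(1.0)

    def test_initial_reputations_are_fair_coins(self, rng):
        st = init_population(_cfg(N=300), rng)
        assert st.image.mean() == pytest.approx(0.5, abs=0.01)

    def test_continuous_mode_draws_from_unit_square(self, rng):
        st = init_population(_cfg(strategy_space="continuous", N=200), rng)
        assert np.all((st.p >= 0) & (st.p <= 1) & (st.q >= 0) & (st.q <= 1))
        assert 0 < st.p.std()


class TestGames:
    def test_all_alld_earns_nothing(self, rng):
        st = init_population(_cfg(init="all_alld"), rng)
        log = play_generation_games(st, GameParams(), rng)
        assert not log.any()
        assert np.all(st.payoffs == 0)

    def test_all_allc_errorfree_payoffs(self, rng):
        p = GameParams(e1=0.0)
        st = init_population(_cfg(init="all_allc", N=12), rng)
        play_generation_games(st, p, rng)
        np.testing.assert_allclose(st.payoffs, 11 * (p.b - p.c))

    def test_payoff_conservation(self, rng):
        st = init_population(_cfg(N=30), rng)
        log = play_generation_games(st, GameParams(), rng)
        assert st.payoffs.sum() == pytest.approx(log.sum() * (5.0 - 1.0))

    def test_cooperation_count_is_binomial(self, rng):
        """All-ALLC at N=6: realized cooperations per generation ~ Binomial(30, 1-e1)."""
        p = GameParams(e1=0.3)
        st = init_population(_cfg(init="all_allc", N=6), rng)
        n_pairs, trials = 30, 10_000
        counts = np.empty(trials, dtype=int)
        for t in range(trials):
            counts[t] = play_generation_games(st, p, rng).sum()
        edges = np.arange(n_pairs + 2) - 0.5
        observed, _ = np.histogram(counts, bins=edges)
        expected = trials * stats.binom.pmf(np.arange(n_pairs + 1), n_pairs, 1 - p.e1)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 1e-4


class TestObservation:
    def test_unanimous_good_views_stay_good_under_error_free_sj(self, rng):
        p = GameParams(e1=0.0, e2=0.0)
        st = init_population(_cfg(init="all_disc", N=10, E=1.0), rng)
        st.image[:, :] = 1
        log = play_generation_games(st, p, rng)
        new = observe_and_update(st, "SJ", p, log, rng)
        assert (new == 1).all()

    def test_egocentric_disagreement_causes_unjustified_blame(self, rng):
        """A DISC donor defects on a (donor-view) bad recipient; an observer who
        sees that recipient as good assigns Bad under egocentric Stern Judging."""
        p = GameParams(e1=0.0, e2=0.0)
        st = init_population(_cfg(init="all_disc", N=2, E=0.0), rng)
        st.image[0, 1] = 0   # donor 0 sees agent 1 as bad -> will defect
        st.image[1, 1] = 1   # observer 1 sees herself (the recipient) as good
        log = play_generation_games(st, p, rng)
        assert not log[0, 1]
        new = observe_and_update(st, "SJ", p, log, rng)
        assert new[1, 0] == 0  # the defection looks unjustified to observer 1

    def test_diagonal_self_opinion_is_carried_over(self, rng):
        st = init_population(_cfg(N=15), rng)
        diag = st.image.diagonal().copy()
        log = play_generation_games(st, GameParams(), rng)
        new = observe_and_update(st, "SJ", GameParams(), log, rng)
        assert (new.diagonal() == diag).all()

    def test_stationary_good_fraction_tracks_mean_field(self):
        """Frozen all-DISC Scoring population: time-averaged good fraction near
        the mean-field fixed point (quick, moderate-N version)."""
        cfg = _cfg(norm="SC", E=0.0, N=200, init="all_disc", freeze=True,
                   mu=0.0, generations=800, seed=11)
        res = run_simulation(cfg)
        target = solve_reputation_fixed_point(
            "SC", cfg.params, 0.0, StrategyMix(0, 0, 1)
        ).g
        assert res.mean_good[0, 100:].mean() == pytest.approx(target, abs=0.03)


class TestImitationAndExploration:
    def test_fermi_probability_limits(self):
        assert fermi_probability(1.0, 2.0, 2.0) == 0.5
        assert fermi_probability(0.0, -3.0, 10.0) == 0.5
        assert fermi_probability(100.0, 1.0, 0.0) == pytest.approx(1.0)
        assert fermi_probability(100.0, 0.0, 1.0) == pytest.approx(0.0)

    def test_imitation_copies_full_strategy(self, rng):
        st = init_population(_cfg(N=2), rng)
        st.p[:] = [0.0, 1.0]
        st.q[:] = [1.0, 1.0]
        st.payoffs = np.array([0.0, 1e9])
        imitation_step(st, w=1.0, rng=rng)
        # agent with the enormous payoff is never the one overwritten by Fermi
        assert (st.p[1], st.q[1]) == (1.0, 1.0)

    def test_zero_exploration_is_a_no_op(self, rng):
        st = init_population(_cfg(N=50), rng)
        p0, q0 = st.p.copy(), st.q.copy()
        exploration_step(st, 0.0, rng)
        assert (st.p == p0).all() and (st.q == q0).all()

    def test_certain_exploration_redraws_every_agent(self, rng):
        st = init_population(_cfg(N=900, init="all_alld"), rng)
        exploration_step(st, 1.0, rng)
        fx, fy, fz = st.strategy_counts()
        for frac in (fx, fy, fz):
            assert frac == pytest.approx(1 / 3, abs=0.06)


class TestRunSimulation:
    def test_deterministic_under_fixed_seed(self):
        cfg = _cfg(generations=50, replicates=2)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert (a.coop == b.coop).all()
        assert (a.mean_good == b.mean_good).all()

    def test_distinct_seeds_decorrelate(self):
        a = run_simulation(_cfg(generations=50, seed=1))
        b = run_simulation(_cfg(generations=50, seed=2))
        assert not (a.coop == b.coop).all()

    def test_engines_agree_statistically(self):
        """The compiled loop and the numpy reference sample the same process."""
        kw = dict(norm="SC", E=0.0, N=60, init="all_disc", freeze=True,
                  mu=0.0, generations=600, replicates=3, seed=9, burn_in=0)
        a = run_simulation(SimulationConfig(**kw), engine="numba")
        b = run_simulation(SimulationConfig(**kw), engine="numpy")
        ga = a.mean_good[:, 100:].mean()
        gb = b.mean_good[:, 100:].mean()
        assert ga == pytest.approx(gb, abs=0.03)
        ca = a.coop[:, 100:].mean()
        cb = b.coop[:, 100:].mean()
        assert ca == pytest.approx(cb, abs=0.03)

    def test_reference_generation_record_schema(self, rng):
        st = init_population(_cfg(), rng)
        rec = run_generation(st, _cfg(), rng)
        assert set(rec) == {"coop_rate", "fX", "fY", "fZ", "mean_good"}
        assert 0 <= rec["coop_rate"] <= 1

    def test_summary_burn_in_excluded(self):
        cfg = _cfg(generations=100, burn_in=50)
        res = run_simulation(cfg)
        assert res.replicate_means[0] == pytest.approx(res.coop[0, 50:].mean())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            _cfg(mu=1.5)
        with pytest.raises(ValueError):
            _cfg(w=-1.0)
        with pytest.raises(ValueError):
            _cfg(burn_in=10, generations=10)
        with pytest.raises(ValueError):
            _cfg(strategy_space="ternary")
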