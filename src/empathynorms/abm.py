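"""Finite-population Monte Carlo of strategy evolution with private reputations.

Each of N agents holds a strategy (p, q) and a private row of opinions about
everyone else (the image matrix; ``image[k, i]`` is i's reputation in k's
eyes — rows may and do disagree).  One generation consists of

1. games: every ordered pair plays one donation game; the donor acts on her
   own view of the recipient, intended cooperation fails with probability e1;
   realized cooperation transfers (+b, -c);
2. observation: every agent observes one randomly chosen interaction per
   donor, resolves the recipient's reputation from the donor's row with
   probability E (else from her own row, both read from the pre-update
   image), applies the norm with assessment error e2, and all opinions are
   rewritten in one synchronized swap;
3. imitation: one random ordered pair; the first agent copies the second's
   full (p, q) with the Fermi probability 1/(1 + exp(-w [Pi_1 - Pi_0]));
4. exploration: each agent independently resets to a uniformly random
   strategy with probability mu.

Two engines compute the same process: readable numpy step functions (the
reference, exposed individually below) and a compiled generation loop in
:mod:`empathynorms._kernels` used by default for long runs.  They share
distributions, not random streams; tests compare them statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .norms import GameParams, SocialNorm, as_empathy, get_norm

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "SimulationResult",
    "fermi_probability",
    "init_population",
    "play_generation_games",
    "observe_and_update",
    "imitation_step",
    "exploration_step",
    "run_generation",
    "run_simulation",
]

_INIT_CHOICES = ("random", "all_allc", "all_alld", "all_disc")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte Carlo experiment.

    Defaults follow the standard study conditions: N = 100 agents, selection
    strength w = 1, summaries over 150,000 generations in 50 replicate
    populations, benefit b = 5, cost c = 1, error rates e1 = e2 = 0.02.  The
    default burn-in discards the first 10% of generations from the summary
    average; set ``burn_in=0`` to average over every generation instead.
    """

    norm: str | SocialNorm = "SJ"
    params: GameParams = field(default_factory=GameParams)
    E: float = 1.0
    N: int = 100
    w: float = 1.0
    mu: float = 0.001
    generations: int = 150_000
    burn_in: int | None = None
    replicates: int = 50
    seed: int = 0
    strategy_space: str = "discrete"
    init: str = "random"
    freeze: bool = False
    thin: int = 1

    def __post_init__(self) -> None:
        get_norm(self.norm)
        as_empathy(self.E)
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.w < 0:
            raise ValueError("selection strength w must be non-negative")
        if not (0 <= self.mu <= 1):
            raise ValueError("exploration rate mu must lie in [0, 1]")
        if self.strategy_space not in ("discrete", "continuous"):
            raise ValueError("strategy_space must be 'discrete' or 'continuous'")
        if self.init not in _INIT_CHOICES:
            raise ValueError(f"init must be one of {_INIT_CHOICES}")
        if self.generations < 1 or self.replicates < 1 or self.thin < 1:
            raise ValueError("generations, replicates and thin must be positive")
        if self.effective_burn_in >= self.generations:
            raise ValueError("burn_in must be smaller than generations")

    @property
    def effective_burn_in(self) -> int:
        return self.generations // 10 if self.burn_in is None else self.burn_in


@dataclass
class PopulationState:
    """Mutable ABM state: strategies, shared empathy, private image matrix."""

    p: np.ndarray          # P(cooperate with bad), per agent
    q: np.ndarray          # P(cooperate with good), per agent
    E: float
    image: np.ndarray      # uint8, image[k, i] = reputation of i in k's eyes
    payoffs: np.ndarray

    @property
    def N(self) -> int:
        return len(self.p)

    def strategy_counts(self) -> tuple[float, float, float]:
        """(fX, fY, fZ): fractions playing exactly ALLC / ALLD / DISC."""
        x = np.mean((self.p == 1.0) & (self.q == 1.0))
        y = np.mean((self.p == 0.0) & (self.q == 0.0))
        z = np.mean((self.p == 0.0) & (self.q == 1.0))
        return float(x), float(y), float(z)

    def mean_good(self) -> float:
        off = self.image.sum() - np.trace(self.image)
        return float(off) / (self.N * (self.N - 1))


def fermi_probability(w: float, pi1: float, pi0: float) -> float:
    """Pairwise-comparison copying probability 1/(1 + exp(-w (pi1 - pi0)))."""
    return 1.0 / (1.0 + np.exp(-w * (pi1 - pi0)))


def _draw_strategies(n: int, space: str, rng: np.random.Generator):
    if space == "discrete":
        # uniform over ALLC (1,1), ALLD (0,0), DISC (0,1); never (1,0)
        k = rng.integers(0, 3, size=n)
        p = np.where(k == 0, 1.0, 0.0)
        q = np.where(k == 1, 0.0, 1.0)
        return p, q
    return rng.random(n), rng.random(n)


def init_population(config: SimulationConfig, rng: np.random.Generator) -> PopulationState:
    """Random strategies and a fair-coin private image matrix."""
    n = config.N
    if config.init == "random":
        p, q = _draw_strategies(n, config.strategy_space, rng)
    else:
        pq = {"all_allc": (1.0, 1.0), "all_alld": (0.0, 0.0), "all_disc": (0.0, 1.0)}[config.init]
        p = np.full(n, pq[0])
        q = np.full(n, pq[1])
    image = rng.integers(0, 2, size=(n, n), dtype=np.uint8)
    return PopulationState(p, q, float(config.E), image, np.zeros(n))


def play_generation_games(
    state: PopulationState, params: GameParams, rng: np.random.Generator
) -> np.ndarray:
    """All N(N-1) donation games; fills payoffs, returns the interaction log.

    The log is the boolean matrix of realized actions, ``log[i, j]`` = donor i
    realized cooperation toward j.  Every realized cooperation moves exactly
    (+b) to the recipient and (-c) from the donor.
    """
    n = state.N
    prob = np.where(state.image == 1, state.q[:, None], state.p[:, None])
    intended = rng.random((n, n)) < prob
    realized = intended & (rng.random((n, n)) >= params.e1)
    np.fill_diagonal(realized, False)
    state.payoffs = params.b * realized.sum(axis=0) - params.c * realized.sum(axis=1)
    return realized


def observe_and_update(
    state: PopulationState,
    norm,
    params: GameParams,
    interaction_log: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronized round of private observation; returns the new image.

    Observer k samples, for each donor i, one of i's N-1 interactions
    (independently of other observers), resolves the recipient's reputation
    from i's row with probability E else from k's own row — both read from
    the pre-update image — and records the norm's verdict with error e2.
    Self-opinions (the diagonal) are carried over unchanged.
    """
    norm = get_norm(norm)
    n = state.N
    image = state.image
    idx = np.arange(n)
    recip = rng.integers(0, n - 1, size=(n, n))
    recip[recip >= idx[None, :]] += 1  # recipient != donor (column = donor index)
    donor_view = image[idx[None, :], recip]
    observer_view = np.take_along_axis(image, recip, axis=1)
    use_donor = rng.random((n, n)) < state.E
    resolved = np.where(use_donor, donor_view, observer_view)
    observed_action = interaction_log[idx[None, :], recip].astype(np.int8)
    verdict = norm.matrix[observed_action, resolved]
    flip = rng.random((n, n)) < params.e2
    new_image = np.where(flip, 1 - verdict, verdict).astype(np.uint8)
    new_image[idx, idx] = image[idx, idx]
    return new_image


def imitation_step(state: PopulationState, w: float, rng: np.random.Generator) -> None:
    """One ordered pair; the first agent copies the second's (p, q) by Fermi."""
    n = state.N
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    if rng.random() < fermi_probability(w, state.payoffs[j], state.payoffs[i]):
        state.p[i] = state.p[j]
        state.q[i] = state.q[j]


def exploration_step(
    state: PopulationState, mu: float, rng: np.random.Generator, strategy_space: str = "discrete"
) -> None:
    """Each agent independently resets to a uniform random strategy w.p. mu."""
    mask = rng.random(state.N) < mu
    k = int(mask.sum())
    if k:
        p, q = _draw_strategies(k, strategy_space, rng)
        state.p[mask] = p
        state.q[mask] = q


def run_generation(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """One full generation (reference path); returns the per-generation record."""
    log = play_generation_games(state, config.params, rng)
    state.image = observe_and_update(state, config.norm, config.params, log, rng)
    if not config.freeze:
        imitation_step(state, config.w, rng)
        exploration_step(state, config.mu, rng, config.strategy_space)
    fx, fy, fz = state.strategy_counts()
    n = state.N
    return {
        "coop_rate": float(log.sum()) / (n * (n - 1)),
        "fX": fx,
        "fY": fy,
        "fZ": fz,
        "mean_good": state.mean_good(),
    }


@dataclass(frozen=True)
class SimulationResult:
    """Replicate trajectories plus the ensemble summary."""

    config: SimulationConfig
    generations: np.ndarray             # recorded generation indices (thinned)
    coop: np.ndarray                    # (replicates, n_recorded)
    fX: np.ndarray
    fY: np.ndarray
    fZ: np.ndarray
    mean_good: np.ndarray
    replicate_means: np.ndarray         # post burn-in mean cooperation per replicate

    @property
    def mean_cooperation(self) -> float:
        return float(self.replicate_means.mean())

    @property
    def sem_cooperation(self) -> float:
        r = len(self.replicate_means)
        if r == 1:
            return 0.0
        return float(self.replicate_means.std(ddof=1) / np.sqrt(r))

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "coop_rate": self.coop[replicate],
                "fX": self.fX[replicate],
                "fY": self.fY[replicate],
                "fZ": self.fZ[replicate],
                "mean_good": self.mean_good[replicate],
            }
        )

    def summary(self) -> dict:
        return {
            "mean_cooperation": self.mean_cooperation,
            "sem_cooperation": self.sem_cooperation,
            "replicates": len(self.replicate_means),
            "generations": int(self.config.generations),
            "burn_in": int(self.config.effective_burn_in),
        }


def _replicate_seeds(seed: int, replicates: int) -> list[tuple[int, int]]:
    """Deterministic (init, loop) child seeds spawned from the master seed."""
    children = np.random.SeedSequence(seed).spawn(replicates)
    return [tuple(int(x) for x in ss.generate_state(2) >> 1) for ss in children]


def run_simulation(config: SimulationConfig, engine: str = "numba") -> SimulationResult:
    """Run all replicates and summarize mean cooperation.

    ``engine="numba"`` uses the compiled generation loop; ``engine="numpy"``
    composes the reference step functions (slower, identical process).  Both
    are fully reproducible from ``config.seed``.
    """
    if engine not in ("numba", "numpy"):
        raise ValueError("engine must be 'numba' or 'numpy'")
    gens = config.generations
    rec_idx = np.arange(0, gens, config.thin)
    n_rec = len(rec_idx)
    R = config.replicates
    coop = np.empty((R, n_rec))
    fX = np.empty((R, n_rec))
    fY = np.empty((R, n_rec))
    fZ = np.empty((R, n_rec))
    good = np.empty((R, n_rec))
    rep_means = np.empty(R)
    burn = config.effective_burn_in
    m = get_norm(config.norm).matrix.astype(np.uint8)  # writable copy for numba

    for r, (init_seed, loop_seed) in enumerate(_replicate_seeds(config.seed, R)):
        rng = np.random.default_rng(init_seed)
        state = init_population(config, rng)
        if engine == "numba":
            c_ = np.empty(gens)
            x_ = np.empty(gens)
            y_ = np.empty(gens)
            z_ = np.empty(gens)
            g_ = np.empty(gens)
            _kernels._abm_run(
                m, config.params.b, config.params.c,
                config.params.e1, config.params.e2, float(config.E),
                state.p, state.q, state.image,
                config.w, config.mu,
                config.strategy_space == "discrete", config.freeze,
                gens, loop_seed,
                c_, x_, y_, z_, g_,
            )
            coop[r] = c_[rec_idx]
            fX[r] = x_[rec_idx]
            fY[r] = y_[rec_idx]
            fZ[r] = z_[rec_idx]
            good[r] = g_[rec_idx]
            rep_means[r] = c_[burn:].mean()
        else:
            loop_rng = np.random.default_rng(loop_seed)
            total = 0.0
            j = 0
            for gen in range(gens):
                rec = run_generation(state, config, loop_rng)
                if gen >= burn:
                    total += rec["coop_rate"]
                if gen % config.thin == 0:
                    coop[r, j] = rec["coop_rate"]
                    fX[r, j] = rec["fX"]
                    fY[r, j] = rec["fY"]
                    fZ[r, j] = rec["fZ"]
                    good[r, j] = rec["mean_good"]
                    j += 1
            rep_means[r] = total / (gens - burn)
    return SimulationResult(config, rec_idx, coop, fX, fY, fZ, good, rep_means)
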