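"""Finite-population Monte Carlo of empathy evolution.

Strategies are fixed at DISC; each agent carries her own continuous empathy
value E in [0, 1], applied whenever she acts as an observer.  Per generation:
the usual game and private-observation phases, then ``n_pairs`` random
ordered pairs in which the first agent copies the second's E with the Fermi
probability on this generation's payoffs, then per-agent Gaussian mutation
(rate mu_E, kernel sd sigma, clipped to the unit interval).

In a near-monomorphic population this process realizes the adaptive-dynamics
limit analysed in :mod:`empathynorms.adaptive_dynamics`: the population mean
E drifts in the direction of the selection gradient and hovers around
convergence-stable singular points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .abm import _replicate_seeds
from .norms import GameParams, SocialNorm, as_empathy, get_norm

__all__ = ["EmpathyEvolutionConfig", "EmpathyEvolutionResult", "run_empathy_evolution"]


@dataclass(frozen=True)
class EmpathyEvolutionConfig:
    """Parameters of one empathy-evolution experiment.

    Defaults follow the standard study conditions: N = 100 discriminators,
    selection strength w = 1, empathy mutation rate mu_E = 0.005 per agent
    per generation with Gaussian kernel sd sigma = 0.01, and five imitation
    pairs per generation.
    """

    norm: str | SocialNorm = "SJ"
    params: GameParams = field(default_factory=GameParams)
    N: int = 100
    w: float = 1.0
    mu_E: float = 0.005
    sigma: float = 0.01
    n_pairs: int = 5
    generations: int = 50_000
    replicates: int = 3
    seed: int = 0
    E_init: float = 0.5
    thin: int = 100

    def __post_init__(self) -> None:
        get_norm(self.norm)
        as_empathy(self.E_init)
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not (0 <= self.mu_E <= 1):
            raise ValueError("mu_E must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.generations < 1 or self.replicates < 1 or self.thin < 1:
            raise ValueError("generations, replicates and thin must be positive")


@dataclass(frozen=True)
class EmpathyEvolutionResult:
    config: EmpathyEvolutionConfig
    mean_E: np.ndarray      # (replicates, generations) population mean E
    coop: np.ndarray        # (replicates, generations) cooperation rate
    mean_good: np.ndarray   # (replicates, generations)
    E_history: np.ndarray   # (replicates, n_sampled, N) all agents' E, thinned
    sampled_generations: np.ndarray

    def final_mean_E(self) -> np.ndarray:
        """Population-mean E at the last generation, one value per replicate."""
        return self.mean_E[:, -1]

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Long-format (generation, agent_id, E) table of the thinned history."""
        n_s, n = self.E_history.shape[1:]
        return pd.DataFrame(
            {
                "generation": np.repeat(self.sampled_generations, n),
                "agent_id": np.tile(np.arange(n), n_s),
                "E": self.E_history[replicate].ravel(),
            }
        )

    def mean_trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.mean_E.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": r,
                        "generation": np.arange(self.mean_E.shape[1]),
                        "mean_E": self.mean_E[r],
                        "coop_rate": self.coop[r],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_empathy_evolution(config: EmpathyEvolutionConfig) -> EmpathyEvolutionResult:
    """Run all replicates of the empathy-evolution Monte Carlo.

    Every agent starts at ``E_init`` with a fair-coin private image matrix;
    the run is fully reproducible from ``config.seed``.
    """
    gens, n, R = config.generations, config.N, config.replicates
    m = get_norm(config.norm).matrix.astype(np.uint8)
    n_sampled = (gens + config.thin - 1) // config.thin
    mean_E = np.empty((R, gens))
    coop = np.empty((R, gens))
    good = np.empty((R, gens))
    e_hist = np.empty((R, n_sampled, n), dtype=np.float32)

    for r, (init_seed, loop_seed) in enumerate(_replicate_seeds(config.seed, R)):
        rng = np.random.default_rng(init_seed)
        image = rng.integers(0, 2, size=(n, n), dtype=np.uint8)
        evals = np.full(n, float(config.E_init))
        hist = np.empty((n_sampled, n), dtype=np.float32)
        _kernels._empathy_abm_run(
            m, config.params.b, config.params.c,
            config.params.e1, config.params.e2,
            evals, image, config.w, config.mu_E, config.sigma,
            config.n_pairs, gens, loop_seed,
            coop[r], mean_E[r], good[r], hist, config.thin,
        )
        e_hist[r] = hist
    sampled = np.arange(0, gens, config.thin)
    return EmpathyEvolutionResult(config, mean_E, coop, good, e_hist, sampled)
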