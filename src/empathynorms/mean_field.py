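"""Infinite-population reputation dynamics and expected payoffs.

In the mean-field model a population of ALLC (X), ALLD (Y) and DISC (Z)
players holds private opinions about one another.  ``gS`` is the frequency of
good reputation of strategy-S players averaged over all observers'
perspectives.  The population moments are

    g  = fX gX + fY gY + fZ gZ           (mean good frequency)
    g2 = fX gX^2 + fY gY^2 + fZ gZ^2     (two observers both see good)
    b2 = 1 - 2 g + g2                    (both see bad)
    d2 = g - g2                          (one sees good, the other bad)

The closure ``g2 = sum_s f_s g_s^2`` treats two observers' opinions of the
same individual as independent within a strategy class; it is part of the
model, not a numerical shortcut.  One synchronous application of the norm to
every (donor, observer) pair defines an update map on (gX, gY, gZ); strategy
payoffs are always evaluated at its fixed point (reputations equilibrate much
faster than strategies change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .norms import (
    ALLC,
    ALLD,
    BAD,
    DISC,
    GOOD,
    GameParams,
    StrategyMix,
    as_empathy,
    get_norm,
    prob_judged_good,
)

__all__ = [
    "ReputationState",
    "PayoffVector",
    "reputation_update_map",
    "solve_reputation_fixed_point",
    "strategy_payoffs",
    "cooperation_rate",
    "fixed_point_record",
    "scan_fixed_point_starts",
    "ReputationConvergenceError",
]

logger = logging.getLogger(__name__)


class ReputationConvergenceError(RuntimeError):
    """Raised when the damped fixed-point iteration fails to converge."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"reputation fixed point not converged after {max_iter} iterations "
            f"(final residual {residual:.3e})"
        )


@dataclass(frozen=True)
class ReputationState:
    """Per-strategy good-reputation frequencies at a given strategy mix."""

    gX: float
    gY: float
    gZ: float
    mix: StrategyMix

    @property
    def g(self) -> float:
        m = self.mix
        return m.fX * self.gX + m.fY * self.gY + m.fZ * self.gZ

    @property
    def g2(self) -> float:
        m = self.mix
        return m.fX * self.gX**2 + m.fY * self.gY**2 + m.fZ * self.gZ**2

    @property
    def b2(self) -> float:
        return 1.0 - 2.0 * self.g + self.g2

    @property
    def d2(self) -> float:
        return self.g - self.g2

    def as_array(self) -> np.ndarray:
        return np.array([self.gX, self.gY, self.gZ])


@dataclass(frozen=True)
class PayoffVector:
    """Expected per-round payoffs of the three strategies and their mean."""

    pX: float
    pY: float
    pZ: float
    mean: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pX, self.pY, self.pZ])


def reputation_update_map(
    norm, params: GameParams, E, mix: StrategyMix, state: ReputationState
) -> ReputationState:
    """One synchronous reputation update.

    For each strategy the new good-frequency mixes an empathetic branch (the
    observer adopts the donor's view, probability E) with an egocentric branch
    in which the (donor view, observer view) pair is drawn from the moments
    (g2, d2, d2, b2).  For norms whose matrix ignores the recipient column
    (Scoring) the two branches coincide, so the output does not depend on E.
    """
    norm = get_norm(norm)
    E = as_empathy(E)
    if norm.ignores_recipient_reputation():
        # both perspective branches coincide; collapse onto the donor-view one
        # so the output is bitwise independent of E
        E = 1.0
    g, g2 = state.g, state.g2
    d2, b2 = state.d2, state.b2
    new = []
    for strat in (ALLC, ALLD, DISC):
        p11 = prob_judged_good(norm, strat, params, GOOD, GOOD)
        p00 = prob_judged_good(norm, strat, params, BAD, BAD)
        p10 = prob_judged_good(norm, strat, params, GOOD, BAD)
        p01 = prob_judged_good(norm, strat, params, BAD, GOOD)
        empathetic = g * p11 + (1 - g) * p00
        egocentric = g2 * p11 + d2 * (p10 + p01) + b2 * p00
        new.append(E * empathetic + (1 - E) * egocentric)
    return ReputationState(new[0], new[1], new[2], mix)


def solve_reputation_fixed_point(
    norm,
    params: GameParams,
    E,
    mix: StrategyMix,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damp: float = 0.5,
    start: float | tuple[float, float, float] = 0.5,
) -> ReputationState:
    """Self-consistent reputation frequencies for a fixed strategy mix.

    Damped iteration ``g <- (1-damp) g + damp map(g)`` from ``start`` until the
    raw-map residual falls below ``tol`` (infinity norm).  The maps are
    quadratic in g and may admit multiple fixed points in bistable regions;
    the returned point is the one reached from ``start`` (default 0.5), see
    :func:`scan_fixed_point_starts`.
    """
    norm = get_norm(norm)
    E = as_empathy(E)
    if tol <= 0:
        raise ValueError("tol must be positive")
    if np.isscalar(start):
        s = (float(start),) * 3
    else:
        s = tuple(float(v) for v in start)
    m = norm.matrix
    gX, gY, gZ, res, _ = _kernels._fixed_point(
        int(m[0, 0]), int(m[0, 1]), int(m[1, 0]), int(m[1, 1]),
        params.e1, params.e2, E,
        mix.fX, mix.fY, mix.fZ,
        s[0], s[1], s[2],
        tol, max_iter, damp,
    )
    if res >= tol:
        raise ReputationConvergenceError(res, max_iter)
    return ReputationState(gX, gY, gZ, mix)


def strategy_payoffs(params: GameParams, mix: StrategyMix, state: ReputationState) -> PayoffVector:
    """Expected payoffs of ALLC / ALLD / DISC at the given reputation state.

    A donor meets a random recipient; ALLC always pays c (when execution
    succeeds), DISC pays only toward recipients it sees as good (probability
    g); benefits arrive from ALLC donors and from DISC donors in proportion to
    one's own good-standing.
    """
    b, c, e1 = params.b, params.c, params.e1
    fX, fZ = mix.fX, mix.fZ
    g = state.g
    pX = b * (fX + fZ * state.gX) * (1 - e1) - c * (1 - e1)
    pY = b * (fX + fZ * state.gY) * (1 - e1)
    pZ = b * (fX + fZ * state.gZ) * (1 - e1) - c * g * (1 - e1)
    mean = mix.fX * pX + mix.fY * pY + mix.fZ * pZ
    return PayoffVector(pX, pY, pZ, mean)


def cooperation_rate(mix: StrategyMix, state: ReputationState, params: GameParams) -> float:
    """Expected fraction of encounters ending in realized cooperation.

    ALLC donors intend to cooperate with everyone, DISC donors with the
    fraction g they see as good; intentions succeed with probability 1-e1.
    """
    return (1 - params.e1) * (mix.fX + mix.fZ * state.g)


def fixed_point_record(norm, params: GameParams, E, mix: StrategyMix) -> dict:
    """One flat CSV-ready row: parameters, equilibrium reputations, cooperation."""
    norm = get_norm(norm)
    E = as_empathy(E)
    state = solve_reputation_fixed_point(norm, params, E, mix)
    return {
        "norm": norm.name,
        "E": E,
        "b": params.b,
        "c": params.c,
        "e1": params.e1,
        "e2": params.e2,
        "fX": mix.fX,
        "fY": mix.fY,
        "fZ": mix.fZ,
        "gX": state.gX,
        "gY": state.gY,
        "gZ": state.gZ,
        "coop_rate": cooperation_rate(mix, state, params),
    }


def scan_fixed_point_starts(
    norm,
    params: GameParams,
    E,
    mix: StrategyMix,
    starts=(0.01, 0.5, 0.99),
    *,
    tol: float = 1e-12,
    atol: float = 1e-6,
) -> list[ReputationState]:
    """Solve from several initial iterates and flag multistability.

    Returns the distinct fixed points found; logs a warning when more than one
    is detected (the model equations do not specify which branch is the
    physically realized one in that case).
    """
    found: list[ReputationState] = []
    for s in starts:
        st = solve_reputation_fixed_point(norm, params, E, mix, tol=tol, start=s)
        if not any(np.allclose(st.as_array(), f.as_array(), atol=atol) for f in found):
            found.append(st)
    if len(found) > 1:
        logger.warning(
            "multiple reputation fixed points for norm=%s E=%s mix=(%.3f,%.3f,%.3f): %s",
            get_norm(norm).name, E, mix.fX, mix.fY, mix.fZ,
            [tuple(np.round(f.as_array(), 6)) for f in found],
        )
    return found
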