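"""Adaptive dynamics of the empathy trait in an all-DISC population.

A rare invader with empathy ``E1`` appears in a resident population of
discriminators with empathy ``E0``.  Three cross-perspective good-reputation
frequencies close the system in the rare-invader limit:

    g00  residents in resident eyes (self-consistent, quadratic),
    g01  residents in invader eyes (linear in g01 given g00),
    g10  invaders in resident eyes (explicit given g00, g01).

Invasion fitness is the payoff difference ``W = Pi_1 - Pi_0`` with
``Pi_0 = (b - c)(1 - e1) g00`` and ``Pi_1 = (1 - e1)(b g10 - c g01)``: an
invader receives help in proportion to her standing in resident eyes and pays
costs in proportion to how often she sees residents as good.  Singular points
are roots of the selection gradient ``dW/dE1`` at ``E1 = E0``; a root where
the gradient decreases through zero is convergence-stable (an attractor of
small-mutation evolution), one where it increases is a repeller.

The norm-specific equation sets follow the published forms exactly; for Stern
Judging the invader-in-resident-eyes equation shares its egocentric term with
the resident-in-invader-eyes one (the two coincide when execution errors are
absent), which keeps the closed-form singular points exactly consistent with
the numeric roots.  Under Scoring reputations are empathy-independent
(``g = e2/(1 - eps + e2)``) and the gradient vanishes identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .norms import GameParams, as_empathy, get_norm

__all__ = [
    "ResidentInvaderState",
    "SingularPoint",
    "solve_resident_invader",
    "invasion_fitness",
    "selection_gradient",
    "find_singular_points",
    "pip_matrix",
    "ess_vs_benefit_curve",
    "sj_singular_points_closed_form",
    "sh_singular_point_closed_form",
]


@dataclass(frozen=True)
class ResidentInvaderState:
    """Cross-perspective good-reputation frequencies in the rare-invader limit."""

    g00: float
    g01: float
    g10: float
    E0: float
    E1: float


@dataclass(frozen=True)
class SingularPoint:
    """A zero of the selection gradient with its convergence-stability class."""

    E_star: float
    stability: str  # "attractor" | "repeller" | "degenerate"
    norm: str
    gradient_slope: float


def _assessment_probs(norm, params: GameParams):
    """(t_GG, t_GB, t_BG, t_BB): P(judged good | donor view, observer-resolved view)
    for a DISC donor; first index is the donor's view, second the resolved one."""
    m = get_norm(norm).matrix
    e1, e2 = params.e1, params.e2

    def judged_good(action, rep):
        return (1 - e2) if m[action, rep] else e2

    def intend_c(rep_resolved):
        return (1 - e1) * judged_good(1, rep_resolved) + e1 * judged_good(0, rep_resolved)

    tGG = intend_c(1)          # donor sees good -> intends C; resolved good
    tGB = intend_c(0)          # donor sees good; resolved bad
    tBG = judged_good(0, 1)    # donor sees bad -> defects; resolved good
    tBB = judged_good(0, 0)
    return tGG, tGB, tBG, tBB


def _solve_g00(norm, params: GameParams, E0: float, tol: float, max_iter: int = 200_000):
    """Resident self-consistent good frequency (damped iteration from 0.5)."""
    tGG, tGB, tBG, tBB = _assessment_probs(norm, params)
    g = 0.5
    for _ in range(max_iter):
        emp = g * tGG + (1 - g) * tBB
        ego = (
            g * g * tGG
            + g * (1 - g) * (tGB + tBG)
            + (1 - g) ** 2 * tBB
        )
        new = E0 * emp + (1 - E0) * ego
        if abs(new - g) < tol:
            return 0.5 * (g + new)
        g = 0.5 * (g + new)
    raise RuntimeError(
        f"resident reputation iteration not converged (residual {abs(new - g):.3e})"
    )


def solve_resident_invader(
    norm, params: GameParams, E0, E1, *, tol: float = 1e-14
) -> ResidentInvaderState:
    """Solve the three coupled reputation equations of the rare-invader system.

    ``g00`` is solved first (it is self-contained), then ``g01`` (linear), then
    ``g10`` (explicit).  At ``E1 = E0`` the invader equations collapse onto the
    resident one, so ``g01 = g10 = g00`` exactly (neutrality).
    """
    norm = get_norm(norm)
    E0 = as_empathy(E0)
    E1 = as_empathy(E1)
    params_ok = params  # validated at construction
    if norm.name == "SC":
        g = params.e2 / (1 - params.epsilon + params.e2)
        return ResidentInvaderState(g, g, g, E0, E1)

    tGG, tGB, tBG, tBB = _assessment_probs(norm, params_ok)
    g00 = _solve_g00(norm, params_ok, E0, tol)

    # g01: donor is a resident (view ~ g00), observer an invader (view ~ g01).
    emp = g00 * tGG + (1 - g00) * tBB
    u = g00 * tGG + (1 - g00) * tBG   # coefficient of the observer-sees-good slot
    v = g00 * tGB + (1 - g00) * tBB   # observer-sees-bad slot
    g01 = (E1 * emp + (1 - E1) * v) / (1 - (1 - E1) * (u - v))

    # g10: donor is an invader (view ~ g01), observer a resident (view ~ g00).
    emp10 = g01 * tGG + (1 - g01) * tBB
    if norm.name == "SJ":
        # Stern Judging's published g10 shares its egocentric term with the
        # g01 line (observer/donor slots paired as above); this coincides
        # with the perspective-consistent pairing exactly when e1 = 0, and
        # it is the form the published closed-form singular points solve.
        ego10 = g01 * u + (1 - g01) * v
    else:
        ego10 = (
            g01 * (g00 * tGG + (1 - g00) * tGB)
            + (1 - g01) * (g00 * tBG + (1 - g00) * tBB)
        )
    g10 = E0 * emp10 + (1 - E0) * ego10
    return ResidentInvaderState(g00, g01, g10, E0, E1)


def invasion_fitness(norm, params: GameParams, E0, E1) -> float:
    """Payoff advantage ``W = Pi_1 - Pi_0`` of a rare invader."""
    st = solve_resident_invader(norm, params, E0, E1)
    b, c, e1 = params.b, params.c, params.e1
    pi0 = (b - c) * (1 - e1) * st.g00
    pi1 = (1 - e1) * (b * st.g10 - c * st.g01)
    return pi1 - pi0


def selection_gradient(norm, params: GameParams, E0, *, h: float = 1e-6) -> float:
    """Central-difference derivative of invasion fitness in E1 at E1 = E0.

    Steps are clipped to [0, 1] near the boundaries (one-sided there).
    """
    E0 = as_empathy(E0)
    hi = min(E0 + h, 1.0)
    lo = max(E0 - h, 0.0)
    w_hi = invasion_fitness(norm, params, E0, hi)
    w_lo = invasion_fitness(norm, params, E0, lo)
    return (w_hi - w_lo) / (hi - lo)


def find_singular_points(
    norm,
    params: GameParams,
    *,
    grid: int = 201,
    tol: float = 1e-12,
    h: float = 1e-6,
    classify_h: float = 1e-4,
) -> list[SingularPoint]:
    """Interior zeros of the selection gradient, classified by its slope.

    Sign changes of the gradient on a uniform grid over (0, 1) are bracketed
    and refined by Brent's method.  A gradient decreasing through zero marks a
    convergence-stable attractor (selection pushes E toward it from both
    sides); an increasing one marks a repeller.  Scoring has no interior
    singular points (the gradient is identically zero and produces no sign
    change).  Boundary behavior is reported separately by
    :func:`boundary_attractors`.
    """
    norm = get_norm(norm)
    if norm.name == "SC":
        return []
    es = np.linspace(1e-4, 1 - 1e-4, grid)
    gs = np.array([selection_gradient(norm, params, e, h=h) for e in es])
    roots: list[SingularPoint] = []
    for i in range(grid - 1):
        if gs[i] == 0.0 and gs[i + 1] == 0.0:
            continue
        if gs[i] * gs[i + 1] < 0 or gs[i] == 0.0:
            if gs[i] == 0.0:
                root = es[i]
            else:
                root = brentq(
                    lambda e: selection_gradient(norm, params, e, h=h),
                    es[i], es[i + 1], xtol=tol,
                )
            slope = (
                selection_gradient(norm, params, min(root + classify_h, 1.0), h=h)
                - selection_gradient(norm, params, max(root - classify_h, 0.0), h=h)
            ) / (min(root + classify_h, 1.0) - max(root - classify_h, 0.0))
            if slope < 0:
                stability = "attractor"
            elif slope > 0:
                stability = "repeller"
            else:  # pragma: no cover - measure-zero
                stability = "degenerate"
            roots.append(SingularPoint(float(root), stability, norm.name, float(slope)))
    return roots


def boundary_attractors(norm, params: GameParams, *, h: float = 1e-6) -> dict[str, bool]:
    """Whether selection points into each boundary (complete egocentrism /
    complete empathy as evolutionary endpoints)."""
    g0 = selection_gradient(norm, params, h, h=h)
    g1 = selection_gradient(norm, params, 1 - h, h=h)
    return {"E0_attracting": g0 < 0, "E1_attracting": g1 > 0}


def pip_matrix(norm, params: GameParams, *, resolution: int = 41, ztol: float = 1e-12):
    """Pairwise invasibility plot: sign of W on a uniform (E0, E1) grid.

    Returns (E_grid, sign matrix) with entry [i, j] = sign W(E0=grid[j],
    E1=grid[i]); the diagonal is identically zero (neutrality).
    """
    if resolution < 20:
        raise ValueError("resolution must be >= 20")
    es = np.linspace(0.0, 1.0, resolution)
    signs = np.zeros((resolution, resolution), dtype=np.int8)
    for jx, e0 in enumerate(es):
        for ix, e1 in enumerate(es):
            w = invasion_fitness(norm, params, e0, e1)
            if abs(w) > ztol:
                signs[ix, jx] = 1 if w > 0 else -1
    return es, signs


def ess_vs_benefit_curve(
    norm, params_base: GameParams, b_over_c_grid, **kwargs
) -> pd.DataFrame:
    """Singular points of empathy as the benefit-cost ratio varies.

    Returns a table (norm, b_over_c, E_star, stability); ratios for which no
    interior singular point exists contribute no rows.
    """
    rows = []
    name = get_norm(norm).name
    for ratio in b_over_c_grid:
        if ratio <= 1:
            raise ValueError("b/c grid must exceed 1")
        p = GameParams(b=ratio * params_base.c, c=params_base.c,
                       e1=params_base.e1, e2=params_base.e2)
        for sp in find_singular_points(norm, p, **kwargs):
            rows.append(
                {"norm": name, "b_over_c": float(ratio),
                 "E_star": sp.E_star, "stability": sp.stability}
            )
    return pd.DataFrame(rows, columns=["norm", "b_over_c", "E_star", "stability"])


# ---------------------------------------------------------------------------
# closed forms for the singular points
# ---------------------------------------------------------------------------


def sj_singular_points_closed_form(params: GameParams) -> tuple[float, float] | None:
    """Stern Judging's repeller/attractor pair ``1/2 -+ sqrt(...)``.

    Returns (repeller, attractor), or ``None`` when the discriminant is
    negative (no interior singular points; below the critical b/c).
    """
    r = params.c / params.b
    e2, eps = params.e2, params.epsilon
    disc = 0.25 + (1 - r) * (e2 + eps - 1 - r) / (eps - e2) ** 2
    if disc < 0:
        return None
    root = math.sqrt(disc)
    return 0.5 - root, 0.5 + root


def sh_singular_point_closed_form(params: GameParams) -> float:
    """Shunning's single repulsive singular value of empathy."""
    r = params.c / params.b
    e2, eps = params.e2, params.epsilon
    return e2 / (r + e2 - 1) * (1 - r / (eps - e2)) + r / (eps - e2)
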