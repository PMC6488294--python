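"""Strategy evolution on the ALLC/ALLD/DISC simplex.

Replicator dynamics ``df_s/dt = f_s (Pi_s - mean Pi)`` with the timescale
separation taken literally: the payoffs entering the vector field are always
evaluated at the reputation fixed point for the current mix.  The dynamics are
bistable for all four norms at the standard parameters: an all-ALLD vertex
attractor coexists with a cooperative attractor (all-DISC for Stern Judging
and Shunning, a mixed ALLC/DISC edge point for Simple Standing), separated by
an unstable equilibrium on or near the ALLD-DISC edge whose closed form is
implemented alongside the numeric root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels
from .mean_field import (
    ReputationState,
    cooperation_rate,
    solve_reputation_fixed_point,
    strategy_payoffs,
)
from .norms import GameParams, StrategyMix, as_empathy, get_norm

__all__ = [
    "StrategyMix",
    "ClosedFormContext",
    "EquilibriumReport",
    "TrajectoryResult",
    "BasinMapResult",
    "replicator_rhs",
    "integrate_trajectory",
    "edge_equilibrium_alld_disc",
    "edge_equilibrium_allc_disc",
    "closed_form_context",
    "closed_form_unstable_fz",
    "simple_standing_mixed_equilibrium",
    "basin_map",
    "equilibrium_report",
]

logger = logging.getLogger(__name__)

#: label values used by :func:`basin_map`
LABEL_DEFECTION, LABEL_COOPERATIVE, LABEL_UNCONVERGED = 0, 1, 2


def _norm_ints(norm):
    m = get_norm(norm).matrix
    return int(m[0, 0]), int(m[0, 1]), int(m[1, 0]), int(m[1, 1])


def replicator_rhs(norm, params: GameParams, E, mix: StrategyMix) -> np.ndarray:
    """Tangent vector ``f_s (Pi_s - mean Pi)`` at the reputation fixed point."""
    state = solve_reputation_fixed_point(norm, params, E, mix)
    pay = strategy_payoffs(params, mix, state)
    f = mix.as_array()
    return f * (pay.as_array() - pay.mean)


@dataclass(frozen=True)
class TrajectoryResult:
    """Time series of a replicator trajectory."""

    t: np.ndarray
    mix: np.ndarray  # shape (len(t), 3)
    coop_rate: np.ndarray

    @property
    def final(self) -> StrategyMix:
        return StrategyMix.from_array(self.mix[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "fX": self.mix[:, 0],
                "fY": self.mix[:, 1],
                "fZ": self.mix[:, 2],
                "coop_rate": self.coop_rate,
            }
        )


def integrate_trajectory(
    norm,
    params: GameParams,
    E,
    mix0: StrategyMix,
    t_end: float = 1000.0,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    n_points: int = 201,
) -> TrajectoryResult:
    """Adaptive Runge-Kutta integration of the replicator ODE.

    Reputations are re-equilibrated at every right-hand-side evaluation,
    warm-started from the previous one.  Output mixes are renormalized onto
    the simplex (integration error is within the solver tolerances).
    """
    n00, n01, n10, n11 = _norm_ints(norm)
    E = as_empathy(E)
    warm = [0.5, 0.5, 0.5]

    def rhs(_t, f):
        dX, dY, dZ, gX, gY, gZ, _ = _kernels._replicator_rhs(
            n00, n01, n10, n11, params.b, params.c, params.e1, params.e2, E,
            f[0], f[1], f[2], warm[0], warm[1], warm[2], 1e-12, 100_000, 0.5,
        )
        warm[0], warm[1], warm[2] = gX, gY, gZ
        return np.array([dX, dY, dZ])

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        mix0.as_array(),
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_end, n_points),
        dense_output=False,
    )
    if not sol.success:  # pragma: no cover - surfaced with solver diagnostics
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    mixes = np.clip(sol.y.T, 0.0, None)
    mixes /= mixes.sum(axis=1, keepdims=True)
    coop = np.empty(len(sol.t))
    for i, f in enumerate(mixes):
        m = StrategyMix.from_array(f)
        st = solve_reputation_fixed_point(norm, params, E, m)
        coop[i] = cooperation_rate(m, st, params)
    return TrajectoryResult(sol.t, mixes, coop)


# ---------------------------------------------------------------------------
# edge equilibria: numeric oracles and closed forms
# ---------------------------------------------------------------------------


def _payoff_gap_alld_disc(norm, params, E, fZ):
    mix = StrategyMix(0.0, 1.0 - fZ, fZ)
    st = solve_reputation_fixed_point(norm, params, E, mix)
    pay = strategy_payoffs(params, mix, st)
    return pay.pZ - pay.pY


def _payoff_gap_allc_disc(norm, params, E, fZ):
    mix = StrategyMix(1.0 - fZ, 0.0, fZ)
    st = solve_reputation_fixed_point(norm, params, E, mix)
    pay = strategy_payoffs(params, mix, st)
    return pay.pX - pay.pZ


def _edge_root(gap, lo=1e-9, hi=1.0 - 1e-9, n_scan=200, xtol=1e-13):
    grid = np.linspace(lo, hi, n_scan)
    vals = [gap(f) for f in grid]
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0:
            return float(brentq(gap, grid[i], grid[i + 1], xtol=xtol))
    return None


def edge_equilibrium_alld_disc(norm, params: GameParams, E, *, crosscheck: bool = True):
    """Discriminator frequency at the unstable ALLD-DISC edge equilibrium.

    Found numerically as the root of ``Pi_Z = Pi_Y`` on the ``fY + fZ = 1``
    edge (reputations at their fixed point throughout).  Returns ``None`` when
    no root lies in (0, 1) — cooperation is then unsupported at these
    parameters.  The result is cross-checked against the closed form; a
    discrepancy beyond 1e-6 indicates a transcription error and is logged.
    """
    norm = get_norm(norm)
    if norm.name not in ("SJ", "SS", "SH"):
        raise ValueError("edge equilibrium closed form applies to SJ, SS, SH only")
    E = as_empathy(E)
    root = _edge_root(lambda f: _payoff_gap_alld_disc(norm, params, E, f))
    if crosscheck and root is not None:
        cf = closed_form_unstable_fz(norm, params, E)
        if abs(cf - root) > 1e-6:
            logger.error(
                "closed-form transcription disagrees with numeric edge root: "
                "norm=%s E=%s numeric=%.9f closed=%.9f",
                norm.name, E, root, cf,
            )
    return root


def edge_equilibrium_allc_disc(norm, params: GameParams, E):
    """Numeric root of ``Pi_X = Pi_Z`` on the ALLC-DISC edge, or ``None``."""
    return _edge_root(lambda f: _payoff_gap_allc_disc(norm, params, E, f))


@dataclass(frozen=True)
class ClosedFormContext:
    """Norm-specific constants of the unstable-equilibrium closed form.

    ``fZ = (c/b) (eps - e2)^{-1} (1 + (1 - E) gamma_norm)``; at E = 1 the gamma
    term vanishes and the threshold reduces to the public-reputation value
    ``(c/b)/(eps - e2)`` for all three norms.
    """

    gamma_SH: float
    gamma_SJ: float
    gamma_SS: float
    s: float
    E: float


def closed_form_context(params: GameParams, E) -> ClosedFormContext:
    E = as_empathy(E)
    s, e2, eps = params.s, params.e2, params.epsilon
    s2 = s * s
    g_sh = (s2 * (1 - e2) - s * (1 + e2 * (eps - e2)) + e2) / (
        e2 * (s2 - 1) + E * (s2 * (1 - e2) - s + e2)
    )
    g_sj = ((s2 + 1) * (1 - e2) - s - s * (1 - e2) * (eps - e2)) / (
        E * ((s2 + 1) * (1 - e2) - s) - 1 + e2 + s / 2
    )
    g_ss = ((s2 + 1) * (1 - e2) - s - s * (eps - e2) * (1 - e2)) / (
        E * ((s2 + 1) * (1 - e2) - s) + (s2 - 1) * (1 - e2)
    )
    return ClosedFormContext(g_sh, g_sj, g_ss, s, E)


def closed_form_unstable_fz(norm, params: GameParams, E) -> float:
    """Closed-form DISC frequency at the unstable ALLD-DISC equilibrium.

    May exceed 1, meaning the threshold lies beyond the edge and cooperation
    cannot be reached from any edge mix (the numeric root is then ``None``).
    """
    norm = get_norm(norm)
    ctx = closed_form_context(params, E)
    gamma = {"SH": ctx.gamma_SH, "SJ": ctx.gamma_SJ, "SS": ctx.gamma_SS}[norm.name]
    E = as_empathy(E)
    return (params.c / params.b) / (params.epsilon - params.e2) * (1 + (1 - E) * gamma)


def simple_standing_mixed_equilibrium(params: GameParams, E) -> float:
    """DISC frequency at Simple Standing's stable mixed ALLC/DISC equilibrium.

    Increases with empathy and is capped at 1 once the interior equilibrium
    leaves the edge.  (Under full empathy the uncapped expression diverges:
    the equilibrium sits at pure DISC.)
    """
    E = as_empathy(E)
    s, e2, eps = params.s, params.e2, params.epsilon
    if E >= 1.0:
        return 1.0
    fz = (1 - eps + (s * (2 - eps - e2) - 1) / ((1 - E) * (eps - e2))) / (
        s * s * (1 - e2) - s + 1 - eps
    )
    return min(fz, 1.0)


# ---------------------------------------------------------------------------
# basin of attraction mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasinMapResult:
    """Per-cell attractor labels on a barycentric lattice plus the basin fraction."""

    cells: pd.DataFrame  # fX0, fY0, fZ0, attractor_label, fX_end, fY_end, fZ_end
    basin_fraction: float
    n_unconverged: int
    grid_resolution: int

    @property
    def labels(self) -> np.ndarray:
        return self.cells["attractor_label"].to_numpy()


def simplex_lattice(resolution: int) -> np.ndarray:
    """Barycentric lattice with ``resolution`` subdivisions per edge."""
    pts = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            pts.append((i / resolution, j / resolution, k / resolution))
    return np.array(pts)


def basin_map(
    norm,
    params: GameParams,
    E,
    *,
    grid_resolution: int = 50,
    dt: float = 0.1,
    t_max: float = 2000.0,
    rhs_tol: float = 1e-9,
    vertex_tol: float = 1e-3,
) -> BasinMapResult:
    """Label every lattice start by the attractor its trajectory reaches.

    A trajectory terminating within ``vertex_tol`` (barycentric L-infinity) of
    the all-ALLD vertex is labeled defection (0); any other converged endpoint
    is labeled cooperative (1); trajectories not converged by ``t_max`` keep
    label 2 and are counted.  The basin fraction is the cooperative share of
    all lattice cells.
    """
    if grid_resolution < 10:
        raise ValueError("grid_resolution must be >= 10")
    n00, n01, n10, n11 = _norm_ints(norm)
    E = as_empathy(E)
    starts = simplex_lattice(grid_resolution)
    labels, finals = _kernels._basin_batch(
        n00, n01, n10, n11,
        params.b, params.c, params.e1, params.e2, E,
        starts, dt, t_max, rhs_tol, 1e-12, 100_000, 0.5, vertex_tol,
    )
    n_unconverged = int((labels == LABEL_UNCONVERGED).sum())
    if n_unconverged:
        logger.warning(
            "basin_map: %d/%d cells unconverged at t_max=%.0f (norm=%s, E=%s)",
            n_unconverged, len(labels), t_max, get_norm(norm).name, E,
        )
    cells = pd.DataFrame(
        {
            "fX0": starts[:, 0],
            "fY0": starts[:, 1],
            "fZ0": starts[:, 2],
            "attractor_label": labels,
            "fX_end": finals[:, 0],
            "fY_end": finals[:, 1],
            "fZ_end": finals[:, 2],
        }
    )
    fraction = float((labels == LABEL_COOPERATIVE).sum() / len(labels))
    return BasinMapResult(cells, fraction, n_unconverged, grid_resolution)


# ---------------------------------------------------------------------------
# equilibrium classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumReport:
    location: StrategyMix
    stability: str  # "stable" | "unstable" | "saddle"
    coop_rate: float
    eigenvalues: tuple[float, float]


def equilibrium_report(
    norm, params: GameParams, E, mix: StrategyMix, *, rhs_tol: float = 1e-7, h: float = 1e-6
) -> EquilibriumReport:
    """Classify a candidate equilibrium by the Jacobian of the reduced 2-D field.

    The simplex is parametrized by (fX, fY); eigen-signs of the 2x2 Jacobian
    (finite differences, stepping inward at boundary points) give the label.
    Raises if the field norm at ``mix`` exceeds ``rhs_tol``.
    """
    v = replicator_rhs(norm, params, E, mix)
    if np.abs(v).max() > rhs_tol:
        raise ValueError(
            f"mix {mix} is not an equilibrium (|rhs| = {np.abs(v).max():.2e} > {rhs_tol})"
        )

    # chart: the two smallest barycentric coordinates; the largest absorbs the
    # steps, so inward differencing is always available (also at vertices)
    f_full = mix.as_array()
    order = np.argsort(f_full)
    c1, c2 = int(order[0]), int(order[1])
    big = int(order[2])

    def field(u, v_):
        coords = np.empty(3)
        coords[c1] = u
        coords[c2] = v_
        coords[big] = 1.0 - u - v_
        r = replicator_rhs(norm, params, E, StrategyMix(*coords))
        return r[[c1, c2]]

    f0 = np.array([f_full[c1], f_full[c2]])
    J = np.empty((2, 2))
    for k in range(2):
        step = h * np.eye(2)[k]
        lo_ok = f0[k] - h >= 0
        hi_ok = 1.0 - (f0 + step).sum() >= 0
        if lo_ok and hi_ok:
            J[:, k] = (field(*(f0 + step)) - field(*(f0 - step))) / (2 * h)
        elif hi_ok:
            J[:, k] = (field(*(f0 + step)) - field(*f0)) / h
        else:
            J[:, k] = (field(*f0) - field(*(f0 - step))) / h
    eig = np.linalg.eigvals(J)
    re = np.sort(np.real(eig))
    if re[1] < 0:
        stability = "stable"
    elif re[0] > 0:
        stability = "unstable"
    else:
        stability = "saddle"
    st = solve_reputation_fixed_point(norm, params, E, mix)
    return EquilibriumReport(mix, stability, cooperation_rate(mix, st, params), (re[0], re[1]))
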