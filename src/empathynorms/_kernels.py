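"""Numba-compiled numerical cores.

Hot loops live here: the damped fixed-point iteration for the mean-field
reputation frequencies, the replicator right-hand side built on it, a batch
basin-of-attraction integrator, and the generation loops of the two
agent-based models.  Everything is scalar nopython code with an inline PCG32
generator so that simulations are deterministic given an integer seed and fast
on a single core.

The Python-facing modules (:mod:`mean_field`, :mod:`replicator`, :mod:`abm`,
:mod:`empathy_abm`) keep readable reference implementations of the same
update rules; tests cross-validate the two routes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# inline PCG32 (O'Neill); 64-bit state carried in a length-1 uint64 array
# ---------------------------------------------------------------------------

_PCG_MULT = np.uint64(6364136223846793005)
_PCG_INC = np.uint64(1442695040888963407)
_U64_32 = np.uint64(32)
_U64_31 = np.uint64(31)
_MASK32 = np.uint64(0xFFFFFFFF)


@njit(cache=True, inline="always")
def _pcg32(st):
    old = st[0]
    st[0] = old * _PCG_MULT + _PCG_INC
    xorshifted = (((old >> np.uint64(18)) ^ old) >> np.uint64(27)) & _MASK32
    rot = old >> np.uint64(59)
    return ((xorshifted >> rot) | (xorshifted << ((_U64_32 - rot) & _U64_31))) & _MASK32


@njit(cache=True, inline="always")
def _runif(st):
    """Uniform double in [0, 1)."""
    return _pcg32(st) * 2.3283064365386963e-10


@njit(cache=True, inline="always")
def _randbelow(st, n):
    """Uniform integer in [0, n) (multiply-shift; bias < 2^-22 for n <= 2^10).

    Cast through int64 so later arithmetic stays integral (uint64 + int64
    would promote to float64 under numpy rules).
    """
    return np.int64((_pcg32(st) * np.uint64(n)) >> _U64_32)


@njit(cache=True, inline="always")
def _rnorm(st):
    """Standard normal via Box-Muller."""
    u1 = 1.0 - _runif(st)
    u2 = _runif(st)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(6.283185307179586 * u2)


@njit(cache=True)
def _rng_state(seed):
    st = np.empty(1, np.uint64)
    st[0] = np.uint64(0)
    _pcg32(st)
    st[0] = st[0] + np.uint64(seed)
    _pcg32(st)
    _pcg32(st)
    return st


# ---------------------------------------------------------------------------
# mean-field reputation dynamics
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _strategy_tables(n00, n01, n10, n11, e1, e2):
    """Per-strategy assessment probabilities assembled from the norm matrix.

    For each strategy s in (ALLC, ALLD, DISC) returns
    ``P11 = P(good | donor-view G, resolved G)``,
    ``P00 = P(good | donor-view B, resolved B)`` and
    ``Ps = P(good | G,B) + P(good | B,G)`` (the two disagreement cases).
    """
    gd0 = (1.0 - e2) if n00 else e2  # judged good | realized D, resolved B
    gd1 = (1.0 - e2) if n01 else e2  # realized D, resolved G
    gc0 = (1.0 - e2) if n10 else e2  # realized C, resolved B
    gc1 = (1.0 - e2) if n11 else e2  # realized C, resolved G
    cc0 = (1.0 - e1) * gc0 + e1 * gd0  # intended C, resolved B
    cc1 = (1.0 - e1) * gc1 + e1 * gd1  # intended C, resolved G

    # ALLC: intends C for either donor view
    x11, x00, xs = cc1, cc0, cc0 + cc1
    # ALLD: always defects
    y11, y00, ys = gd1, gd0, gd0 + gd1
    # DISC: intends C iff donor view good
    z11, z00 = cc1, gd0
    zs = cc0 + gd1  # (dv G, resolved B) + (dv B, resolved G)
    return x11, x00, xs, y11, y00, ys, z11, z00, zs


@njit(cache=True)
def _fixed_point(
    n00, n01, n10, n11, e1, e2, E, fX, fY, fZ, gX, gY, gZ, tol, max_iter, damp
):
    """Damped iteration of the reputation update map; returns (gX,gY,gZ,res,iters)."""
    x11, x00, xs, y11, y00, ys, z11, z00, zs = _strategy_tables(n00, n01, n10, n11, e1, e2)
    if n00 == n01 and n10 == n11:
        # recipient-blind norm (e.g. Scoring): the two perspective branches are
        # identical by construction; collapse onto one so that E is exactly
        # (bitwise) irrelevant.
        E = 1.0
    res = 1.0
    it = 0
    for it in range(max_iter):
        g = fX * gX + fY * gY + fZ * gZ
        g2 = fX * gX * gX + fY * gY * gY + fZ * gZ * gZ
        d2 = g - g2
        b2 = 1.0 - 2.0 * g + g2
        om = 1.0 - g
        nX = E * (g * x11 + om * x00) + (1.0 - E) * (g2 * x11 + d2 * xs + b2 * x00)
        nY = E * (g * y11 + om * y00) + (1.0 - E) * (g2 * y11 + d2 * ys + b2 * y00)
        nZ = E * (g * z11 + om * z00) + (1.0 - E) * (g2 * z11 + d2 * zs + b2 * z00)
        rX = nX - gX
        rY = nY - gY
        rZ = nZ - gZ
        res = max(abs(rX), abs(rY), abs(rZ))
        gX += damp * rX
        gY += damp * rY
        gZ += damp * rZ
        if res < tol:
            break
    return gX, gY, gZ, res, it + 1


@njit(cache=True, inline="always")
def _payoffs(b, c, e1, fX, fY, fZ, gX, gY, gZ):
    g = fX * gX + fY * gY + fZ * gZ
    pX = b * (fX + fZ * gX) * (1.0 - e1) - c * (1.0 - e1)
    pY = b * (fX + fZ * gY) * (1.0 - e1)
    pZ = b * (fX + fZ * gZ) * (1.0 - e1) - c * g * (1.0 - e1)
    return pX, pY, pZ


@njit(cache=True)
def _replicator_rhs(
    n00, n01, n10, n11, b, c, e1, e2, E, fX, fY, fZ, gX, gY, gZ, tol, max_iter, damp
):
    """Replicator vector field with reputations at their fixed point.

    The warm-start (gX,gY,gZ) is returned converged so integrators can chain
    calls cheaply.  Returns (dX,dY,dZ,gX,gY,gZ,res).
    """
    gX, gY, gZ, res, _ = _fixed_point(
        n00, n01, n10, n11, e1, e2, E, fX, fY, fZ, gX, gY, gZ, tol, max_iter, damp
    )
    pX, pY, pZ = _payoffs(b, c, e1, fX, fY, fZ, gX, gY, gZ)
    avg = fX * pX + fY * pY + fZ * pZ
    return fX * (pX - avg), fY * (pY - avg), fZ * (pZ - avg), gX, gY, gZ, res


@njit(cache=True)
def _basin_batch(
    n00,
    n01,
    n10,
    n11,
    b,
    c,
    e1,
    e2,
    E,
    starts,
    dt,
    t_max,
    rhs_tol,
    fp_tol,
    fp_max_iter,
    damp,
    vertex_tol,
):
    """Integrate every start to convergence and label its attractor.

    Labels: 0 = ALLD vertex (defection), 1 = cooperative attractor,
    2 = unconverged within t_max.  Fixed-step RK4; reputations are re-solved to
    their fixed point at every stage, warm-started from the previous stage.
    """
    n = starts.shape[0]
    labels = np.full(n, 2, np.int8)
    finals = np.empty((n, 3), np.float64)
    for idx in range(n):
        fX = starts[idx, 0]
        fY = starts[idx, 1]
        fZ = starts[idx, 2]
        gX = 0.5
        gY = 0.5
        gZ = 0.5
        d1X, d1Y, d1Z, gX, gY, gZ, _ = _replicator_rhs(
            n00, n01, n10, n11, b, c, e1, e2, E, fX, fY, fZ, gX, gY, gZ, fp_tol, fp_max_iter, damp
        )
        t = 0.0
        while t < t_max:
            if max(abs(d1X), abs(d1Y), abs(d1Z)) < rhs_tol:
                break
            if fY >= 1.0 - vertex_tol:
                break
            h = dt
            aX = fX + 0.5 * h * d1X
            aY = fY + 0.5 * h * d1Y
            aZ = fZ + 0.5 * h * d1Z
            d2X, d2Y, d2Z, gX, gY, gZ, _ = _replicator_rhs(
                n00, n01, n10, n11, b, c, e1, e2, E, aX, aY, aZ, gX, gY, gZ, fp_tol, fp_max_iter, damp
            )
            aX = fX + 0.5 * h * d2X
            aY = fY + 0.5 * h * d2Y
            aZ = fZ + 0.5 * h * d2Z
            d3X, d3Y, d3Z, gX, gY, gZ, _ = _replicator_rhs(
                n00, n01, n10, n11, b, c, e1, e2, E, aX, aY, aZ, gX, gY, gZ, fp_tol, fp_max_iter, damp
            )
            aX = fX + h * d3X
            aY = fY + h * d3Y
            aZ = fZ + h * d3Z
            d4X, d4Y, d4Z, gX, gY, gZ, _ = _replicator_rhs(
                n00, n01, n10, n11, b, c, e1, e2, E, aX, aY, aZ, gX, gY, gZ, fp_tol, fp_max_iter, damp
            )
            fX += h / 6.0 * (d1X + 2.0 * d2X + 2.0 * d3X + d4X)
            fY += h / 6.0 * (d1Y + 2.0 * d2Y + 2.0 * d3Y + d4Y)
            fZ += h / 6.0 * (d1Z + 2.0 * d2Z + 2.0 * d3Z + d4Z)
            if fX < 0.0:
                fX = 0.0
            if fY < 0.0:
                fY = 0.0
            if fZ < 0.0:
                fZ = 0.0
            tot = fX + fY + fZ
            fX /= tot
            fY /= tot
            fZ /= tot
            t += h
            d1X, d1Y, d1Z, gX, gY, gZ, _ = _replicator_rhs(
                n00, n01, n10, n11, b, c, e1, e2, E, fX, fY, fZ, gX, gY, gZ, fp_tol, fp_max_iter, damp
            )
        converged = (
            max(abs(d1X), abs(d1Y), abs(d1Z)) < rhs_tol or fY >= 1.0 - vertex_tol
        )
        if converged:
            near_alld = max(abs(fX), abs(fY - 1.0), abs(fZ)) < vertex_tol
            labels[idx] = 0 if near_alld else 1
        finals[idx, 0] = fX
        finals[idx, 1] = fY
        finals[idx, 2] = fZ
    return labels, finals


# ---------------------------------------------------------------------------
# agent-based model: strategy evolution with private reputations
# ---------------------------------------------------------------------------


@njit(cache=True)
def _abm_run(
    norm_mat,
    b,
    c,
    e1,
    e2,
    E,
    p,
    q,
    image,
    w,
    mu,
    discrete,
    freeze,
    n_gen,
    seed,
    coop_out,
    fX_out,
    fY_out,
    fZ_out,
    good_out,
):
    """Full generation loop: games -> observation -> imitation -> exploration.

    Mutates ``p``, ``q`` and ``image`` in place and fills the per-generation
    record arrays.  ``image[k, i]`` is agent i's reputation in the eyes of k;
    rows may disagree (fully private assessment).  Payoffs are reset at the
    start of every generation.
    """
    N = p.shape[0]
    st = _rng_state(seed)
    act_row = np.zeros(N, np.uint8)        # donor's realized actions, L1-hot
    new_t = np.empty((N, N), np.uint8)     # new_t[i, k] = new rep of i in k's eyes
    payoff = np.zeros(N, np.float64)
    pairs = N * (N - 1)
    nm00 = norm_mat[0, 0]
    nm01 = norm_mat[0, 1]
    nm10 = norm_mat[1, 0]
    nm11 = norm_mat[1, 1]

    for gen in range(n_gen):
        for i in range(N):
            payoff[i] = 0.0
        ncoop = 0
        good_sum = 0
        # per donor: play all N-1 games, then serve every observer of this
        # donor (each samples one of those interactions).  Both phases read
        # only the pre-update image; new opinions are buffered in new_t.
        for i in range(N):
            pi = p[i]
            qi = q[i]
            img_i = image[i]
            # --- donation games of donor i ---------------------------------
            pay_i = 0.0
            for j in range(N):
                if j == i:
                    act_row[j] = np.uint8(0)
                    continue
                prob = qi if img_i[j] == 1 else pi
                a = np.uint8(0)
                if prob >= 1.0 or (prob > 0.0 and _runif(st) < prob):
                    # intended cooperation; fails with probability e1
                    if e1 <= 0.0 or _runif(st) >= e1:
                        a = np.uint8(1)
                act_row[j] = a
                if a == 1:
                    ncoop += 1
                    if not freeze:
                        pay_i -= c
                        payoff[j] += b
            payoff[i] += pay_i
            # --- every observer k watches one interaction of donor i --------
            out_i = new_t[i]
            for k in range(N):
                if k == i:
                    out_i[k] = img_i[i]  # self-opinion carried over, never used
                    continue
                r = _randbelow(st, N - 1)
                if r >= i:
                    r += 1
                if E >= 1.0:
                    rep = img_i[r]
                elif E <= 0.0:
                    rep = image[k, r]
                elif _runif(st) < E:
                    rep = img_i[r]
                else:
                    rep = image[k, r]
                if act_row[r] == 1:
                    newrep = nm11 if rep == 1 else nm10
                else:
                    newrep = nm01 if rep == 1 else nm00
                if e2 > 0.0 and _runif(st) < e2:
                    newrep = 1 - newrep
                out_i[k] = newrep
                good_sum += newrep
        # synchronized swap: tiled transpose of new_t into image
        for i0 in range(0, N, 64):
            i1 = min(i0 + 64, N)
            for k0 in range(0, N, 64):
                k1 = min(k0 + 64, N)
                for i in range(i0, i1):
                    for k in range(k0, k1):
                        image[k, i] = new_t[i, k]

        # --- imitation: one random ordered pair, Fermi rule ------------------
        if not freeze:
            i = _randbelow(st, N)
            j = _randbelow(st, N - 1)
            if j >= i:
                j += 1
            if _runif(st) < 1.0 / (1.0 + math.exp(-w * (payoff[j] - payoff[i]))):
                p[i] = p[j]
                q[i] = q[j]

            # --- exploration: independent strategy reset w.p. mu -------------
            if mu > 0.0:
                for i in range(N):
                    if _runif(st) < mu:
                        if discrete:
                            kk = _randbelow(st, 3)
                            if kk == 0:
                                p[i] = 1.0
                                q[i] = 1.0
                            elif kk == 1:
                                p[i] = 0.0
                                q[i] = 0.0
                            else:
                                p[i] = 0.0
                                q[i] = 1.0
                        else:
                            p[i] = _runif(st)
                            q[i] = _runif(st)

        # --- per-generation records -----------------------------------------
        coop_out[gen] = ncoop / pairs
        nx = 0
        ny = 0
        nz = 0
        for i in range(N):
            if p[i] == 1.0 and q[i] == 1.0:
                nx += 1
            elif p[i] == 0.0 and q[i] == 0.0:
                ny += 1
            elif p[i] == 0.0 and q[i] == 1.0:
                nz += 1
        fX_out[gen] = nx / N
        fY_out[gen] = ny / N
        fZ_out[gen] = nz / N
        good_out[gen] = good_sum / pairs


# ---------------------------------------------------------------------------
# agent-based model: empathy evolution in an all-DISC population
# ---------------------------------------------------------------------------


@njit(cache=True)
def _empathy_abm_run(
    norm_mat,
    b,
    c,
    e1,
    e2,
    Evals,
    image,
    w,
    mu_e,
    sigma,
    n_pairs,
    n_gen,
    seed,
    coop_out,
    mean_e_out,
    good_out,
    e_hist,
    thin,
):
    """Empathy trait evolution with strategies fixed at DISC.

    Each agent carries its own empathy value, applied when it acts as an
    observer.  Per generation: games, observation, ``n_pairs`` Fermi copy
    events on E, then Gaussian mutation (rate ``mu_e``, sd ``sigma``, clipped
    to [0, 1]).  ``e_hist[row]`` stores all agents' E every ``thin`` generations.
    """
    N = Evals.shape[0]
    st = _rng_state(seed)
    actions = np.zeros((N, N), np.uint8)
    new_image = np.empty((N, N), np.uint8)
    payoff = np.zeros(N, np.float64)
    pairs = N * (N - 1)

    for gen in range(n_gen):
        for i in range(N):
            payoff[i] = 0.0
        ncoop = 0
        # games: DISC donors cooperate iff recipient looks good to them
        for i in range(N):
            for j in range(N):
                if j == i:
                    continue
                a = np.uint8(0)
                if image[i, j] == 1:
                    if e1 <= 0.0 or _runif(st) >= e1:
                        a = np.uint8(1)
                actions[i, j] = a
                if a == 1:
                    ncoop += 1
                    payoff[i] -= c
                    payoff[j] += b

        nm00 = norm_mat[0, 0]
        nm01 = norm_mat[0, 1]
        nm10 = norm_mat[1, 0]
        nm11 = norm_mat[1, 1]
        good_sum = 0
        for k in range(N):
            Ek = Evals[k]
            obs_row = image[k]
            out_row = new_image[k]
            for i in range(N):
                if i == k:
                    out_row[i] = obs_row[i]
                    continue
                r = _randbelow(st, N - 1)
                if r >= i:
                    r += 1
                if _runif(st) < Ek:
                    rep = image[i, r]
                else:
                    rep = obs_row[r]
                if actions[i, r] == 1:
                    newrep = nm11 if rep == 1 else nm10
                else:
                    newrep = nm01 if rep == 1 else nm00
                if e2 > 0.0 and _runif(st) < e2:
                    newrep = 1 - newrep
                out_row[i] = newrep
                good_sum += newrep
        image[:, :] = new_image

        # social contagion of empathy: n_pairs Fermi copy events
        for _ in range(n_pairs):
            i = _randbelow(st, N)
            j = _randbelow(st, N - 1)
            if j >= i:
                j += 1
            if _runif(st) < 1.0 / (1.0 + math.exp(-w * (payoff[j] - payoff[i]))):
                Evals[i] = Evals[j]

        # Gaussian mutation, clipped to [0, 1]
        if mu_e > 0.0:
            for i in range(N):
                if _runif(st) < mu_e:
                    e = Evals[i] + sigma * _rnorm(st)
                    if e < 0.0:
                        e = 0.0
                    elif e > 1.0:
                        e = 1.0
                    Evals[i] = e

        coop_out[gen] = ncoop / pairs
        s = 0.0
        for i in range(N):
            s += Evals[i]
        mean_e_out[gen] = s / N
        good_out[gen] = good_sum / pairs
        if gen % thin == 0:
            row = gen // thin
            for i in range(N):
                e_hist[row, i] = Evals[i]
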