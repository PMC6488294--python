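# Methods

## Model

A well-mixed population plays one-shot donation games: a donor either pays
`c` to deliver `b > c` to the recipient, or defects at no cost.  Strategies
condition on the recipient's reputation in the *donor's own eyes*:
`S = (p, q)` is the probability of cooperating with a bad / good recipient.
The discrete space is ALLC `(1,1)`, ALLD `(0,0)`, DISC `(0,1)`;
anti-discriminators `(1,0)` are excluded (they never reach high frequency and
are conventionally dropped).  A continuous mode with `(p, q) ∈ [0,1]²` is
available in the agent-based model.

Reputations are binary (1 = Good) and **private**: every individual keeps her
own opinion of everyone else.  After observing a donor act toward a
recipient, an observer assigns the donor the norm-matrix entry
`N[action, r]`, flipped with assessment-error probability `e2`, where `r` is
the recipient's reputation *as resolved by the perspective rule*: the donor's
view with probability `E` (empathetic perspective-taking), the observer's own
view with probability `1 − E`.  The perspective choice is a fresh draw per
observation event, not a fixed individual type.  Intended cooperation is
executed as defection with probability `e1`; defection always succeeds.
`ε = (1−e1)(1−e2) + e1·e2` is the probability that an intended cooperator
ends up judged good under a norm that rewards cooperation.

For norms whose matrix ignores the recipient column (Scoring), the two
perspective branches are identical by construction; the implementation
collapses them onto the donor-view branch so that every downstream quantity
is *bitwise* independent of `E`, not merely equal to rounding.

## Mean-field reputation dynamics

With strategy frequencies `f = (fX, fY, fZ)` and per-strategy good
frequencies `(gX, gY, gZ)` (averaged over observers), the population moments
are `g = Σ f_s g_s`, `g₂ = Σ f_s g_s²`, `d₂ = g − g₂`, `b₂ = 1 − 2g + g₂`.
The closure `g₂ = Σ f_s g_s²` — two observers' opinions of the same
individual are independent within a strategy class — is a model assumption,
implemented exactly as stated; no higher-order opinion correlations are
tracked.

One synchronous update maps `g_s` to
`E·[g·P_s(G,G) + (1−g)·P_s(B,B)] + (1−E)·[g₂·P_s(G,G) + d₂·(P_s(G,B)+P_s(B,G)) + b₂·P_s(B,B)]`,
where `P_s(dv, rr)` is the probability that a strategy-`s` donor whose own
view of the recipient is `dv` is judged good when the observer resolves the
reputation to `rr`.  `P_s` is assembled generically from the norm matrix and
the error rates; the four per-norm equation sets in the literature are
special cases, and the test suite carries them as independently transcribed
oracles against the generic implementation.

Fixed points are found by damped iteration `g ← g + λ(map(g) − g)` with
`λ = 0.5`, tolerance `1e-12` on the raw-map residual (∞-norm), and iteration
cap `1e5`; the maps are quadratic in `g` and undamped iteration can
oscillate near bistable regions.  The default start is `(0.5, 0.5, 0.5)`.
Multiple fixed points can coexist; `scan_fixed_point_starts` probes starts
`{0.01, 0.5, 0.99}` and logs a warning when distinct solutions appear, since
the model itself does not prescribe a branch choice.

Expected payoffs at the fixed point are

    ΠX = b(fX + fZ gX)(1−e1) − c(1−e1)
    ΠY = b(fX + fZ gY)(1−e1)
    ΠZ = b(fX + fZ gZ)(1−e1) − c·g(1−e1)

and the realized cooperation rate is `(1−e1)(fX + fZ·g)`.

## Replicator dynamics

`ḟ_s = f_s (Π_s − Π̄)` with the timescale separation taken literally:
payoffs at every right-hand-side evaluation use the converged reputation
fixed point for the current mix (reputations equilibrate faster than
strategies change).  `integrate_trajectory` uses adaptive RK45
(`rtol 1e-9`, `atol 1e-11`) with the fixed point warm-started between
evaluations.

**Closed forms.**  The unstable ALLD–DISC edge equilibrium is
`f_Z = (c/b)(ε−e₂)⁻¹(1 + (1−E)γ_norm)` with norm-specific rational constants
`γ` (linear in `E` in numerator and denominator); at `E = 1` the `γ` term
vanishes and the threshold reduces to the objective-reputation value
`(c/b)/(ε−e₂)`.  Simple Standing's stable mixed ALLC/DISC equilibrium is

    fZ* = [1 − ε + (s(2−ε−e₂) − 1) / ((1−E)(ε−e₂))] / [s²(1−e₂) − s + 1 − ε]

with `s = b/c`, capped at 1.  Both expressions are *exact* solutions of the
edge equilibrium conditions: on the ALLD–DISC edge the equal-payoff condition
forces `g = gY + g/s`, which pins `g` independently of `E`, and the moment
`g₂` becomes linear in `gZ`, so the remaining equation is solvable in closed
form (an equivalent derivation exists for the ALLC–DISC edge).  The package
still computes the equilibria numerically (grid scan + Brent bisection on the
payoff gap, fixed points re-solved at every evaluation) and treats the
numeric root as authoritative: a closed-form/numeric discrepancy beyond
`1e-6` is logged as a transcription error.  Values beyond the unit interval
mean the threshold lies outside the edge (no interior root; cooperation
unreachable from edge mixes) and the numeric routine returns `None`.

**Basins.**  `basin_map` integrates every node of a barycentric lattice
(default 50 subdivisions per edge, 1,326 cells) with a compiled fixed-step
RK4 integrator (`dt = 0.1`, warm-started fixed points at every stage,
clipping + renormalization after each step).  A trajectory terminates when
`‖ḟ‖∞ < 1e-9` or when it enters the `1e-3` (barycentric L∞) neighborhood of
the all-ALLD vertex; endpoints within that neighborhood are labeled
*defection*, any other converged endpoint *cooperative* (the cooperative
attractor is the DISC vertex for Stern Judging and Shunning but a mixed edge
point for Simple Standing, so attractor identity is decided by location
relative to the ALLD vertex only).  Cells not converged by `t_max = 2000`
keep a distinct label and are counted and logged; cells starting on
separatrices or on invariant faces are labeled by their own trajectory's
outcome, with no special-casing.  Note that simplex faces are invariant under
replicator dynamics, so e.g. the ALLC–DISC edge retains a small cooperative
set even where the interior basin is empty.

**Stability classification** (`equilibrium_report`) uses a 2-D chart spanned
by the two smallest barycentric coordinates (so inward finite differences
exist at vertices), a `1e-6` step, and the eigenvalue signs of the resulting
Jacobian.

## Agent-based model

State: per-agent `(p, q)`, a shared empathy level `E`, and the private image
matrix `image[k, i]` (i's reputation in k's eyes; rows disagree freely; the
diagonal self-opinion is stored but never used).  Per generation, in order:

1. **Games** — every ordered pair `(i, j)`, donor `i` acting on
   `image[i, j]` with execution error `e1`; realized cooperation transfers
   exactly `(+b, −c)`.  Payoffs are reset at the start of each generation.
2. **Observation** — every observer `k` samples, for each donor `i`, one of
   `i`'s `N−1` interactions uniformly (with replacement across observers:
   each observer evaluates a donor based on its own sampled interaction);
   resolves the recipient's reputation from row `i` with probability `E`
   else from row `k` (both read from the pre-update image); applies the norm
   with error `e2`.  All opinions are rewritten in one synchronized swap.
3. **Imitation** — one random ordered pair per generation; the first agent
   adopts the second's full `(p, q)` with probability
   `1/(1 + exp(−w[Π₁ − Π₀]))`.
4. **Exploration** — each agent independently resets to a uniform random
   strategy with probability `μ` (the redraw may return the current
   strategy; at the discrete space this merely rescales the effective
   innovation rate by 2/3).

Defaults are the full study conditions: `N = 100`, `w = 1`, 150,000
generations, 50 replicates, `μ = 0.001` (the low-exploration regime).  The
summary cooperation rate counts realized (post-`e1`) cooperative acts per
donor–recipient pair, averaged over generations and replicates; the default
burn-in discards the first 10% of generations (set `burn_in=0` to average
over every generation).  The reported per-generation good fraction excludes
the unused diagonal.

Two engines implement the identical process: readable numpy step functions
(`play_generation_games`, `observe_and_update`, `imitation_step`,
`exploration_step` — the testable reference), and a compiled generation loop
(numba, inline PCG32 generator) used by default.  They share distributions
but not random streams; the suite compares them statistically.  Seeding: the
master seed expands through `numpy.random.SeedSequence.spawn` into
per-replicate (initialization, loop) child seeds, making every run bit-wise
reproducible.

## Adaptive dynamics of empathy

In an all-DISC resident population with empathy `E0`, a rare invader with
`E1` introduces three cross-perspective good frequencies: `g00` (residents in
resident eyes; self-consistent quadratic, solved by damped iteration from
0.5), `g01` (residents in invader eyes; linear given `g00`), and `g10`
(invaders in resident eyes; explicit given the other two).  Invasion fitness
is `W = Π₁ − Π₀` with `Π₀ = (b−c)(1−e1)g00` and
`Π₁ = (1−e1)(b·g10 − c·g01)`.

A modelling convention of this analytic layer: in the Stern Judging `g10`
equation the egocentric disagreement terms are paired as in the `g01`
equation (the published form of the system), which coincides with the
perspective-consistent pairing exactly when `e1 = 0` and differs by `O(e1)`
otherwise; the closed-form singular points

    E*_SJ = 1/2 ± sqrt(1/4 + (1 − c/b)(e₂ + ε − 1 − c/b)/(ε − e₂)²)
    E*_SH = e₂/(c/b + e₂ − 1) · (1 − (c/b)/(ε − e₂)) + (c/b)/(ε − e₂)

are exact for that convention (at `b/c = 5`, `e = 0.02`: 0.2722/0.7278 and
0.1924; the perspective-consistent pairing would shift the Stern Judging pair
to 0.2519/0.7350 without changing any qualitative conclusion).  Simple
Standing and Shunning use the perspective-consistent pairing (for Shunning
the two coincide identically).  Under Scoring the system reduces to
`g = e₂/(1 − ε + e₂)` and `W ≡ 0`.

Selection gradients are central finite differences in `E1` at `E1 = E0`
(`h = 1e-6`, one-sided at the boundaries); the closed forms above stay
independent cross-checks rather than dependencies.  Singular points are
bracketed by sign changes on a 201-point grid and refined by Brent's method;
a gradient decreasing through zero is convergence-stable (attractor),
increasing is a repeller.  Boundary attraction at `E = 0` and `E = 1` is
reported from the gradient sign adjacent to the boundary.  Pairwise
invasibility plots tabulate `sign W` on a uniform grid (diagonal zero by
neutrality, which the solver reproduces to `1e-13` — a strong end-to-end
check of the coupled system).

## Empathy Monte Carlo

Strategies fixed at DISC; each agent carries her own `E`, applied when she
observes.  Per generation: games and observation as above (heterogeneous
`E` during transients; the analytic monomorphic limit is recovered near
fixation), then five Fermi copy events on `E`, then per-agent Gaussian
mutation at rate `μ_E = 0.005` with kernel sd `σ = 0.01`, clipped to
`[0, 1]`.  Clipping (rather than reflection or resampling) is the
minimal-assumption boundary rule; with `σ = 0.01` the choice only matters
within `~σ` of the boundaries.  Mutation follows imitation, matching the
order in which the processes are specified.

## What the simulations do and do not show

All data in this package are generated by its own models; there is no
empirical input.  The agent-based layers emulate the finite-population,
private-information versions of the analytic models — demographic noise,
opinion disagreement, mutation–selection balance — and agreement between the
layers (e.g. frozen-strategy good fractions within ±0.02 of mean-field fixed
points at `N = 1000`, drift directions matching selection gradients) shows
internal consistency of model and implementation, not correspondence with any
behavioral data.  Real moral-evaluation settings involve gossip, norm
heterogeneity, structured interaction networks and higher-order assessment
rules, all outside this model class (the package deliberately excludes
third-order norms, public-reputation broadcasting beyond the `E = 1` limit,
and group-structured norm competition).

## Problem sizes and tolerances used in the checks

The test suite runs the Monte Carlo layers at reduced scale chosen to keep
statistical power while remaining desk-friendly: norm-ranking comparisons at
`N = 100`, 20,000 generations, 10 replicates (non-overlapping 95% confidence
intervals across replicates); mean-field agreement at `N = 1000`, 5,000
generations; empathy-evolution directionality at `N = 100`, 20,000
generations, 10 replicates; basins at 50 subdivisions per edge.
`scripts/acceptance.py` uses 10,000-generation, 3–5-replicate runs.  The
full study conditions (150,000 generations, 50 replicates) remain the
library defaults.  Deterministic cross-checks (closed form vs numeric
oracle) are asserted at `1e-6`, neutrality at `1e-10`, fixed-point residuals
at `1e-12`.
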