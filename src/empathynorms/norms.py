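"""Social norms, strategies, errors, and the single-interaction assessment rule.

The donation game is played between a donor and a recipient: cooperation costs the
donor ``c`` and delivers ``b > c`` to the recipient; defection transfers nothing.
Third-party observers update the donor's reputation according to a *second-order
social norm*, a binary matrix ``N[action, reputation]`` that maps the donor's
realized action and the recipient's (perspective-resolved) reputation to a new
reputation for the donor, ``1`` = Good, ``0`` = Bad.

Two error processes operate: an intended cooperative act is executed as defection
with probability ``e1`` (defection always succeeds), and the assigned reputation is
flipped with probability ``e2``.  The probability that an intended cooperator ends
up judged good under a norm that rewards cooperation is
``epsilon = (1 - e1)(1 - e2) + e1*e2``.

Empathy ``E`` is the probability that an observer resolves the recipient's
reputation from the *donor's* point of view rather than her own.  The perspective
choice itself is made by the caller (one fresh draw per observation event); this
module only defines the assessment once the perspective is resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOOD",
    "BAD",
    "COOPERATE",
    "DEFECT",
    "SocialNorm",
    "NORMS",
    "get_norm",
    "GameParams",
    "Strategy",
    "ALLC",
    "ALLD",
    "DISC",
    "DISCRETE_STRATEGIES",
    "EmpathyParam",
    "StrategyMix",
    "assess",
    "act",
    "prob_judged_good",
]

#: Reputation symbols (integer encoding: 1 = Good = column 2 of the norm matrix).
GOOD, BAD = 1, 0
#: Action symbols (integer encoding: 1 = Cooperate = row 2 of the norm matrix).
COOPERATE, DEFECT = 1, 0

_REP_SYMBOLS = {"G": GOOD, "B": BAD, GOOD: GOOD, BAD: BAD, True: GOOD, False: BAD}
_ACT_SYMBOLS = {"C": COOPERATE, "D": DEFECT, COOPERATE: COOPERATE, DEFECT: DEFECT}


@dataclass(frozen=True)
class SocialNorm:
    """A second-order norm of moral assessment.

    ``matrix[i, j]`` is the reputation (1 good / 0 bad) assigned to a donor who
    took action ``i`` (0 defect, 1 cooperate) toward a recipient of reputation
    ``j`` (0 bad, 1 good).  The conventional four-letter string encoding reads
    the entries in the order (defect,bad) (defect,good) (cooperate,bad)
    (cooperate,good), e.g. Stern Judging = ``GBBG``.
    """

    name: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.shape != (2, 2) or not np.isin(m, (0, 1)).all():
            raise ValueError("norm matrix must be 2x2 binary")
        object.__setattr__(self, "matrix", m)
        m.setflags(write=False)

    @property
    def encoding(self) -> str:
        """Four-letter G/B string, read row-wise: defect row then cooperate row."""
        return "".join("G" if v else "B" for v in self.matrix.ravel())

    def ignores_recipient_reputation(self) -> bool:
        """True when the two reputation columns coincide (Scoring-like norms)."""
        return bool((self.matrix[:, 0] == self.matrix[:, 1]).all())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SocialNorm({self.name}={self.encoding})"


#: The four canonical second-order norms, by string encoding:
#: Stern Judging GBBG, Simple Standing GBGG, Scoring BBGG, Shunning BBBG.
NORMS: dict[str, SocialNorm] = {
    "SJ": SocialNorm("SJ", np.array([[1, 0], [0, 1]])),
    "SS": SocialNorm("SS", np.array([[1, 0], [1, 1]])),
    "SC": SocialNorm("SC", np.array([[0, 0], [1, 1]])),
    "SH": SocialNorm("SH", np.array([[0, 0], [0, 1]])),
}

_ALIASES = {
    "SJ": "SJ",
    "STERNJUDGING": "SJ",
    "STERN-JUDGING": "SJ",
    "STERN_JUDGING": "SJ",
    "GBBG": "SJ",
    "SS": "SS",
    "SIMPLESTANDING": "SS",
    "SIMPLE-STANDING": "SS",
    "SIMPLE_STANDING": "SS",
    "STANDING": "SS",
    "GBGG": "SS",
    "SC": "SC",
    "SCORING": "SC",
    "IMAGESCORING": "SC",
    "BBGG": "SC",
    "SH": "SH",
    "SHUNNING": "SH",
    "BBBG": "SH",
}


def get_norm(name: str | SocialNorm) -> SocialNorm:
    """Resolve a norm by short code, full name, or GBBG-style string (case-insensitive)."""
    if isinstance(name, SocialNorm):
        return name
    key = str(name).strip().upper().replace(" ", "")
    try:
        return NORMS[_ALIASES[key]]
    except KeyError:
        raise KeyError(
            f"unknown social norm {name!r}; expected one of "
            f"{sorted(NORMS)} (or full names / GBBG-style encodings)"
        ) from None


@dataclass(frozen=True)
class GameParams:
    """Donation-game payoffs and error rates.

    Parameters
    ----------
    b, c : float
        Benefit to the recipient and cost to the donor of one cooperative act,
        in payoff units; requires ``b > c > 0``.
    e1, e2 : float
        Execution error (intended cooperation realized as defection) and
        assessment error (assigned reputation flipped); both in ``[0, 1/2)``.
    """

    b: float = 5.0
    c: float = 1.0
    e1: float = 0.02
    e2: float = 0.02

    def __post_init__(self) -> None:
        if not (self.b > self.c > 0):
            raise ValueError(f"require b > c > 0, got b={self.b}, c={self.c}")
        for lbl, e in (("e1", self.e1), ("e2", self.e2)):
            if not (0 <= e < 0.5):
                raise ValueError(f"{lbl} must lie in [0, 1/2), got {e}")

    @property
    def epsilon(self) -> float:
        """Probability that an intended cooperator is judged good: (1-e1)(1-e2)+e1*e2."""
        return (1 - self.e1) * (1 - self.e2) + self.e1 * self.e2

    @property
    def s(self) -> float:
        """Benefit-to-cost ratio b/c."""
        return self.b / self.c


@dataclass(frozen=True)
class Strategy:
    """Reputation-conditioned action rule (p, q).

    ``p`` is the probability of cooperating with a bad recipient, ``q`` with a
    good recipient.  The discrete strategy space is {ALLC=(1,1), ALLD=(0,0),
    DISC=(0,1)}; anti-discriminators (1,0) are excluded from it.
    """

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ValueError(f"p, q must lie in [0, 1], got ({self.p}, {self.q})")

    def cooperation_prob(self, recipient_rep: int) -> float:
        return self.q if recipient_rep == GOOD else self.p


ALLC = Strategy(1.0, 1.0)
ALLD = Strategy(0.0, 0.0)
DISC = Strategy(0.0, 1.0)
DISCRETE_STRATEGIES = (ALLC, ALLD, DISC)


@dataclass(frozen=True)
class EmpathyParam:
    """Probability E that an observer adopts the donor's view of the recipient."""

    E: float

    def __post_init__(self) -> None:
        if not (0 <= self.E <= 1):
            raise ValueError(f"empathy E must lie in [0, 1], got {self.E}")

    def __float__(self) -> float:
        return float(self.E)


def as_empathy(E: float | EmpathyParam) -> float:
    """Validate and unwrap an empathy value."""
    return EmpathyParam(float(E)).E


@dataclass(frozen=True)
class StrategyMix:
    """A point (fX, fY, fZ) on the 2-simplex of ALLC/ALLD/DISC frequencies."""

    fX: float
    fY: float
    fZ: float

    def __post_init__(self) -> None:
        if min(self.fX, self.fY, self.fZ) < -1e-12:
            raise ValueError(f"strategy frequencies must be non-negative: {self}")
        if abs(self.fX + self.fY + self.fZ - 1.0) > 1e-9:
            raise ValueError(f"strategy frequencies must sum to 1: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fX, self.fY, self.fZ], dtype=float)

    @classmethod
    def from_array(cls, f) -> "StrategyMix":
        fX, fY, fZ = np.asarray(f, dtype=float)
        return cls(fX, fY, fZ)


def _coerce_action(a) -> int:
    try:
        return _ACT_SYMBOLS[a.upper() if isinstance(a, str) else a]
    except (KeyError, AttributeError):
        raise ValueError(f"invalid action symbol {a!r}; expected 'C'/'D' or 1/0") from None


def _coerce_rep(r) -> int:
    try:
        return _REP_SYMBOLS[r.upper() if isinstance(r, str) else r]
    except (KeyError, AttributeError, TypeError):
        raise ValueError(f"invalid reputation symbol {r!r}; expected 'G'/'B' or 1/0") from None


def assess(norm, donor_action, recipient_rep_used, e2: float = 0.0, rng=None) -> str:
    """Assessment of a single observed interaction.

    ``recipient_rep_used`` must already be the perspective-resolved reputation
    (the donor's view with probability E, the observer's otherwise; that draw is
    the caller's responsibility).  The norm-matrix entry for (action, reputation)
    is returned, flipped with probability ``e2``.

    Returns ``"G"`` or ``"B"``.
    """
    norm = get_norm(norm)
    a = _coerce_action(donor_action)
    r = _coerce_rep(recipient_rep_used)
    rep = int(norm.matrix[a, r])
    if e2 > 0:
        if rng is None:
            raise ValueError("rng required when e2 > 0")
        if rng.random() < e2:
            rep = 1 - rep
    return "G" if rep == GOOD else "B"


def act(strategy: Strategy, recipient_rep_in_donor_eyes, e1: float = 0.0, rng=None) -> str:
    """Realized action of a donor toward a recipient.

    The intended action is drawn from the strategy's (p, q) given the recipient's
    reputation in the donor's own eyes; an intended cooperation fails (becomes
    defection) with probability ``e1``.  Defection always succeeds.

    Returns ``"C"`` or ``"D"``.
    """
    r = _coerce_rep(recipient_rep_in_donor_eyes)
    pc = strategy.cooperation_prob(r)
    needs_rng = (0 < pc < 1) or (pc > 0 and 0 < e1 < 1)
    if needs_rng and rng is None:
        raise ValueError("rng required for stochastic action")
    intended_c = pc >= 1.0 or (pc > 0 and rng.random() < pc)
    if intended_c and e1 > 0:
        if e1 >= 1.0 or rng.random() < e1:
            return "D"
    return "C" if intended_c else "D"


def prob_judged_good(
    norm, strategy: Strategy, params: GameParams, donor_view: int, resolved_rep: int
) -> float:
    """P(donor assigned good | donor's view of recipient, perspective-resolved rep).

    Marginalizes the intended action (from the strategy and the donor's own view),
    the execution error e1, and the assessment error e2.  This is the elementary
    probability from which all mean-field reputation maps are assembled.
    """
    norm = get_norm(norm)
    pc = strategy.cooperation_prob(donor_view)
    g_if_c = (1 - params.e2) if norm.matrix[COOPERATE, resolved_rep] else params.e2
    g_if_d = (1 - params.e2) if norm.matrix[DEFECT, resolved_rep] else params.e2
    return pc * ((1 - params.e1) * g_if_c + params.e1 * g_if_d) + (1 - pc) * g_if_d
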