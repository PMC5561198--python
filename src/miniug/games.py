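"""Mini-ultimatum-game (mini-UG) games, utilities and choice probabilities.

A mini-UG trial: a proposer chose one of two predefined divisions of a fixed
stake; the responder accepts (payoffs realized) or rejects (both get zero).
Two utility models for the responder are implemented:

* **Inequity aversion** (Fehr–Schmidt): utility is own payoff minus separate
  penalties for disadvantageous (weight ``alpha``) and advantageous (weight
  ``beta``) payoff differences.  It depends only on the chosen division.
* **Intention-based reciprocity** (psychological game theory, after Rabin and
  Dufwenberg & Kirchsteiger): utility is own payoff plus a reciprocity term
  ``c * theta * k_i * k_j`` built from kindness terms that compare delivered
  payoffs to the midpoint of the payoffs available in the proposer's choice
  set.  It depends on the *alternative* the proposer declined, so it predicts
  condition-dependent acceptance of the same unfair offer.

Acceptance probabilities come from a two-action softmax over accept/reject
utilities, with rejection utility fixed at 0 (both payoffs zero; under the
reciprocity model no reciprocity term accrues to a rejection — this is the
documented convention that yields the models' stated condition predictions).

All computational kernels accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CONDITIONS",
    "NO_ALTERNATIVE",
    "FAIR_ALTERNATIVE",
    "HYPERFAIR_ALTERNATIVE",
    "Game",
    "IEParams",
    "RCParams",
    "KindnessTerms",
    "ChoiceModelConfig",
    "kindness_to_responder",
    "kindness_to_proposer",
    "context_switch",
    "kindness_terms",
    "utility_inequity_aversion",
    "utility_reciprocity",
    "choice_probability",
    "games_to_frame",
]

NO_ALTERNATIVE = "no_alternative"
FAIR_ALTERNATIVE = "fair_alternative"
HYPERFAIR_ALTERNATIVE = "hyperfair_alternative"
CONDITIONS = (NO_ALTERNATIVE, FAIR_ALTERNATIVE, HYPERFAIR_ALTERNATIVE)

ACCEPT = "accept"
REJECT = "reject"


@dataclass(frozen=True)
class Game:
    """One proposer decision faced by the responder.

    Parameters
    ----------
    x_i, x_j
        Proposer / responder payoff (coins) of the *chosen* division.
    x_i_alt, x_j_alt
        Payoffs of the division the proposer declined.  In the
        no-alternative condition the alternative equals the chosen division.
    condition
        One of ``no_alternative``, ``fair_alternative``,
        ``hyperfair_alternative``.
    """

    x_i: float
    x_j: float
    x_i_alt: float
    x_j_alt: float
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        payoffs = (self.x_i, self.x_j, self.x_i_alt, self.x_j_alt)
        if any(p < 0 for p in payoffs):
            raise ValueError(f"payoffs must be non-negative, got {payoffs}")
        if self.x_i + self.x_j != self.x_i_alt + self.x_j_alt:
            raise ValueError(
                "chosen and alternative divisions must split the same stake: "
                f"{self.x_i}+{self.x_j} != {self.x_i_alt}+{self.x_j_alt}"
            )
        same = (self.x_i_alt, self.x_j_alt) == (self.x_i, self.x_j)
        if (self.condition == NO_ALTERNATIVE) != same:
            raise ValueError(
                "condition is no_alternative iff the alternative equals the "
                f"chosen division; got condition={self.condition!r} with "
                f"chosen=({self.x_i},{self.x_j}) alt=({self.x_i_alt},{self.x_j_alt})"
            )

    @property
    def stake(self) -> float:
        return self.x_i + self.x_j


@dataclass(frozen=True)
class IEParams:
    """Inequity-aversion weights, each constrained to [0, 1].

    ``alpha`` penalizes disadvantageous inequity (x_i > x_j), ``beta``
    advantageous inequity (x_j > x_i).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RCParams:
    """Reciprocity concern ``theta``, constrained to [0, 1]."""

    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")


@dataclass(frozen=True)
class KindnessTerms:
    """Kindness decomposition of one game: ``k_i``, ``k_j`` and the context
    switch ``c`` (0 in the no-alternative condition, otherwise the sign of
    ``k_j``)."""

    k_i: float
    k_j: float
    c: int


@dataclass(frozen=True)
class ChoiceModelConfig:
    """Softmax configuration.

    ``temperature`` divides utilities before exponentiation (default 1,
    matching the fixed-temperature analysis).  ``free_temperature`` marks
    the model variant in which a per-subject inverse temperature is treated
    as an additional free parameter during fitting.  ``symmetric_kindness``
    switches the responder-kindness reference point to the symmetric form
    (max and min both over the proposer's payoffs) for sensitivity analysis;
    the default reproduces the published asymmetric form exactly.
    """

    temperature: float = 1.0
    free_temperature: bool = False
    symmetric_kindness: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def _game_arrays(game):
    """Extract (x_i, x_j, x_i_alt, x_j_alt, is_no_alt) from a Game or a
    record with those fields (e.g. a DataFrame row or dict)."""
    if isinstance(game, Game):
        return (
            game.x_i,
            game.x_j,
            game.x_i_alt,
            game.x_j_alt,
            game.condition == NO_ALTERNATIVE,
        )
    return (
        np.asarray(game["x_i"], dtype=float),
        np.asarray(game["x_j"], dtype=float),
        np.asarray(game["x_i_alt"], dtype=float),
        np.asarray(game["x_j_alt"], dtype=float),
        np.asarray(game["condition"]) == NO_ALTERNATIVE,
    )


def kindness_to_responder(game) -> float:
    """Proposer's kindness to the responder, ``k_i``.

    Signed deviation of the responder's delivered payoff from the midpoint
    of the responder payoffs available in the proposer's choice set:
    ``k_i = x_j - (max(x_j, x_j') + min(x_j, x_j')) / 2``.
    """
    _, x_j, _, x_j_alt, _ = _game_arrays(game)
    return x_j - (np.maximum(x_j, x_j_alt) + np.minimum(x_j, x_j_alt)) / 2.0


def kindness_to_proposer(game, k_i, *, symmetric: bool = False):
    """Responder's conditional kindness to the proposer, ``k_j``.

    The proposer's delivered payoff is zeroed when ``k_i < 0`` (an unkind
    proposer is assumed not to be reciprocated).  The published reference
    point mixes the two players: ``(max(x_i, x_i') + min(x_j, x_j')) / 2``;
    it is implemented exactly as printed.  ``symmetric=True`` substitutes
    ``min(x_i, x_i')`` for the second term as a sensitivity variant.
    """
    x_i, x_j, x_i_alt, x_j_alt, _ = _game_arrays(game)
    k_i = np.asarray(k_i, dtype=float)
    lo = np.minimum(x_i, x_i_alt) if symmetric else np.minimum(x_j, x_j_alt)
    reference = (np.maximum(x_i, x_i_alt) + lo) / 2.0
    x_i_eff = np.where(k_i < 0, 0.0, x_i)
    out = x_i_eff - reference
    return float(out) if out.ndim == 0 else out


def context_switch(game, k_j):
    """Context switch ``c``: 0 in the no-alternative condition, else the
    sign of ``k_j`` (−1 if ``k_j < 0``, +1 otherwise)."""
    *_, no_alt = _game_arrays(game)
    k_j = np.asarray(k_j, dtype=float)
    c = np.where(no_alt, 0, np.where(k_j < 0, -1, 1))
    return int(c) if c.ndim == 0 else c


def kindness_terms(game, *, symmetric: bool = False) -> KindnessTerms:
    """Full kindness decomposition of a single :class:`Game`."""
    k_i = kindness_to_responder(game)
    k_j = kindness_to_proposer(game, k_i, symmetric=symmetric)
    c = context_switch(game, k_j)
    return KindnessTerms(k_i=float(k_i), k_j=float(k_j), c=int(c))


def utility_inequity_aversion(game, params: IEParams, action: str = ACCEPT):
    """Fehr–Schmidt utility of the responder's action.

    Accepting yields ``x_j - alpha*max(x_i - x_j, 0) - beta*max(x_j - x_i, 0)``
    at the chosen division; rejecting zeroes both payoffs, hence utility 0.
    """
    if action == REJECT:
        return 0.0
    if action != ACCEPT:
        raise ValueError(f"action must be 'accept' or 'reject', got {action!r}")
    x_i, x_j, *_ = _game_arrays(game)
    u = (
        x_j
        - params.alpha * np.maximum(x_i - x_j, 0.0)
        - params.beta * np.maximum(x_j - x_i, 0.0)
    )
    u = np.asarray(u, dtype=float)
    return float(u) if u.ndim == 0 else u


def utility_reciprocity(game, params: RCParams, action: str = ACCEPT,
                        *, symmetric: bool = False):
    """Reciprocity-model utility ``x_j + c*theta*k_i*k_j`` of accepting;
    rejecting yields 0 by convention (both payoffs zero, no reciprocity
    term)."""
    if action == REJECT:
        return 0.0
    if action != ACCEPT:
        raise ValueError(f"action must be 'accept' or 'reject', got {action!r}")
    _, x_j, *_ = _game_arrays(game)
    k_i = kindness_to_responder(game)
    k_j = kindness_to_proposer(game, k_i, symmetric=symmetric)
    c = context_switch(game, k_j)
    u = np.asarray(x_j + c * params.theta * k_i * k_j, dtype=float)
    return float(u) if u.ndim == 0 else u


def choice_probability(u_accept, u_reject=0.0,
                       config: ChoiceModelConfig | None = None):
    """Softmax probability of accepting given the two action utilities.

    Computed in shifted form (subtracting the max utility) so that large
    utilities never overflow; invariant under adding a constant to both
    utilities.
    """
    temperature = 1.0 if config is None else config.temperature
    u_accept = np.asarray(u_accept, dtype=float)
    u_reject = np.asarray(u_reject, dtype=float)
    if not (np.all(np.isfinite(u_accept)) and np.all(np.isfinite(u_reject))):
        raise ValueError("utilities must be finite")
    a = u_accept / temperature
    r = u_reject / temperature
    m = np.maximum(a, r)
    ea = np.exp(a - m)
    er = np.exp(r - m)
    p = ea / (ea + er)
    return float(p) if p.ndim == 0 else p


def games_to_frame(games):
    """Tabulate an iterable of :class:`Game` as a DataFrame with columns
    x_i, x_j, x_i_alt, x_j_alt, condition."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "x_i": g.x_i,
                "x_j": g.x_j,
                "x_i_alt": g.x_i_alt,
                "x_j_alt": g.x_j_alt,
                "condition": g.condition,
            }
            for g in games
        ]
    )
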