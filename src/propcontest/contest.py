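"""Two-player proportional-prize contest.

Two risk-neutral players each receive an endowment ``E`` of experimental
francs and simultaneously sink an irreversible expenditure (a *bid*)
``e`` in ``[min_bid, max_bid]`` to compete for a prize ``V``.  Unlike a
winner-take-all (lottery) contest, the prize is *shared* in proportion
to expenditures:

    P_i = e_i / (e_i + e_j)          (each player gets 1/2 if both bid 0)

so player *i*'s per-period earning is ``E - e_i + P_i * V``.  The
first-order condition gives the best response

    BR(e_j) = sqrt(e_j * V) - e_j

whose symmetric fixed point is the unique pure-strategy Nash
equilibrium ``e* = V / 4`` (20 francs when V = 80).  Bidding above
``e*`` is never a best response to any opponent expenditure.

This module holds the game's constants (:class:`ContestSpec`), the
share and earning rules, the analytic best response, a brute-force
grid-search oracle for it, and the equilibrium solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "ContestSpec",
    "BidPair",
    "Equilibrium",
    "DEFAULT_SPEC",
    "prize_share",
    "period_earning",
    "best_response",
    "best_response_oracle",
    "nash_equilibrium",
]


class ContestConfigError(ValueError):
    """A contest specification that breaks the game's invariants."""


@dataclass(frozen=True)
class ContestSpec:
    """Constants of the proportional-prize contest.

    Parameters
    ----------
    n_players
        Number of contestants; the share rule below is the two-player one.
    endowment
        Per-period endowment ``E`` in francs.
    prize
        Prize value ``V`` in francs.
    min_bid, max_bid
        Admissible expenditure range (inclusive).
    epsilon_bid
        The bid returned by :func:`best_response` against a zero
        opponent bid, where the best response is a supremum rather than
        a maximum (any positive bid captures the whole prize).
    """

    n_players: int = 2
    endowment: float = 80.0
    prize: float = 80.0
    min_bid: float = 0.0
    max_bid: float = 80.0
    epsilon_bid: float = 0.01

    def __post_init__(self) -> None:
        if self.n_players != 2:
            raise ContestConfigError("only the two-player contest is modelled")
        if not self.endowment > 0:
            raise ContestConfigError(f"endowment must be positive, got {self.endowment}")
        if not self.prize > 0:
            raise ContestConfigError(f"prize must be positive, got {self.prize}")
        if not (0 <= self.min_bid <= self.max_bid <= self.endowment):
            raise ContestConfigError(
                "bid range must satisfy 0 <= min_bid <= max_bid <= endowment, "
                f"got [{self.min_bid}, {self.max_bid}] with E={self.endowment}"
            )
        if not self.epsilon_bid > 0:
            raise ContestConfigError("epsilon_bid must be positive")


DEFAULT_SPEC = ContestSpec()


@dataclass(frozen=True)
class BidPair:
    """Expenditures of the two players in one period (francs)."""

    e_i: float
    e_j: float


@dataclass(frozen=True)
class Equilibrium:
    """A solved symmetric equilibrium expenditure."""

    e_star: float
    method: str  # "analytic" | "fixed_point"
    iterations: int = 0


PairLike = Union[BidPair, Iterable[float]]


def _as_pair(pair: PairLike) -> BidPair:
    if isinstance(pair, BidPair):
        return pair
    e_i, e_j = pair
    return BidPair(float(e_i), float(e_j))


def _check_bid(value: float, spec: ContestSpec, name: str) -> float:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    if value < spec.min_bid or value > spec.max_bid:
        raise ValueError(
            f"{name}={value} outside the admissible range "
            f"[{spec.min_bid}, {spec.max_bid}]"
        )
    return float(value)


def prize_share(pair: PairLike, spec: ContestSpec = DEFAULT_SPEC) -> float:
    """Player *i*'s share of the prize, ``e_i / (e_i + e_j)``.

    When both expenditures are zero each player receives the prize with
    probability one half, so the expected share is exactly 0.5.
    """
    p = _as_pair(pair)
    e_i = _check_bid(p.e_i, spec, "e_i")
    e_j = _check_bid(p.e_j, spec, "e_j")
    total = e_i + e_j
    if total == 0:
        return 0.5
    return e_i / total


def period_earning(pair: PairLike, spec: ContestSpec = DEFAULT_SPEC) -> float:
    """Per-period earning ``E - e_i + P_i * V`` in francs."""
    p = _as_pair(pair)
    share = prize_share(p, spec)
    return spec.endowment - p.e_i + share * spec.prize


def best_response(e_opp: float, spec: ContestSpec = DEFAULT_SPEC) -> float:
    """Analytic best response ``sqrt(e_opp * V) - e_opp``, clipped to the bid range.

    Against a zero opponent bid the payoff has no maximiser (any
    positive bid wins the whole prize and beats the coin-flip payoff of
    a zero bid), so the configured ``epsilon_bid`` is returned.
    """
    if not np.isfinite(e_opp) or e_opp < 0:
        raise ValueError(f"opponent bid must be nonnegative, got {e_opp}")
    if e_opp == 0:
        return spec.epsilon_bid
    br = math.sqrt(e_opp * spec.prize) - e_opp
    return float(min(max(br, spec.min_bid), spec.max_bid))


def best_response_oracle(
    e_opp: float,
    spec: ContestSpec = DEFAULT_SPEC,
    grid_step: float = 0.01,
) -> float:
    """Brute-force best response: maximise the period earning on a bid grid.

    Ties are broken toward the smaller bid (``argmax`` takes the first
    maximiser on the ascending grid).  Used as an independent check of
    :func:`best_response`; it never calls the analytic formula.
    """
    if not grid_step > 0:
        raise ValueError("grid_step must be positive")
    if not np.isfinite(e_opp) or e_opp < 0:
        raise ValueError(f"opponent bid must be nonnegative, got {e_opp}")
    grid = np.arange(spec.min_bid, spec.max_bid + grid_step / 2, grid_step)
    total = grid + e_opp
    share = np.where(total > 0, np.divide(grid, np.where(total > 0, total, 1.0)), 0.5)
    earnings = spec.endowment - grid + share * spec.prize
    return float(grid[int(np.argmax(earnings))])


def nash_equilibrium(
    spec: ContestSpec = DEFAULT_SPEC,
    method: str = "analytic",
    start: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> Equilibrium:
    """Symmetric pure-strategy Nash equilibrium expenditure ``e* = V / 4``.

    ``method="analytic"`` returns ``V / 4`` exactly; ``method="fixed_point"``
    iterates the best response from an interior starting bid until
    successive iterates differ by less than ``tol`` (undamped iteration;
    the map is a contraction near the fixed point for this game).
    """
    e_star = spec.prize / 4.0
    if e_star < spec.min_bid or e_star > spec.max_bid:
        raise ContestConfigError(
            f"equilibrium bid V/4={e_star} lies outside [{spec.min_bid}, {spec.max_bid}]"
        )
    if method == "analytic":
        return Equilibrium(e_star=e_star, method="analytic")
    if method != "fixed_point":
        raise ValueError(f"unknown method {method!r}")

    e = spec.prize / 8.0 if start is None else float(start)
    if not (spec.min_bid < e <= spec.max_bid) or e <= 0:
        raise ValueError(f"start={e} must be a positive interior bid")
    for it in range(1, max_iter + 1):
        e_next = math.sqrt(e * spec.prize) - e
        if abs(e_next - e) < tol:
            return Equilibrium(e_star=float(e_next), method="fixed_point", iterations=it)
        e = e_next
    raise RuntimeError(f"fixed-point iteration did not converge in {max_iter} steps")
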