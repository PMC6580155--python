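"""Replay of the 20-period contest protocol.

Each participant plays 20 periods against a fixed, pseudorandomized
schedule of computer-generated opponent bids (every participant faces
the same schedule in the same order).  After each period the engine
records the share won, the prize amount, and the earning
``E - e + share * V``.  At the end of a session two periods are drawn
uniformly at random (per participant) and their earnings summed as the
realized payment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .contest import ContestSpec, DEFAULT_SPEC, prize_share

__all__ = [
    "PAPER_OPPONENT_BIDS",
    "OpponentSchedule",
    "PeriodRecord",
    "Session",
    "settle_period",
    "run_session",
    "realized_payment",
    "session_to_frame",
]

#: The fixed opponent bid sequence used in every session, periods 1-20.
PAPER_OPPONENT_BIDS: tuple[float, ...] = (
    19, 22, 25, 27, 30, 26, 29, 31, 30, 27,
    29, 31, 34, 37, 39, 39, 25, 26, 34, 37,
)


@dataclass(frozen=True)
class OpponentSchedule:
    """Ordered pseudo-opponent bids, one per period."""

    bids: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bids) == 0:
            raise ValueError("schedule must contain at least one period")
        object.__setattr__(self, "bids", tuple(float(b) for b in self.bids))

    def __len__(self) -> int:
        return len(self.bids)

    @classmethod
    def standard(cls) -> "OpponentSchedule":
        """The 20-period schedule used in the experiment."""
        return cls(bids=PAPER_OPPONENT_BIDS)


@dataclass(frozen=True)
class PeriodRecord:
    """One resolved contest period (1-based period index)."""

    period: int
    own_bid: float
    opp_bid: float
    share: float
    prize_won: float
    earning: float


@dataclass(frozen=True)
class Session:
    """One participant's full trajectory plus (optionally) the payment draw."""

    participant_id: str
    condition: str
    records: tuple[PeriodRecord, ...]
    paid_periods: frozenset[int] | None = None
    payment: float | None = None

    @property
    def bids(self) -> tuple[float, ...]:
        return tuple(r.own_bid for r in self.records)

    @property
    def earnings(self) -> tuple[float, ...]:
        return tuple(r.earning for r in self.records)


def settle_period(
    own_bid: float,
    opp_bid: float,
    spec: ContestSpec = DEFAULT_SPEC,
    period: int = 1,
) -> PeriodRecord:
    """Resolve one period: share, prize won, and earning."""
    try:
        share = prize_share((own_bid, opp_bid), spec)
    except ValueError as exc:
        raise ValueError(f"period {period}: {exc}") from None
    prize_won = share * spec.prize
    earning = spec.endowment - own_bid + prize_won
    return PeriodRecord(
        period=int(period),
        own_bid=float(own_bid),
        opp_bid=float(opp_bid),
        share=share,
        prize_won=prize_won,
        earning=earning,
    )


def run_session(
    bid_sequence: Sequence[float],
    schedule: OpponentSchedule | None = None,
    spec: ContestSpec = DEFAULT_SPEC,
    participant_id: str = "",
    condition: str = "",
) -> Session:
    """Play a full session deterministically; payment is left unset."""
    if schedule is None:
        schedule = OpponentSchedule.standard()
    if len(bid_sequence) != len(schedule):
        raise ValueError(
            f"bid sequence has {len(bid_sequence)} entries but the schedule "
            f"has {len(schedule)} periods"
        )
    records = tuple(
        settle_period(own, opp, spec, period=t)
        for t, (own, opp) in enumerate(zip(bid_sequence, schedule.bids), start=1)
    )
    return Session(participant_id=participant_id, condition=condition, records=records)


def realized_payment(
    session: Session,
    rng: np.random.Generator,
    n_paid: int = 2,
) -> Session:
    """Draw ``n_paid`` distinct periods uniformly and sum their earnings."""
    n_periods = len(session.records)
    if n_paid > n_periods:
        raise ValueError(f"cannot pay {n_paid} of {n_periods} periods")
    chosen = rng.choice(n_periods, size=n_paid, replace=False)
    paid = frozenset(int(i) + 1 for i in chosen)
    payment = float(sum(r.earning for r in session.records if r.period in paid))
    return replace(session, paid_periods=paid, payment=payment)


def session_to_frame(session: Session) -> pd.DataFrame:
    """Long-format view of a session, one row per period."""
    return pd.DataFrame(
        {
            "participant_id": session.participant_id,
            "condition": session.condition,
            "period": [r.period for r in session.records],
            "own_bid": [r.own_bid for r in session.records],
            "opp_bid": [r.opp_bid for r in session.records],
            "share": [r.share for r in session.records],
            "prize_won": [r.prize_won for r in session.records],
            "earning": [r.earning for r in session.records],
        }
    )
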