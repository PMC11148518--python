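"""Three-type compensation queue with scheduling and denomination.

Compensation is paid as e-money redemption codes, in three types: the
completed interview (US $9.40), successful peer recruitment (US $1.60
per referral whose recruit completed the interview, queued once the
recruiter's referral coupons are all spent or expired), and the blood
draw (US $19.40).  Amounts are integer cents.  Interview and blood
requests are paid on a 3-minute processing tick; referral requests only
on the daily 02:00 run.  One phone number can be paid at most once per
payment type, and every payout is revalidated first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

from .clock import DAY, HOUR, MINUTE, to_iso
from .coupons import CouponRegistry
from .funnel import ParticipantRecord, Roster
from .quality import PaymentTimingPolicy


class PaymentType(str, Enum):
    INTERVIEW = "interview"
    REFERRAL = "referral"
    BLOOD_DRAW = "blood_draw"


class PaymentStatus(str, Enum):
    QUEUED = "queued"
    PAID = "paid"
    REJECTED = "rejected"


class PaymentError(Exception):
    pass


@dataclass
class PaymentAmounts:
    """Compensation schedule in integer cents (USD as printed)."""

    interview: int = 940
    referral_per_completion: int = 160
    blood_draw: int = 1940


@dataclass
class PaymentRequest:
    phone: str
    ptype: PaymentType
    amount: int  # cents
    queued_at: int
    due_at: int
    processed_at: Optional[int] = None
    status: PaymentStatus = PaymentStatus.QUEUED
    basis: str = ""


INTERVIEW_TICK = 3 * MINUTE
REFERRAL_TICK_TIME = 2 * HOUR  # 02:00 on the survey's single reference clock


@dataclass
class PaymentLedger:
    requests: list[PaymentRequest] = field(default_factory=list)
    _paid_or_queued: set[tuple[str, PaymentType]] = field(default_factory=set)

    def has(self, phone: str, ptype: PaymentType) -> bool:
        return (phone, ptype) in self._paid_or_queued

    def add(self, req: PaymentRequest) -> PaymentRequest:
        key = (req.phone, req.ptype)
        if key in self._paid_or_queued:
            req.status = PaymentStatus.REJECTED
            self.requests.append(req)
            return req
        self._paid_or_queued.add(key)
        self.requests.append(req)
        return req

    def total_paid(self) -> int:
        return sum(r.amount for r in self.requests if r.status == PaymentStatus.PAID)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["phone", "ptype", "amount_usd", "queued_at", "due_at", "processed_at", "status"]
            )
            for r in self.requests:
                w.writerow(
                    [
                        r.phone,
                        r.ptype.value,
                        f"{r.amount / 100:.2f}",
                        to_iso(r.queued_at),
                        to_iso(r.due_at),
                        to_iso(r.processed_at),
                        r.status.value,
                    ]
                )


def queue_interview_payment(
    participant: ParticipantRecord,
    ledger: PaymentLedger,
    timing: PaymentTimingPolicy,
    now: int,
    amounts: PaymentAmounts | None = None,
    ptype: PaymentType = PaymentType.INTERVIEW,
) -> PaymentRequest:
    """Queue the interview (or blood-draw) payment after revalidation.

    The due time is now + the effective-dated delay (3 minutes before the
    anti-fraud mitigation, 3 days after).  A second request for the same
    phone and type is recorded as rejected.
    """
    amounts = amounts or PaymentAmounts()
    if ptype == PaymentType.INTERVIEW and not participant.interview_complete:
        raise PaymentError("revalidation failed: interview not complete")
    amount = amounts.interview if ptype == PaymentType.INTERVIEW else amounts.blood_draw
    req = PaymentRequest(
        phone=participant.phone,
        ptype=ptype,
        amount=amount,
        queued_at=now,
        due_at=now + timing.delay_at(now),
        basis=participant.participant_id,
    )
    return ledger.add(req)


def queue_referral_payment(
    recruiter: ParticipantRecord,
    registry: CouponRegistry,
    roster: Roster,
    ledger: PaymentLedger,
    now: int,
    amounts: PaymentAmounts | None = None,
) -> Optional[PaymentRequest]:
    """Queue the peer-recruitment payment once all referral coupons settled.

    A successful referral is a recruit who completed the interview.  The
    request is only allowed after every coupon the recruiter issued is
    used, cancelled, or expired; otherwise a PaymentError asks the caller
    to retry later.  Returns None when there is nothing to pay.
    """
    amounts = amounts or PaymentAmounts()
    coupons = [c for c in registry.records() if c.issuer == recruiter.participant_id]
    for c in coupons:
        if not c.used and not c.cancelled and now <= c.expiration_date:
            raise PaymentError(f"coupon {c.code} still live; retry after expiry")
    completions = 0
    for c in coupons:
        if c.used and c.redeemed_by is not None:
            recruit = roster.participants.get(c.redeemed_by)
            if recruit is not None and recruit.interview_complete:
                completions += 1
    if completions == 0:
        return None
    req = PaymentRequest(
        phone=recruiter.phone,
        ptype=PaymentType.REFERRAL,
        amount=amounts.referral_per_completion * completions,
        queued_at=now,
        due_at=now,  # becomes payable at the next daily 02:00 run
        basis=f"{completions} completed referrals",
    )
    return ledger.add(req)


def _next_interview_tick(t: int) -> int:
    return ((t + INTERVIEW_TICK - 1) // INTERVIEW_TICK) * INTERVIEW_TICK


def _next_daily_tick(t: int) -> int:
    """First 02:00 at or after t."""
    day, tod = divmod(t, DAY)
    if tod <= REFERRAL_TICK_TIME:
        return day * DAY + REFERRAL_TICK_TIME
    return (day + 1) * DAY + REFERRAL_TICK_TIME


def process_queue(
    ledger: PaymentLedger,
    now: int,
    revalidate: Callable[[PaymentRequest], bool] | None = None,
) -> list[PaymentRequest]:
    """Pay every queued request whose processing tick has passed.

    Interview and blood-draw requests are paid on the first 3-minute tick
    at or after their due time; referral requests only on the first daily
    02:00 tick after queuing.  Each payout re-runs revalidation; failures
    are marked rejected, not paid.
    """
    payouts: list[PaymentRequest] = []
    for req in ledger.requests:
        if req.status != PaymentStatus.QUEUED:
            continue
        if req.ptype == PaymentType.REFERRAL:
            tick = _next_daily_tick(req.queued_at + 1)
        else:
            tick = _next_interview_tick(req.due_at)
        if tick > now:
            continue
        if revalidate is not None and not revalidate(req):
            req.status = PaymentStatus.REJECTED
            req.processed_at = tick
            continue
        req.status = PaymentStatus.PAID
        req.processed_at = tick
        payouts.append(req)
    return payouts


DEFAULT_DENOMINATIONS = (500, 200, 100, 20)  # cents


def denominate(amount: int, denominations: Sequence[int] = DEFAULT_DENOMINATIONS) -> list[int]:
    """Minimal-count multiset of e-money codes summing exactly to `amount`.

    Exact change-making by dynamic programming (denomination sets need
    not be canonical, so greedy would not always be minimal).  Raises
    PaymentError when the amount is not representable.
    """
    if amount < 0 or any(d <= 0 for d in denominations):
        raise ValueError("amount must be >= 0 and denominations positive")
    if amount == 0:
        return []
    INF = amount + 1
    best = [0] + [INF] * amount
    choice = [0] * (amount + 1)
    for v in range(1, amount + 1):
        for d in denominations:
            if d <= v and best[v - d] + 1 < best[v]:
                best[v] = best[v - d] + 1
                choice[v] = d
    if best[amount] >= INF:
        raise PaymentError(
            f"amount {amount} not representable with denominations {list(denominations)}"
        )
    out: list[int] = []
    v = amount
    while v:
        out.append(choice[v])
        v -= choice[v]
    out.sort(reverse=True)
    assert sum(out) == amount
    return out
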