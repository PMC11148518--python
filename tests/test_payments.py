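"""Compensation queue, schedules, one-payment-per-type, denomination."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from webrds.clock import DAY, HOUR, MINUTE
from webrds.coupons import CouponRegistry
from webrds.funnel import ParticipantRecord, Roster
from webrds.payments import (
    PaymentError,
    PaymentLedger,
    PaymentStatus,
    PaymentType,
    denominate,
    process_queue,
    queue_interview_payment,
    queue_referral_payment,
)
from webrds.quality import PaymentTimingPolicy, apply_mitigation


def _completer(pid="P1", phone="ph1"):
    rec = ParticipantRecord(participant_id=pid, role="seed", phone=phone)
    rec.interview_complete = True
    return rec


class TestInterviewPayment:
    def test_amount_and_due(self):
        req = queue_interview_payment(_completer(), PaymentLedger(),
                                      PaymentTimingPolicy(), now=1000)
        assert req.amount == 940  # US $9.40 in cents
        assert req.due_at == 1000 + 3 * MINUTE
        assert req.status == PaymentStatus.QUEUED

    def test_second_request_same_phone_rejected(self):
        ledger = PaymentLedger()
        queue_interview_payment(_completer(), ledger, PaymentTimingPolicy(), now=0)
        again = queue_interview_payment(_completer(), ledger, PaymentTimingPolicy(), now=50)
        assert again.status == PaymentStatus.REJECTED

    def test_incomplete_interview_fails_revalidation(self):
        rec = _completer()
        rec.interview_complete = False
        with pytest.raises(PaymentError):
            queue_interview_payment(rec, PaymentLedger(), PaymentTimingPolicy(), now=0)

    def test_blood_draw_amount(self):
        req = queue_interview_payment(_completer(), PaymentLedger(),
                                      PaymentTimingPolicy(), now=0,
                                      ptype=PaymentType.BLOOD_DRAW)
        assert req.amount == 1940

    def test_post_mitigation_delay(self):
        timing = apply_mitigation(PaymentTimingPolicy(), at=33 * DAY)
        req = queue_interview_payment(_completer(), PaymentLedger(), timing, now=40 * DAY)
        assert req.due_at - req.queued_at == 3 * DAY


class TestReferralPayment:
    def _scene(self, completions, extra_label=None, live=False):
        reg = CouponRegistry()
        roster = Roster()
        recruiter = _completer("R1", "phR")
        roster.add(recruiter)
        coupons = reg.generate(3, issuer="R1", now=0, rng=0)
        now = 20 * DAY
        for i, c in enumerate(coupons):
            if i < completions:
                reg.redeem(c.code, by=f"C{i}", at=100)
                child = ParticipantRecord(participant_id=f"C{i}", role="recruit",
                                          phone=f"phC{i}", recruiter_id="R1",
                                          coupon_code_used=c.code)
                child.interview_complete = True
                roster.add(child)
            elif extra_label == "incomplete" and i == completions:
                reg.redeem(c.code, by=f"C{i}", at=100)
                child = ParticipantRecord(participant_id=f"C{i}", role="recruit",
                                          phone=f"phC{i}", recruiter_id="R1",
                                          coupon_code_used=c.code)
                roster.add(child)  # screened out / never completed
            elif live:
                reg.set_expiration([c.code], now + DAY)  # still live
        return reg, roster, recruiter, now

    def test_three_completions(self):
        reg, roster, recruiter, now = self._scene(3)
        req = queue_referral_payment(recruiter, reg, roster, PaymentLedger(), now=now)
        assert req.amount == 480  # 3 x US $1.60

    def test_zero_completions_no_request(self):
        reg, roster, recruiter, now = self._scene(0)
        assert queue_referral_payment(recruiter, reg, roster, PaymentLedger(), now=now) is None

    def test_incomplete_recruit_not_successful(self):
        reg, roster, recruiter, now = self._scene(2, extra_label="incomplete")
        req = queue_referral_payment(recruiter, reg, roster, PaymentLedger(), now=now)
        assert req.amount == 320  # only completed interviews count

    def test_live_coupons_block_queuing(self):
        reg, roster, recruiter, now = self._scene(2, live=True)
        with pytest.raises(PaymentError, match="still live"):
            queue_referral_payment(recruiter, reg, roster, PaymentLedger(), now=now)


class TestProcessing:
    def test_referral_queued_0300_paid_next_day_0200(self):
        ledger = PaymentLedger()
        reg, roster = CouponRegistry(), Roster()
        recruiter = _completer("R1", "phR")
        roster.add(recruiter)
        c = reg.generate(1, issuer="R1", now=0, rng=0)[0]
        reg.redeem(c.code, by="C0", at=100)
        child = ParticipantRecord(participant_id="C0", role="recruit", phone="phC",
                                  recruiter_id="R1", coupon_code_used=c.code)
        child.interview_complete = True
        roster.add(child)
        t_queue = 20 * DAY + 3 * HOUR
        queue_referral_payment(recruiter, reg, roster, ledger, now=t_queue)
        assert process_queue(ledger, now=t_queue + 10 * HOUR) == []  # before 02:00
        payouts = process_queue(ledger, now=21 * DAY + 2 * HOUR)
        assert len(payouts) == 1
        assert payouts[0].processed_at == 21 * DAY + 2 * HOUR

    def test_interview_paid_on_3_minute_tick(self):
        ledger = PaymentLedger()
        req = queue_interview_payment(_completer(), ledger, PaymentTimingPolicy(), now=100)
        payouts = process_queue(ledger, now=req.due_at + 3 * MINUTE)
        assert len(payouts) == 1
        assert payouts[0].processed_at % (3 * MINUTE) == 0
        assert payouts[0].processed_at >= req.due_at

    def test_empty_queue(self):
        assert process_queue(PaymentLedger(), now=10 * DAY) == []

    def test_revalidation_failure_rejects(self):
        ledger = PaymentLedger()
        queue_interview_payment(_completer(), ledger, PaymentTimingPolicy(), now=0)
        payouts = process_queue(ledger, now=DAY, revalidate=lambda r: False)
        assert payouts == []
        assert ledger.requests[0].status == PaymentStatus.REJECTED

    def test_referral_payouts_always_at_0200(self):
        ledger = PaymentLedger()
        for i, t in enumerate([0, 5 * HOUR, DAY + 1, 3 * DAY + 2 * HOUR]):
            rec = _completer(f"R{i}", f"ph{i}")
            from webrds.payments import PaymentRequest
            ledger.add(PaymentRequest(phone=rec.phone, ptype=PaymentType.REFERRAL,
                                      amount=160, queued_at=t, due_at=t))
        payouts = process_queue(ledger, now=30 * DAY)
        assert len(payouts) == 4
        for p in payouts:
            assert p.processed_at % DAY == 2 * HOUR


class TestLedgerConservation:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["q_int", "q_blood", "process"]),
                              st.sampled_from(["ph1", "ph2", "ph3"]),
                              st.integers(0, 10 * DAY)),
                    min_size=1, max_size=30))
    def test_never_pays_phone_type_twice(self, ops):
        """Under arbitrary interleavings of queue/process calls, at most one
        payout per (phone, type), and total paid equals the sum of paid rows."""
        ledger = PaymentLedger()
        timing = PaymentTimingPolicy()
        for op, phone, t in ops:
            if op == "process":
                process_queue(ledger, now=t)
            else:
                ptype = PaymentType.INTERVIEW if op == "q_int" else PaymentType.BLOOD_DRAW
                queue_interview_payment(_completer(phone, phone), ledger, timing,
                                        now=t, ptype=ptype)
        process_queue(ledger, now=100 * DAY)
        paid = [r for r in ledger.requests if r.status == PaymentStatus.PAID]
        keys = [(r.phone, r.ptype) for r in paid]
        assert len(keys) == len(set(keys))
        assert ledger.total_paid() == sum(r.amount for r in paid)


def _brute_force_min_count(amount, denoms):
    """Minimal multiset by exhaustive enumeration of per-denomination counts."""
    best = None
    ranges = [range(amount // d + 1) for d in denoms]
    for counts in itertools.product(*ranges):
        if sum(c * d for c, d in zip(counts, denoms)) == amount:
            if best is None or sum(counts) < sum(best):
                best = counts
    if best is None:
        return None
    out = []
    for c, d in zip(best, denoms):
        out.extend([d] * c)
    return sorted(out, reverse=True)


class TestDenomination:
    def test_interview_amount(self):
        assert denominate(940, (500, 200, 100, 20)) == [500, 200, 200, 20, 20]

    def test_zero(self):
        assert denominate(0, (500, 200)) == []

    def test_exact_pair(self):
        assert denominate(160, (100, 60)) == [100, 60]

    def test_non_canonical_set_still_minimal(self):
        # greedy would return [400, 100, 100]; the minimum is two codes
        assert denominate(600, (400, 300, 100)) == [300, 300]

    def test_unrepresentable(self):
        with pytest.raises(PaymentError):
            denominate(130, (100, 60))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(25, 400), min_size=1, max_size=3),
        st.integers(0, 500),
    )
    def test_matches_brute_force_oracle(self, denom_set, amount):
        denoms = tuple(sorted(denom_set, reverse=True))
        oracle = _brute_force_min_count(amount, denoms)
        if oracle is None:
            with pytest.raises(PaymentError):
                denominate(amount, denoms)
        else:
            result = denominate(amount, denoms)
            assert sum(result) == amount
            assert len(result) == len(oracle)
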