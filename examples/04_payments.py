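"""Compensation queue: scheduling, one-payment-per-type, denomination.

Queues an interview payment before and after the anti-fraud mitigation,
processes the queue on its ticks, and splits amounts into e-money
redemption codes.
"""

from webrds import (
    PaymentLedger,
    PaymentTimingPolicy,
    apply_mitigation,
    denominate,
    process_queue,
    queue_interview_payment,
)
from webrds.clock import DAY, MINUTE
from webrds.funnel import ParticipantRecord

def completer(pid, phone):
    rec = ParticipantRecord(participant_id=pid, role="seed", phone=phone)
    rec.interview_complete = True
    return rec

ledger = PaymentLedger()
timing = PaymentTimingPolicy()

req = queue_interview_payment(completer("P1", "ph1"), ledger, timing, now=1000)
print(f"pre-mitigation: ${req.amount/100:.2f} due after {(req.due_at-req.queued_at)//MINUTE} min")

apply_mitigation(timing, at=33 * DAY)
req2 = queue_interview_payment(completer("P2", "ph2"), ledger, timing, now=40 * DAY)
print(f"post-mitigation: ${req2.amount/100:.2f} due after {(req2.due_at-req2.queued_at)//DAY} days")
# delaying the payout from 3 minutes to 3 days makes rapid repeated
# fraudulent enrollment unattractive

dup = queue_interview_payment(completer("P1b", "ph1"), ledger, timing, now=2000)
print(f"second request for ph1: {dup.status.value} (one payment per phone per type)")

payouts = process_queue(ledger, now=44 * DAY)
print(f"processed: {len(payouts)} payouts, total ${ledger.total_paid()/100:.2f}")

codes = denominate(940, (500, 200, 100, 20))
print("US $9.40 as e-money codes:", [f"${c/100:.2f}" for c in codes])
# minimal-count combination summing exactly to the amount
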