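"""Fraud detection, the invalidation cascade, and data-quality screens.

Fraud signals are advisory: the scan reports suspicious patterns (rapid
coupon redemption, recruiter and recruit sharing an IP address, reuse
attempts on spent codes, re-enrolling devices, and externally reported
phone rentals), and a separate explicit marking step flags records and
cancels their outstanding referral coupons.  The two quality screens
are an attention-filter item (the respondent is told which category to
pick) and a straightlining scan over nine adjacent skip-free items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .clock import DAY, MINUTE
from .coupons import CouponRegistry, FailureReason
from .eventlog import SurveyEventLog
from .funnel import Roster
from .questionnaire import Questionnaire, SchemaError


@dataclass(frozen=True)
class FraudSignal:
    record_id: str
    signal: str  # shared_ip_with_recruiter | rapid_redemption | coupon_reuse_attempt
    #              | phone_rental_report | cookie_anomaly
    evidence: str = ""


@dataclass(frozen=True)
class QualityFlag:
    record_id: str
    failed_attention: bool
    straightlined: bool


@dataclass
class FraudThresholds:
    #: redemption faster than this after coupon activation is suspicious
    min_latency: int = 1 * MINUTE


@dataclass
class PaymentTimingPolicy:
    """Effective-dated delay between interview completion and payout.

    The anti-fraud mitigation changes the delay from 3 minutes to 3 days
    from a cutover time onward; requests queued earlier keep the delay
    in force when they were queued.
    """

    initial_delay: int = 3 * MINUTE
    mitigated_delay: int = 3 * DAY
    mitigation_at: int | None = None  # survey time of the cutover, None = never

    def delay_at(self, now: int) -> int:
        if self.mitigation_at is not None and now >= self.mitigation_at:
            return self.mitigated_delay
        return self.initial_delay


def apply_mitigation(
    policy: PaymentTimingPolicy, at: int, sim_config: Any | None = None
) -> PaymentTimingPolicy:
    """Activate the anti-fraud payment delay (3 min -> 3 days) at `at`.

    If a simulator config is passed, its fraud agents switch to the
    reduced post-mitigation attempt rate at the same time.
    """
    policy.mitigation_at = at
    if sim_config is not None and getattr(sim_config, "fraud", None) is not None:
        sim_config.mitigation_day = at // DAY
    return policy


def scan_fraud_signals(
    log: SurveyEventLog,
    registry: CouponRegistry,
    thresholds: FraudThresholds | None = None,
) -> list[FraudSignal]:
    """Run the fraud-detecting rules over a time-ordered event log.

    Deterministic given inputs; one signal per rule hit.  The
    phone-rental rule is driven by injected report events, modeling the
    staff call-back discovery rather than an inference.
    """
    thresholds = thresholds or FraudThresholds()
    signals: list[FraudSignal] = []
    issue_t: dict[str, int] = {}
    issuer_of: dict[str, str] = {}
    ip_of: dict[str, str] = {}

    for ev in log:
        p = ev.payload
        if ev.kind == "coupon_issued":
            issue_t[p["code"]] = ev.t
            issuer_of[p["code"]] = p["issuer"]
        elif ev.kind == "portal_entry":
            pid = p.get("participant_id", "")
            code = p.get("code")
            ip = p.get("ip")
            if ip and pid:
                ip_of[pid] = ip
            if code is not None and code in issue_t:
                rec = registry._by_code.get(code)
                already_redeemed = (
                    rec is not None
                    and rec.redeemed_by is not None
                    and rec.redeemed_by != pid
                )
                if already_redeemed:
                    signals.append(
                        FraudSignal(pid, "coupon_reuse_attempt", f"code={code}")
                    )
                    continue
                latency = ev.t - issue_t[code]
                if latency < thresholds.min_latency:
                    signals.append(
                        FraudSignal(pid, "rapid_redemption", f"latency={latency}s")
                    )
                recruiter = issuer_of.get(code)
                if ip and recruiter in ip_of and ip_of[recruiter] == ip:
                    signals.append(
                        FraudSignal(pid, "shared_ip_with_recruiter", f"ip={ip}")
                    )
            if p.get("device_state") == "already_used":
                signals.append(
                    FraudSignal(pid, "cookie_anomaly", f"device={p.get('device')}")
                )
        elif ev.kind == "phone_rental_report":
            for pid in p["participant_ids"]:
                signals.append(FraudSignal(pid, "phone_rental_report"))
    return signals


@dataclass
class CascadeReport:
    flagged: list[str] = field(default_factory=list)
    already_flagged: list[str] = field(default_factory=list)
    cancelled_codes: list[str] = field(default_factory=list)


def mark_fraud(
    roster: Roster,
    registry: CouponRegistry,
    record_ids: Sequence[str],
) -> CascadeReport:
    """Flag records as fraudulent and disable their outstanding coupons.

    All unredeemed referral coupons issued by flagged records are
    cancelled; recruits who already redeemed a coupon from a flagged
    recruiter are NOT retroactively flagged — they stand on their own
    signals.  Idempotent: re-marking a flagged record changes nothing.
    """
    report = CascadeReport()
    for pid in record_ids:
        rec = roster.get(pid)
        if rec.fraud:
            report.already_flagged.append(pid)
            continue
        rec.fraud = True
        report.flagged.append(pid)
        for coupon in registry.records():
            if coupon.issuer == pid and not coupon.used and not coupon.cancelled:
                coupon.cancelled = True
                report.cancelled_codes.append(coupon.code)
    return report


def attention_filter(responses: Mapping[str, Any], questionnaire: Questionnaire) -> bool:
    """True iff the designated attention item carries the instructed answer."""
    item = questionnaire.attention_item
    if item not in responses or responses[item] is None:
        raise SchemaError(f"attention item {item!r} missing from responses")
    return responses[item] == questionnaire.attention_expected


def straightline_detect(
    responses: Mapping[str, Any], questionnaire: Questionnaire
) -> bool:
    """True iff all answers in the designated 9-item window are identical."""
    window = questionnaire.straightline_window
    values = [responses.get(name) for name in window]
    if any(v is None for v in values):
        raise SchemaError("straightline window items not all answered")
    return len(set(values)) == 1


def quality_flags(
    roster: Roster, questionnaire: Questionnaire
) -> dict[str, QualityFlag]:
    """Compute attention/straightline flags for every completed interview."""
    flags: dict[str, QualityFlag] = {}
    for pid, rec in roster.participants.items():
        if not rec.interview_complete:
            continue
        flags[pid] = QualityFlag(
            record_id=pid,
            failed_attention=not attention_filter(rec.interview_responses, questionnaire),
            straightlined=straightline_detect(rec.interview_responses, questionnaire),
        )
    return flags


def audit(
    log: SurveyEventLog,
    registry: CouponRegistry,
    roster: Roster,
    questionnaire: Questionnaire,
    thresholds: FraudThresholds | None = None,
) -> dict:
    """Full quality audit: scan signals, mark phone-rental fraud with its
    cascade, and compute quality flags.  Returns a JSON-ready report."""
    signals = scan_fraud_signals(log, registry, thresholds)
    rental_ids = sorted(
        {s.record_id for s in signals if s.signal == "phone_rental_report"}
    )
    cascade = mark_fraud(roster, registry, rental_ids)
    flags = quality_flags(roster, questionnaire)
    return {
        "signals": [
            {"record_id": s.record_id, "signal": s.signal, "evidence": s.evidence}
            for s in signals
        ],
        "fraud_flagged": cascade.flagged,
        "cancelled_codes": cascade.cancelled_codes,
        "quality_flags": {
            pid: {"failed_attention": f.failed_attention, "straightlined": f.straightlined}
            for pid, f in flags.items()
        },
    }
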