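"""Rebuild registry and roster state by replaying a survey event log.

The replay re-executes the funnel logic on the raw event material —
coupon validation and phone dedup at the portal, eligibility screening
on the recorded answers, questionnaire completeness against the skip
logic — rather than trusting any outcome labels, so downstream
tabulations are genuine recomputations.
"""

from __future__ import annotations

from .coupons import CouponRecord, CouponRegistry
from .eventlog import SurveyEventLog
from .funnel import EligibilityRule, Roster, enter_portal, screen
from .questionnaire import Questionnaire, default_questionnaire


def replay(
    log: SurveyEventLog,
    questionnaire: Questionnaire | None = None,
    rule: EligibilityRule | None = None,
) -> tuple[CouponRegistry, Roster]:
    """Replay a time-ordered event log into (registry, roster)."""
    questionnaire = questionnaire or default_questionnaire()
    rule = rule or EligibilityRule()
    registry = CouponRegistry()
    roster = Roster()

    for ev in log:
        p = ev.payload
        if ev.kind == "coupon_issued":
            registry.insert(
                CouponRecord(
                    code=p["code"],
                    issuer=p["issuer"],
                    activated=True,
                    activation_date=ev.t,
                    expiration_date=p.get("expires", ev.t),
                )
            )
        elif ev.kind == "portal_entry":
            enter_portal(
                p.get("code"),
                p["phone"],
                registry,
                roster,
                now=ev.t,
                participant_id=p.get("participant_id"),
                ip=p.get("ip"),
                device=p.get("device"),
                device_state=p.get("device_state", "not_used_before"),
                user_agent=p.get("user_agent", ""),
            )
        elif ev.kind == "screened":
            rec = roster.get(p["participant_id"])
            rec.screening_answers = dict(p["answers"])
            rec.screening_result = screen(rec.screening_answers, rule)
        elif ev.kind == "consented":
            roster.get(p["participant_id"]).consent = bool(p["consent"])
        elif ev.kind == "interview_started":
            rec = roster.get(p["participant_id"])
            rec.interview_start = ev.t
            rec.interview_token = p.get("token", rec.interview_token)
        elif ev.kind == "interview_completed":
            rec = roster.get(p["participant_id"])
            responses = dict(p["responses"])
            rec.interview_responses = responses
            rec.interview_complete = questionnaire.is_complete(responses)
            rec.interview_end = ev.t
            if responses.get("degree") is not None:
                rec.degree = int(responses["degree"])
            rec.region = responses.get("region", rec.region)
            rec.province = responses.get("province", rec.province)
        elif ev.kind == "fraud_flagged":
            roster.get(p["participant_id"]).fraud = True
        # otp_verified, coupons_sent, payment_*, phone_rental_report:
        # no roster state; the fraud scan consumes rental reports itself.
    return registry, roster
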