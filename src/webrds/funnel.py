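"""Participant journey: portal entry, dedup, screening, consent, interview.

Every issued e-coupon ends up with exactly one funnel disposition.  A
coupon that is never submitted is *unredeemed*; a submitted coupon is
consumed by the attempt and its record moves through phone
deduplication, eligibility screening, consent, the interview, and the
post-hoc fraud and attention-filter screens.  Classification follows a
fixed precedence (first match wins) mirroring the nested funnel
accounting: duplicate phone, screening incomplete, ineligible, consent
refused, questionnaire incomplete, fraud, failed attention filter,
valid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Optional

import numpy as np

from .coupons import CouponPolicy, CouponRecord, CouponRegistry
from .eventlog import SurveyEventLog
from .questionnaire import Questionnaire, SchemaError, default_questionnaire

SEED_PORTAL = "SEED_PORTAL"


class Disposition(str, Enum):
    UNREDEEMED = "unredeemed"
    DUPLICATE_PHONE = "duplicate_phone"
    SCREENING_INCOMPLETE = "screening_incomplete"
    INELIGIBLE = "ineligible"
    CONSENT_REFUSED = "consent_refused"
    QUESTIONNAIRE_INCOMPLETE = "questionnaire_incomplete"
    FRAUD = "fraud"
    FAILED_ATTENTION_FILTER = "failed_attention_filter"
    VALID = "valid"


class PortalOutcome(str, Enum):
    REJECTED_COUPON = "rejected_coupon"
    REJECTED_DUPLICATE_PHONE = "rejected_duplicate_phone"
    PROCEED = "proceed"


class ScreenResult(str, Enum):
    ELIGIBLE = "eligible"
    INELIGIBLE = "ineligible"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class EligibilityRule:
    """Self-reported inclusion criteria; all must hold.

    Defaults encode the survey population: men aged 15+ reporting anal
    sex with a man in the last 6 months, resident in-country, able to
    read the survey language.  Seeds are exempt from the coupon
    requirement, which is checked upstream at the portal.
    """

    criteria: tuple[str, ...] = (
        "male",
        "age",
        "anal_sex_6m",
        "resides_in_country",
        "reads_language",
    )
    min_age: int = 15

    def satisfied(self, key: str, answer: Any) -> bool:
        if key == "age":
            return int(answer) >= self.min_age
        return bool(answer)


def screen(answers: Mapping[str, Any], rule: EligibilityRule) -> ScreenResult:
    """Evaluate eligibility screening answers against the rule.

    Incomplete if any criterion is unanswered; ineligible if any answered
    criterion fails.  Which criterion failed is deliberately not part of
    the result: candidates are exited without disclosing the reason.
    """
    for key in answers:
        if key not in rule.criteria:
            raise SchemaError(f"unknown screening criterion: {key!r}")
    if any(answers.get(k) is None for k in rule.criteria):
        return ScreenResult.INCOMPLETE
    if any(not rule.satisfied(k, answers[k]) for k in rule.criteria):
        return ScreenResult.INELIGIBLE
    return ScreenResult.ELIGIBLE


@dataclass
class ParticipantRecord:
    participant_id: str
    role: str  # "seed" | "recruit"
    phone: str
    recruiter_id: Optional[str] = None
    coupon_code_used: Optional[str] = None
    ip: Optional[str] = None
    device_fingerprint: Optional[str] = None
    device_state: str = "not_used_before"
    user_agent: str = ""
    entered_at: Optional[int] = None
    duplicate_phone: bool = False
    screening_answers: dict = field(default_factory=dict)
    screening_result: Optional[ScreenResult] = None
    consent: Optional[bool] = None
    interview_token: Optional[str] = None
    interview_responses: dict = field(default_factory=dict)
    interview_start: Optional[int] = None
    interview_end: Optional[int] = None
    interview_complete: bool = False
    degree: Optional[int] = None
    region: Optional[str] = None
    province: Optional[str] = None
    fraud: bool = False

    def __post_init__(self) -> None:
        if self.role == "recruit" and not (self.coupon_code_used and self.recruiter_id):
            raise ValueError("recruit records need coupon_code_used and recruiter_id")
        if self.role == "seed" and (self.coupon_code_used or self.recruiter_id):
            raise ValueError("seed records must not carry a coupon or recruiter")


@dataclass
class Roster:
    """All participant records plus the phone and token uniqueness sets."""

    participants: dict[str, ParticipantRecord] = field(default_factory=dict)
    phones: set[str] = field(default_factory=set)
    tokens: set[str] = field(default_factory=set)
    _counter: int = 0

    def __len__(self) -> int:
        return len(self.participants)

    def get(self, pid: str) -> ParticipantRecord:
        try:
            return self.participants[pid]
        except KeyError:
            raise KeyError(f"unknown participant: {pid!r}") from None

    def new_id(self) -> str:
        self._counter += 1
        return f"P{self._counter:05d}"

    def add(self, record: ParticipantRecord) -> None:
        if record.participant_id in self.participants:
            raise ValueError(f"duplicate participant id: {record.participant_id!r}")
        self.participants[record.participant_id] = record


def enter_portal(
    code: Optional[str],
    phone: str,
    registry: CouponRegistry,
    roster: Roster,
    now: int,
    *,
    participant_id: Optional[str] = None,
    ip: Optional[str] = None,
    device: Optional[str] = None,
    device_state: str = "not_used_before",
    user_agent: str = "",
) -> tuple[PortalOutcome, Optional[ParticipantRecord]]:
    """Process one portal access: coupon validation, then phone dedup.

    Seeds enter through a separate portal with no coupon and skip the
    coupon check but not the duplicate-phone check.  On PROCEED the
    coupon is marked used and the phone registered; a duplicate-phone
    rejection still consumes (redeems) the coupon, since the submission
    itself is the redemption.
    """
    role = "seed" if code is None else "recruit"
    recruiter_id = None
    if code is not None:
        result = registry.validate(code, now)
        if not result.valid:
            return PortalOutcome.REJECTED_COUPON, None
        recruiter_id = registry.get(code).issuer

    pid = participant_id or roster.new_id()
    if phone in roster.phones:
        if code is not None:
            registry.redeem(code, by=pid, at=now)
        if role == "recruit":
            rec = ParticipantRecord(
                participant_id=pid,
                role=role,
                phone=phone,
                recruiter_id=recruiter_id,
                coupon_code_used=code,
                ip=ip,
                device_fingerprint=device,
                device_state=device_state,
                user_agent=user_agent,
                entered_at=now,
                duplicate_phone=True,
            )
            roster.add(rec)
            return PortalOutcome.REJECTED_DUPLICATE_PHONE, rec
        return PortalOutcome.REJECTED_DUPLICATE_PHONE, None

    if code is not None:
        registry.redeem(code, by=pid, at=now)
    rec = ParticipantRecord(
        participant_id=pid,
        role=role,
        phone=phone,
        recruiter_id=recruiter_id,
        coupon_code_used=code,
        ip=ip,
        device_fingerprint=device,
        device_state=device_state,
        user_agent=user_agent,
        entered_at=now,
    )
    roster.add(rec)
    roster.phones.add(phone)
    return PortalOutcome.PROCEED, rec


def issue_token(
    participant: ParticipantRecord,
    roster: Roster,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Autogenerate the participant's unique 11-digit interview token.

    The token gates interview access (wrong or inactive tokens are
    ignored upstream); collisions with existing tokens are retried
    internally and never surfaced.
    """
    if participant.consent is not True:
        raise ValueError("token issued only after consent")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    while True:
        token = "".join(str(d) for d in rng.integers(0, 10, size=11))
        if token not in roster.tokens:
            roster.tokens.add(token)
            participant.interview_token = token
            return token


def complete_interview(
    participant: ParticipantRecord,
    responses: Mapping[str, Any],
    policy: CouponPolicy,
    registry: CouponRegistry,
    now: int,
    questionnaire: Questionnaire | None = None,
    rng: np.random.Generator | int | None = None,
    log: SurveyEventLog | None = None,
) -> list[CouponRecord]:
    """Finish the interview and issue the recruiter's referral coupons.

    Programmed skips are honored: only applicable required items must be
    answered.  An incomplete submission leaves the record in the
    questionnaire-incomplete state and issues nothing.
    """
    questionnaire = questionnaire or default_questionnaire()
    participant.interview_responses = dict(responses)
    missing = questionnaire.missing_required(responses)
    if missing:
        participant.interview_complete = False
        return []
    participant.interview_complete = True
    participant.interview_end = now
    participant.degree = int(responses.get("degree") or 0) or participant.degree
    participant.region = responses.get("region", participant.region)
    participant.province = responses.get("province", participant.province)
    n = policy.coupons_for(
        {"region": participant.region, "age": responses.get("age")}
    )
    coupons = registry.generate(n, issuer=participant.participant_id, now=now, rng=rng)
    if log is not None and n > 0:
        # models the SMS carrying the referral codes
        log.append(
            now,
            "coupons_sent",
            participant_id=participant.participant_id,
            codes=[c.code for c in coupons],
        )
    return coupons


#: Precedence for multiply-flagged records; first match wins.  Fraud
#: outranks the attention filter because the filter is applied only
#: within non-fraud completers in the funnel accounting.
_PRECEDENCE_DOC = True


def classify_disposition(
    record: ParticipantRecord, quality_flags: Optional[object] = None
) -> Disposition:
    """Assign the single funnel disposition of an enrolled record."""
    if record.duplicate_phone:
        return Disposition.DUPLICATE_PHONE
    if record.screening_result in (None, ScreenResult.INCOMPLETE):
        return Disposition.SCREENING_INCOMPLETE
    if record.screening_result == ScreenResult.INELIGIBLE:
        return Disposition.INELIGIBLE
    if record.consent is not True:
        return Disposition.CONSENT_REFUSED
    if not record.interview_complete:
        return Disposition.QUESTIONNAIRE_INCOMPLETE
    if record.fraud:
        return Disposition.FRAUD
    if quality_flags is not None and getattr(quality_flags, "failed_attention", False):
        return Disposition.FAILED_ATTENTION_FILTER
    return Disposition.VALID


def coupon_dispositions(
    registry: CouponRegistry,
    roster: Roster,
    flags: Mapping[str, object] | None = None,
) -> dict[str, Disposition]:
    """Disposition of every issued coupon (unredeemed ones included)."""
    flags = flags or {}
    out: dict[str, Disposition] = {}
    for rec in registry.records():
        if not rec.used or rec.redeemed_by is None:
            out[rec.code] = Disposition.UNREDEEMED
            continue
        participant = roster.get(rec.redeemed_by)
        out[rec.code] = classify_disposition(
            participant, flags.get(participant.participant_id)
        )
    return out


def export_roster(roster: Roster, path: str, flags: Mapping[str, object] | None = None) -> None:
    """Participant roster CSV: id, role, recruiter, coupon, geography, degree, disposition."""
    flags = flags or {}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "participant_id",
                "role",
                "recruiter_id",
                "coupon_code_used",
                "region",
                "province",
                "degree",
                "disposition",
            ]
        )
        for rec in roster.participants.values():
            w.writerow(
                [
                    rec.participant_id,
                    rec.role,
                    rec.recruiter_id or "",
                    rec.coupon_code_used or "",
                    rec.region or "",
                    rec.province or "",
                    rec.degree if rec.degree is not None else "",
                    classify_disposition(rec, flags.get(rec.participant_id)).value,
                ]
            )
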