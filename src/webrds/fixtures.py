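"""Deterministic record-level fixture emulating the observed survey funnel.

The generator emits a full event log — 35 seeds plus 6207 issued
e-coupons of which 3000 are redeemed — whose latent record attributes
(phone reuse, screening answers, consent, interview completeness,
rented-phone fraud markers, attention-filter answers, one straightlined
fraud record, redemption delays, and device user agents) are constructed
so that replaying the log through the real funnel, fraud audit, and
tabulation code recovers the published record-level accounting:

* funnel: 3207 unredeemed / 3000 redeemed / 464 duplicate phone /
  2536 screened (297 incomplete, 136 ineligible, 2103 eligible) /
  8 consent refusals / 2095 consented / 64 questionnaire-incomplete /
  2031 completed / 317 fraud recruits (+1 fraud seed) / 99 attention-
  filter failures / 1615 valid;
* redemption delays: bin counts 1441, 294, 574, 445, 159, 49, 36, 2
  over (0,30min], (30min,1h], (1h,6h], (6h,1d], (1d,3d], (3d,7d],
  (7d,14d], >14d;
* devices: 2090 mobile (1664 Chrome, 393 Safari, 33 other) and
  910 desktop/laptop redemptions.

Counts are invariant to the seed; the seed only permutes which records
carry which attributes and the within-bin delay draws.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

from .clock import DAY, HOUR, MINUTE
from .coupons import CouponRegistry
from .eventlog import SurveyEventLog
from .questionnaire import Questionnaire, default_questionnaire
from .sim import DELAY_BIN_COUNTS, DELAY_BIN_EDGES

DEFAULT_FIXTURE_SEED = 20220201

N_SEEDS_INITIAL = 21
N_SEEDS_ADDED = 14
N_COUPONS = 6207
N_REDEEMED = 3000

_LABEL_COUNTS = {
    "duplicate_phone": 464,
    "screening_incomplete": 297,
    "ineligible": 136,
    "consent_refused": 8,
    "questionnaire_incomplete": 64,
    "fraud": 317,
    "failed_attention_filter": 99,
    "valid": 1615,
}
_COMPLETER_LABELS = frozenset({"fraud", "failed_attention_filter", "valid"})

UA_MOBILE_CHROME = (
    "Mozilla/5.0 (Linux; Android 12; SM-G991B) AppleWebKit/537.36 "
    "(KHTML, like Gecko) Chrome/98.0.4758.87 Mobile Safari/537.36"
)
UA_MOBILE_SAFARI = (
    "Mozilla/5.0 (iPhone; CPU iPhone OS 15_3 like Mac OS X) AppleWebKit/605.1.15 "
    "(KHTML, like Gecko) Version/15.3 Mobile/15E148 Safari/604.1"
)
UA_MOBILE_OTHER = "Mozilla/5.0 (Android 12; Mobile; rv:97.0) Gecko/97.0 Firefox/97.0"
UA_DESKTOP_CHROME = (
    "Mozilla/5.0 (Windows NT 10.0; Win64; x64) AppleWebKit/537.36 "
    "(KHTML, like Gecko) Chrome/98.0.4758.82 Safari/537.36"
)
UA_DESKTOP_SAFARI = (
    "Mozilla/5.0 (Macintosh; Intel Mac OS X 10_15_7) AppleWebKit/605.1.15 "
    "(KHTML, like Gecko) Version/15.3 Safari/605.1.15"
)

# browser mix observed among the 2090 mobile redemptions; desktop browsers
# are not part of the published browser split
_UA_COUNTS = (
    (UA_MOBILE_CHROME, 1664),
    (UA_MOBILE_SAFARI, 393),
    (UA_MOBILE_OTHER, 33),
    (UA_DESKTOP_CHROME, 610),
    (UA_DESKTOP_SAFARI, 300),
)


def _feasible_label_order(labels: list[str], initial_supply: int) -> list[str]:
    """Reorder labels so the coupon queue never runs dry.

    Each redemption consumes one outstanding coupon; only completer
    labels replenish the queue (3 codes each).  Whenever the running
    supply would hit zero, the next completer label ahead is swapped
    forward.  With the survey's totals a swap is almost never needed,
    but the guard makes the generator valid under any permutation.
    """
    labels = list(labels)
    supply = initial_supply
    for k in range(len(labels)):
        if supply <= 1 and labels[k] not in _COMPLETER_LABELS:
            for j in range(k + 1, len(labels)):
                if labels[j] in _COMPLETER_LABELS:
                    labels[k], labels[j] = labels[j], labels[k]
                    break
            else:
                raise RuntimeError("coupon supply infeasible")  # pragma: no cover
        supply -= 1
        if labels[k] in _COMPLETER_LABELS:
            supply += 3
        assert supply >= 0
    return labels


def _delay_multiset(rng: np.random.Generator) -> list[int]:
    delays: list[int] = []
    for i, count in enumerate(DELAY_BIN_COUNTS):
        lo, hi = DELAY_BIN_EDGES[i], DELAY_BIN_EDGES[i + 1]
        delays.extend(int(x) for x in rng.integers(lo + 1, hi + 1, size=count))
    return [delays[i] for i in rng.permutation(len(delays))]


def _ua_multiset(rng: np.random.Generator) -> list[str]:
    uas: list[str] = []
    for ua, count in _UA_COUNTS:
        uas.extend([ua] * count)
    return [uas[i] for i in rng.permutation(len(uas))]


def _eligible_answers(rng: np.random.Generator) -> dict:
    return {
        "male": True,
        "age": int(rng.integers(15, 60)),
        "anal_sex_6m": True,
        "resides_in_country": True,
        "reads_language": True,
    }


def _completer_responses(
    rng: np.random.Generator,
    questionnaire: Questionnaire,
    *,
    attention_pass: bool,
    straightline: bool,
    province: int,
) -> dict:
    responses = {
        "degree": int(rng.integers(1, 40)),
        "region": f"R{province % 6}",
        "province": f"P{province:02d}",
        "age": int(rng.integers(15, 60)),
        "hiv_test_12m": int(rng.random() < 0.6),
        "knows_status": int(rng.random() < 0.7),
        "condom_last_sex": int(rng.random() < 0.5),
    }
    window = questionnaire.straightline_window
    if straightline:
        val = int(rng.integers(1, 5))
        for name in window:
            responses[name] = val
    else:
        vals = [int(x) for x in rng.integers(1, 5, size=len(window))]
        if len(set(vals)) == 1:
            vals[0] = vals[0] % 4 + 1
        responses.update(zip(window, vals))
    if attention_pass:
        responses["attention"] = questionnaire.attention_expected
    else:
        wrong = [a for a in ("red", "green", "yellow")]
        responses["attention"] = wrong[int(rng.integers(len(wrong)))]
    if responses["hiv_test_12m"] == 1:
        responses["test_result_received"] = int(rng.random() < 0.8)
    return responses


def generate_funnel_fixture(rng_seed: int = DEFAULT_FIXTURE_SEED) -> SurveyEventLog:
    """Emit the deterministic funnel fixture event log.

    35 seeds (the first of which is the fraudulent one) enroll and issue
    3 coupons each; 3 seeds receive one administrative re-issue of 3
    codes, for 114 seed-attributed coupons; the 2031 completing recruits
    issue 3 each, totalling 6207 issued coupons.  Fraudulent recruits
    preferentially redeem codes from the fraud subtree with fresh
    "rented" phone numbers and a shared IP pool; a phone-rental report
    event after the last fraudulent enrollment drives the audit.
    """
    rng = np.random.default_rng(rng_seed)
    questionnaire = default_questionnaire()
    registry = CouponRegistry(expiry_interval=28 * DAY)
    log = SurveyEventLog(meta={"seed": int(rng_seed), "kind": "funnel-fixture"})
    counter = itertools.count()

    labels = [lab for lab, cnt in _LABEL_COUNTS.items() for _ in range(cnt)]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    labels = _feasible_label_order(labels, initial_supply=114)
    delays = _delay_multiset(rng)
    uas = _ua_multiset(rng)

    fraud_queue: list[tuple[int, int, str]] = []
    normal_queue: list[tuple[int, int, str]] = []
    token_pool: set[str] = set()
    # (portal time, phone) of every enrolled phone, for duplicate draws
    registered: list[tuple[int, str]] = []
    fraud_ips = [f"ip-fx{i}" for i in range(3)]
    fraud_pids: list[str] = []
    last_fraud_t = 0

    def new_token() -> str:
        while True:
            tok = "".join(str(d) for d in rng.integers(0, 10, size=11))
            if tok not in token_pool:
                token_pool.add(tok)
                return tok

    def issue_coupons(pid: str, t: int, n: int, to_fraud: bool) -> None:
        codes = []
        for c in registry.generate(n, issuer=pid, now=t, rng=rng):
            log.append(t, "coupon_issued", code=c.code, issuer=pid, expires=c.expiration_date)
            heapq.heappush(
                fraud_queue if to_fraud else normal_queue,
                (t, next(counter), c.code),
            )
            codes.append(c.code)
        log.append(t + 30, "coupons_sent", participant_id=pid, codes=codes)

    # --- seeds -----------------------------------------------------------
    seed_times = [HOUR + i * 10 * MINUTE for i in range(N_SEEDS_INITIAL)] + [
        int(t) for t in np.linspace(20 * DAY, 80 * DAY, N_SEEDS_ADDED)
    ]
    for i, t0 in enumerate(seed_times):
        pid = f"S{i + 1:02d}"
        is_fraud_seed = i == 0
        phone = f"ph-rental-seed" if is_fraud_seed else f"ph-{pid}"
        ip = fraud_ips[0] if is_fraud_seed else f"ip-{pid}"
        log.append(
            t0,
            "portal_entry",
            participant_id=pid,
            code=None,
            phone=phone,
            ip=ip,
            device=f"dev-{pid}",
            device_state="not_used_before",
            user_agent=UA_MOBILE_CHROME,
        )
        registered.append((t0, phone))
        log.append(t0 + 30, "otp_verified", participant_id=pid)
        log.append(t0 + 60, "screened", participant_id=pid, answers=_eligible_answers(rng))
        log.append(t0 + 120, "consented", participant_id=pid, consent=True)
        log.append(t0 + 180, "interview_started", participant_id=pid, token=new_token())
        prov = int(rng.integers(75))
        responses = _completer_responses(
            rng, questionnaire, attention_pass=True, straightline=False, province=prov
        )
        log.append(t0 + 780, "interview_completed", participant_id=pid, responses=responses)
        issue_coupons(pid, t0 + 840, 3, to_fraud=is_fraud_seed)
        if is_fraud_seed:
            fraud_pids.append(pid)
            last_fraud_t = t0 + 840
    # administrative re-issue: 3 extra codes to each of 3 seeds
    for i in (1, 2, 3):
        issue_coupons(f"S{i + 1:02d}", 60 * DAY, 3, to_fraud=False)

    # --- recruits: 3000 redemption slots ---------------------------------
    fraud_slot_indices = [k for k, lab in enumerate(labels) if lab == "fraud"]
    straightliner_slot = fraud_slot_indices[0]

    for k, label in enumerate(labels):
        is_fraud = label == "fraud"
        primary, fallback = (
            (fraud_queue, normal_queue) if is_fraud else (normal_queue, fraud_queue)
        )
        issue_t, _, code = heapq.heappop(primary if primary else fallback)
        t = issue_t + delays[k]
        pid = f"P{k + 1:04d}"

        if label == "duplicate_phone":
            earlier = [ph for (pt, ph) in registered if pt < t]
            phone = earlier[int(rng.integers(len(earlier)))]
        elif is_fraud:
            phone = f"ph-rental-{k:04d}"
        else:
            phone = f"ph-{pid}"
        ip = (
            fraud_ips[int(rng.integers(len(fraud_ips)))]
            if is_fraud
            else f"ip-{pid}"
        )
        device_state = (
            "already_used" if is_fraud and rng.random() < 0.25 else "not_used_before"
        )
        log.append(
            t,
            "portal_entry",
            participant_id=pid,
            code=code,
            phone=phone,
            ip=ip,
            device="dev-fx" if is_fraud else f"dev-{pid}",
            device_state=device_state,
            user_agent=uas[k],
        )
        if label == "duplicate_phone":
            continue
        registered.append((t, phone))
        log.append(t + 30, "otp_verified", participant_id=pid)

        if label == "screening_incomplete":
            answers = _eligible_answers(rng)
            answers[("age", "anal_sex_6m")[int(rng.integers(2))]] = None
            log.append(t + 60, "screened", participant_id=pid, answers=answers)
            continue
        if label == "ineligible":
            answers = _eligible_answers(rng)
            fail = ("male", "age", "anal_sex_6m", "resides_in_country", "reads_language")[
                int(rng.integers(5))
            ]
            answers[fail] = 14 if fail == "age" else False
            log.append(t + 60, "screened", participant_id=pid, answers=answers)
            continue
        log.append(t + 60, "screened", participant_id=pid, answers=_eligible_answers(rng))

        if label == "consent_refused":
            log.append(t + 120, "consented", participant_id=pid, consent=False)
            continue
        log.append(t + 120, "consented", participant_id=pid, consent=True)
        log.append(t + 180, "interview_started", participant_id=pid, token=new_token())

        if label == "questionnaire_incomplete":
            continue  # abandoned: no completion event, no coupons

        prov = int(rng.integers(75))
        responses = _completer_responses(
            rng,
            questionnaire,
            attention_pass=(label != "failed_attention_filter"),
            straightline=(k == straightliner_slot),
            province=prov,
        )
        log.append(t + 780, "interview_completed", participant_id=pid, responses=responses)
        issue_coupons(pid, t + 840, 3, to_fraud=is_fraud)
        if is_fraud:
            fraud_pids.append(pid)
            last_fraud_t = max(last_fraud_t, t + 840)

    # staff call-backs reveal the rented phones; one report event drives
    # the audit's fraud marking and its coupon-invalidation cascade
    log.append(last_fraud_t + DAY, "phone_rental_report", participant_ids=sorted(fraud_pids))

    log.sort()
    return log
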