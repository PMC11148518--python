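"""Agent-based simulator of the web-RDS recruitment process.

Seeds enroll through the seed portal and, like every later completer,
are issued referral e-coupons that they offer to up-to-k uniformly
chosen not-yet-enrolled neighbors in the contact graph.  Each offer is
redeemed with a configurable probability after a delay drawn from the
redemption-delay distribution (default: piecewise-uniform over the
observed delay bins).  All funnel stages run through the real engine
(coupon validation, phone dedup, screening, consent, interview,
issuance), so a simulated run produces the same event-log schema as the
deterministic fixture.  Optional fraud agents repeatedly enroll with
"rented" phone numbers and fresh device fingerprints at a configurable
daily attempt rate that drops after the mitigation day.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .clock import DAY, HOUR, MINUTE
from .coupons import CouponPolicy, CouponRegistry
from .eventlog import SurveyEventLog
from .funnel import PortalOutcome, Roster, enter_portal, issue_token, screen, EligibilityRule
from .questionnaire import Questionnaire, default_questionnaire

#: Redemption-delay bin edges in seconds (half-open (lo, hi]) and the
#: observed bin masses used as the default delay distribution.
DELAY_BIN_EDGES = (
    0,
    30 * MINUTE,
    1 * HOUR,
    6 * HOUR,
    1 * DAY,
    3 * DAY,
    7 * DAY,
    14 * DAY,
    21 * DAY,  # open upper bin capped at 21 days for sampling
)
DELAY_BIN_COUNTS = (1441, 294, 574, 445, 159, 49, 36, 2)


def sample_delay(rng: np.random.Generator) -> int:
    """Draw a redemption delay: bin by observed mass, uniform within bin."""
    total = sum(DELAY_BIN_COUNTS)
    idx = rng.choice(len(DELAY_BIN_COUNTS), p=[c / total for c in DELAY_BIN_COUNTS])
    lo, hi = DELAY_BIN_EDGES[idx], DELAY_BIN_EDGES[idx + 1]
    return int(rng.integers(lo + 1, hi + 1))


@dataclass
class FraudConfig:
    agent_count: int = 1
    attempt_rate: float = 10.0  # enrollment attempts per day before mitigation
    post_mitigation_rate: float = 0.5
    straightline_probability: float = 0.0


@dataclass
class SimConfig:
    initial_seeds: int = 21
    added_seeds: int = 14
    seed_add_times: Optional[list[int]] = None  # default: evenly spaced
    duration_days: int = 120
    coupon_schedule: list[tuple[int, int]] = field(default_factory=lambda: [(0, 3)])
    redemption_probability: float = 0.48
    delay_sampler: Callable[[np.random.Generator], int] = sample_delay
    coupon_expiry_days: int = 28
    p_screen_incomplete: float = 297 / 2536
    p_ineligible: float = 136 / 2536
    p_consent_refuse: float = 8 / 2103
    p_quest_incomplete: float = 64 / 2095
    p_attention_fail: float = 99 / 1714
    fraud: Optional[FraudConfig] = None
    mitigation_day: int = 33
    rng_seed: int = 0

    def coupons_at(self, day: int) -> int:
        count = 0
        for start, c in sorted(self.coupon_schedule):
            if day >= start:
                count = c
        return count


@dataclass
class SimResult:
    log: SurveyEventLog
    registry: CouponRegistry
    roster: Roster
    graph: nx.Graph


def _responses_for(
    node_attrs: dict,
    degree: int,
    rng: np.random.Generator,
    questionnaire: Questionnaire,
    attention_pass: bool,
    straightline: bool = False,
) -> dict:
    battery_val = int(rng.integers(1, 5))
    responses = {
        "degree": int(max(1, degree)),
        "region": node_attrs.get("region", "R0"),
        "province": node_attrs.get("province", "P00"),
        "age": int(rng.integers(15, 60)),
        "hiv_test_12m": int(node_attrs.get("trait", False)),
        "knows_status": int(rng.random() < 0.5),
        "condom_last_sex": int(rng.random() < 0.5),
    }
    for i, name in enumerate(questionnaire.straightline_window):
        if straightline:
            responses[name] = battery_val
        else:
            responses[name] = int(rng.integers(1, 5))
    if not straightline:
        vals = [responses[n] for n in questionnaire.straightline_window]
        if len(set(vals)) == 1:  # keep accidental straightlining out
            responses[questionnaire.straightline_window[0]] = (vals[0] % 4) + 1
    if attention_pass:
        responses["attention"] = questionnaire.attention_expected
    else:
        others = [a for a in ("red", "green", "yellow")]
        responses["attention"] = others[int(rng.integers(len(others)))]
    if responses["hiv_test_12m"] == 1:
        responses["test_result_received"] = int(rng.random() < 0.8)
    return responses


def run_recruitment(graph: nx.Graph, config: SimConfig) -> SimResult:
    """Run the full recruitment process on a population graph.

    Event-driven loop over a priority queue of seed additions, coupon
    redemption attempts, and fraud-agent attempts.  Reproducible under
    config.rng_seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    registry = CouponRegistry(expiry_interval=config.coupon_expiry_days * DAY)
    roster = Roster()
    log = SurveyEventLog(meta={"seed": config.rng_seed, "kind": "simulation"})
    horizon = config.duration_days * DAY
    counter = itertools.count()  # heap tie-break
    heap: list[tuple[int, int, tuple]] = []
    rule = EligibilityRule()
    questionnaire = default_questionnaire()
    enrolled_nodes: set[int] = set()
    fraud_pids: list[str] = []

    # --- seed scheduling -------------------------------------------------
    all_nodes = list(graph.nodes)
    n_seeds = min(config.initial_seeds + config.added_seeds, len(all_nodes))
    seed_nodes = list(rng.choice(all_nodes, size=n_seeds, replace=False))
    if config.seed_add_times is None:
        add_times = np.linspace(
            10 * DAY, 0.7 * horizon, max(config.added_seeds, 1)
        ).astype(int)
    else:
        add_times = config.seed_add_times
    for i, node in enumerate(seed_nodes):
        if i < config.initial_seeds:
            t = int(i * 10 * MINUTE)
        else:
            t = int(add_times[min(i - config.initial_seeds, len(add_times) - 1)])
        heapq.heappush(heap, (t, next(counter), ("seed_enroll", node)))

    if config.fraud is not None and config.fraud.agent_count > 0:
        for a in range(config.fraud.agent_count):
            heapq.heappush(
                heap, (int(HOUR + a * MINUTE), next(counter), ("fraud_seed", a))
            )

    def _enroll(
        t: int,
        node: Optional[int],
        code: Optional[str],
        *,
        phone: str,
        ip: str,
        device: str,
        device_state: str = "not_used_before",
        is_fraud: bool = False,
        straightline: bool = False,
    ) -> None:
        """One candidate works through the funnel; completers recruit."""
        pid = roster.new_id()
        ua = "Mozilla/5.0 (Linux; Android 12) Chrome/96.0 Mobile Safari/537.36"
        log.append(
            t,
            "portal_entry",
            participant_id=pid,
            code=code,
            phone=phone,
            ip=ip,
            device=device,
            device_state=device_state,
            user_agent=ua,
        )
        outcome, rec = enter_portal(
            code,
            phone,
            registry,
            roster,
            now=t,
            participant_id=pid,
            ip=ip,
            device=device,
            device_state=device_state,
            user_agent=ua,
        )
        if outcome != PortalOutcome.PROCEED:
            return
        if node is not None:
            enrolled_nodes.add(node)
        if is_fraud:
            fraud_pids.append(pid)
        log.append(t + 30, "otp_verified", participant_id=pid)

        attrs = graph.nodes[node] if node is not None else {}
        # screening
        u = rng.random()
        if not is_fraud and u < config.p_screen_incomplete:
            answers = {"male": True, "age": None, "anal_sex_6m": True,
                       "resides_in_country": True, "reads_language": True}
            log.append(t + MINUTE, "screened", participant_id=pid, answers=answers)
            rec.screening_answers = answers
            rec.screening_result = screen(answers, rule)
            return
        ineligible = (not is_fraud) and u < config.p_screen_incomplete + config.p_ineligible
        answers = {
            "male": True,
            "age": 14 if ineligible else int(rng.integers(15, 60)),
            "anal_sex_6m": True,
            "resides_in_country": True,
            "reads_language": True,
        }
        log.append(t + MINUTE, "screened", participant_id=pid, answers=answers)
        rec.screening_answers = answers
        rec.screening_result = screen(answers, rule)
        if ineligible:
            return
        # consent
        consent = is_fraud or rng.random() >= config.p_consent_refuse
        log.append(t + 2 * MINUTE, "consented", participant_id=pid, consent=consent)
        rec.consent = consent
        if not consent:
            return
        token = issue_token(rec, roster, rng)
        log.append(t + 3 * MINUTE, "interview_started", participant_id=pid, token=token)
        rec.interview_start = t + 3 * MINUTE
        if not is_fraud and rng.random() < config.p_quest_incomplete:
            return  # abandoned interview: no completion event, no coupons
        attention_pass = is_fraud or rng.random() >= config.p_attention_fail
        responses = _responses_for(
            attrs,
            graph.degree[node] if node is not None else int(rng.integers(1, 30)),
            rng,
            questionnaire,
            attention_pass,
            straightline=straightline,
        )
        t_done = t + 3 * MINUTE + int(rng.integers(60, 240))
        log.append(
            t_done, "interview_completed", participant_id=pid, responses=responses
        )
        rec.interview_responses = responses
        rec.interview_complete = True
        rec.interview_end = t_done
        rec.degree = responses["degree"]
        rec.region = responses["region"]
        rec.province = responses["province"]
        # referral coupons
        n_coupons = config.coupons_at(t_done // DAY)
        if n_coupons <= 0:
            return
        coupons = registry.generate(n_coupons, issuer=pid, now=t_done, rng=rng)
        for c in coupons:
            log.append(
                t_done, "coupon_issued", code=c.code, issuer=pid,
                expires=c.expiration_date,
            )
        log.append(
            t_done + 30, "coupons_sent", participant_id=pid,
            codes=[c.code for c in coupons],
        )
        if is_fraud:
            # the imposter keeps their own codes for later self-enrollment
            fraud_coupon_pool.extend(c.code for c in coupons)
            return
        if node is None:
            return
        free = [v for v in graph.neighbors(node) if v not in enrolled_nodes]
        free = [free[i] for i in rng.permutation(len(free))]
        for c, target in zip(coupons, free):
            if rng.random() < config.redemption_probability:
                delay = config.delay_sampler(rng)
                heapq.heappush(
                    heap,
                    (t_done + delay, next(counter), ("redeem", c.code, target)),
                )

    fraud_coupon_pool: list[str] = []
    rental_counter = itertools.count()

    while heap:
        t, _, action = heapq.heappop(heap)
        if t > horizon:
            break
        if action[0] == "seed_enroll":
            node = action[1]
            if node in enrolled_nodes:
                continue
            _enroll(
                t, node, None,
                phone=f"ph-n{node}", ip=f"ip-n{node}", device=f"dev-n{node}",
            )
        elif action[0] == "redeem":
            code, target = action[1], action[2]
            _enroll(
                t, target, code,
                phone=f"ph-n{target}", ip=f"ip-n{target}", device=f"dev-n{target}",
            )
        elif action[0] == "fraud_seed":
            agent = action[1]
            _enroll(
                t, None, None,
                phone=f"ph-rental{next(rental_counter)}",
                ip=f"ip-fraud{agent}", device=f"dev-fraud{agent}",
                is_fraud=True,
            )
            _schedule_fraud_attempt(heap, counter, t, agent, config, rng)
        elif action[0] == "fraud_attempt":
            agent = action[1]
            if fraud_coupon_pool:
                code = fraud_coupon_pool.pop(0)
                fc = config.fraud
                _enroll(
                    t, None, code,
                    phone=f"ph-rental{next(rental_counter)}",
                    ip=f"ip-fraud{agent}",
                    device=f"dev-fraud{agent}",
                    device_state="already_used" if rng.random() < 0.3 else "not_used_before",
                    is_fraud=True,
                    straightline=rng.random() < fc.straightline_probability,
                )
            _schedule_fraud_attempt(heap, counter, t, agent, config, rng)

    if fraud_pids:
        # rental reports surface on the mitigation day (or at the horizon
        # if the run ends first), then keep covering later enrollments
        report_t = min(config.mitigation_day * DAY, horizon)
        log.append(
            max(report_t, log.events[-1].t if log.events else 0),
            "phone_rental_report",
            participant_ids=sorted(fraud_pids),
        )
    log.sort()
    return SimResult(log=log, registry=registry, roster=roster, graph=graph)


def _schedule_fraud_attempt(heap, counter, t, agent, config: SimConfig, rng) -> None:
    fc = config.fraud
    rate = (
        fc.attempt_rate
        if t < config.mitigation_day * DAY
        else fc.post_mitigation_rate
    )
    if rate <= 0:
        return
    gap = int(rng.exponential(DAY / rate)) + 1
    heapq.heappush(heap, (t + gap, next(counter), ("fraud_attempt", agent)))
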