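"""Recruitment forests and monitoring statistics.

Implements the dashboard quantities tracked during sampling: recruitment
trees and waves, sampling speed, geographic coverage, convergence of the
running weighted estimate, homophily, and the standard tabulations
(funnel accounting, redemption devices/browsers, redemption delays).

The population estimator is RDS-II (Volz–Heckathorn): with self-reported
personal network sizes (degrees) d_i, the weighted proportion of a
binary indicator A is

    p_hat = (sum_{i in A} 1/d_i) / (sum_i 1/d_i),

i.e. inclusion probability is taken proportional to degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clock import DAY
from .coupons import CouponRegistry
from .eventlog import SurveyEventLog
from .funnel import Disposition, Roster, coupon_dispositions
from .quality import audit as run_audit
from .questionnaire import Questionnaire, default_questionnaire
from .replay import replay
from .sim import DELAY_BIN_COUNTS, DELAY_BIN_EDGES


class ForestError(ValueError):
    """Roster does not form a valid recruiter forest."""


@dataclass
class RecruitmentForest:
    """Seeds-rooted trees of recruiter -> recruit edges with waves."""

    parent: dict[str, Optional[str]]
    wave: dict[str, int]
    seeds: set[str]
    excluded: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return {n for n in self.parent if n not in self.excluded}

    def edges(self) -> list[tuple[str, str]]:
        return [
            (p, c)
            for c, p in self.parent.items()
            if p is not None and c not in self.excluded and p not in self.excluded
        ]

    def max_wave(self) -> int:
        return max((self.wave[n] for n in self.nodes), default=0)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g


def build_forest(roster: Roster, exclude_fraud: bool = False) -> RecruitmentForest:
    """Build the recruitment forest with per-node waves (seeds are wave 0).

    Duplicate-phone rejections never enrolled and are not forest nodes.
    With exclude_fraud the flagged nodes are dropped from the analysis
    view, but ancestry is preserved so the waves of retained descendants
    are unchanged.  Dangling recruiter references and cycles raise
    ForestError.
    """
    enrolled = {
        pid: rec
        for pid, rec in roster.participants.items()
        if not rec.duplicate_phone
    }
    parent: dict[str, Optional[str]] = {}
    seeds: set[str] = set()
    for pid, rec in enrolled.items():
        if rec.role == "seed":
            parent[pid] = None
            seeds.add(pid)
        else:
            if rec.recruiter_id not in enrolled:
                raise ForestError(
                    f"recruit {pid!r} cites unknown recruiter {rec.recruiter_id!r}"
                )
            parent[pid] = rec.recruiter_id

    wave: dict[str, int] = {}

    def _wave(pid: str, trail: set[str]) -> int:
        if pid in wave:
            return wave[pid]
        if pid in trail:
            raise ForestError(f"cycle through {pid!r}")
        p = parent[pid]
        w = 0 if p is None else _wave(p, trail | {pid}) + 1
        wave[pid] = w
        return w

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(parent) + 100))
    try:
        for pid in parent:
            _wave(pid, set())
    finally:
        sys.setrecursionlimit(old_limit)

    excluded = (
        {pid for pid, rec in enrolled.items() if rec.fraud} if exclude_fraud else set()
    )
    return RecruitmentForest(parent=parent, wave=wave, seeds=seeds, excluded=excluded)


def rds2_estimate(
    indicator: Sequence[bool] | np.ndarray, degree: Sequence[int] | np.ndarray
) -> float:
    """RDS-II (inverse self-reported degree) weighted proportion."""
    ind = np.asarray(indicator, dtype=bool)
    deg = np.asarray(degree, dtype=float)
    if ind.size == 0 or ind.shape != deg.shape:
        raise ValueError("need one degree per indicator, at least one node")
    if np.any(deg < 1):
        raise ValueError("degrees must be >= 1")
    w = 1.0 / deg
    return float(w[ind].sum() / w.sum())


@dataclass
class EstimateTrace:
    sample_sizes: list[int]
    estimates: list[float]
    converged_at: Optional[int] = None


def convergence_trace(
    indicator: Sequence[bool],
    degree: Sequence[int],
    tolerance: float = 0.02,
    window: int = 100,
) -> EstimateTrace:
    """Running RDS-II estimate in enrollment order, plus the convergence point.

    The monitor declares convergence once `window` consecutive running
    estimates have stayed within +/- tolerance of the final estimate and
    never leave that band again; converged_at is the sample size at the
    end of that first window (None if stability is never reached).
    """
    ind = np.asarray(indicator, dtype=bool)
    deg = np.asarray(degree, dtype=float)
    n = ind.size
    w = 1.0 / deg
    num = np.cumsum(w * ind)
    den = np.cumsum(w)
    trace = num / den
    final = trace[-1]
    within = np.abs(trace - final) <= tolerance
    # first index from which the trace never leaves the band
    stable_from = n
    for i in range(n - 1, -1, -1):
        if within[i]:
            stable_from = i
        else:
            break
    converged_at = None
    if n - stable_from >= window:
        converged_at = stable_from + window  # sample size (1-based index + window - 1)
    return EstimateTrace(
        sample_sizes=list(range(1, n + 1)),
        estimates=[float(x) for x in trace],
        converged_at=converged_at,
    )


def homophily(
    forest: RecruitmentForest,
    attribute: Mapping[str, str],
    degree: Mapping[str, int],
) -> dict[str, Optional[float]]:
    """Observed/expected in-group recruitment ratio per category.

    For category a, H_a divides the proportion of recruiter->recruit
    pairs with an a-recruiter whose recruit is also in a by the RDS-II
    estimated population proportion of a.  H = 1 means recruitment is
    neutral with respect to the attribute; H_a = 1/p_a under perfect
    assortativity.  Categories with no pairs or zero estimated
    proportion are reported as None.
    """
    nodes = sorted(forest.nodes)
    cats = sorted({attribute[n] for n in nodes if n in attribute})
    ind = {c: np.array([attribute.get(n) == c for n in nodes]) for c in cats}
    deg = np.array([degree[n] for n in nodes], dtype=float)
    out: dict[str, Optional[float]] = {}
    pairs = forest.edges()
    for c in cats:
        p_hat = rds2_estimate(ind[c], deg) if nodes else 0.0
        from_c = [(p, ch) for p, ch in pairs if attribute.get(p) == c]
        if not from_c or p_hat == 0.0:
            out[c] = None
            continue
        within = sum(1 for _, ch in from_c if attribute.get(ch) == c)
        out[c] = (within / len(from_c)) / p_hat
    return out


# ---------------------------------------------------------------------------
# tabulations


def parse_user_agent(ua: str) -> tuple[str, str]:
    """Classify a user-agent string into (device class, browser family)."""
    mobile = any(tok in ua for tok in ("Mobile", "Android", "iPhone", "iPad"))
    device = "mobile" if mobile else "desktop_or_laptop"
    if "Edg" in ua or "OPR" in ua:
        browser = "other"
    elif "Chrome/" in ua:
        browser = "chrome"
    elif "Safari" in ua:
        browser = "safari"
    else:
        browser = "other"
    return device, browser


DELAY_BIN_LABELS = (
    "<=30 minutes",
    ">30 minutes to 1 hour",
    ">1 hour to 6 hours",
    ">6 hours to 1 day",
    ">1 day to 3 days",
    ">3 days to 7 days",
    ">7 days to 14 days",
    ">14 days",
)


def delay_bin_index(delay: int) -> int:
    """Half-open (lo, hi] binning of an issuance-to-redemption delay."""
    for i in range(len(DELAY_BIN_LABELS) - 1):
        if DELAY_BIN_EDGES[i] < delay <= DELAY_BIN_EDGES[i + 1]:
            return i
    return len(DELAY_BIN_LABELS) - 1  # > 14 days, unbounded above


@dataclass
class PipelineResult:
    """Everything the full replay + audit pipeline produces from a log."""

    registry: CouponRegistry
    roster: Roster
    flags: dict
    dispositions: dict[str, Disposition]
    audit_report: dict


def run_pipeline(
    log: SurveyEventLog, questionnaire: Questionnaire | None = None
) -> PipelineResult:
    """Replay a log, run the fraud audit and quality screens, classify."""
    from .quality import QualityFlag

    questionnaire = questionnaire or default_questionnaire()
    registry, roster = replay(log, questionnaire)
    report = run_audit(log, registry, roster, questionnaire)
    flags = {
        pid: QualityFlag(pid, f["failed_attention"], f["straightlined"])
        for pid, f in report["quality_flags"].items()
    }
    dispositions = coupon_dispositions(registry, roster, flags)
    return PipelineResult(registry, roster, flags, dispositions, report)


def funnel_table(result: PipelineResult) -> pd.DataFrame:
    """Nested funnel accounting over issued e-coupons.

    Counts and percentages use the total number of issued coupons as the
    denominator throughout.  Seeds are not coupon-based enrollments and
    are excluded from this table.
    """
    disp = list(result.dispositions.values())
    n_issued = len(disp)

    def count(d: Disposition) -> int:
        return sum(1 for x in disp if x == d)

    unredeemed = count(Disposition.UNREDEEMED)
    redeemed = n_issued - unredeemed
    dup = count(Disposition.DUPLICATE_PHONE)
    screened = redeemed - dup
    scr_inc = count(Disposition.SCREENING_INCOMPLETE)
    inel = count(Disposition.INELIGIBLE)
    eligible = screened - scr_inc - inel
    refused = count(Disposition.CONSENT_REFUSED)
    consented = eligible - refused
    q_inc = count(Disposition.QUESTIONNAIRE_INCOMPLETE)
    completed = consented - q_inc
    fraud = count(Disposition.FRAUD)
    non_fraud = completed - fraud
    attn = count(Disposition.FAILED_ATTENTION_FILTER)
    valid = count(Disposition.VALID)

    rows = [
        ("issued", n_issued),
        ("unredeemed", unredeemed),
        ("redeemed", redeemed),
        ("duplicate_phone", dup),
        ("screened", screened),
        ("screening_incomplete", scr_inc),
        ("ineligible", inel),
        ("eligible", eligible),
        ("consent_refused", refused),
        ("consented", consented),
        ("questionnaire_incomplete", q_inc),
        ("completed", completed),
        ("fraud", fraud),
        ("completed_non_fraud", non_fraud),
        ("failed_attention_filter", attn),
        ("valid", valid),
    ]
    denom = n_issued or 1
    return pd.DataFrame(
        {
            "stage": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "pct_of_issued": [round(100 * r[1] / denom, 1) for r in rows],
        }
    )


def _redemption_entries(log: SurveyEventLog) -> list:
    return [e for e in log.of_kind("portal_entry") if e.payload.get("code") is not None]


def devices_table(log: SurveyEventLog) -> pd.DataFrame:
    """Device class of every coupon redemption, and browser family among
    mobile redemptions (the published browser split covers mobile only)."""
    entries = _redemption_entries(log)
    rows = []
    devices: dict[str, int] = {"mobile": 0, "desktop_or_laptop": 0}
    browsers: dict[str, int] = {"chrome": 0, "safari": 0, "other": 0}
    for e in entries:
        device, browser = parse_user_agent(e.payload.get("user_agent", ""))
        devices[device] = devices.get(device, 0) + 1
        if device == "mobile":
            browsers[browser] = browsers.get(browser, 0) + 1
    n = len(entries) or 1
    n_mob = devices["mobile"] or 1
    for k, v in devices.items():
        rows.append(("device", k, v, round(100 * v / n, 1)))
    for k, v in browsers.items():
        rows.append(("browser_mobile", k, v, round(100 * v / n_mob, 1)))
    return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])


def delays_table(log: SurveyEventLog) -> pd.DataFrame:
    """Issuance-to-redemption delay, binned with per-bin and cumulative counts."""
    issue_t = {e.payload["code"]: e.t for e in log.of_kind("coupon_issued")}
    counts = [0] * len(DELAY_BIN_LABELS)
    for e in _redemption_entries(log):
        counts[delay_bin_index(e.t - issue_t[e.payload["code"]])] += 1
    total = sum(counts) or 1
    cum = np.cumsum(counts)
    return pd.DataFrame(
        {
            "bin": DELAY_BIN_LABELS,
            "count": counts,
            "pct": [round(100 * c / total, 1) for c in counts],
            "cumulative_count": cum,
            "cumulative_pct": [round(100 * c / total, 1) for c in cum],
        }
    )


def coverage_table(roster: Roster) -> pd.DataFrame:
    regions = {r.region for r in roster.participants.values() if r.region}
    provinces = {r.province for r in roster.participants.values() if r.province}
    return pd.DataFrame(
        {"measure": ["regions", "provinces"], "distinct": [len(regions), len(provinces)]}
    )


def speed_table(log: SurveyEventLog) -> pd.DataFrame:
    """Enrollments (screened portal proceeds) per survey day."""
    days: dict[int, int] = {}
    for e in log.of_kind("screened"):
        days[e.t // DAY] = days.get(e.t // DAY, 0) + 1
    items = sorted(days.items())
    return pd.DataFrame({"day": [d for d, _ in items], "enrollments": [c for _, c in items]})


def tabulate(log: SurveyEventLog, view: str) -> pd.DataFrame:
    """Standard tabulations of an event log.

    Views: 'funnel' (nested disposition accounting), 'devices'
    (device/browser split of redemptions), 'delays' (issuance-to-
    redemption bins), 'coverage' (distinct regions/provinces), 'speed'
    (enrollments per day).
    """
    if view == "funnel":
        return funnel_table(run_pipeline(log))
    if view == "devices":
        return devices_table(log)
    if view == "delays":
        return delays_table(log)
    if view == "coverage":
        _, roster = replay(log)
        return coverage_table(roster)
    if view == "speed":
        return speed_table(log)
    raise ValueError(f"unknown view {view!r}")


def export_rds_flat(
    roster: Roster, registry: CouponRegistry, path: str, seed_sentinel: str = "0"
) -> None:
    """Flat CSV for standard RDS analysis tools: id, recruiter id (seed
    sentinel), network size, the coupon redeemed, and issued coupons."""
    issued_by: dict[str, list[str]] = {}
    for c in registry.records():
        issued_by.setdefault(c.issuer, []).append(c.code)
    rows = []
    for pid, rec in roster.participants.items():
        if rec.duplicate_phone:
            continue
        rows.append(
            {
                "id": pid,
                "recruiter_id": rec.recruiter_id or seed_sentinel,
                "network_size": rec.degree if rec.degree is not None else "",
                "own_coupon": rec.coupon_code_used or "",
                "issued_coupons": ";".join(sorted(issued_by.get(pid, []))),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
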