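"""Forests and waves, RDS-II estimation, convergence, homophily, tabulations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from webrds.analytics import (
    ForestError,
    build_forest,
    convergence_trace,
    delay_bin_index,
    delays_table,
    export_rds_flat,
    homophily,
    parse_user_agent,
    rds2_estimate,
    tabulate,
)
from webrds.clock import DAY, HOUR, MINUTE
from webrds.eventlog import SurveyEventLog
from webrds.funnel import ParticipantRecord, Roster


def _roster_from_parents(parents: dict[str, str | None]) -> Roster:
    roster = Roster()
    for pid, parent in parents.items():
        if parent is None:
            roster.add(ParticipantRecord(participant_id=pid, role="seed", phone=f"ph{pid}"))
        else:
            roster.add(ParticipantRecord(participant_id=pid, role="recruit",
                                         phone=f"ph{pid}", recruiter_id=parent,
                                         coupon_code_used="XXXXX"))
    return roster


class TestForest:
    def test_chain_waves(self):
        roster = _roster_from_parents({"S": None, "A": "S", "B": "A"})
        forest = build_forest(roster)
        assert forest.wave == {"S": 0, "A": 1, "B": 2}
        assert forest.max_wave() == 2
        assert forest.seeds == {"S"}

    def test_dangling_recruiter(self):
        roster = _roster_from_parents({"S": None, "A": "GHOST"})
        with pytest.raises(ForestError, match="unknown recruiter"):
            build_forest(roster)

    def test_cycle_detected(self):
        roster = _roster_from_parents({"A": "B", "B": "A"})
        with pytest.raises(ForestError, match="cycle"):
            build_forest(roster)

    def test_fraud_excluded_view_preserves_waves(self):
        roster = _roster_from_parents({"S": None, "A": "S", "B": "A"})
        roster.get("A").fraud = True
        forest = build_forest(roster, exclude_fraud=True)
        assert "A" not in forest.nodes
        assert forest.wave["B"] == 2  # ancestry preserved through excluded node

    @pytest.mark.parametrize("seed", range(10))
    def test_waves_match_dfs_path_length_oracle(self, seed):
        """Wave equals brute-force root-path length on random forests, n<=100."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 101))
        n_seeds = int(rng.integers(1, max(2, n // 5)))
        parents: dict[str, str | None] = {}
        ids = [f"N{i}" for i in range(n)]
        for i, pid in enumerate(ids):
            if i < n_seeds:
                parents[pid] = None
            else:
                parents[pid] = ids[int(rng.integers(i))]  # earlier node
        forest = build_forest(_roster_from_parents(parents))

        def path_len(pid):  # independent oracle: walk to the root
            steps = 0
            while parents[pid] is not None:
                pid = parents[pid]
                steps += 1
            return steps

        for pid in ids:
            assert forest.wave[pid] == path_len(pid)


class TestRdsII:
    def test_hand_computed_example(self):
        # degrees {1,2,4}, indicator {T,F,T}: (1 + 1/4) / (1 + 1/2 + 1/4)
        est = rds2_estimate([True, False, True], [1, 2, 4])
        assert est == pytest.approx(1.25 / 1.75)
        assert est == pytest.approx(0.7142857142857143)

    def test_indicator_all_true(self):
        assert rds2_estimate([True] * 5, [3, 1, 9, 2, 7]) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(1, 50))
    def test_constant_degree_equals_sample_mean(self, indicator, degree):
        est = rds2_estimate(indicator, [degree] * len(indicator))
        assert est == pytest.approx(np.mean(indicator))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rds2_estimate([], [])
        with pytest.raises(ValueError):
            rds2_estimate([True], [0])

    def test_parameter_recovery_under_degree_proportional_sampling(self):
        """Mean estimate over replicates stays within 2 Monte-Carlo SEs of the
        true prevalence when draws are made with probability proportional
        to degree (the estimator's inclusion model)."""
        rng = np.random.default_rng(2024)
        true_p = 0.3
        n_pop, n_sample, reps = 2000, 400, 120
        degrees = rng.integers(1, 30, size=n_pop)
        trait = rng.random(n_pop) < true_p
        pop_p = trait.mean()  # the estimand is the realized population proportion
        w = degrees / degrees.sum()
        estimates = []
        for _ in range(reps):
            idx = rng.choice(n_pop, size=n_sample, replace=True, p=w)
            estimates.append(rds2_estimate(trait[idx], degrees[idx]))
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(mean - pop_p) < 2 * se + 1e-9


class TestConvergence:
    def test_constant_indicator_converges_at_window(self):
        trace = convergence_trace([True] * 300, [2] * 300, tolerance=0.02, window=100)
        assert trace.converged_at == 100
        assert all(e == 1.0 for e in trace.estimates)

    def test_alternating_indicator_zero_tolerance_never_converges(self):
        ind = [i % 2 == 0 for i in range(200)]
        trace = convergence_trace(ind, [3] * 200, tolerance=0.0, window=20)
        assert trace.converged_at is None

    def test_estimates_bounded_and_sizes_increasing(self):
        rng = np.random.default_rng(4)
        ind = rng.random(150) < 0.4
        deg = rng.integers(1, 20, size=150)
        trace = convergence_trace(ind, deg)
        assert all(0.0 <= e <= 1.0 for e in trace.estimates)
        assert trace.sample_sizes == sorted(set(trace.sample_sizes))


class TestHomophily:
    def _forest_with_attrs(self, pairs, seed_cat="a"):
        parents = {"S": None}
        attrs = {"S": seed_cat}
        for i, (pc, cc) in enumerate(pairs):
            pid = f"N{i}"
            parents[pid] = "S" if i == 0 else f"N{i-1}"
            attrs[pid] = cc
        return parents, attrs

    def test_neutral_recruitment_gives_h_near_one(self):
        rng = np.random.default_rng(8)
        parents: dict[str, str | None] = {"S": None}
        attrs = {"S": "a"}
        ids = ["S"]
        for i in range(4000):
            pid = f"N{i}"
            parents[pid] = ids[int(rng.integers(len(ids)))]
            attrs[pid] = "a" if rng.random() < 0.6 else "b"
            ids.append(pid)
        forest = build_forest(_roster_from_parents(parents))
        h = homophily(forest, attrs, {pid: 5 for pid in parents})
        assert h["a"] == pytest.approx(1.0, abs=0.08)
        assert h["b"] == pytest.approx(1.0, abs=0.12)

    def test_perfect_assortativity_gives_reciprocal_proportion(self):
        # two seeds, each recruiting only within its own category
        parents = {"Sa": None, "Sb": None}
        attrs = {"Sa": "a", "Sb": "b"}
        for i in range(10):
            parents[f"A{i}"] = "Sa" if i == 0 else f"A{i-1}"
            attrs[f"A{i}"] = "a"
            parents[f"B{i}"] = "Sb" if i == 0 else f"B{i-1}"
            attrs[f"B{i}"] = "b"
        forest = build_forest(_roster_from_parents(parents))
        degrees = {pid: 4 for pid in parents}
        h = homophily(forest, attrs, degrees)
        p_a = 11 / 22  # constant degrees: estimate reduces to sample proportion
        assert h["a"] == pytest.approx(1 / p_a)
        assert h["b"] == pytest.approx(1 / (1 - p_a))

    def test_single_node_forest_all_missing(self):
        forest = build_forest(_roster_from_parents({"S": None}))
        h = homophily(forest, {"S": "a"}, {"S": 3})
        assert h == {"a": None}


class TestTabulate:
    def test_fixture_views(self, fixture_log):
        dev = tabulate(fixture_log, "devices").set_index(["section", "category"])["count"]
        assert dev[("device", "mobile")] == 2090
        delays = tabulate(fixture_log, "delays")
        assert delays["count"].iloc[0] == 1441
        coverage = tabulate(fixture_log, "coverage").set_index("measure")["distinct"]
        assert coverage["regions"] == 6
        assert coverage["provinces"] <= 75
        speed = tabulate(fixture_log, "speed")
        assert speed["enrollments"].sum() == 2536 + 35  # screened recruits + seeds

    def test_empty_log_all_zero(self):
        empty = SurveyEventLog()
        assert tabulate(empty, "delays")["count"].sum() == 0
        assert tabulate(empty, "devices")["count"].sum() == 0
        assert tabulate(empty, "funnel")["count"].sum() == 0

    def test_unknown_view(self, fixture_log):
        with pytest.raises(ValueError):
            tabulate(fixture_log, "nope")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 30 * DAY), max_size=60))
    def test_delay_bins_conserve_total(self, delays):
        """Half-open (lo, hi] bins partition arbitrary positive delays."""
        log = SurveyEventLog()
        for i, d in enumerate(delays):
            code = f"C{i:04d}"
            log.append(0, "coupon_issued", code=code, issuer="S")
            log.append(d, "portal_entry", participant_id=f"P{i}", code=code,
                       phone=f"ph{i}", user_agent="")
        table = delays_table(log)
        assert table["count"].sum() == len(delays)

    def test_bin_edges_half_open(self):
        assert delay_bin_index(30 * MINUTE) == 0      # boundary in lower bin
        assert delay_bin_index(30 * MINUTE + 1) == 1
        assert delay_bin_index(14 * DAY) == 6
        assert delay_bin_index(14 * DAY + 1) == 7
        assert delay_bin_index(400 * DAY) == 7        # unbounded top bin


class TestUserAgents:
    @pytest.mark.parametrize(
        "ua,device,browser",
        [
            ("Mozilla/5.0 (Linux; Android 12) Chrome/98.0 Mobile Safari/537.36",
             "mobile", "chrome"),
            ("Mozilla/5.0 (iPhone; CPU iPhone OS 15_3) Version/15.3 Mobile Safari/604.1",
             "mobile", "safari"),
            ("Mozilla/5.0 (Android 12; Mobile; rv:97.0) Gecko Firefox/97.0",
             "mobile", "other"),
            ("Mozilla/5.0 (Windows NT 10.0) Chrome/98.0 Safari/537.36",
             "desktop_or_laptop", "chrome"),
            ("Mozilla/5.0 (Macintosh; Intel Mac OS X) Version/15.3 Safari/605.1.15",
             "desktop_or_laptop", "safari"),
        ],
    )
    def test_classification(self, ua, device, browser):
        assert parse_user_agent(ua) == (device, browser)


def test_rds_flat_export(pipeline, tmp_path):
    import pandas as pd

    path = tmp_path / "flat.csv"
    export_rds_flat(pipeline.roster, pipeline.registry, str(path))
    df = pd.read_csv(path, dtype=str)
    assert set(df.columns) == {"id", "recruiter_id", "network_size", "own_coupon",
                               "issued_coupons"}
    seeds = df[df["recruiter_id"] == "0"]
    assert len(seeds) == 35
    # no duplicate-phone rejections in the analysis export
    assert len(df) == 35 + 3000 - 464
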