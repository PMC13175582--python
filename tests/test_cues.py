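"""Reasoning-cue logic: plans, discrepancies, risks, Fisher test, consensus."""

import math

import numpy as np
import pytest

from sepcue.cohort import DomainError
from sepcue.config import CueConfig
from sepcue.cues import (
    MORTALITY_IN_ADMISSION,
    VASOPRESSOR_AT_12H,
    action_frequencies,
    consensus,
    consistent_features,
    feature_discrepancy,
    observed_plan,
    plan_conditional_risk,
    plan_window_is_partial,
    recommend,
    risk_score,
    unusual_features,
)
from sepcue.embedding import CohortStats
from sepcue.features import FEATURE_NAMES
from sepcue.plans import ALL_PLANS, TreatmentPlan

from conftest import make_neighbors, make_traj

CFG = CueConfig()
N_FEAT = len(FEATURE_NAMES)


def fisher_two_sided_oracle(a, b, c, d):
    """Full-enumeration two-sided hypergeometric p-value."""
    n1, n2, k = a + b, c + d, a + c
    total = n1 + n2

    def pmf(x):
        return (
            math.comb(n1, x) * math.comb(n2, k - x) / math.comb(total, k)
        )

    p_obs = pmf(a)
    lo, hi = max(0, k - n2), min(n1, k)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def binary_cohort(pos_ids, neg_ids, vaso12=None):
    """Single-state trajectories with mortality labels for neighbor tests."""
    store = {}
    for pid in pos_ids:
        store[pid] = make_traj(pid=pid, n_bins=1, died=True, vaso12=vaso12)
    for pid in neg_ids:
        store[pid] = make_traj(pid=pid, n_bins=1, died=False, vaso12=vaso12)
    return store


def plan_cohort(plan_by_pid, died_by_pid=None):
    """One trajectory per patient whose bin-0 observed plan is forced."""
    store = {}
    for pid, plan in plan_by_pid.items():
        n = 4
        fluid = np.zeros(n)
        diur = np.zeros(n)
        vaso = np.zeros(n, dtype=bool)
        if plan.volume_action == "give_fluids":
            fluid[1] = 500.0
        elif plan.volume_action == "give_diuretics":
            diur[2] = 1.0
        if plan.pressor_action == "increase_or_start":
            vaso[3] = True
        elif plan.pressor_action == "decrease_or_stop":
            vaso[0] = True
        elif plan.pressor_action == "maintain":
            pass
        store[pid] = make_traj(
            pid=pid,
            n_bins=n,
            fluid=fluid,
            diur=diur,
            vaso=vaso,
            died=bool(died_by_pid and died_by_pid.get(pid, False)),
        )
    return store


class TestObservedPlan:
    def test_null_activity_with_pressor_throughout(self):
        traj = make_traj(n_bins=5, vaso=[1, 1, 1, 1, 1])
        assert observed_plan(traj, 0, CFG) == TreatmentPlan("none", "maintain")

    def test_fluid_in_next_bin_no_pressor(self):
        traj = make_traj(n_bins=5, fluid=[0, 500, 0, 0, 0])
        assert observed_plan(traj, 0, CFG) == TreatmentPlan("give_fluids", "maintain")

    def test_diuretic_and_pressor_stop(self):
        traj = make_traj(n_bins=5, diur=[0, 0, 1, 0, 0], vaso=[1, 0, 0, 0, 0])
        assert observed_plan(traj, 0, CFG) == TreatmentPlan(
            "give_diuretics", "decrease_or_stop"
        )

    def test_both_volume_actions_coded_as_fluids(self):
        traj = make_traj(n_bins=5, fluid=[0, 250, 0, 0, 0], diur=[0, 0, 1, 0, 0])
        assert observed_plan(traj, 0, CFG).volume_action == "give_fluids"

    def test_window_excludes_current_bin(self):
        traj = make_traj(n_bins=5, fluid=[900, 0, 0, 0, 0])
        assert observed_plan(traj, 0, CFG).volume_action == "none"

    def test_partial_window_flag(self):
        traj = make_traj(n_bins=4)
        assert not plan_window_is_partial(traj, 0, CFG)
        assert plan_window_is_partial(traj, 2, CFG)

    def test_bad_bin_rejected(self):
        with pytest.raises(DomainError):
            observed_plan(make_traj(n_bins=2), 5, CFG)


class TestFeatureDiscrepancy:
    @pytest.fixture()
    def stats(self):
        mean = np.zeros(N_FEAT)
        sd = np.ones(N_FEAT)
        return CohortStats(tuple(FEATURE_NAMES), mean, sd)

    def test_query_at_neighbor_mean_scores_zero(self, stats):
        store = {p: make_traj(pid=p, features=np.full((1, N_FEAT), 2.0)) for p in "abc"}
        query = make_traj(features=np.full((1, N_FEAT), 2.0)).state(0)
        table = feature_discrepancy(query, make_neighbors([(p, 0) for p in "abc"]), stats, store)
        assert np.allclose(table["d"], 0.0)

    def test_two_sd_away_from_identical_neighbors(self, stats):
        store = {p: make_traj(pid=p, features=np.zeros((1, N_FEAT))) for p in "abc"}
        feats = np.zeros((1, N_FEAT))
        feats[0, 0] = 2.0
        query = make_traj(features=feats).state(0)
        table = feature_discrepancy(query, make_neighbors([(p, 0) for p in "abc"]), stats, store)
        assert table.loc[FEATURE_NAMES[0], "d"] == pytest.approx(2.0)
        assert table.loc[FEATURE_NAMES[0], "s"] == 0.0

    def test_matches_independent_arithmetic_on_random_instance(self, stats):
        rng = np.random.default_rng(6)
        neighbor_feats = rng.normal(size=(5, N_FEAT))
        store = {
            f"n{i}": make_traj(pid=f"n{i}", features=neighbor_feats[i : i + 1])
            for i in range(5)
        }
        qf = rng.normal(size=(1, N_FEAT))
        query = make_traj(features=qf).state(0)
        neighbors = make_neighbors([(f"n{i}", 0) for i in range(5)])
        table = feature_discrepancy(query, neighbors, stats, store)
        for j in range(0, N_FEAT, 7):
            name = FEATURE_NAMES[j]
            expected_d = abs(qf[0, j] - neighbor_feats[:, j].mean())
            expected_s = neighbor_feats[:, j].std()
            assert table.loc[name, "d"] == pytest.approx(expected_d)
            assert table.loc[name, "s"] == pytest.approx(expected_s)


class TestFeatureCues:
    @pytest.fixture()
    def stats(self, small_trajectories):
        return CohortStats.from_trajectories(list(small_trajectories.values()))

    def test_forced_ordering(self, stats):
        # neighbors identical; query deviates on exactly one feature
        base = np.tile(stats.mean, (1, 1))
        store = {p: make_traj(pid=p, features=base.copy()) for p in "abcde"}
        qf = base.copy()
        qf[0, 3] = stats.mean[3] + 5 * stats.sd[3]
        query = make_traj(features=qf).state(0)
        neighbors = make_neighbors([(p, 0) for p in "abcde"])
        unusual = unusual_features(query, neighbors, stats, store, CFG)
        assert unusual.entries[0].feature == FEATURE_NAMES[3]
        consistent = consistent_features(query, neighbors, stats, store, CFG)
        assert FEATURE_NAMES[3] not in [e.feature for e in consistent.entries]

    def test_selection_matches_brute_force(self, stats, small_trajectories):
        pids = sorted(small_trajectories)[:12]
        store = small_trajectories
        query = store[pids[0]].state(0)
        neighbors = make_neighbors([(p, 1) for p in pids[1:]])
        table = feature_discrepancy(query, neighbors, stats, store)
        table = table[~table["query_imputed"]]
        expected_unusual = list(
            table.reset_index()
            .sort_values(["d", "feature"], ascending=[False, True])
            .head(3)["feature"]
        )
        cue = unusual_features(query, neighbors, stats, store, CFG)
        assert [e.feature for e in cue.entries] == expected_unusual
        low_dispersion = table[table["s"] <= table["s"].median()]
        expected_consistent = list(
            low_dispersion.reset_index()
            .sort_values(["d", "feature"], ascending=[True, True])
            .head(3)["feature"]
        )
        r1 = consistent_features(query, neighbors, stats, store, CFG)
        assert [e.feature for e in r1.entries] == expected_consistent

    def test_at_most_max_features_and_imputed_excluded(self, stats):
        store = {p: make_traj(pid=p, features=np.zeros((1, N_FEAT))) for p in "ab"}
        imputed = np.ones((1, N_FEAT), dtype=bool)
        imputed[0, :2] = False  # only two eligible features
        query = make_traj(features=np.zeros((1, N_FEAT)), imputed=imputed).state(0)
        cue = unusual_features(query, make_neighbors([("a", 0), ("b", 0)]), stats, store, CFG)
        assert len(cue.entries) == 2


class TestRiskScore:
    def test_thirty_of_hundred_is_low(self):
        store = binary_cohort([f"p{i}" for i in range(30)], [f"n{i}" for i in range(70)])
        neighbors = make_neighbors([(pid, 0) for pid in store])
        cue = risk_score(neighbors, MORTALITY_IN_ADMISSION, store, CFG)
        assert cue.probability == pytest.approx(0.30)
        assert cue.level == "low" and cue.cue_code == "R3-L"

    def test_fifty_fifty_is_moderate(self):
        store = binary_cohort([f"p{i}" for i in range(50)], [f"n{i}" for i in range(50)])
        neighbors = make_neighbors([(pid, 0) for pid in store])
        cue = risk_score(neighbors, MORTALITY_IN_ADMISSION, store, CFG)
        assert cue.probability == 0.5
        assert cue.level == "moderate" and cue.cue_code == "R3-M"

    def test_undefined_labels_drop_from_denominator(self):
        # 100 neighbors on the vasopressor outcome: 20 undefined, 40/80 positive
        store = {}
        for i in range(100):
            if i < 20:
                v12 = [np.nan]
            elif i < 60:
                v12 = [1.0]
            else:
                v12 = [0.0]
            store[f"p{i}"] = make_traj(pid=f"p{i}", n_bins=1, vaso12=v12)
        neighbors = make_neighbors([(pid, 0) for pid in store])
        cue = risk_score(neighbors, VASOPRESSOR_AT_12H, store, CFG)
        assert cue.probability == pytest.approx(0.5)
        assert cue.n_defined == 80

    def test_all_undefined_raises(self):
        store = {"a": make_traj(pid="a", n_bins=1, vaso12=[np.nan])}
        with pytest.raises(DomainError):
            risk_score(make_neighbors([("a", 0)]), VASOPRESSOR_AT_12H, store, CFG)


class TestPlanConditionalRisk:
    target = TreatmentPlan("give_fluids", "maintain")
    rest = TreatmentPlan("none", "maintain")

    def build(self, n_plan, pos_plan, n_rest, pos_rest):
        plans, died = {}, {}
        for i in range(n_plan):
            pid = f"t{i}"
            plans[pid] = self.target
            died[pid] = i < pos_plan
        for i in range(n_rest):
            pid = f"r{i}"
            plans[pid] = self.rest
            died[pid] = i < pos_rest
        store = plan_cohort(plans, died)
        return store, make_neighbors([(pid, 0) for pid in store])

    def test_matches_full_enumeration_oracle(self):
        store, neighbors = self.build(40, 5, 60, 30)
        prd = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        assert prd.n_plan == 40 and prd.n_rest == 60
        assert prd.risk_plan == pytest.approx(5 / 40)
        assert prd.risk_rest == pytest.approx(30 / 60)
        assert prd.p_value == pytest.approx(fisher_two_sided_oracle(5, 35, 30, 30), abs=1e-12)
        assert prd.significant and prd.cue_code == "R4-Y"

    def test_support_gate_at_nine(self):
        store, neighbors = self.build(9, 0, 91, 60)
        prd = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        assert not prd.sufficient_support
        assert prd.risk_plan is None and prd.p_value is None
        assert not prd.significant

    def test_support_gate_at_ten(self):
        store, neighbors = self.build(10, 1, 90, 10)
        prd = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        assert prd.sufficient_support
        assert prd.p_value is not None

    def test_identical_risks_give_p_one(self):
        store, neighbors = self.build(40, 20, 60, 30)
        prd = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        assert prd.p_value == pytest.approx(1.0)
        assert not prd.significant

    def test_swapping_partitions_preserves_p_and_negates_difference(self):
        store, neighbors = self.build(40, 5, 60, 30)
        a = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        b = plan_conditional_risk(neighbors, self.rest, MORTALITY_IN_ADMISSION, store, CFG)
        assert a.p_value == pytest.approx(b.p_value)
        assert (a.risk_plan - a.risk_rest) == pytest.approx(-(b.risk_plan - b.risk_rest))

    def test_all_neighbors_in_one_partition(self):
        store, neighbors = self.build(100, 30, 0, 0)
        prd = plan_conditional_risk(neighbors, self.target, MORTALITY_IN_ADMISSION, store, CFG)
        assert prd.p_value is None and not prd.significant


class TestActionFrequencies:
    def test_degenerate_single_plan(self):
        plans = {f"p{i}": TreatmentPlan("give_fluids", "maintain") for i in range(100)}
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        freq = action_frequencies(neighbors, "volume", store, CFG)
        assert freq.frequencies["give_fluids"] == 1.0
        assert freq.frequencies["none"] == 0.0

    def test_normalization_61_30_9(self):
        plans = {}
        for i in range(61):
            plans[f"a{i}"] = TreatmentPlan("give_fluids", "maintain")
        for i in range(30):
            plans[f"b{i}"] = TreatmentPlan("none", "maintain")
        for i in range(9):
            plans[f"c{i}"] = TreatmentPlan("give_diuretics", "maintain")
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        freq = action_frequencies(neighbors, "volume", store, CFG)
        assert freq.frequencies == {
            "give_fluids": 0.61, "none": 0.30, "give_diuretics": 0.09,
        }
        assert sum(freq.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(freq.counts.values()) == neighbors.k_actual

    def test_matches_brute_force_tally_on_fuzzed_plans(self):
        rng = np.random.default_rng(2)
        plans = {
            f"p{i}": ALL_PLANS[rng.integers(0, len(ALL_PLANS))] for i in range(60)
        }
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        for category in ("volume", "pressor"):
            freq = action_frequencies(neighbors, category, store, CFG)
            for action, count in freq.counts.items():
                expected = sum(1 for p in plans.values() if p.action(category) == action)
                assert count == expected


class TestConsensus:
    def make_freq(self, counts):
        plans = {}
        i = 0
        for action, count in counts.items():
            for _ in range(count):
                plans[f"p{i}"] = TreatmentPlan(action, "maintain")
                i += 1
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        return action_frequencies(neighbors, "volume", store, CFG)

    def test_sixty_one_percent_is_consensus(self):
        cons = consensus(self.make_freq({"give_fluids": 61, "none": 39}), CFG)
        assert cons.consensus and cons.cue_code == "R6-Y"
        assert cons.modal_action == "give_fluids"

    def test_sixty_percent_exactly_is_not(self):
        cons = consensus(self.make_freq({"give_fluids": 60, "none": 40}), CFG)
        assert not cons.consensus and cons.cue_code == "R6-N"

    def test_tied_mode_is_no_consensus(self):
        cons = consensus(self.make_freq({"give_fluids": 45, "none": 45, "give_diuretics": 10}), CFG)
        assert not cons.consensus


class TestRecommend:
    def test_by_risk_unique_qualifier(self):
        target = TreatmentPlan("give_diuretics", "maintain")
        plans, died = {}, {}
        for i in range(40):
            pid = f"t{i}"
            plans[pid] = target
            died[pid] = i < 4          # 10% risk under the plan
        for i in range(60):
            pid = f"r{i}"
            plans[pid] = TreatmentPlan("give_fluids", "maintain")
            died[pid] = i < 30         # 50% risk otherwise
        store = plan_cohort(plans, died)
        neighbors = make_neighbors([(p, 0) for p in store])
        rec = recommend(neighbors, "by_risk", MORTALITY_IN_ADMISSION, store, CFG)
        assert rec.plan == target

    def test_by_risk_absent_without_support(self):
        plans = {f"p{i}": ALL_PLANS[i % 9] for i in range(18)}  # 2 takers per plan
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        rec = recommend(neighbors, "by_risk", MORTALITY_IN_ADMISSION, store, CFG)
        assert rec.plan is None

    def test_by_peer_equals_argmax_per_category(self):
        rng = np.random.default_rng(4)
        plans = {f"p{i}": ALL_PLANS[rng.integers(0, 9)] for i in range(80)}
        store = plan_cohort(plans)
        neighbors = make_neighbors([(p, 0) for p in store])
        rec = recommend(neighbors, "by_peer", MORTALITY_IN_ADMISSION, store, CFG)
        for category in ("volume", "pressor"):
            freq = action_frequencies(neighbors, category, store, CFG)
            best = max(freq.counts.values())
            assert freq.counts[rec.plan.action(category)] == best
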