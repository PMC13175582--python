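"""Statistical calibration experiments for the plan-conditional risk flag.

These experiments characterize the operating behavior of the R4 cue
(two-sided Fisher exact test on neighbor outcomes, gated at 10 of 100
supporting neighbors) under known generating conditions:

* **Type-I error** under a zero-effect generator.  Replicates must be
  statistically independent for the flag rate to be interpretable, so the
  experiment draws many independent cohorts (a few queries each) and uses
  one state per patient (the decision state) as the retrieval pool: a
  patient's mortality label is shared by all their states and plan windows
  overlap across adjacent bins, so multi-state pools violate the test's
  independence assumptions and inflate the flag rate.
* **Power** against a generator that shifts a target plan's outcome risk,
  evaluated on neighbor sets with a fixed number of supporting neighbors.
* **Risk-estimator consistency**: the MAE of the k-neighbor outcome risk
  against the generator's closed-form per-patient probability, as a
  function of cohort size.

The simulated clinician policy in these experiments is uniform
(``policy_temperature`` large) and fully persistent: uniformity makes plan
assignment ignorable (the zero-effect null actually holds), persistence
makes the observed plan equal the sampled plan and concentrates support at
~1/3 of the pool, where the exact test's 2x2 tables are least discrete.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logit

from .cohort import build_cohort_trajectories, split_cohort
from .config import CohortConfig, CueConfig, NeighborQueryConfig, SimConfig
from .cues import MORTALITY_IN_ADMISSION, observed_plan, plan_conditional_risk, risk_score
from .embedding import CohortStats, baseline_embed
from .engine import CueEngine
from .plans import ALL_PLANS, TreatmentPlan
from .retrieval import NeighborSet
from .synthetic import simulate_cohort

_MOD = 2**31


def _decision_state_engine(sim: SimConfig, k: int = 100):
    """Build a baseline-embedding engine whose pool/queries are one decision
    state per train/eval patient."""
    cohort_config = CohortConfig()
    records, ground_truth = simulate_cohort(sim)
    trajectories = build_cohort_trajectories(records, cohort_config)
    usable = [r for r in records if r.patient_id in trajectories]
    train_ids, eval_ids = split_cohort(usable, cohort_config)
    stats = CohortStats.from_trajectories([trajectories[p] for p in train_ids])
    decision_bin = dict(
        zip(ground_truth.patients.patient_id, ground_truth.patients.decision_bin)
    )

    def decision_embeddings(pids):
        out = []
        for pid in pids:
            b = int(decision_bin[pid])
            if b < trajectories[pid].n_states:
                out.append(baseline_embed(trajectories[pid], stats)[b])
        return out

    engine = CueEngine(
        trajectories,
        stats,
        decision_embeddings(train_ids),
        decision_embeddings(eval_ids),
        query_config=NeighborQueryConfig(k=k),
    )
    n_states = sum(t.n_states for t in trajectories.values())
    return engine, decision_embeddings(eval_ids), ground_truth, n_states


def type_i_error_rate(
    seed: int,
    n_cohorts: int = 50,
    queries_per_cohort: int = 10,
    n_patients: int = 560,
    cue_config: CueConfig | None = None,
) -> tuple[float, int]:
    """Fraction of significant R4 flags under a zero-effect generator.

    Returns (rate, number of tests performed).  Each cohort contributes
    ``queries_per_cohort`` evaluation-split decision states; each query
    tests the patient's own observed plan against the rest of its 100
    nearest neighbors.  Queries without sufficient support are not tests
    and do not count.
    """
    cue_config = cue_config or CueConfig()
    tested, significant = 0, 0
    for c in range(n_cohorts):
        sim = SimConfig(
            n_patients=n_patients,
            mean_stay_hours=16,
            seed=(seed * 100_003 + c * 37) % _MOD,
            policy_temperature=50.0,
            action_persistence=1.0,
        )
        engine, queries, _, _ = _decision_state_engine(sim)
        rng = np.random.default_rng((seed + c + 1) % _MOD)
        picks = rng.choice(
            len(queries), size=min(queries_per_cohort, len(queries)), replace=False
        )
        for qi in picks:
            q = queries[qi]
            plan = observed_plan(
                engine.trajectories[q.patient_id], q.bin_index, cue_config
            )
            neighbors = engine.neighbors(q.patient_id, q.bin_index)
            prd = plan_conditional_risk(
                neighbors, plan, MORTALITY_IN_ADMISSION, engine.trajectories, cue_config
            )
            if prd.sufficient_support and prd.p_value is not None:
                tested += 1
                significant += prd.significant
    return significant / tested, tested


def r4_power(
    seed: int,
    n_replicates: int = 500,
    risk_plan: float = 0.2,
    risk_rest: float = 0.5,
    n_plan: int = 35,
    cue_config: CueConfig | None = None,
) -> tuple[float, int]:
    """Power of the R4 flag against a generator effect of ``risk_plan`` vs
    ``risk_rest`` with ``n_plan`` of 100 supporting neighbors."""
    cue_config = cue_config or CueConfig()
    target = TreatmentPlan("give_diuretics", "maintain")
    effects = {p: 0.0 for p in ALL_PLANS}
    effects[target] = float(logit(risk_plan) - logit(risk_rest))
    sim = SimConfig(
        n_patients=800,
        mean_stay_hours=16,
        seed=seed % _MOD,
        policy_temperature=50.0,
        action_persistence=1.0,
        base_mortality_logit=float(logit(risk_rest)),
        severity_mortality_coef=0.0,
        action_effects=effects,
        cmo_hazard=0.0,
    )
    records, ground_truth = simulate_cohort(sim)
    trajectories = build_cohort_trajectories(records, CohortConfig())
    patients = ground_truth.patients[
        ground_truth.patients.patient_id.isin(trajectories)
    ]
    takers = list(
        map(
            tuple,
            patients[patients.decision_plan == str(target)][
                ["patient_id", "decision_bin"]
            ].values,
        )
    )
    others = list(
        map(
            tuple,
            patients[patients.decision_plan != str(target)][
                ["patient_id", "decision_bin"]
            ].values,
        )
    )
    rng = np.random.default_rng((seed + 1) % _MOD)
    flagged = 0
    for _ in range(n_replicates):
        chosen = [takers[i] for i in rng.choice(len(takers), n_plan, replace=False)]
        chosen += [others[i] for i in rng.choice(len(others), 100 - n_plan, replace=False)]
        ns = NeighborSet("Q", 0, [(p, int(b), 0.0) for p, b in chosen], 100)
        prd = plan_conditional_risk(
            ns, target, MORTALITY_IN_ADMISSION, trajectories, cue_config
        )
        flagged += prd.significant
    return flagged / n_replicates, n_replicates


def risk_mae_curve(
    seed: int,
    target_states: tuple[int, ...] = (500, 2000, 8000),
    n_queries: int = 500,
) -> dict[int, tuple[float, int]]:
    """MAE of the 100-neighbor mortality risk vs the generator's closed-form
    per-patient probability, as the cohort grows.

    One large cohort is generated once; each target size uses a *nested*
    subset of training patients as the retrieval pool and the same fixed
    evaluation queries, so the comparison across sizes isolates the effect
    of cohort size (common random numbers) instead of confounding it with
    between-cohort sampling noise.  Returns
    {target: (MAE, actual cohort state count)} where the cohort count is
    pool states plus query-split states scaled to the same fraction.
    """
    sim = SimConfig(
        n_patients=int(max(target_states) * 2.2),  # half are pool patients
        mean_stay_hours=16,
        seed=seed % _MOD,
        policy_temperature=50.0,
    )
    cohort_config = CohortConfig()
    records, ground_truth = simulate_cohort(sim)
    trajectories = build_cohort_trajectories(records, cohort_config)
    usable = [r for r in records if r.patient_id in trajectories]
    train_ids, eval_ids = split_cohort(usable, cohort_config)
    p_true = dict(
        zip(ground_truth.patients.patient_id, ground_truth.patients.p_death)
    )
    decision_bin = dict(
        zip(ground_truth.patients.patient_id, ground_truth.patients.decision_bin)
    )

    def decision_state(pid):
        b = int(decision_bin[pid])
        return (pid, b) if b < trajectories[pid].n_states else None

    pool_all = [s for s in map(decision_state, train_ids) if s is not None]
    eval_states = [s for s in map(decision_state, eval_ids) if s is not None]
    rng = np.random.default_rng((seed + 9) % _MOD)
    picks = rng.choice(
        len(eval_states), size=n_queries, replace=len(eval_states) < n_queries
    )
    query_ids = [eval_states[i] for i in picks]

    out: dict[int, tuple[float, int]] = {}
    for target in sorted(target_states):
        pool_ids = pool_all[:target]  # nested prefixes of the same ordering
        stats = CohortStats.from_trajectories(
            [trajectories[p] for p, _ in pool_ids]
        )
        pool = [baseline_embed(trajectories[p], stats)[b] for p, b in pool_ids]
        queries = [baseline_embed(trajectories[p], stats)[b] for p, b in query_ids]
        engine = CueEngine(
            trajectories, stats, pool, queries,
            query_config=NeighborQueryConfig(k=100),
        )
        errors = []
        for (pid, b), _ in zip(query_ids, queries):
            neighbors = engine.neighbors(pid, b)
            cue = risk_score(neighbors, MORTALITY_IN_ADMISSION, engine.trajectories)
            errors.append(abs(cue.probability - p_true[pid]))
        out[target] = (float(np.mean(errors)), len(pool_ids))
    return out
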