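"""Intelligent reasoning cues computed from a state's nearest neighbors.

Eight cue families are supported, all derived from the 100 (by default)
nearest cohort states of a query patient state:

* R1/R2 — features of the query that are most consistent with / most
  unusual against the neighbors, scored by z-space discrepancy;
* R3 — outcome risk: the fraction of neighbors with the outcome
  (vasopressor at +12h, or death in the admission), banded low/moderate/high;
* R4 — whether neighbors who took a given treatment plan had a
  significantly different risk than the rest (two-sided Fisher exact test);
* R5 — how frequently each action was taken among neighbors;
* R6 — whether a single action reaches strict >60% consensus;
* R7 — a plan mention (assembled by the interface layer);
* R8 — a recommendation, by peer actions or by risk scores.

Conditional risks and recommendations are gated on a plan being taken by
at least ``min_support`` (10 of 100) neighbors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DomainError, StateVector, Trajectory
from .config import CueConfig
from .embedding import CohortStats
from .plans import (
    ALL_PLANS,
    CATEGORIES,
    PLAN_ORDER,
    PRESSOR,
    PRESSOR_ACTIONS,
    TreatmentPlan,
    VOLUME,
    VOLUME_ACTIONS,
    discretize_plan,
)
from .retrieval import NeighborSet

logger = logging.getLogger(__name__)

VASOPRESSOR_AT_12H = "vasopressor_at_12h"
MORTALITY_IN_ADMISSION = "mortality_in_admission"
OUTCOME_KINDS = (VASOPRESSOR_AT_12H, MORTALITY_IN_ADMISSION)

TrajectoryStore = dict[str, Trajectory]


def inputs_digest(*parts: object) -> str:
    text = json.dumps([str(p) for p in parts], sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cue payload types


@dataclass
class FeatureCueEntry:
    feature: str
    query_value: float
    neighbor_mean: float
    discrepancy: float


@dataclass
class FeatureCue:
    kind: str  # "consistent" (R1) | "unusual" (R2)
    entries: list[FeatureCueEntry]

    @property
    def cue_code(self) -> str:
        return "R1" if self.kind == "consistent" else "R2"

    def to_dict(self) -> dict:
        return {
            "cue_code": self.cue_code,
            "kind": self.kind,
            "entries": [vars(e) for e in self.entries],
        }


@dataclass
class RiskCue:
    outcome_kind: str
    probability: float
    n_defined: int
    level: str  # low | moderate | high

    @property
    def cue_code(self) -> str:
        return {"low": "R3-L", "moderate": "R3-M", "high": "R3-H"}[self.level]

    def to_dict(self) -> dict:
        return {"cue_code": self.cue_code, **vars(self)}


@dataclass
class PlanRiskDifference:
    plan: TreatmentPlan
    outcome_kind: str
    risk_plan: float | None
    risk_rest: float | None
    n_plan: int
    n_rest: int
    p_value: float | None
    significant: bool
    sufficient_support: bool

    @property
    def cue_code(self) -> str:
        return "R4-Y" if self.significant else "R4-N"

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["plan"] = str(self.plan)
        d["cue_code"] = self.cue_code
        return d


@dataclass
class ActionFrequency:
    category: str  # volume | pressor
    counts: dict[str, int]
    frequencies: dict[str, float]

    @property
    def cue_code(self) -> str:
        return "R5"

    def to_dict(self) -> dict:
        return {"cue_code": self.cue_code, **vars(self)}


@dataclass
class ConsensusAction:
    category: str
    modal_action: str
    modal_frequency: float
    consensus: bool

    @property
    def cue_code(self) -> str:
        return "R6-Y" if self.consensus else "R6-N"

    def to_dict(self) -> dict:
        return {"cue_code": self.cue_code, **vars(self)}


@dataclass
class Recommendation:
    mode: str  # by_risk | by_peer
    plan: TreatmentPlan | None
    basis: dict

    @property
    def cue_code(self) -> str:
        return "R8"

    def to_dict(self) -> dict:
        return {
            "cue_code": self.cue_code,
            "mode": self.mode,
            "plan": None if self.plan is None else str(self.plan),
            "basis": self.basis,
        }


# ---------------------------------------------------------------------------
# Observed plans and labels


def observed_plan(
    traj: Trajectory, bin_index: int, config: CueConfig | None = None
) -> TreatmentPlan:
    """Discretize a neighbor's treatment activity over the decision window.

    Volume activity is read over the ``plan_window_bins`` bins following
    ``bin_index``; the vasopressor action compares activity in the bin at
    the window end against the current bin.  A window cut short by the end
    of the trajectory is computed on the available bins.
    """
    config = config or CueConfig()
    if not 0 <= bin_index < traj.n_states:
        raise DomainError(f"bin {bin_index} outside trajectory")
    w = config.plan_window_bins
    window = range(bin_index + 1, min(bin_index + w + 1, traj.n_states))
    end_bin = min(bin_index + w, traj.n_states - 1)
    fluid = bool(any(traj.fluid_ml[t] > 0 for t in window))
    diuretic = bool(any(traj.diuretic_given[t] for t in window))
    if fluid and diuretic:
        logger.debug(
            "%s bin %d: fluids and diuretics in the same window; coding give_fluids",
            traj.patient_id,
            bin_index,
        )
    return discretize_plan(
        fluid_in_window=fluid,
        diuretic_in_window=diuretic,
        pressor_now=bool(traj.vasopressor_active[bin_index]),
        pressor_at_end=bool(traj.vasopressor_active[end_bin]),
    )


def plan_window_is_partial(
    traj: Trajectory, bin_index: int, config: CueConfig | None = None
) -> bool:
    config = config or CueConfig()
    return bin_index + config.plan_window_bins > traj.n_states - 1


def outcome_label(
    traj: Trajectory, bin_index: int, outcome_kind: str
) -> bool | None:
    """A neighbor's outcome label; None when undefined (censored)."""
    if outcome_kind == MORTALITY_IN_ADMISSION:
        return bool(traj.died)
    if outcome_kind == VASOPRESSOR_AT_12H:
        v = traj.vaso12[bin_index]
        return None if np.isnan(v) else bool(v)
    raise DomainError(f"unknown outcome kind: {outcome_kind!r}")


def _neighbor_plans(
    neighbors: NeighborSet, trajectories: TrajectoryStore, config: CueConfig
) -> list[TreatmentPlan]:
    return [
        observed_plan(trajectories[pid], b, config) for pid, b in neighbors.ids
    ]


def _neighbor_labels(
    neighbors: NeighborSet, trajectories: TrajectoryStore, outcome_kind: str
) -> list[bool | None]:
    return [
        outcome_label(trajectories[pid], b, outcome_kind)
        for pid, b in neighbors.ids
    ]


# ---------------------------------------------------------------------------
# R1 / R2: feature consistency and unusualness


def feature_discrepancy(
    query: StateVector,
    neighbors: NeighborSet,
    cohort_stats: CohortStats,
    trajectories: TrajectoryStore,
) -> pd.DataFrame:
    """Per-feature discrepancy between the query and its neighbors.

    For each feature f, ``d`` = |z(query_f) - mean neighbor z| and ``s`` =
    SD of neighbor z-values, both in cohort-train z-space.  Zero-SD cohort
    features are excluded (logged).  Also reports whether the query entry
    was imputed.
    """
    if neighbors.k_actual == 0:
        raise DomainError("feature discrepancy needs at least one neighbor")
    names = cohort_stats.feature_names
    qz = cohort_stats.zscore(query.features[None, :])[0]
    nz = np.vstack(
        [
            cohort_stats.zscore(trajectories[pid].features[b][None, :])[0]
            for pid, b in neighbors.ids
        ]
    )
    keep = cohort_stats.sd > 0
    for j in np.flatnonzero(~keep):
        logger.info("feature %s has zero cohort SD; excluded from R1/R2", names[j])
    rows = []
    for j in np.flatnonzero(keep):
        rows.append(
            {
                "feature": names[j],
                "query_z": float(qz[j]),
                "neighbor_mean_z": float(nz[:, j].mean()),
                "d": float(abs(qz[j] - nz[:, j].mean())),
                "s": float(nz[:, j].std()),
                "query_value": float(query.features[j]),
                "neighbor_mean_value": float(
                    np.mean([trajectories[p].features[b][j] for p, b in neighbors.ids])
                ),
                "query_imputed": bool(query.imputed[j]),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _feature_cue(
    query: StateVector,
    neighbors: NeighborSet,
    cohort_stats: CohortStats,
    trajectories: TrajectoryStore,
    config: CueConfig,
    kind: str,
) -> FeatureCue:
    table = feature_discrepancy(query, neighbors, cohort_stats, trajectories)
    table = table[~table["query_imputed"]]
    if kind == "consistent" and len(table):
        # tight agreement: small discrepancy among low-dispersion features
        table = table[table["s"] <= table["s"].median()]
    if len(table) == 0:
        return FeatureCue(kind=kind, entries=[])
    ascending = kind == "consistent"
    table = table.reset_index().sort_values(
        by=["d", "feature"], ascending=[ascending, True], kind="mergesort"
    ).set_index("feature")
    entries = [
        FeatureCueEntry(
            feature=str(name),
            query_value=row["query_value"],
            neighbor_mean=row["neighbor_mean_value"],
            discrepancy=row["d"],
        )
        for name, row in table.head(config.max_features).iterrows()
    ]
    return FeatureCue(kind=kind, entries=entries)


def consistent_features(query, neighbors, cohort_stats, trajectories, config=None):
    """R1: up to ``max_features`` features most consistent with neighbors."""
    return _feature_cue(
        query, neighbors, cohort_stats, trajectories, config or CueConfig(),
        kind="consistent",
    )


def unusual_features(query, neighbors, cohort_stats, trajectories, config=None):
    """R2: up to ``max_features`` features most different from neighbors."""
    return _feature_cue(
        query, neighbors, cohort_stats, trajectories, config or CueConfig(),
        kind="unusual",
    )


# ---------------------------------------------------------------------------
# R3: neighbor risk


def _band(p: float, config: CueConfig) -> str:
    lo, hi = config.risk_band_edges
    if p < lo:
        return "low"
    if p > hi:
        return "high"
    return "moderate"


def risk_score(
    neighbors: NeighborSet,
    outcome_kind: str,
    trajectories: TrajectoryStore,
    config: CueConfig | None = None,
) -> RiskCue:
    """R3: outcome probability among neighbors with a defined label."""
    config = config or CueConfig()
    labels = [
        lab
        for lab in _neighbor_labels(neighbors, trajectories, outcome_kind)
        if lab is not None
    ]
    if not labels:
        raise DomainError(f"no neighbor has a defined {outcome_kind} label")
    p = sum(labels) / len(labels)
    return RiskCue(
        outcome_kind=outcome_kind,
        probability=float(p),
        n_defined=len(labels),
        level=_band(p, config),
    )


# ---------------------------------------------------------------------------
# R4: plan-conditional risk difference


def plan_conditional_risk(
    neighbors: NeighborSet,
    plan: TreatmentPlan,
    outcome_kind: str,
    trajectories: TrajectoryStore,
    config: CueConfig | None = None,
) -> PlanRiskDifference:
    """R4: risk among neighbors who took ``plan`` vs the rest.

    The two-sided p-value comes from Fisher's exact test on the 2x2
    outcome table.  When fewer than ``min_support`` neighbors took the
    plan, the conditional risk and p-value are reported undefined and the
    significance flag is false.
    """
    config = config or CueConfig()
    if neighbors.k_actual == 0:
        raise DomainError("plan-conditional risk needs at least one neighbor")
    plans = _neighbor_plans(neighbors, trajectories, config)
    labels = _neighbor_labels(neighbors, trajectories, outcome_kind)

    in_plan = [p == plan for p in plans]
    n_plan = sum(in_plan)
    n_rest = neighbors.k_actual - n_plan

    a = sum(1 for i, lab in zip(in_plan, labels) if i and lab is True)
    b = sum(1 for i, lab in zip(in_plan, labels) if i and lab is False)
    c = sum(1 for i, lab in zip(in_plan, labels) if not i and lab is True)
    d = sum(1 for i, lab in zip(in_plan, labels) if not i and lab is False)

    risk_rest = c / (c + d) if (c + d) > 0 else None
    sufficient_support = n_plan >= config.min_support
    if not sufficient_support:
        return PlanRiskDifference(
            plan=plan,
            outcome_kind=outcome_kind,
            risk_plan=None,
            risk_rest=risk_rest,
            n_plan=n_plan,
            n_rest=n_rest,
            p_value=None,
            significant=False,
            sufficient_support=False,
        )
    risk_plan = a / (a + b) if (a + b) > 0 else None
    if (a + b) == 0 or (c + d) == 0:
        p_value = None
    else:
        _, p_value = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p_value = float(p_value)
    significant = p_value is not None and p_value < config.alpha
    return PlanRiskDifference(
        plan=plan,
        outcome_kind=outcome_kind,
        risk_plan=risk_plan,
        risk_rest=risk_rest,
        n_plan=n_plan,
        n_rest=n_rest,
        p_value=p_value,
        significant=significant,
        sufficient_support=True,
    )


# ---------------------------------------------------------------------------
# R5 / R6: peer actions


def action_frequencies(
    neighbors: NeighborSet,
    category: str,
    trajectories: TrajectoryStore,
    config: CueConfig | None = None,
) -> ActionFrequency:
    """R5: how often each action of a category was taken among neighbors."""
    config = config or CueConfig()
    if category not in CATEGORIES:
        raise DomainError(f"unknown category: {category!r}")
    actions = VOLUME_ACTIONS if category == VOLUME else PRESSOR_ACTIONS
    plans = _neighbor_plans(neighbors, trajectories, config)
    counts = {action: 0 for action in actions}
    for plan in plans:
        counts[plan.action(category)] += 1
    k = neighbors.k_actual
    frequencies = {action: counts[action] / k for action in actions}
    return ActionFrequency(category=category, counts=counts, frequencies=frequencies)


def consensus(freq: ActionFrequency, config: CueConfig | None = None) -> ConsensusAction:
    """R6: a single action strictly above the consensus threshold.

    A tie for the mode means no single plan dominates: consensus is false
    and the modal action reported is the first tied action in canonical
    order.
    """
    config = config or CueConfig()
    actions = VOLUME_ACTIONS if freq.category == VOLUME else PRESSOR_ACTIONS
    best = max(freq.counts.values())
    tied = [a for a in actions if freq.counts[a] == best]
    modal = tied[0]
    modal_frequency = freq.frequencies[modal]
    has_consensus = len(tied) == 1 and modal_frequency > config.consensus_threshold
    return ConsensusAction(
        category=freq.category,
        modal_action=modal,
        modal_frequency=float(modal_frequency),
        consensus=has_consensus,
    )


# ---------------------------------------------------------------------------
# R8: recommendation


def recommend(
    neighbors: NeighborSet,
    mode: str,
    outcome_kind: str,
    trajectories: TrajectoryStore,
    config: CueConfig | None = None,
) -> Recommendation:
    """R8: a plan positioned as best, by peer actions or by risk scores.

    ``by_peer`` composes the modal action of each category.  ``by_risk``
    returns the sufficiently-supported plan whose conditional risk is
    significantly lower than the rest, choosing the lowest such risk
    (canonical plan order breaks ties); absent when no plan qualifies.
    """
    config = config or CueConfig()
    if mode == "by_peer":
        basis = {}
        actions = {}
        for category in CATEGORIES:
            cons = consensus(
                action_frequencies(neighbors, category, trajectories, config), config
            )
            actions[category] = cons.modal_action
            basis[category] = cons.to_dict()
        plan = TreatmentPlan(actions[VOLUME], actions[PRESSOR])
        return Recommendation(mode=mode, plan=plan, basis=basis)
    if mode != "by_risk":
        raise DomainError(f"unknown recommendation mode: {mode!r}")

    best_plan: TreatmentPlan | None = None
    best_risk = math.inf
    basis = {}
    for plan in ALL_PLANS:
        prd = plan_conditional_risk(neighbors, plan, outcome_kind, trajectories, config)
        basis[str(plan)] = prd.to_dict()
        if (
            prd.significant
            and prd.risk_plan is not None
            and prd.risk_rest is not None
            and prd.risk_plan < prd.risk_rest
        ):
            if prd.risk_plan < best_risk or (
                prd.risk_plan == best_risk
                and best_plan is not None
                and PLAN_ORDER[plan] < PLAN_ORDER[best_plan]
            ):
                best_plan = plan
                best_risk = prd.risk_plan
    return Recommendation(mode="by_risk", plan=best_plan, basis=basis)
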