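"""Assembly of the seven decision-support interface payloads.

Each interface is a machine-readable JSON payload composed of a fixed set
of reasoning cues:

====================================  =======================================
interface                             cues
====================================  =======================================
case_features                         R1, R2
treatment_risk                        R3 (vasopressor at +12h)
mortality_risk                        R3 (mortality in admission)
interactive_treatment_risk            R7, R3 (plan-conditional), R4, R5 (+R8)
interactive_mortality_risk            R7, R3 (plan-conditional), R4, R5 (+R8)
prior_clinician_actions               R7, R5, R6 (+implicit R8)
treatment_recommendation              R7, R8
====================================  =======================================

The interactive variants require a selected plan; the conditional risk is
undefined and a no-recommendation flag is set when fewer than
``min_support`` neighbors took that plan.  The prior-clinician-actions
payload never contains outcome-derived numbers; its modal plan is emitted
as a derived field flagged implicit, since a frequency summary can be read
as a recommendation without ever showing outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .config import CueConfig
from .cues import (
    MORTALITY_IN_ADMISSION,
    VASOPRESSOR_AT_12H,
    RiskCue,
    action_frequencies,
    consensus,
    consistent_features,
    inputs_digest,
    plan_conditional_risk,
    plan_window_is_partial,
    recommend,
    risk_score,
    unusual_features,
)
from .engine import CueEngine
from .plans import CATEGORIES, PRESSOR, TreatmentPlan, VOLUME


class UsageError(ValueError):
    """The interface request itself is malformed."""


SCHEMA_VERSION = 1

INTERFACE_CUES: dict[str, set[str]] = {
    "case_features": {"R1", "R2"},
    "treatment_risk": {"R3"},
    "mortality_risk": {"R3"},
    "interactive_treatment_risk": {"R7", "R3", "R4", "R5"},
    "interactive_mortality_risk": {"R7", "R3", "R4", "R5"},
    "prior_clinician_actions": {"R7", "R5", "R6"},
    "treatment_recommendation": {"R7", "R8"},
}
INTERACTIVE = {"interactive_treatment_risk", "interactive_mortality_risk"}
OPTIONAL_CUES: dict[str, set[str]] = {
    "interactive_treatment_risk": {"R8"},
    "interactive_mortality_risk": {"R8"},
    "prior_clinician_actions": {"R8"},
}

# Outcome fields that must never appear in outcome-free interfaces.
_OUTCOME_FIELDS = {"probability", "risk_plan", "risk_rest", "p_value", "n_defined"}


@dataclass
class InterfacePayload:
    interface_name: str
    patient_id: str
    bin_index: int
    cues: list[dict]
    selected_plan: TreatmentPlan | None = None
    no_recommendation: bool = False
    digest: str = ""
    schema_version: int = SCHEMA_VERSION
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "interface_name": self.interface_name,
            "patient_id": self.patient_id,
            "bin_index": self.bin_index,
            "selected_plan": None if self.selected_plan is None else str(self.selected_plan),
            "no_recommendation": self.no_recommendation,
            "inputs_digest": self.digest,
            "cues": self.cues,
            **self.extras,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _plan_mention(plan: TreatmentPlan | None, partial: bool | None = None) -> dict:
    cue = {"cue_code": "R7", "plan": None if plan is None else str(plan)}
    if partial is not None:
        cue["partial_window"] = partial
    return cue


def _interactive_payload(
    name: str, engine: CueEngine, patient_id: str, bin_index: int,
    selected_plan: TreatmentPlan, outcome_kind: str,
) -> tuple[list[dict], bool]:
    cue_config = engine.cue_config
    neighbors = engine.neighbors(patient_id, bin_index)
    traj = engine.trajectories[patient_id]
    cues: list[dict] = [
        _plan_mention(selected_plan, plan_window_is_partial(traj, bin_index, cue_config))
    ]
    prd = plan_conditional_risk(
        neighbors, selected_plan, outcome_kind, engine.trajectories, cue_config
    )
    if prd.sufficient_support and prd.risk_plan is not None:
        conditional = RiskCue(
            outcome_kind=outcome_kind,
            probability=prd.risk_plan,
            n_defined=prd.n_plan,
            level="",
        )
        lo, hi = cue_config.risk_band_edges
        level = (
            "low" if prd.risk_plan < lo else "high" if prd.risk_plan > hi else "moderate"
        )
        conditional.level = level
        r3 = conditional.to_dict()
        r3["conditional_on_plan"] = str(selected_plan)
        cues.append(r3)
    else:
        cues.append(
            {
                "cue_code": "R3",
                "outcome_kind": outcome_kind,
                "probability": None,
                "n_defined": prd.n_plan,
                "level": None,
                "conditional_on_plan": str(selected_plan),
            }
        )
    cues.append(prd.to_dict())
    frequency_cue = {
        "cue_code": "R5-Y" if prd.n_plan >= cue_config.min_support else "R5-N",
        "category": "plan",
        "plan": str(selected_plan),
        "count": prd.n_plan,
        "frequency": prd.n_plan / max(neighbors.k_actual, 1),
    }
    cues.append(frequency_cue)
    no_recommendation = not prd.sufficient_support
    if (
        prd.significant
        and prd.risk_plan is not None
        and prd.risk_rest is not None
        and prd.risk_plan < prd.risk_rest
    ):
        cues.append(
            {
                "cue_code": "R8",
                "mode": "by_risk",
                "plan": str(selected_plan),
                "inferred": True,
            }
        )
    return cues, no_recommendation


def build_payload(
    interface_name: str,
    patient_id: str,
    bin_index: int,
    engine: CueEngine,
    selected_plan: TreatmentPlan | None = None,
) -> InterfacePayload:
    """Assemble one interface payload for a patient state."""
    if interface_name not in INTERFACE_CUES:
        raise UsageError(f"unknown interface name: {interface_name!r}")
    if interface_name in INTERACTIVE and selected_plan is None:
        raise UsageError(f"{interface_name} requires a selected treatment plan")

    cue_config = engine.cue_config
    query = engine.state(patient_id, bin_index)
    neighbors = engine.neighbors(patient_id, bin_index)
    no_recommendation = False
    extras: dict = {}

    if interface_name == "case_features":
        cues = [
            consistent_features(
                query, neighbors, engine.cohort_stats, engine.trajectories, cue_config
            ).to_dict(),
            unusual_features(
                query, neighbors, engine.cohort_stats, engine.trajectories, cue_config
            ).to_dict(),
        ]
    elif interface_name in ("treatment_risk", "mortality_risk"):
        outcome = (
            VASOPRESSOR_AT_12H
            if interface_name == "treatment_risk"
            else MORTALITY_IN_ADMISSION
        )
        cues = [risk_score(neighbors, outcome, engine.trajectories, cue_config).to_dict()]
    elif interface_name in INTERACTIVE:
        outcome = (
            VASOPRESSOR_AT_12H
            if interface_name == "interactive_treatment_risk"
            else MORTALITY_IN_ADMISSION
        )
        cues, no_recommendation = _interactive_payload(
            interface_name, engine, patient_id, bin_index, selected_plan, outcome
        )
    elif interface_name == "prior_clinician_actions":
        cues = [_plan_mention(None)]
        modal_actions = {}
        for category in CATEGORIES:
            freq = action_frequencies(neighbors, category, engine.trajectories, cue_config)
            cons = consensus(freq, cue_config)
            modal_actions[category] = cons.modal_action
            cues.append(freq.to_dict())
            cues.append(cons.to_dict())
        extras["modal_plan"] = {
            "plan": str(TreatmentPlan(modal_actions[VOLUME], modal_actions[PRESSOR])),
            "implicit": True,
        }
    else:  # treatment_recommendation
        rec = recommend(
            neighbors, "by_risk", MORTALITY_IN_ADMISSION, engine.trajectories, cue_config
        )
        rec_dict = rec.to_dict()
        rec_dict.pop("basis", None)  # direct recommendation shows no outcome table
        cues = [_plan_mention(rec.plan), rec_dict]
        no_recommendation = rec.plan is None

    digest = inputs_digest(
        interface_name, patient_id, bin_index, selected_plan,
        cue_config.to_dict(), engine.query_config.to_dict(), engine.index.source,
    )
    return InterfacePayload(
        interface_name=interface_name,
        patient_id=patient_id,
        bin_index=bin_index,
        cues=cues,
        selected_plan=selected_plan,
        no_recommendation=no_recommendation,
        digest=digest,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# Validation


def load_schema() -> dict:
    text = resources.files("sepcue").joinpath("payload_schema.json").read_text()
    return json.loads(text)


def base_code(cue_code: str) -> str:
    return cue_code.split("-")[0]


def validate_payload(payload: dict) -> list[str]:
    """Validate a payload dict against the shipped schema; returns a list
    of problems (empty when valid)."""
    problems: list[str] = []
    schema = load_schema()
    for key in schema["required_fields"]:
        if key not in payload:
            problems.append(f"missing field: {key}")
    name = payload.get("interface_name")
    if name not in INTERFACE_CUES:
        problems.append(f"unknown interface_name: {name!r}")
        return problems
    cues = payload.get("cues", [])
    seen = {base_code(c.get("cue_code", "")) for c in cues}
    required = INTERFACE_CUES[name]
    optional = OPTIONAL_CUES.get(name, set())
    if not required.issubset(seen):
        problems.append(f"{name}: missing cues {sorted(required - seen)}")
    extra = seen - required - optional
    if extra:
        problems.append(f"{name}: unexpected cues {sorted(extra)}")
    if name in INTERACTIVE and payload.get("selected_plan") is None:
        problems.append(f"{name}: selected_plan is required")
    if name == "prior_clinician_actions":
        for cue in cues:
            leaked = _OUTCOME_FIELDS.intersection(cue)
            if leaked:
                problems.append(
                    f"prior_clinician_actions: outcome fields {sorted(leaked)} leaked"
                )
    return problems
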