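"""The discrete treatment-plan grid.

A plan is a pair of decisions over the next decision window: a volume
action (give IV fluids, do nothing, or give diuretics) and a vasopressor
action (increase/start, maintain, or decrease/stop).  The 3x3 grid
enumerates every plan the cue engine reasons about.
"""

from __future__ import annotations

from dataclasses import dataclass

VOLUME_ACTIONS: tuple[str, ...] = ("give_fluids", "none", "give_diuretics")
PRESSOR_ACTIONS: tuple[str, ...] = ("increase_or_start", "maintain", "decrease_or_stop")

VOLUME = "volume"
PRESSOR = "pressor"
CATEGORIES: tuple[str, ...] = (VOLUME, PRESSOR)


@dataclass(frozen=True, order=True)
class TreatmentPlan:
    """One cell of the 3x3 volume x vasopressor plan grid."""

    volume_action: str
    pressor_action: str

    def __post_init__(self) -> None:
        if self.volume_action not in VOLUME_ACTIONS:
            raise ValueError(f"unknown volume action: {self.volume_action!r}")
        if self.pressor_action not in PRESSOR_ACTIONS:
            raise ValueError(f"unknown pressor action: {self.pressor_action!r}")

    def action(self, category: str) -> str:
        if category == VOLUME:
            return self.volume_action
        if category == PRESSOR:
            return self.pressor_action
        raise ValueError(f"unknown category: {category!r}")

    def as_tuple(self) -> tuple[str, str]:
        return (self.volume_action, self.pressor_action)

    def __str__(self) -> str:  # used in JSON payloads and ground-truth keys
        return f"{self.volume_action}|{self.pressor_action}"

    @classmethod
    def from_string(cls, text: str) -> "TreatmentPlan":
        vol, _, prs = text.partition("|")
        return cls(vol, prs)


ALL_PLANS: tuple[TreatmentPlan, ...] = tuple(
    TreatmentPlan(v, p) for v in VOLUME_ACTIONS for p in PRESSOR_ACTIONS
)

# Canonical deterministic ordering used for tie-breaking everywhere.
PLAN_ORDER: dict[TreatmentPlan, int] = {plan: i for i, plan in enumerate(ALL_PLANS)}


def discretize_plan(
    fluid_in_window: bool,
    diuretic_in_window: bool,
    pressor_now: bool,
    pressor_at_end: bool,
) -> TreatmentPlan:
    """Map raw treatment activity over a decision window onto the plan grid.

    Volume: any fluid administration wins (fluid + diuretic in the same
    window is logged by callers and coded as ``give_fluids``); a diuretic
    alone codes ``give_diuretics``; otherwise ``none``.  Vasopressors are
    coded by comparing activity at the window end against the current bin.
    """
    if fluid_in_window:
        volume = "give_fluids"
    elif diuretic_in_window:
        volume = "give_diuretics"
    else:
        volume = "none"

    if pressor_at_end and not pressor_now:
        pressor = "increase_or_start"
    elif pressor_now and not pressor_at_end:
        pressor = "decrease_or_stop"
    else:
        pressor = "maintain"
    return TreatmentPlan(volume, pressor)
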