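"""Configuration objects for every pipeline stage.

Each config is a plain dataclass with eager validation in ``__post_init__``;
an invalid field raises :class:`ConfigurationError` naming the field.  All
configs round-trip through plain dicts (YAML/JSON friendly) via
``to_dict`` / ``from_dict``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .plans import ALL_PLANS, TreatmentPlan


class ConfigurationError(ValueError):
    """An invalid configuration field."""


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{field_name}: {message}")


def _default_action_effects() -> dict[TreatmentPlan, float]:
    return {plan: 0.0 for plan in ALL_PLANS}


@dataclass
class SimConfig:
    """Synthetic sepsis cohort generator settings.

    ``action_effects`` maps every plan of the 3x3 grid to an additive
    log-odds shift on in-admission mortality, applied at the patient's
    decision state.  ``policy_temperature`` controls how strongly the
    simulated clinician policy tracks latent severity (large values give a
    near-uniform, ignorable policy).
    """

    n_patients: int = 100
    mean_stay_hours: float = 120.0      # matches ~5 days average ICU data
    severity_drift: float = 0.0         # per-4h-step drift of latent severity
    action_effects: dict[TreatmentPlan, float] = field(
        default_factory=_default_action_effects
    )
    policy_temperature: float = 1.0
    measurement_noise_sd: float = 1.0   # multiplies per-feature noise scales
    missingness_rate: float = 0.15      # per-bin probability a vital is absent
    cmo_hazard: float = 0.005           # per-bin probability of a CMO order
    seed: int = 0
    # --- secondary knobs (defaults are the study conditions) ---
    severity_rho: float = 0.9           # AR(1) persistence of severity
    severity_innovation_sd: float = 0.35
    base_mortality_logit: float = -1.2  # ~30% mortality at severity 0, plan-free
    severity_mortality_coef: float = 1.8
    decision_bin: int = 2               # plan whose effect drives mortality
    action_persistence: float = 0.75    # per-bin probability of repeating the plan
    suspected_fraction: float = 0.95    # fraction with antibiotic+culture pair
    short_stay_fraction: float = 0.05   # fraction with <12h (ineligible) stays
    lab_rate_factor: float = 0.35       # lab measurement rate vs vitals

    def __post_init__(self) -> None:
        _require(int(self.n_patients) == self.n_patients and self.n_patients >= 1,
                 "n_patients", "must be a positive integer")
        _require(self.mean_stay_hours > 0, "mean_stay_hours", "must be positive")
        _require(self.policy_temperature > 0, "policy_temperature", "must be positive")
        _require(self.measurement_noise_sd > 0, "measurement_noise_sd",
                 "must be positive")
        for name in ("missingness_rate", "cmo_hazard", "action_persistence",
                     "suspected_fraction", "short_stay_fraction"):
            value = getattr(self, name)
            _require(0.0 <= value <= 1.0, name, "must be in [0, 1]")
        _require(0.0 <= self.severity_rho <= 1.0, "severity_rho", "must be in [0, 1]")
        _require(self.severity_innovation_sd >= 0, "severity_innovation_sd",
                 "must be non-negative")
        _require(self.decision_bin >= 0, "decision_bin", "must be non-negative")
        effects = {}
        for key, value in self.action_effects.items():
            plan = key if isinstance(key, TreatmentPlan) else TreatmentPlan.from_string(key)
            effects[plan] = float(value)
        missing = [p for p in ALL_PLANS if p not in effects]
        _require(not missing, "action_effects",
                 f"must cover the full plan grid; missing {missing}")
        self.action_effects = effects

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "action_effects"
        }
        d["action_effects"] = {str(k): v for k, v in self.action_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class CohortConfig:
    """Cohort filters and trajectory binning constants.

    Defaults encode the suspected-sepsis cohort definition: antibiotics and
    a culture within 24 hours of each other, at least 12 hours in the ICU,
    truncation at the 95th percentile of stay length, 4-hour timesteps, and
    a half/half patient-level train/evaluation split.
    """

    suspicion_window_hours: float = 24.0
    min_stay_hours: float = 12.0
    truncation_percentile: float = 95.0
    bin_hours: float = 4.0
    split_fraction: float = 0.5
    split_seed: int = 0
    label_horizon_hours: float = 12.0   # vasopressor-at-+12h label offset

    def __post_init__(self) -> None:
        for name in ("suspicion_window_hours", "min_stay_hours", "bin_hours",
                     "label_horizon_hours"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(0 < self.truncation_percentile <= 100, "truncation_percentile",
                 "must be in (0, 100]")
        _require(0 < self.split_fraction < 1, "split_fraction", "must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class EncoderConfig:
    """Denoising sequence-autoencoder hyperparameters (desk-scale defaults)."""

    embed_dim: int = 32
    n_layers: int = 2
    n_heads: int = 4
    corruption_rate: float = 0.3
    corruption_kind: str = "mask"       # mask | gaussian | shuffle-mix
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    ffn_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.embed_dim >= 2, "embed_dim", "must be >= 2")
        _require(self.n_layers >= 1, "n_layers", "must be >= 1")
        _require(self.n_heads >= 1, "n_heads", "must be >= 1")
        _require(self.embed_dim % self.n_heads == 0, "n_heads",
                 "must divide embed_dim")
        _require(0.0 <= self.corruption_rate <= 1.0, "corruption_rate",
                 "must be in [0, 1]")
        _require(self.corruption_kind in ("mask", "gaussian", "shuffle-mix"),
                 "corruption_kind", "must be one of mask|gaussian|shuffle-mix")
        _require(self.epochs >= 0, "epochs", "must be non-negative")
        _require(self.batch_size >= 1, "batch_size", "must be >= 1")
        _require(self.learning_rate > 0, "learning_rate", "must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


@dataclass
class NeighborQueryConfig:
    """k-nearest-neighbor retrieval settings (exact search only)."""

    k: int = 100
    metric: str = "euclidean"           # euclidean | cosine
    exclude_same_patient: bool = True

    def __post_init__(self) -> None:
        _require(self.k >= 1, "k", "must be >= 1")
        _require(self.metric in ("euclidean", "cosine"), "metric",
                 "must be euclidean or cosine")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeighborQueryConfig":
        return cls(**d)


@dataclass
class CueConfig:
    """Reasoning-cue thresholds.

    ``consensus_threshold`` is strict (>60% of neighbors), ``min_support``
    gates conditional risks and recommendations at 10 of 100 neighbors, and
    ``risk_band_edges`` split probabilities into low/moderate/high.
    """

    max_features: int = 3
    consensus_threshold: float = 0.60
    min_support: int = 10
    alpha: float = 0.05
    risk_band_edges: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    plan_window_bins: int = 3           # 3 x 4h = the 12h decision window

    def __post_init__(self) -> None:
        _require(self.max_features >= 1, "max_features", "must be >= 1")
        _require(0 < self.consensus_threshold < 1, "consensus_threshold",
                 "must be in (0, 1)")
        _require(self.min_support >= 0, "min_support", "must be non-negative")
        _require(0 < self.alpha < 1, "alpha", "must be in (0, 1)")
        lo, hi = self.risk_band_edges
        _require(0 < lo < hi < 1, "risk_band_edges",
                 "must be strictly increasing within (0, 1)")
        self.risk_band_edges = (float(lo), float(hi))
        _require(self.plan_window_bins >= 1, "plan_window_bins", "must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["risk_band_edges"] = list(self.risk_band_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CueConfig":
        d = dict(d)
        if "risk_band_edges" in d:
            d["risk_band_edges"] = tuple(d["risk_band_edges"])
        return cls(**d)
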