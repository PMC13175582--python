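"""Cohort filtering and 4-hour trajectory construction.

The suspected-sepsis cohort is defined by two filters: an antibiotic
administration and a microbial culture within 24 hours of each other, and
an ICU stay of at least 12 hours.  Eligible stays are cut into half-open
4-hour bins aligned to ICU admission; vitals are averaged within a bin,
labs carry the most recent value forward, and timesteps after a
comfort-measures-only (CMO) order or beyond the cohort-level 95th-percentile
stay-length cutoff are removed.

Two outcome labels are attached to every state: whether a vasopressor is
active in the bin starting 12 hours later (undefined when that bin does not
exist in the truncated trajectory) and whether the patient died during the
admission.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .features import DEMOGRAPHIC_NAMES, FEATURE_NAMES, VITAL_NAMES


class DomainError(ValueError):
    """A precondition on the data was violated."""


# ---------------------------------------------------------------------------
# Records


@dataclass
class PatientRecord:
    """One patient's raw events, stay, treatments and outcome.

    All times are hours from ICU admission (``icu_intime`` is 0 for
    synthetic cohorts but kept so real extracts can be aligned on read).
    """

    patient_id: str
    demographics: dict[str, float]
    diagnosis_history: frozenset[str] = frozenset()
    icu_intime: float = 0.0
    icu_outtime: float = 0.0
    death_flag: bool = False
    death_time: float | None = None
    events: list[tuple[float, str, float]] = field(default_factory=list)
    treatments: list[tuple[float, str, float]] = field(default_factory=list)
    cmo_time: float | None = None
    antibiotic_times: list[float] = field(default_factory=list)
    culture_times: list[float] = field(default_factory=list)

    @property
    def stay_hours(self) -> float:
        return self.icu_outtime - self.icu_intime

    def validate(self) -> None:
        if self.icu_outtime < self.icu_intime:
            raise DomainError(f"{self.patient_id}: icu_outtime < icu_intime")
        if self.death_flag and self.death_time is not None and self.events:
            last = max(t for t, _, _ in self.events)
            if self.death_time < last:
                raise DomainError(
                    f"{self.patient_id}: death_time precedes last measurement"
                )


@dataclass
class StateVector:
    """One 4-hour timestep of a trajectory."""

    patient_id: str
    bin_index: int
    features: np.ndarray            # fixed feature order (see schema)
    imputed: np.ndarray             # True where the value was carried forward
    fluid_ml: float
    vasopressor_active: bool
    diuretic_given: bool
    on_vasopressor_at_plus_12h: bool | None
    died_in_admission: bool


@dataclass
class Trajectory:
    """Gap-free ordered 4-hour states for one eligible patient."""

    patient_id: str
    feature_names: tuple[str, ...]
    features: np.ndarray            # (T, F) floats
    imputed: np.ndarray             # (T, F) bools
    fluid_ml: np.ndarray            # (T,)
    vasopressor_active: np.ndarray  # (T,) bools
    diuretic_given: np.ndarray      # (T,) bools
    vaso12: np.ndarray              # (T,) 1.0 / 0.0 / nan (undefined)
    died: bool
    truncated_at_cmo: bool
    truncated_at_percentile: bool
    bin_hours: float

    @property
    def n_states(self) -> int:
        return int(self.features.shape[0])

    def state(self, bin_index: int) -> StateVector:
        if not 0 <= bin_index < self.n_states:
            raise DomainError(
                f"{self.patient_id}: bin {bin_index} outside trajectory"
            )
        v12 = self.vaso12[bin_index]
        return StateVector(
            patient_id=self.patient_id,
            bin_index=bin_index,
            features=self.features[bin_index],
            imputed=self.imputed[bin_index],
            fluid_ml=float(self.fluid_ml[bin_index]),
            vasopressor_active=bool(self.vasopressor_active[bin_index]),
            diuretic_given=bool(self.diuretic_given[bin_index]),
            on_vasopressor_at_plus_12h=None if np.isnan(v12) else bool(v12),
            died_in_admission=self.died,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.feature_names == other.feature_names
            and np.allclose(self.features, other.features, equal_nan=True)
            and np.array_equal(self.imputed, other.imputed)
            and np.allclose(self.fluid_ml, other.fluid_ml)
            and np.array_equal(self.vasopressor_active, other.vasopressor_active)
            and np.array_equal(self.diuretic_given, other.diuretic_given)
            and np.allclose(self.vaso12, other.vaso12, equal_nan=True)
            and self.died == other.died
            and self.truncated_at_cmo == other.truncated_at_cmo
            and self.truncated_at_percentile == other.truncated_at_percentile
            and self.bin_hours == other.bin_hours
        )


# ---------------------------------------------------------------------------
# Filters


def suspicion_time(record: PatientRecord, config: CohortConfig) -> float | None:
    """Earliest suspected-infection time: min(a, c) over antibiotic times a
    and culture times c with |a - c| <= the suspicion window; None if no
    qualifying pair exists."""
    best: float | None = None
    for a in record.antibiotic_times:
        for c in record.culture_times:
            if abs(a - c) <= config.suspicion_window_hours:
                t = min(a, c)
                if best is None or t < best:
                    best = t
    return best


def eligible(record: PatientRecord, config: CohortConfig) -> bool:
    """Suspected sepsis and at least ``min_stay_hours`` in the ICU (inclusive)."""
    if record.stay_hours < config.min_stay_hours:
        return False
    return suspicion_time(record, config) is not None


def stay_length_cutoff(
    records: list[PatientRecord], config: CohortConfig
) -> float:
    """Cohort-level truncation cutoff: the configured percentile (linear
    interpolation between order statistics) of eligible patients' stay
    lengths."""
    stays = [r.stay_hours for r in records if eligible(r, config)]
    if not stays:
        raise DomainError("no eligible records to compute a stay-length cutoff")
    return float(np.percentile(stays, config.truncation_percentile))


def split_cohort(
    records: list[PatientRecord], config: CohortConfig
) -> tuple[list[str], list[str]]:
    """Deterministic patient-level train/eval split with
    |train| = floor(split_fraction * n)."""
    if len(records) < 2:
        raise DomainError("need at least 2 patients to split")
    ids = sorted(r.patient_id for r in records)
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(len(ids))
    n_train = int(math.floor(config.split_fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    evaluation = sorted(ids[i] for i in perm[n_train:])
    return train, evaluation


# ---------------------------------------------------------------------------
# Trajectory construction


def cohort_medians(records: list[PatientRecord]) -> dict[str, float]:
    """Per-feature cohort medians used for cold-start imputation."""
    values: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    for record in records:
        for _, feat, value in record.events:
            if feat in values:
                values[feat].append(value)
        for name in DEMOGRAPHIC_NAMES:
            if name in record.demographics:
                values[name].append(float(record.demographics[name]))
    return {
        name: (float(np.median(vals)) if vals else 0.0)
        for name, vals in values.items()
    }


def build_trajectory(
    record: PatientRecord,
    cutoff: float,
    config: CohortConfig,
    medians: dict[str, float] | None = None,
) -> Trajectory:
    """Bin one eligible record into half-open [i*b, (i+1)*b) hour states.

    Vitals are averaged within each bin; labs take the most recent
    observation; both carry forward (imputed flag set) when a bin has no
    observation, seeded from the cohort median when nothing has been
    observed yet.  States are dropped from the first bin starting at or
    after the CMO order and from any bin starting at or after ``cutoff``.
    """
    if not eligible(record, config):
        raise DomainError(f"record {record.patient_id} is not eligible")
    if medians is None:
        medians = cohort_medians([record])

    b = config.bin_hours
    stay = record.stay_hours
    limits = [stay, cutoff]
    if record.cmo_time is not None:
        limits.append(record.cmo_time)
    effective_end = min(limits)
    n_bins = int(math.ceil(effective_end / b))

    def bins_below(limit: float) -> int:
        return int(math.ceil(limit / b))

    truncated_at_cmo = (
        record.cmo_time is not None
        and bins_below(min(stay, cutoff)) > bins_below(record.cmo_time)
    )
    truncated_at_percentile = bins_below(stay) > bins_below(cutoff)

    n_feat = len(FEATURE_NAMES)
    features = np.zeros((n_bins, n_feat))
    imputed = np.zeros((n_bins, n_feat), dtype=bool)

    # Group events by feature for in-bin lookup.
    by_feature: dict[str, list[tuple[float, float]]] = {}
    for t, feat, value in record.events:
        by_feature.setdefault(feat, []).append((t, value))
    for obs in by_feature.values():
        obs.sort(key=lambda tv: tv[0])

    for j, name in enumerate(FEATURE_NAMES):
        if name in DEMOGRAPHIC_NAMES:
            features[:, j] = float(record.demographics.get(name, medians[name]))
            continue
        obs = by_feature.get(name, [])
        last_value = medians[name]
        for i in range(n_bins):
            lo, hi = i * b, (i + 1) * b
            in_bin = [v for t, v in obs if lo <= t < hi]
            if in_bin:
                if name in VITAL_NAMES:
                    value = float(np.mean(in_bin))
                else:  # lab: most recent observation in the bin
                    value = float(in_bin[-1])
                features[i, j] = value
                last_value = value
            else:
                features[i, j] = last_value
                imputed[i, j] = True

    fluid_ml = np.zeros(n_bins)
    vaso = np.zeros(n_bins, dtype=bool)
    diur = np.zeros(n_bins, dtype=bool)
    for t, kind, amount in record.treatments:
        i = int(math.floor(t / b))
        if not 0 <= i < n_bins:
            continue
        if kind == "fluid_ml":
            fluid_ml[i] += amount
        elif kind == "vasopressor_rate":
            vaso[i] = True
        elif kind == "diuretic_mg":
            diur[i] = True

    horizon_bins = int(round(config.label_horizon_hours / b))
    vaso12 = np.full(n_bins, np.nan)
    for i in range(n_bins):
        j = i + horizon_bins
        if j < n_bins:
            vaso12[i] = float(vaso[j])

    return Trajectory(
        patient_id=record.patient_id,
        feature_names=tuple(FEATURE_NAMES),
        features=features,
        imputed=imputed,
        fluid_ml=fluid_ml,
        vasopressor_active=vaso,
        diuretic_given=diur,
        vaso12=vaso12,
        died=record.death_flag,
        truncated_at_cmo=truncated_at_cmo,
        truncated_at_percentile=truncated_at_percentile,
        bin_hours=b,
    )


def build_cohort_trajectories(
    records: list[PatientRecord], config: CohortConfig
) -> dict[str, Trajectory]:
    """Filter, truncate and bin a whole cohort; returns patient_id -> Trajectory."""
    elig = [r for r in records if eligible(r, config)]
    if not elig:
        raise DomainError("no eligible patients in cohort")
    cutoff = stay_length_cutoff(records, config)
    medians = cohort_medians(elig)
    out: dict[str, Trajectory] = {}
    for record in elig:
        traj = build_trajectory(record, cutoff, config, medians)
        if traj.n_states > 0:
            out[record.patient_id] = traj
    return out


# ---------------------------------------------------------------------------
# I/O: raw cohort CSV schema and trajectory export


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read the documented CSV schema (patients/icustays/events/treatments)."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv", float_precision="round_trip")
    icustays = pd.read_csv(directory / "icustays.csv", float_precision="round_trip")
    events = pd.read_csv(directory / "events.csv", float_precision="round_trip")
    treatments = pd.read_csv(directory / "treatments.csv", float_precision="round_trip")

    events_by_pid = dict(tuple(events.groupby("patient_id", sort=False))) if len(events) else {}
    trt_by_pid = dict(tuple(treatments.groupby("patient_id", sort=False))) if len(treatments) else {}
    stays_by_pid = {row.patient_id: row for row in icustays.itertuples()}

    demo_cols = [c for c in patients.columns if c != "patient_id"]
    records: list[PatientRecord] = []
    for row in patients.itertuples():
        pid = row.patient_id
        stay = stays_by_pid[pid]
        demographics = {c: float(getattr(row, c)) for c in demo_cols}
        dx = frozenset(
            c for c in demo_cols if c.startswith("dx_") and getattr(row, c)
        )
        ev = events_by_pid.get(pid)
        event_list = (
            [
                (float(t), str(f), float(v))
                for t, f, v in zip(ev["time_hours"], ev["feature_name"], ev["value"])
            ]
            if ev is not None
            else []
        )
        trt = trt_by_pid.get(pid)
        treatment_list: list[tuple[float, str, float]] = []
        antibiotic_times: list[float] = []
        culture_times: list[float] = []
        cmo_time: float | None = None
        if trt is not None:
            for t, kind, amount in zip(
                trt["time_hours"], trt["treatment"], trt["amount"]
            ):
                t = float(t)
                if kind == "antibiotic":
                    antibiotic_times.append(t)
                elif kind == "culture":
                    culture_times.append(t)
                elif kind == "cmo":
                    cmo_time = t if cmo_time is None else min(cmo_time, t)
                else:
                    treatment_list.append((t, str(kind), float(amount)))
        death_time = None if pd.isna(stay.death_time) else float(stay.death_time)
        records.append(
            PatientRecord(
                patient_id=str(pid),
                demographics=demographics,
                diagnosis_history=dx,
                icu_intime=float(stay.intime),
                icu_outtime=float(stay.outtime),
                death_flag=bool(stay.death_flag),
                death_time=death_time,
                events=event_list,
                treatments=treatment_list,
                cmo_time=cmo_time,
                antibiotic_times=sorted(antibiotic_times),
                culture_times=sorted(culture_times),
            )
        )
    return records


def write_trajectories(
    trajectories: dict[str, Trajectory], directory: str | Path
) -> None:
    """Export binned states to states.csv / labels.csv plus a schema.json
    sidecar documenting the fixed feature order and per-patient flags."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state_rows = []
    label_rows = []
    patients_meta = {}
    some = next(iter(trajectories.values()))
    feature_names = list(some.feature_names)
    for pid in sorted(trajectories):
        traj = trajectories[pid]
        patients_meta[pid] = {
            "died": bool(traj.died),
            "truncated_at_cmo": bool(traj.truncated_at_cmo),
            "truncated_at_percentile": bool(traj.truncated_at_percentile),
        }
        for i in range(traj.n_states):
            row = {"patient_id": pid, "bin_index": i}
            for j, name in enumerate(feature_names):
                row[name] = traj.features[i, j]
                row[f"imp_{name}"] = int(traj.imputed[i, j])
            row["fluid_ml"] = traj.fluid_ml[i]
            row["vasopressor_active"] = int(traj.vasopressor_active[i])
            row["diuretic_given"] = int(traj.diuretic_given[i])
            state_rows.append(row)
            v12 = traj.vaso12[i]
            label_rows.append(
                {
                    "patient_id": pid,
                    "bin_index": i,
                    "on_vasopressor_at_plus_12h": "" if np.isnan(v12) else int(v12),
                    "died_in_admission": int(traj.died),
                }
            )
    pd.DataFrame(state_rows).to_csv(directory / "states.csv", index=False)
    pd.DataFrame(label_rows).to_csv(directory / "labels.csv", index=False)
    schema = {
        "version": 1,
        "feature_names": feature_names,
        "bin_hours": some.bin_hours,
        "patients": patients_meta,
    }
    (directory / "schema.json").write_text(json.dumps(schema, indent=2))


def read_trajectories(directory: str | Path) -> dict[str, Trajectory]:
    directory = Path(directory)
    schema = json.loads((directory / "schema.json").read_text())
    feature_names = tuple(schema["feature_names"])
    states = pd.read_csv(directory / "states.csv", float_precision="round_trip")
    labels = pd.read_csv(directory / "labels.csv", float_precision="round_trip")
    out: dict[str, Trajectory] = {}
    lab_by_pid = dict(tuple(labels.groupby("patient_id", sort=False)))
    for pid, group in states.groupby("patient_id", sort=False):
        pid = str(pid)
        group = group.sort_values("bin_index")
        meta = schema["patients"][pid]
        lab = lab_by_pid[pid].sort_values("bin_index")
        v12 = lab["on_vasopressor_at_plus_12h"].to_numpy(dtype=float)
        out[pid] = Trajectory(
            patient_id=pid,
            feature_names=feature_names,
            features=group[list(feature_names)].to_numpy(dtype=float),
            imputed=group[[f"imp_{n}" for n in feature_names]]
            .to_numpy(dtype=int)
            .astype(bool),
            fluid_ml=group["fluid_ml"].to_numpy(dtype=float),
            vasopressor_active=group["vasopressor_active"]
            .to_numpy(dtype=int)
            .astype(bool),
            diuretic_given=group["diuretic_given"].to_numpy(dtype=int).astype(bool),
            vaso12=v12,
            died=bool(meta["died"]),
            truncated_at_cmo=bool(meta["truncated_at_cmo"]),
            truncated_at_percentile=bool(meta["truncated_at_percentile"]),
            bin_hours=float(schema["bin_hours"]),
        )
    return out
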