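"""Synthetic sepsis cohort generator with closed-form ground truth.

The generator emulates the data regime the cue engine is designed for:
ICU stays with irregular vital/lab measurements, fluid / vasopressor /
diuretic administrations produced by a severity-tracking clinician policy,
antibiotic+culture suspicion events, occasional comfort-measures-only
orders, and an in-admission mortality outcome.

The generating model is deliberately the simplest one whose neighborhood
structure matches the assumptions of nearest-neighbor risk cues:

* latent severity follows a bounded AR(1) process per patient;
* vitals and labs are linear-Gaussian emissions of severity;
* the clinician policy is a softmax over plan utilities that penalize the
  mismatch between an action's intensity and current severity, with a
  temperature knob controlling consensus strength;
* mortality is Bernoulli with logit = base + coef * severity(decision bin)
  + action_effect(plan at the decision bin), making every plan-conditional
  outcome probability closed-form.

All randomness flows from ``SimConfig.seed``; identical configs produce
identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .config import SimConfig
from .features import DEMOGRAPHIC_NAMES, FEATURES, LAB, VITAL
from .plans import (
    ALL_PLANS,
    PRESSOR_ACTIONS,
    TreatmentPlan,
    VOLUME_ACTIONS,
    discretize_plan,
)

_SEVERITY_CLIP = 3.0
_STAY_CAP_HOURS = 40 * 24.0


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GroundTruth:
    """Closed-form generating quantities for every simulated state.

    ``states`` holds one row per (patient, bin): the latent severity, the
    patient-level realized mortality probability, and the plan-conditional
    mortality probability for every cell of the 3x3 grid evaluated at that
    state's severity.  ``patients`` holds the decision bin, the plan
    realized there, and the probability the outcome was drawn from.
    """

    states: pd.DataFrame
    patients: pd.DataFrame
    base_logit: float
    severity_coef: float
    action_effects: dict[TreatmentPlan, float]
    seed: int

    def probability(self, severity: float, plan: TreatmentPlan) -> float:
        """Closed-form P(death | severity, plan)."""
        return float(
            _sigmoid(
                self.base_logit
                + self.severity_coef * severity
                + self.action_effects[plan]
            )
        )


def _volume_policy(s: float, temperature: float) -> np.ndarray:
    intensity = np.array([1.0, 0.0, -1.0])  # fluids / none / diuretics
    u = -((intensity - math.tanh(s)) ** 2)
    z = u / temperature
    p = np.exp(z - z.max())
    return p / p.sum()


def _pressor_policy(s: float, temperature: float) -> np.ndarray:
    intensity = np.array([1.0, 0.0, -1.0])  # increase / maintain / decrease
    u = -((intensity - math.tanh(s - 0.5)) ** 2)
    z = u / temperature
    p = np.exp(z - z.max())
    return p / p.sum()


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a cohort of PatientRecords plus its GroundTruth."""
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    state_rows: list[dict] = []
    patient_rows: list[dict] = []

    plan_cols = {plan: f"p_plan_{plan}" for plan in ALL_PLANS}

    for idx in range(config.n_patients):
        pid = f"P{idx:05d}"
        age = float(rng.integers(40, 91))
        sex_male = float(rng.integers(0, 2))
        dx_hf = float(rng.random() < 0.30)
        dx_renal = float(rng.random() < 0.20)
        demographics = {
            "age": age,
            "sex_male": sex_male,
            "dx_heart_failure": dx_hf,
            "dx_renal_disease": dx_renal,
        }

        if rng.random() < config.short_stay_fraction:
            stay = float(rng.uniform(4.0, 11.0))
        else:
            scale = max(config.mean_stay_hours - 13.0, 1.0)
            stay = float(min(13.0 + rng.exponential(scale), _STAY_CAP_HOURS))
        n_bins = int(math.ceil(stay / 4.0))

        # Latent severity: bounded AR(1).
        s = np.empty(n_bins)
        s[0] = rng.normal(0.0, 1.0)
        for t in range(1, n_bins):
            s[t] = (
                config.severity_rho * s[t - 1]
                + config.severity_drift
                + rng.normal(0.0, config.severity_innovation_sd)
            )
        s = np.clip(s, -_SEVERITY_CLIP, _SEVERITY_CLIP)

        # Clinician policy with per-bin persistence.
        vol_idx = np.empty(n_bins, dtype=int)
        prs_idx = np.empty(n_bins, dtype=int)
        for t in range(n_bins):
            if t == 0 or rng.random() >= config.action_persistence:
                vol_idx[t] = rng.choice(
                    3, p=_volume_policy(s[t], config.policy_temperature)
                )
                prs_idx[t] = rng.choice(
                    3, p=_pressor_policy(s[t], config.policy_temperature)
                )
            else:
                vol_idx[t] = vol_idx[t - 1]
                prs_idx[t] = prs_idx[t - 1]

        # Vasopressor device state evolves from the pressor intents.
        active = np.zeros(n_bins, dtype=bool)
        state = False
        for t in range(n_bins):
            intent = PRESSOR_ACTIONS[prs_idx[t]]
            if intent == "increase_or_start":
                state = True
            elif intent == "decrease_or_stop":
                state = False
            active[t] = state

        events: list[tuple[float, str, float]] = []
        treatments: list[tuple[float, str, float]] = []
        fluid_bin = np.zeros(n_bins, dtype=bool)
        diur_bin = np.zeros(n_bins, dtype=bool)

        for t in range(n_bins):
            lo = t * 4.0
            hi = min((t + 1) * 4.0, stay)
            span = hi - lo
            vol = VOLUME_ACTIONS[vol_idx[t]]
            if vol == "give_fluids":
                amount = 250.0 * float(rng.integers(1, 5))
                treatments.append(
                    (lo + rng.uniform(0.1, max(span - 0.1, 0.2)), "fluid_ml", amount)
                )
                fluid_bin[t] = True
            elif vol == "give_diuretics":
                amount = 20.0 * float(rng.integers(1, 3))
                treatments.append(
                    (lo + rng.uniform(0.1, max(span - 0.1, 0.2)), "diuretic_mg", amount)
                )
                diur_bin[t] = True
            if active[t]:
                rate = round(0.05 + 0.1 * float(_sigmoid(s[t])), 3)
                treatments.append((lo + min(0.5, span / 2), "vasopressor_rate", rate))

            for f in FEATURES:
                if f.kind == VITAL:
                    p_obs = 1.0 - config.missingness_rate
                elif f.kind == LAB:
                    p_obs = (1.0 - config.missingness_rate) * config.lab_rate_factor
                else:
                    continue
                if rng.random() < p_obs:
                    tt = lo + rng.uniform(0.0, span)
                    value = (
                        f.mean
                        + f.loading * s[t]
                        + rng.normal(0.0, config.measurement_noise_sd * f.noise_scale)
                    )
                    events.append((min(tt, stay - 1e-6), f.name, float(value)))

        antibiotic_times: list[float] = []
        culture_times: list[float] = []
        if rng.random() < config.suspected_fraction:
            t_a = float(rng.uniform(0.0, min(3.0, stay / 2)))
            t_c = float(min(t_a + rng.uniform(0.0, 12.0), stay - 0.1))
            antibiotic_times.append(t_a)
            culture_times.append(t_c)
        elif rng.random() < 0.5:
            t_a = float(rng.uniform(0.0, min(3.0, stay / 2)))
            antibiotic_times.append(t_a)

        cmo_time: float | None = None
        for t in range(n_bins):
            if rng.random() < config.cmo_hazard:
                cmo_time = t * 4.0
                break

        # Decision state: plan realized over the 12h window after the
        # decision bin, discretized exactly as the cue engine observes it.
        d = min(config.decision_bin, n_bins - 1)
        window = range(d + 1, min(d + 4, n_bins))
        end_bin = min(d + 3, n_bins - 1)
        plan = discretize_plan(
            fluid_in_window=bool(any(fluid_bin[t] for t in window)),
            diuretic_in_window=bool(any(diur_bin[t] for t in window)),
            pressor_now=bool(active[d]),
            pressor_at_end=bool(active[end_bin]),
        )
        logit = (
            config.base_mortality_logit
            + config.severity_mortality_coef * s[d]
            + config.action_effects[plan]
        )
        p_death = float(_sigmoid(logit))
        died = bool(rng.random() < p_death)
        death_time = stay if died else None

        records.append(
            PatientRecord(
                patient_id=pid,
                demographics=demographics,
                diagnosis_history=frozenset(
                    k for k, v in demographics.items() if k.startswith("dx_") and v
                ),
                icu_intime=0.0,
                icu_outtime=stay,
                death_flag=died,
                death_time=death_time,
                events=sorted(events),
                treatments=sorted(treatments),
                cmo_time=cmo_time,
                antibiotic_times=antibiotic_times,
                culture_times=culture_times,
            )
        )

        patient_rows.append(
            {
                "patient_id": pid,
                "decision_bin": d,
                "decision_plan": str(plan),
                "severity_at_decision": float(s[d]),
                "p_death": p_death,
                "died": died,
                "stay_hours": stay,
            }
        )
        for t in range(n_bins):
            row = {
                "patient_id": pid,
                "bin_index": t,
                "severity": float(s[t]),
                "p_death_patient": p_death,
            }
            base = config.base_mortality_logit + config.severity_mortality_coef * s[t]
            for p, col in plan_cols.items():
                row[col] = float(_sigmoid(base + config.action_effects[p]))
            state_rows.append(row)

    ground_truth = GroundTruth(
        states=pd.DataFrame(state_rows),
        patients=pd.DataFrame(patient_rows),
        base_logit=config.base_mortality_logit,
        severity_coef=config.severity_mortality_coef,
        action_effects=dict(config.action_effects),
        seed=config.seed,
    )
    return records, ground_truth


# ---------------------------------------------------------------------------
# CSV export


def write_cohort(
    records: list[PatientRecord],
    directory: str | Path,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write the documented cohort CSV schema; round-trips through
    :func:`sepcue.cohort.read_cohort`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patient_rows = []
    stay_rows = []
    event_rows = []
    treatment_rows = []
    for record in records:
        row = {"patient_id": record.patient_id}
        for name in DEMOGRAPHIC_NAMES:
            row[name] = record.demographics.get(name, 0.0)
        patient_rows.append(row)
        stay_rows.append(
            {
                "stay_id": f"S-{record.patient_id}",
                "patient_id": record.patient_id,
                "intime": record.icu_intime,
                "outtime": record.icu_outtime,
                "death_flag": int(record.death_flag),
                "death_time": record.death_time,
            }
        )
        for t, feat, value in record.events:
            event_rows.append(
                {
                    "patient_id": record.patient_id,
                    "time_hours": t,
                    "feature_name": feat,
                    "value": value,
                }
            )
        all_trt = list(record.treatments)
        all_trt += [(t, "antibiotic", 0.0) for t in record.antibiotic_times]
        all_trt += [(t, "culture", 0.0) for t in record.culture_times]
        if record.cmo_time is not None:
            all_trt.append((record.cmo_time, "cmo", 0.0))
        for t, kind, amount in sorted(all_trt):
            treatment_rows.append(
                {
                    "patient_id": record.patient_id,
                    "time_hours": t,
                    "treatment": kind,
                    "amount": amount,
                }
            )

    patient_cols = ["patient_id", *DEMOGRAPHIC_NAMES]
    stay_cols = ["stay_id", "patient_id", "intime", "outtime", "death_flag", "death_time"]
    event_cols = ["patient_id", "time_hours", "feature_name", "value"]
    treatment_cols = ["patient_id", "time_hours", "treatment", "amount"]
    pd.DataFrame(patient_rows, columns=patient_cols).to_csv(
        directory / "patients.csv", index=False
    )
    pd.DataFrame(stay_rows, columns=stay_cols).to_csv(
        directory / "icustays.csv", index=False
    )
    pd.DataFrame(event_rows, columns=event_cols).to_csv(
        directory / "events.csv", index=False
    )
    pd.DataFrame(treatment_rows, columns=treatment_cols).to_csv(
        directory / "treatments.csv", index=False
    )
    if ground_truth is not None:
        merged = ground_truth.states.merge(
            ground_truth.patients, on="patient_id", how="left"
        )
        merged.to_csv(directory / "ground_truth.csv", index=False)
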