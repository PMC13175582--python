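"""Feature vocabulary for ICU patient states.

The state vector is a fixed-order concatenation of 16 vital-sign / lab
features and 4 constant per-patient demographic features.  Vitals are
measured frequently and aggregated by within-bin mean; labs are sparse and
carried forward ("most recent value"); demographics are repeated on every
timestep.

Each feature carries a population mean, a loading on the latent severity
process used by the synthetic cohort generator, and a noise scale.  The
loadings encode ordinary clinical direction: a sicker patient is
tachycardic, hypotensive, lactataemic, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

VITAL = "vital"
LAB = "lab"
DEMOGRAPHIC = "demographic"


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str          # vital | lab | demographic
    mean: float        # population mean when severity = 0
    loading: float     # additive shift per unit of latent severity
    noise_scale: float # measurement noise SD multiplier


FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("heart_rate", VITAL, 88.0, 12.0, 6.0),
    FeatureDef("sys_bp", VITAL, 115.0, -14.0, 8.0),
    FeatureDef("dia_bp", VITAL, 65.0, -8.0, 5.0),
    FeatureDef("mean_bp", VITAL, 80.0, -10.0, 5.0),
    FeatureDef("resp_rate", VITAL, 19.0, 4.0, 2.5),
    FeatureDef("temp_c", VITAL, 37.1, 0.5, 0.4),
    FeatureDef("spo2", VITAL, 96.5, -2.0, 1.2),
    FeatureDef("gcs", VITAL, 13.5, -2.5, 1.0),
    FeatureDef("lactate", LAB, 2.2, 1.5, 0.6),
    FeatureDef("creatinine", LAB, 1.3, 0.7, 0.3),
    FeatureDef("wbc", LAB, 11.5, 3.5, 2.0),
    FeatureDef("platelets", LAB, 210.0, -45.0, 30.0),
    FeatureDef("bilirubin", LAB, 1.1, 0.8, 0.4),
    FeatureDef("bun", LAB, 24.0, 9.0, 5.0),
    FeatureDef("sodium", LAB, 139.0, -1.5, 2.0),
    FeatureDef("hemoglobin", LAB, 10.8, -0.8, 0.7),
    FeatureDef("age", DEMOGRAPHIC, 65.0, 0.0, 0.0),
    FeatureDef("sex_male", DEMOGRAPHIC, 0.5, 0.0, 0.0),
    FeatureDef("dx_heart_failure", DEMOGRAPHIC, 0.3, 0.0, 0.0),
    FeatureDef("dx_renal_disease", DEMOGRAPHIC, 0.2, 0.0, 0.0),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
VITAL_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES if f.kind == VITAL)
LAB_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES if f.kind == LAB)
DEMOGRAPHIC_NAMES: tuple[str, ...] = tuple(
    f.name for f in FEATURES if f.kind == DEMOGRAPHIC
)
FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(FEATURE_NAMES)}
N_FEATURES = len(FEATURES)


def feature_kind(name: str) -> str:
    return FEATURES[FEATURE_INDEX[name]].kind
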