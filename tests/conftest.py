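import numpy as np
import pytest

from sepcue.cohort import PatientRecord, Trajectory, build_cohort_trajectories, split_cohort
from sepcue.config import CohortConfig, NeighborQueryConfig, SimConfig
from sepcue.embedding import CohortStats, baseline_embed
from sepcue.engine import CueEngine
from sepcue.features import FEATURE_NAMES
from sepcue.retrieval import NeighborSet
from sepcue.synthetic import simulate_cohort

N_FEAT = len(FEATURE_NAMES)


def make_record(
    pid="P1",
    stay=48.0,
    antibiotics=(1.0,),
    cultures=(2.0,),
    events=(),
    treatments=(),
    cmo=None,
    died=False,
    demographics=None,
):
    """Hand-built patient record with suspicion present by default."""
    return PatientRecord(
        patient_id=pid,
        demographics=demographics
        or {"age": 70.0, "sex_male": 1.0, "dx_heart_failure": 0.0, "dx_renal_disease": 0.0},
        icu_intime=0.0,
        icu_outtime=stay,
        death_flag=died,
        death_time=stay if died else None,
        events=list(events),
        treatments=list(treatments),
        cmo_time=cmo,
        antibiotic_times=list(antibiotics),
        culture_times=list(cultures),
    )


def make_traj(
    pid="T1",
    n_bins=4,
    died=False,
    features=None,
    fluid=None,
    vaso=None,
    diur=None,
    vaso12=None,
    imputed=None,
):
    """Minimal hand-built trajectory for cue tests."""
    features = (
        np.asarray(features, dtype=float)
        if features is not None
        else np.zeros((n_bins, N_FEAT))
    )
    n_bins = features.shape[0]

    def arr(x, dtype=float):
        if x is None:
            return np.zeros(n_bins, dtype=dtype)
        return np.asarray(x, dtype=dtype)

    v12 = np.full(n_bins, np.nan) if vaso12 is None else np.asarray(vaso12, dtype=float)
    return Trajectory(
        patient_id=pid,
        feature_names=tuple(FEATURE_NAMES),
        features=features,
        imputed=np.zeros_like(features, dtype=bool) if imputed is None else np.asarray(imputed, bool),
        fluid_ml=arr(fluid),
        vasopressor_active=arr(vaso, bool),
        diuretic_given=arr(diur, bool),
        vaso12=v12,
        died=died,
        truncated_at_cmo=False,
        truncated_at_percentile=False,
        bin_hours=4.0,
    )


def make_neighbors(ids, query=("Q", 0)):
    return NeighborSet(
        query_patient_id=query[0],
        query_bin_index=query[1],
        neighbors=[(pid, b, float(i)) for i, (pid, b) in enumerate(ids)],
        k_actual=len(ids),
    )


@pytest.fixture(scope="session")
def small_sim():
    config = SimConfig(n_patients=80, mean_stay_hours=24, seed=5)
    records, ground_truth = simulate_cohort(config)
    return config, records, ground_truth


@pytest.fixture(scope="session")
def small_trajectories(small_sim):
    _, records, _ = small_sim
    return build_cohort_trajectories(records, CohortConfig())


@pytest.fixture(scope="session")
def baseline_engine(small_sim, small_trajectories):
    """Baseline-embedding engine over the small synthetic cohort."""
    _, records, _ = small_sim
    trajectories = small_trajectories
    usable = [r for r in records if r.patient_id in trajectories]
    config = CohortConfig()
    train_ids, eval_ids = split_cohort(usable, config)
    stats = CohortStats.from_trajectories([trajectories[p] for p in train_ids])
    pool = [e for p in train_ids for e in baseline_embed(trajectories[p], stats)]
    queries = [e for p in eval_ids for e in baseline_embed(trajectories[p], stats)]
    engine = CueEngine(
        trajectories,
        stats,
        pool,
        queries,
        query_config=NeighborQueryConfig(k=50),
    )
    return engine, train_ids, eval_ids
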