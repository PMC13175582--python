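"""Pipeline wiring: cohort -> embeddings -> neighbor retrieval -> cues.

``CueEngine`` bundles everything a cue computation needs: the trajectory
store, the train-split normalization statistics, an exact neighbor index
over the peer pool (the training half of the cohort), and embeddings for
query states (the evaluation half).  ``run_pipeline`` builds the whole
stack from a synthetic cohort with one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    DomainError,
    StateVector,
    Trajectory,
    build_cohort_trajectories,
    split_cohort,
)
from .config import (
    CohortConfig,
    CueConfig,
    EncoderConfig,
    NeighborQueryConfig,
    SimConfig,
)
from .embedding import (
    CohortStats,
    EncoderModel,
    StateEmbedding,
    baseline_embed,
    embed_states,
    train_encoder,
)
from .retrieval import NeighborIndex, NeighborSet, build_index, nearest_states
from .synthetic import GroundTruth, simulate_cohort


class CueEngine:
    """Answer neighbor queries and expose state lookups for cue functions."""

    def __init__(
        self,
        trajectories: dict[str, Trajectory],
        cohort_stats: CohortStats,
        pool_embeddings: list[StateEmbedding],
        query_embeddings: list[StateEmbedding] | None = None,
        query_config: NeighborQueryConfig | None = None,
        cue_config: CueConfig | None = None,
    ) -> None:
        self.trajectories = trajectories
        self.cohort_stats = cohort_stats
        self.query_config = query_config or NeighborQueryConfig()
        self.cue_config = cue_config or CueConfig()
        self.index: NeighborIndex = build_index(pool_embeddings)
        self._embeddings: dict[tuple[str, int], StateEmbedding] = {}
        for emb in pool_embeddings:
            self._embeddings[(emb.patient_id, emb.bin_index)] = emb
        for emb in query_embeddings or []:
            self._embeddings[(emb.patient_id, emb.bin_index)] = emb

    def embedding(self, patient_id: str, bin_index: int) -> StateEmbedding:
        try:
            return self._embeddings[(patient_id, bin_index)]
        except KeyError:
            raise DomainError(
                f"no embedding for state ({patient_id}, {bin_index})"
            ) from None

    def state(self, patient_id: str, bin_index: int) -> StateVector:
        if patient_id not in self.trajectories:
            raise DomainError(f"unknown patient: {patient_id}")
        return self.trajectories[patient_id].state(bin_index)

    def neighbors(self, patient_id: str, bin_index: int) -> NeighborSet:
        return nearest_states(
            self.index, self.embedding(patient_id, bin_index), self.query_config
        )


@dataclass
class PipelineResult:
    records: list
    ground_truth: GroundTruth
    trajectories: dict[str, Trajectory]
    train_ids: list[str]
    eval_ids: list[str]
    stats: CohortStats
    model: EncoderModel | None
    engine: CueEngine
    configs: dict = field(default_factory=dict)


def run_pipeline(
    sim_config: SimConfig,
    cohort_config: CohortConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    query_config: NeighborQueryConfig | None = None,
    cue_config: CueConfig | None = None,
    use_autoencoder: bool = True,
) -> PipelineResult:
    """Simulate, filter, (optionally) train, embed and index in one call.

    The encoder and the normalization statistics see only the training half
    of the patient-level split; the neighbor pool is the training half and
    queries come from the evaluation half.
    """
    cohort_config = cohort_config or CohortConfig()
    records, ground_truth = simulate_cohort(sim_config)
    trajectories = build_cohort_trajectories(records, cohort_config)
    usable = [r for r in records if r.patient_id in trajectories]
    train_ids, eval_ids = split_cohort(usable, cohort_config)
    train_trajs = [trajectories[p] for p in train_ids]
    eval_trajs = [trajectories[p] for p in eval_ids]

    stats = CohortStats.from_trajectories(train_trajs)
    model: EncoderModel | None = None
    if use_autoencoder:
        encoder_config = encoder_config or EncoderConfig()
        model = train_encoder(train_trajs, encoder_config, eval_trajectories=eval_trajs)
        pool = [e for t in train_trajs for e in embed_states(model, t)]
        queries = [e for t in eval_trajs for e in embed_states(model, t)]
    else:
        pool = [e for t in train_trajs for e in baseline_embed(t, stats)]
        queries = [e for t in eval_trajs for e in baseline_embed(t, stats)]

    engine = CueEngine(
        trajectories=trajectories,
        cohort_stats=stats,
        pool_embeddings=pool,
        query_embeddings=queries,
        query_config=query_config,
        cue_config=cue_config,
    )
    return PipelineResult(
        records=records,
        ground_truth=ground_truth,
        trajectories=trajectories,
        train_ids=train_ids,
        eval_ids=eval_ids,
        stats=stats,
        model=model,
        engine=engine,
        configs={
            "sim": sim_config.to_dict(),
            "cohort": cohort_config.to_dict(),
            "encoder": encoder_config.to_dict() if encoder_config else None,
            "query": (query_config or NeighborQueryConfig()).to_dict(),
            "cue": (cue_config or CueConfig()).to_dict(),
        },
    )


def all_states(trajectories: dict[str, Trajectory]) -> list[tuple[str, int]]:
    return [
        (pid, i)
        for pid in sorted(trajectories)
        for i in range(trajectories[pid].n_states)
    ]


def severity_lookup(ground_truth: GroundTruth) -> dict[tuple[str, int], float]:
    states = ground_truth.states
    return {
        (pid, int(b)): float(s)
        for pid, b, s in zip(
            states["patient_id"], states["bin_index"], states["severity"]
        )
    }
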