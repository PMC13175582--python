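"""Exact k-nearest-neighbor retrieval over state embeddings.

Cue statistics are computed over only 100 neighbors, so retrieval noise
propagates directly into every downstream number; the index is therefore
exact (vectorized brute force), with deterministic lexicographic
tie-breaking by (distance, patient_id, bin_index).  Approximate backends
are intentionally not supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import DomainError
from .config import NeighborQueryConfig
from .embedding import StateEmbedding


class SchemaError(ValueError):
    """Embedding inputs are inconsistent with the index."""


@dataclass
class NeighborSet:
    """A query state plus its k nearest cohort states."""

    query_patient_id: str
    query_bin_index: int
    neighbors: list[tuple[str, int, float]]  # (patient_id, bin_index, distance)
    k_actual: int

    @property
    def ids(self) -> list[tuple[str, int]]:
        return [(pid, b) for pid, b, _ in self.neighbors]

    def to_dict(self) -> dict:
        return {
            "query": {
                "patient_id": self.query_patient_id,
                "bin_index": self.query_bin_index,
            },
            "k_actual": self.k_actual,
            "neighbors": [
                {"patient_id": pid, "bin_index": b, "distance": d}
                for pid, b, d in self.neighbors
            ],
        }


class NeighborIndex:
    """Exact search structure over a homogeneous embedding set."""

    def __init__(
        self,
        vectors: np.ndarray,
        patient_ids: list[str],
        bin_indices: np.ndarray,
        source: str,
    ) -> None:
        self.vectors = vectors
        self.patient_ids = list(patient_ids)
        self.bin_indices = np.asarray(bin_indices, dtype=int)
        self.source = source
        # ranks give lexicographic patient order for tie-breaking
        order = {pid: r for r, pid in enumerate(sorted(set(self.patient_ids)))}
        self._pid_ranks = np.array([order[p] for p in self.patient_ids])
        self._norms = np.linalg.norm(vectors, axis=1)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def build_index(embeddings: list[StateEmbedding]) -> NeighborIndex:
    """Index embeddings for exact retrieval; all must share source and length."""
    if not embeddings:
        raise DomainError("cannot index an empty embedding set")
    sources = {e.source for e in embeddings}
    if len(sources) > 1:
        raise SchemaError(f"mixed embedding sources: {sorted(sources)}")
    lengths = {len(e.vector) for e in embeddings}
    if len(lengths) > 1:
        raise SchemaError(f"mixed embedding lengths: {sorted(lengths)}")
    vectors = np.vstack([np.asarray(e.vector, dtype=float) for e in embeddings])
    return NeighborIndex(
        vectors=vectors,
        patient_ids=[e.patient_id for e in embeddings],
        bin_indices=np.array([e.bin_index for e in embeddings]),
        source=next(iter(sources)),
    )


def _distances(index: NeighborIndex, q: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = index.vectors - q
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))
    # cosine distance; zero vectors are maximally distant from everything
    qn = np.linalg.norm(q)
    denom = index._norms * qn
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (index.vectors @ q) / denom
    cos = np.where(denom > 0, cos, -1.0)
    return 1.0 - np.clip(cos, -1.0, 1.0)


def nearest_states(
    index: NeighborIndex,
    query: StateEmbedding,
    config: NeighborQueryConfig | None = None,
) -> NeighborSet:
    """Exact k nearest states to the query under the configured metric.

    The query's own state is always excluded; with ``exclude_same_patient``
    every state of the query's patient is excluded.  Ties in distance are
    broken by (patient_id, bin_index) lexicographic order.
    """
    config = config or NeighborQueryConfig()
    q = np.asarray(query.vector, dtype=float)
    if q.shape[0] != index.dim:
        raise SchemaError(
            f"query dimension {q.shape[0]} does not match index dimension {index.dim}"
        )
    dist = _distances(index, q, config.metric)

    if config.exclude_same_patient:
        keep = np.array([p != query.patient_id for p in index.patient_ids])
    else:
        keep = np.array(
            [
                not (p == query.patient_id and b == query.bin_index)
                for p, b in zip(index.patient_ids, index.bin_indices)
            ]
        )
    candidates = np.flatnonzero(keep)
    if candidates.size == 0:
        raise DomainError("no candidate states remain after exclusions")

    sub_order = np.lexsort(
        (
            index.bin_indices[candidates],
            index._pid_ranks[candidates],
            dist[candidates],
        )
    )
    k_actual = min(config.k, candidates.size)
    chosen = candidates[sub_order[:k_actual]]
    neighbors = [
        (index.patient_ids[i], int(index.bin_indices[i]), float(dist[i]))
        for i in chosen
    ]
    return NeighborSet(
        query_patient_id=query.patient_id,
        query_bin_index=query.bin_index,
        neighbors=neighbors,
        k_actual=k_actual,
    )
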