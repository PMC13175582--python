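"""Patient-state embeddings from a denoising trajectory autoencoder.

Trajectories are z-scored with train-split statistics, corrupted (feature
masking by default), and fed through a causal self-attention encoder that
reconstructs the uncorrupted state sequence at every timestep (mean squared
error on continuous features, cross-entropy on binary action flags).  The
hidden state at each timestep is the patient-state embedding; because
attention is causally masked, it summarizes only the patient's past.

A deterministic, model-free baseline embedding (the z-scored raw feature
vector) satisfies the same contract and is interchangeable with the
autoencoder everywhere downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import DomainError, Trajectory
from .config import EncoderConfig
from .nn import Adam, CausalEncoderNet, reconstruction_loss_and_grad

logger = logging.getLogger(__name__)

SENTINEL = np.nan  # corrupted entries are marked missing
_N_FLAGS = 3       # fluid given / vasopressor active / diuretic given


@dataclass
class CohortStats:
    """Per-feature mean/SD (train split only) used for z-scoring."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_trajectories(cls, trajectories: list[Trajectory]) -> "CohortStats":
        if not trajectories:
            raise DomainError("cannot compute stats from an empty cohort")
        names = trajectories[0].feature_names
        stacked = np.vstack([t.features for t in trajectories])
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        for j in np.flatnonzero(sd == 0):
            logger.info("feature %s has zero SD; it will contribute 0", names[j])
        return cls(feature_names=names, mean=mean, sd=sd)

    def zscore(self, features: np.ndarray) -> np.ndarray:
        """Z-score; zero-SD features map to 0, missing entries map to 0."""
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        z = (features - self.mean) / safe_sd
        z = np.where(self.sd > 0, z, 0.0)
        return np.nan_to_num(z, nan=0.0)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortStats":
        return cls(
            feature_names=tuple(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
        )


@dataclass
class StateEmbedding:
    """One state's position in embedding space."""

    patient_id: str
    bin_index: int
    vector: np.ndarray
    source: str  # "autoencoder" | "baseline"


# ---------------------------------------------------------------------------
# Corruption


def corrupt(traj: Trajectory, config: EncoderConfig, seed: int) -> Trajectory:
    """Seeded corruption of a trajectory's feature entries.

    ``mask``: each entry independently replaced by the missing-value
    sentinel with probability ``corruption_rate``.  ``gaussian``: selected
    entries are jittered by noise scaled to the trajectory's own feature
    spread.  ``shuffle-mix``: selected entries take the same feature's
    value at a random other timestep.  Structure (length, ordering,
    actions, labels) is never changed.
    """
    if traj.n_states == 0:
        raise DomainError("cannot corrupt an empty trajectory")
    rng = np.random.default_rng(seed)
    features = traj.features.copy()
    hit = rng.random(features.shape) < config.corruption_rate
    if config.corruption_kind == "mask":
        features[hit] = SENTINEL
    elif config.corruption_kind == "gaussian":
        scale = features.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        features = np.where(
            hit, features + rng.normal(0.0, 1.0, features.shape) * scale, features
        )
    else:  # shuffle-mix
        donor_rows = rng.integers(0, traj.n_states, size=features.shape)
        cols = np.broadcast_to(np.arange(features.shape[1]), features.shape)
        features = np.where(hit, traj.features[donor_rows, cols], features)
    return Trajectory(
        patient_id=traj.patient_id,
        feature_names=traj.feature_names,
        features=features,
        imputed=traj.imputed.copy(),
        fluid_ml=traj.fluid_ml.copy(),
        vasopressor_active=traj.vasopressor_active.copy(),
        diuretic_given=traj.diuretic_given.copy(),
        vaso12=traj.vaso12.copy(),
        died=traj.died,
        truncated_at_cmo=traj.truncated_at_cmo,
        truncated_at_percentile=traj.truncated_at_percentile,
        bin_hours=traj.bin_hours,
    )


# ---------------------------------------------------------------------------
# Model wrapper


def _flags(traj: Trajectory) -> np.ndarray:
    return np.stack(
        [
            (traj.fluid_ml > 0).astype(float),
            traj.vasopressor_active.astype(float),
            traj.diuretic_given.astype(float),
        ],
        axis=1,
    )


@dataclass
class EncoderModel:
    """Trained denoising autoencoder plus its normalization statistics."""

    net: CausalEncoderNet
    config: EncoderConfig
    stats: CohortStats
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.stats.feature_names)

    def _inputs(self, traj: Trajectory) -> np.ndarray:
        z = self.stats.zscore(traj.features)
        return np.concatenate([z, _flags(traj)], axis=1)

    def embed(self, traj: Trajectory) -> np.ndarray:
        """(T, embed_dim) hidden states, causal in the trajectory's past."""
        if traj.feature_names != self.stats.feature_names:
            raise DomainError("trajectory schema does not match the model")
        X = self._inputs(traj)[None, :, :]
        valid = np.ones((1, X.shape[1]), dtype=bool)
        _, hidden, _ = self.net.forward(X, valid)
        return hidden[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "encoder_config": self.config.to_dict(),
            "stats": self.stats.to_dict(),
            "history": self.history,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.net.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "EncoderModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        config = EncoderConfig.from_dict(meta["encoder_config"])
        stats = CohortStats.from_dict(meta["stats"])
        n_feat = len(stats.feature_names)
        net = CausalEncoderNet(
            d_in=n_feat + _N_FLAGS,
            d_out=n_feat + _N_FLAGS,
            d_model=config.embed_dim,
            n_layers=config.n_layers,
            n_heads=config.n_heads,
            ffn_factor=config.ffn_factor,
            seed=config.seed,
        )
        with np.load(directory / "weights.npz") as weights:
            net.load_state_dict({k: weights[k] for k in weights.files})
        return cls(net=net, config=config, stats=stats, history=meta["history"])


# ---------------------------------------------------------------------------
# Training


def _make_batches(n: int, batch_size: int) -> list[np.ndarray]:
    order = np.arange(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def _pad_batch(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    T = max(a.shape[0] for a in arrays)
    D = arrays[0].shape[1]
    X = np.zeros((len(arrays), T, D))
    valid = np.zeros((len(arrays), T), dtype=bool)
    for i, a in enumerate(arrays):
        X[i, : a.shape[0]] = a
        valid[i, : a.shape[0]] = True
    return X, valid


def evaluate_reconstruction(
    model: EncoderModel, trajectories: list[Trajectory], corruption_seed: int
) -> float:
    """Mean squared reconstruction error of clean z-scored features from
    corrupted input, averaged over states (fixed corruption seed)."""
    total, count = 0.0, 0
    n_feat = model.n_features
    for i, traj in enumerate(trajectories):
        noisy = corrupt(traj, model.config, seed=corruption_seed + i)
        X = model._inputs(noisy)[None, :, :]
        valid = np.ones((1, X.shape[1]), dtype=bool)
        out, _, _ = model.net.forward(X, valid)
        target = model.stats.zscore(traj.features)
        err = (out[0, :, :n_feat] - target) ** 2
        total += float(err.sum())
        count += err.size
    return total / max(count, 1)


def train_encoder(
    trajectories: list[Trajectory],
    config: EncoderConfig,
    eval_trajectories: list[Trajectory] | None = None,
) -> EncoderModel:
    """Train the denoising autoencoder; seeded-deterministic.

    ``history`` records per-epoch mean training loss plus the held-out
    reconstruction MSE before the first update (``initial_eval_mse``) and
    after the last (``final_eval_mse``) when ``eval_trajectories`` is given.
    """
    if len(trajectories) < 2:
        raise DomainError("need at least 2 trajectories to train")
    schema = trajectories[0].feature_names
    for traj in trajectories:
        if traj.feature_names != schema:
            raise DomainError("inconsistent feature schema across trajectories")

    stats = CohortStats.from_trajectories(trajectories)
    n_feat = len(schema)
    max_len = max(
        max(t.n_states for t in trajectories),
        max((t.n_states for t in (eval_trajectories or [])), default=1),
    )
    net = CausalEncoderNet(
        d_in=n_feat + _N_FLAGS,
        d_out=n_feat + _N_FLAGS,
        d_model=config.embed_dim,
        n_layers=config.n_layers,
        n_heads=config.n_heads,
        ffn_factor=config.ffn_factor,
        seed=config.seed,
        max_len=max(max_len, 8),
    )
    model = EncoderModel(net=net, config=config, stats=stats)
    optimizer = Adam(net.params, lr=config.learning_rate)

    targets = [stats.zscore(t.features) for t in trajectories]
    flags = [_flags(t) for t in trajectories]

    history: dict = {"epoch": [], "train_loss": []}
    if eval_trajectories:
        history["initial_eval_mse"] = evaluate_reconstruction(
            model, eval_trajectories, corruption_seed=config.seed + 10_000
        )

    shuffle_rng = np.random.default_rng(config.seed + 1)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(trajectories))
        epoch_loss, n_batches = 0.0, 0
        for batch_ids in _make_batches(len(order), config.batch_size):
            ids = order[batch_ids]
            inputs = []
            for j, ti in enumerate(ids):
                noisy = corrupt(
                    trajectories[ti],
                    config,
                    seed=config.seed + 1_000_003 * epoch + 7 * int(ti) + j,
                )
                inputs.append(model._inputs(noisy))
            X, valid = _pad_batch(inputs)
            Y, _ = _pad_batch([targets[ti] for ti in ids])
            Fl, _ = _pad_batch([flags[ti] for ti in ids])
            out, _, fcache = net.forward(X, valid)
            loss, _, dout = reconstruction_loss_and_grad(out, Y, Fl, valid, n_feat)
            grads = net.backward(dout, fcache)
            optimizer.step(grads)
            epoch_loss += loss
            n_batches += 1
        mean_loss = epoch_loss / max(n_batches, 1)
        history["epoch"].append(epoch)
        history["train_loss"].append(mean_loss)
        logger.info("epoch %d: training loss %.5f", epoch, mean_loss)

    if eval_trajectories:
        history["final_eval_mse"] = evaluate_reconstruction(
            model, eval_trajectories, corruption_seed=config.seed + 10_000
        )
    model.history = history
    return model


# ---------------------------------------------------------------------------
# Embedding surfaces


def embed_states(model: EncoderModel, traj: Trajectory) -> list[StateEmbedding]:
    """One autoencoder embedding per state of the trajectory."""
    hidden = model.embed(traj)
    return [
        StateEmbedding(traj.patient_id, i, hidden[i].copy(), source="autoencoder")
        for i in range(traj.n_states)
    ]


def baseline_embed(
    traj: Trajectory, cohort_stats: CohortStats
) -> list[StateEmbedding]:
    """Model-free oracle embedding: the z-scored raw feature vector."""
    if traj.feature_names != cohort_stats.feature_names:
        raise DomainError("trajectory schema does not match cohort stats")
    z = cohort_stats.zscore(traj.features)
    return [
        StateEmbedding(traj.patient_id, i, z[i].copy(), source="baseline")
        for i in range(traj.n_states)
    ]
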