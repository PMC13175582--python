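"""Corruption, autoencoder training, embeddings, and the baseline oracle."""

import numpy as np
import pytest

from sepcue.cohort import DomainError, split_cohort
from sepcue.config import CohortConfig, EncoderConfig
from sepcue.embedding import (
    CohortStats,
    EncoderModel,
    baseline_embed,
    corrupt,
    embed_states,
    evaluate_reconstruction,
    train_encoder,
)
from sepcue.engine import severity_lookup
from sepcue.nn import CausalEncoderNet, reconstruction_loss_and_grad
from sepcue.retrieval import build_index, nearest_states
from sepcue.config import NeighborQueryConfig

from conftest import make_traj

SMALL = EncoderConfig(embed_dim=16, n_layers=2, n_heads=4, epochs=3, seed=0)


class TestCorrupt:
    def test_rate_zero_is_identity(self, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        out = corrupt(traj, EncoderConfig(corruption_rate=0.0), seed=1)
        assert np.array_equal(out.features, traj.features)

    def test_rate_one_masks_everything(self, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        out = corrupt(traj, EncoderConfig(corruption_rate=1.0), seed=1)
        assert np.isnan(out.features).all()

    def test_masked_fraction_binomial(self):
        traj = make_traj(features=np.zeros((500, 20)))
        out = corrupt(traj, EncoderConfig(corruption_rate=0.3), seed=2)
        n = out.features.size
        frac = np.isnan(out.features).sum() / n
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_seeded_determinism_and_structure(self, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        a = corrupt(traj, SMALL, seed=9)
        b = corrupt(traj, SMALL, seed=9)
        assert np.array_equal(a.features, b.features, equal_nan=True)
        assert a.n_states == traj.n_states
        assert np.array_equal(a.fluid_ml, traj.fluid_ml)

    @pytest.mark.parametrize("kind", ["gaussian", "shuffle-mix"])
    def test_other_kinds_keep_shape(self, kind, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        out = corrupt(traj, EncoderConfig(corruption_kind=kind), seed=3)
        assert out.features.shape == traj.features.shape
        assert not np.isnan(out.features).any()

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DomainError):
            corrupt(make_traj(features=np.zeros((0, 20))), SMALL, seed=0)


class TestBaselineEmbedding:
    def test_zscore_arithmetic_oracle(self, small_trajectories):
        trajs = list(small_trajectories.values())
        stats = CohortStats.from_trajectories(trajs)
        traj = trajs[0]
        embs = baseline_embed(traj, stats)
        # independent arithmetic for one state and three features
        for j in (0, 5, 11):
            expected = (traj.features[1, j] - stats.mean[j]) / stats.sd[j]
            assert embs[1].vector[j] == pytest.approx(expected)

    def test_mean_feature_maps_to_zero(self, small_trajectories):
        trajs = list(small_trajectories.values())
        stats = CohortStats.from_trajectories(trajs)
        traj = trajs[0]
        patched = make_traj(features=np.tile(stats.mean, (2, 1)))
        embs = baseline_embed(patched, stats)
        assert np.allclose(embs[0].vector, 0.0)

    def test_zero_sd_feature_contributes_zero(self):
        trajs = [make_traj(pid=p, features=np.ones((3, 20)) * 5.0) for p in "ab"]
        trajs[0].features[:, 1] = [1, 2, 3]
        trajs[1].features[:, 1] = [4, 5, 6]
        stats = CohortStats.from_trajectories(trajs)
        embs = baseline_embed(trajs[0], stats)
        assert embs[0].vector[0] == 0.0  # constant feature
        assert embs[0].vector[1] != 0.0

    def test_equal_states_have_zero_distance(self, small_trajectories):
        trajs = list(small_trajectories.values())
        stats = CohortStats.from_trajectories(trajs)
        a = baseline_embed(trajs[0], stats)[0]
        b = baseline_embed(trajs[0], stats)[0]
        assert np.linalg.norm(a.vector - b.vector) == 0.0


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = CausalEncoderNet(
            d_in=5, d_out=5, d_model=8, n_layers=2, n_heads=2,
            ffn_factor=2, seed=1, max_len=6,
        )
        X = rng.normal(size=(2, 4, 5))
        valid = np.array([[1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool)
        Yc = rng.normal(size=(2, 4, 3))
        Fl = rng.integers(0, 2, size=(2, 4, 2)).astype(float)

        def loss():
            out, _, cache = net.forward(X, valid)
            L, _, dout = reconstruction_loss_and_grad(out, Yc, Fl, valid, 3)
            return L, dout, cache

        _, dout, cache = loss()
        grads = net.backward(dout, cache)
        eps = 1e-6
        for key, param in net.params.items():
            idx = tuple(rng.integers(0, s) for s in param.shape)
            orig = param[idx]
            param[idx] = orig + eps
            up, _, _ = loss()
            param[idx] = orig - eps
            down, _, _ = loss()
            param[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9), key


class TestTraining:
    @pytest.fixture(scope="class")
    def split_trajs(self, small_trajectories):
        ids = sorted(small_trajectories)
        train = [small_trajectories[p] for p in ids[: len(ids) // 2]]
        held = [small_trajectories[p] for p in ids[len(ids) // 2 :]]
        return train, held

    def test_training_beats_untrained_initialization(self, split_trajs):
        train, held = split_trajs
        model = train_encoder(train, SMALL, eval_trajectories=held)
        assert model.history["final_eval_mse"] < model.history["initial_eval_mse"]
        assert len(model.history["train_loss"]) == SMALL.epochs

    def test_identical_trajectories_reconstruct_near_zero(self):
        rng = np.random.default_rng(1)
        base = make_traj(features=rng.normal(size=(6, 20)))
        clones = [
            make_traj(pid=f"C{i}", features=base.features.copy()) for i in range(12)
        ]
        config = EncoderConfig(
            embed_dim=16, n_heads=4, epochs=150, corruption_rate=0.0,
            learning_rate=3e-3, seed=2,
        )
        model = train_encoder(clones, config)
        mse = evaluate_reconstruction(model, clones[:2], corruption_seed=0)
        # features are identical across patients: variance is zero, so the
        # reconstruction should be near-exact
        assert mse < 1e-2

    def test_same_seed_gives_identical_loss(self, split_trajs):
        train, _ = split_trajs
        m1 = train_encoder(train, SMALL)
        m2 = train_encoder(train, SMALL)
        assert m1.history["train_loss"] == m2.history["train_loss"]

    def test_schema_mismatch_rejected(self, split_trajs):
        train, _ = split_trajs
        bad = make_traj(features=np.zeros((3, 20)))
        bad.feature_names = tuple(f"x{i}" for i in range(20))
        with pytest.raises(DomainError):
            train_encoder(train + [bad], SMALL)


class TestEmbeddings:
    @pytest.fixture(scope="class")
    def model(self, small_trajectories):
        train = [small_trajectories[p] for p in sorted(small_trajectories)[:30]]
        return train_encoder(train, SMALL)

    def test_identical_trajectories_identical_embeddings(self, model, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        twin = make_traj(
            pid="TWIN",
            features=traj.features.copy(),
            fluid=traj.fluid_ml,
            vaso=traj.vasopressor_active,
            diur=traj.diuretic_given,
        )
        a = model.embed(traj)
        b = model.embed(twin)
        assert np.array_equal(a, b)

    def test_causal_masking_truncation_invariance(self, model, small_trajectories):
        traj = max(small_trajectories.values(), key=lambda t: t.n_states)
        cut = traj.n_states // 2
        truncated = make_traj(
            pid=traj.patient_id,
            features=traj.features[:cut].copy(),
            fluid=traj.fluid_ml[:cut],
            vaso=traj.vasopressor_active[:cut],
            diur=traj.diuretic_given[:cut],
        )
        full = model.embed(traj)
        part = model.embed(truncated)
        assert np.allclose(full[:cut], part, atol=1e-10)

    def test_save_load_round_trip(self, model, small_trajectories, tmp_path):
        model.save(tmp_path / "ckpt")
        loaded = EncoderModel.load(tmp_path / "ckpt")
        traj = next(iter(small_trajectories.values()))
        assert np.allclose(model.embed(traj), loaded.embed(traj))

    def test_embed_states_indexing(self, model, small_trajectories):
        traj = next(iter(small_trajectories.values()))
        embs = embed_states(model, traj)
        assert [e.bin_index for e in embs] == list(range(traj.n_states))
        assert all(e.source == "autoencoder" for e in embs)
        assert all(len(e.vector) == SMALL.embed_dim for e in embs)


def test_autoencoder_neighbors_are_severity_coherent(small_sim, small_trajectories):
    """Embedding-space neighbors share latent severity more than random
    states do, for every query seed tested."""
    _, _, ground_truth = small_sim
    config = CohortConfig()
    ids = sorted(small_trajectories)
    train = [small_trajectories[p] for p in ids[:40]]
    model = train_encoder(train, EncoderConfig(embed_dim=16, n_heads=4, epochs=5, seed=3))
    pool = [e for t in train for e in embed_states(model, t)]
    index = build_index(pool)
    severity = severity_lookup(ground_truth)
    sev = np.array([severity[(e.patient_id, e.bin_index)] for e in pool])
    for seed in (0, 1):
        rng = np.random.default_rng(seed)
        nn_gaps, random_gaps = [], []
        for qi in rng.choice(len(pool), size=60, replace=False):
            q = pool[qi]
            s_q = severity[(q.patient_id, q.bin_index)]
            ns = nearest_states(index, q, NeighborQueryConfig(k=10))
            nn_gaps.append(
                np.mean([abs(severity[(p, b)] - s_q) for p, b, _ in ns.neighbors])
            )
            random_gaps.append(
                np.mean(np.abs(sev[rng.choice(len(pool), size=10, replace=False)] - s_q))
            )
        assert np.mean(nn_gaps) < np.mean(random_gaps)
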