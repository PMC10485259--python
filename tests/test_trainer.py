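"""Alternating training loop, baselines, checkpoints and reproducibility."""

import csv

import numpy as np
import pytest

import splitreg.trainer as trainer_mod
from splitreg.core import Hyperparams
from splitreg.networks import DenoiserNetSpec, SimilarityNetSpec
from splitreg.synthetic import SyntheticSpec, make_dataset
from splitreg.trainer import (
    Adam,
    TrainingConfig,
    init_state,
    load_checkpoint,
    register,
    save_checkpoint,
    save_history,
    train,
)

TINY_SIM = SimilarityNetSpec((2, 2, 2, 2), (2, 2, 2, 2), (2, 2))
TINY_DEN = DenoiserNetSpec(2, (1, 2), 2, 2)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset(SyntheticSpec(shape=(32, 32), n_pairs=3, seed=5))


def _cfg(**kw):
    base = dict(
        mode="decoupled",
        iterations=3,
        learning_rate=1e-3,
        batch_size=2,
        seed=0,
        checkpoint_every=1,
    )
    base.update(kw)
    return TrainingConfig(**base)


class TestConfigValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            _cfg(mode="unsupervised")

    @pytest.mark.parametrize(
        "kw",
        [{"iterations": -1}, {"batch_size": 0}, {"checkpoint_every": 0},
         {"learning_rate": 0.0}],
    )
    def test_bad_numbers(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            train([], _cfg(), TINY_SIM, TINY_DEN)


class TestTrainingLoop:
    def test_zero_iterations_returns_initial_state(self, tiny_dataset):
        state, history = train(tiny_dataset, _cfg(iterations=0), TINY_SIM, TINY_DEN)
        assert history == []
        assert state.iteration == 0
        ref = init_state(_cfg(iterations=0), 2, TINY_SIM, TINY_DEN)
        for k, v in ref.sim_params.items():
            np.testing.assert_array_equal(state.sim_params[k], v)

    def test_initial_registration_is_near_identity(self, tiny_dataset):
        state, _ = train(tiny_dataset, _cfg(iterations=0), TINY_SIM, TINY_DEN)
        pair = tiny_dataset[0]
        u, warped, v = register(state, pair.fixed, pair.moving)
        assert np.abs(u.displacements).max() <= 1e-3
        assert v is not None

    def test_bitwise_reproducible(self, tiny_dataset):
        s1, h1 = train(tiny_dataset, _cfg(), TINY_SIM, TINY_DEN)
        s2, h2 = train(tiny_dataset, _cfg(), TINY_SIM, TINY_DEN)
        for k in s1.sim_params:
            np.testing.assert_array_equal(s1.sim_params[k], s2.sim_params[k])
        for k in s1.den_params:
            np.testing.assert_array_equal(s1.den_params[k], s2.den_params[k])
        assert h1 == h2

    def test_history_schedule_and_fields(self, tiny_dataset):
        _, history = train(
            tiny_dataset, _cfg(iterations=5, checkpoint_every=2), TINY_SIM, TINY_DEN
        )
        assert [h["iteration"] for h in history] == [1, 2, 4]
        for h in history:
            assert set(h) == {"iteration", "sim_loss", "denoise_loss", "joint_objective"}
            assert np.isfinite(h["sim_loss"])
            assert np.isfinite(h["joint_objective"])

    def test_decoupled_updates_both_networks(self, tiny_dataset):
        cfg = _cfg(iterations=2)
        init = init_state(cfg, 2, TINY_SIM, TINY_DEN)
        state, _ = train(tiny_dataset, cfg, TINY_SIM, TINY_DEN)
        assert any(
            not np.array_equal(init.sim_params[k], state.sim_params[k])
            for k in init.sim_params
        )
        assert any(
            not np.array_equal(init.den_params[k], state.den_params[k])
            for k in init.den_params
        )

    def test_each_substep_touches_only_its_network(self, tiny_dataset, monkeypatch):
        """Step (a) steps only similarity parameters, step (b) only denoiser ones."""
        calls = []
        orig = Adam.step

        def spy(self, params, grads):
            calls.append((id(params), frozenset(grads)))
            return orig(self, params, grads)

        monkeypatch.setattr(Adam, "step", spy)
        state, _ = train(tiny_dataset, _cfg(iterations=2), TINY_SIM, TINY_DEN)
        assert len(calls) == 4  # (a) and (b) per iteration
        sim_keys = frozenset(state.sim_params)
        den_keys = frozenset(state.den_params)
        for pid, keys in calls[0::2]:
            assert pid == id(state.sim_params) and keys <= sim_keys
        for pid, keys in calls[1::2]:
            assert pid == id(state.den_params) and keys <= den_keys

    def test_s_net_never_instantiates_denoiser(self, tiny_dataset):
        for mode in ("s_net", "ss_net"):
            state, history = train(
                tiny_dataset, _cfg(mode=mode, iterations=2), TINY_SIM, TINY_DEN
            )
            assert state.den_net is None and state.den_params is None
            assert all(np.isnan(h["denoise_loss"]) for h in history)
            u, warped, v = register(state, tiny_dataset[0].fixed, tiny_dataset[0].moving)
            assert v is None

    def test_ss_net_with_zero_lambda_matches_s_net(self, tiny_dataset):
        hp = Hyperparams(lambda_=0.0)
        s1, _ = train(
            tiny_dataset, _cfg(mode="s_net", hyperparams=hp), TINY_SIM, TINY_DEN
        )
        s2, _ = train(
            tiny_dataset, _cfg(mode="ss_net", hyperparams=hp), TINY_SIM, TINY_DEN
        )
        for k in s1.sim_params:
            np.testing.assert_array_equal(s1.sim_params[k], s2.sim_params[k])

    def test_ss_net_differs_from_s_net_with_smoothing(self, tiny_dataset):
        s1, _ = train(tiny_dataset, _cfg(mode="s_net", iterations=3), TINY_SIM, TINY_DEN)
        s2, _ = train(tiny_dataset, _cfg(mode="ss_net", iterations=3), TINY_SIM, TINY_DEN)
        assert any(
            not np.array_equal(s1.sim_params[k], s2.sim_params[k])
            for k in s1.sim_params
        )

    def test_augmentation_changes_training_but_not_shape_contract(self, tiny_dataset):
        s_on, _ = train(tiny_dataset, _cfg(augment=True), TINY_SIM, TINY_DEN)
        s_off, _ = train(tiny_dataset, _cfg(augment=False), TINY_SIM, TINY_DEN)
        assert any(
            not np.array_equal(s_on.sim_params[k], s_off.sim_params[k])
            for k in s_on.sim_params
        )
        pair = tiny_dataset[0]
        u, _, _ = register(s_on, pair.fixed, pair.moving)
        assert u.displacements.shape == (2, 32, 32)


class TestAdam:
    def test_single_step_matches_hand_formula(self):
        opt = Adam(lr=0.1)
        p = {"w": np.array([1.0, 2.0])}
        g = {"w": np.array([0.5, -0.5])}
        opt.step(p, g)
        # first step: m_hat = g, v_hat = g^2 -> update = lr * sign-ish
        expect = np.array([1.0, 2.0]) - 0.1 * g["w"] / (np.abs(g["w"]) + 1e-8)
        np.testing.assert_allclose(p["w"], expect, rtol=1e-6)

    def test_none_gradients_skipped(self):
        opt = Adam(lr=0.1)
        p = {"w": np.ones(2)}
        opt.step(p, {"w": None})
        np.testing.assert_array_equal(p["w"], np.ones(2))


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        state, _ = train(tiny_dataset, _cfg(), TINY_SIM, TINY_DEN)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state)
        loaded = load_checkpoint(path)
        assert loaded.config == state.config
        assert loaded.iteration == state.iteration
        for k in state.sim_params:
            np.testing.assert_array_equal(loaded.sim_params[k], state.sim_params[k])
        for k in state.den_params:
            np.testing.assert_array_equal(loaded.den_params[k], state.den_params[k])
        pair = tiny_dataset[1]
        u1, w1, v1 = register(state, pair.fixed, pair.moving)
        u2, w2, v2 = register(loaded, pair.fixed, pair.moving)
        np.testing.assert_array_equal(u1.displacements, u2.displacements)
        np.testing.assert_array_equal(v1.displacements, v2.displacements)

    def test_checkpoint_round_trip_s_net(self, tiny_dataset, tmp_path):
        state, _ = train(tiny_dataset, _cfg(mode="s_net"), TINY_SIM, TINY_DEN)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state)
        loaded = load_checkpoint(path)
        assert loaded.den_net is None and loaded.den_params is None

    def test_history_csv_round_trip(self, tiny_dataset, tmp_path):
        _, history = train(tiny_dataset, _cfg(), TINY_SIM, TINY_DEN)
        path = tmp_path / "history.csv"
        save_history(path, history)
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(history)
        for row, h in zip(rows, history):
            assert int(row["iteration"]) == h["iteration"]
            assert float(row["sim_loss"]) == pytest.approx(h["sim_loss"])


class TestRandomSymmetry:
    def test_identical_transform_for_both_images(self):
        rng = np.random.default_rng(3)
        fb = rng.uniform(size=(2, 16, 16))
        diff = rng.uniform(size=(2, 16, 16))
        fa, ma = trainer_mod._random_symmetry(fb, fb + diff, np.random.default_rng(1))
        # the same symmetry applied to both: their difference is the
        # transformed difference, and content is preserved up to reordering
        np.testing.assert_allclose(np.sort((ma - fa).ravel()), np.sort(diff.ravel()))
        np.testing.assert_allclose(np.sort(fa.ravel()), np.sort(fb.ravel()))

    def test_non_square_grids_only_flip(self):
        rng = np.random.default_rng(0)
        fb = rng.uniform(size=(1, 16, 32))
        for seed in range(10):
            fa, _ = trainer_mod._random_symmetry(fb, fb, np.random.default_rng(seed))
            assert fa.shape == fb.shape
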