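"""Training protocol: loss, early stopping, freezing, grid search."""

import numpy as np
import pytest

from nptarget.balance import build_cost_matrix
from nptarget.model import forward_batch, init_parameters, predict_proba
from nptarget.synthdata import SyntheticSpec, generate
from nptarget.train import (
    FINETUNE_GRID,
    PRETRAIN_GRID,
    FinetuneConfig,
    OptimizerConfig,
    PretrainConfig,
    TrainingHistory,
    finetune,
    grid_search,
    pretrain,
    weighted_bce_loss,
)


class TestWeightedBce:
    def test_unit_costs_equal_plain_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, (4, 3))
        y = rng.integers(0, 2, (4, 3))
        plain = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert weighted_bce_loss(p, y, np.ones_like(p)) == pytest.approx(plain)

    def test_exact_prediction_zero_loss(self):
        y = np.array([[0.0, 1.0]])
        assert weighted_bce_loss(y, y, np.ones_like(y)) == 0.0

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.99, (4, 3))
        y = rng.integers(0, 2, (4, 3)).astype(float)
        c = rng.uniform(0, 5, (4, 3))
        total = 0.0
        for i in range(4):
            for j in range(3):
                bce = -(y[i, j] * np.log(p[i, j])
                        + (1 - y[i, j]) * np.log(1 - p[i, j]))
                total += c[i, j] * bce
        assert weighted_bce_loss(p, y, c) == pytest.approx(total / 12,
                                                           abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_bce_loss(np.ones((2, 2)), np.ones((2, 2)), np.ones(4))


def _tiny_problem(n=60, bits=12, targets=3, seed=0):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, bits)) < 0.3).astype(float)
    Y = (rng.random((n, targets)) < 0.3).astype(np.int8)
    Y[0, 0] = 1  # both classes somewhere
    Y[1, 0] = 0
    return X, Y


class TestEarlyStopping:
    def _scripted_pretrain(self, scores, **cfg_kw):
        """Run pretrain with a scripted evaluation trajectory.

        The metric records a snapshot of the parameters at every call, so
        checkpoint restoration can be verified from outside.
        """
        X, Y = _tiny_problem()
        calls = []

        def metric(params, X_val, Y_val):
            calls.append(params.copy())
            return scores[len(calls) - 1]

        cfg = PretrainConfig(folds=2, eval_every=5, patience=5,
                             layer_sizes=(12, 6, 5, 4), **cfg_kw)
        opt = OptimizerConfig(learning_rate=1e-3, batch_size=16)
        params, history = pretrain(Y, X, cfg, opt, seed=3, eval_metric=metric)
        return params, history, calls

    def test_monotone_decline_stops_after_five_evaluations(self):
        # per fold: baseline + 5 non-improving evaluations, stop at epoch 25
        scores = [0.90 - 0.01 * i for i in range(20)]
        params, history, calls = self._scripted_pretrain(scores)
        for fold in (0, 1):
            evals = [r for r in history.records
                     if r["fold"] == fold and "event" not in r]
            assert [r["epoch"] for r in evals] == [0, 5, 10, 15, 20, 25]
        # the best checkpoint is the epoch-0 baseline of fold 0
        best = calls[0]
        for a, b in zip(params.capsule_linear_arrays(),
                        best.capsule_linear_arrays()):
            assert np.array_equal(a, b)

    def test_restores_mid_training_peak(self):
        # fold 0 peaks at its third evaluation (epoch 10), then declines;
        # fold 1 stays poor throughout
        scores = [0.5, 0.7, 0.9, 0.6, 0.59, 0.58, 0.57, 0.56] + [0.1] * 12
        params, history, calls = self._scripted_pretrain(scores)
        assert history.best["val_auroc"] == 0.9
        best = calls[2]
        for a, b in zip(params.adaptable_arrays(), best.adaptable_arrays()):
            assert np.array_equal(a, b)

    def test_epoch_cap_when_patience_never_exhausted(self):
        scores = [0.1 + 0.001 * i for i in range(200)]  # always improving
        params, history, _ = self._scripted_pretrain(scores, epoch_cap=20)
        fold0 = [r for r in history.records
                 if r["fold"] == 0 and "event" not in r]
        assert fold0[-1]["epoch"] == 20


class TestPretrain:
    def test_determinism(self):
        X, Y = _tiny_problem()
        cfg = PretrainConfig(folds=2, epoch_cap=10, layer_sizes=(12, 6, 5, 4))
        opt = OptimizerConfig(learning_rate=5e-3, batch_size=16)
        p1, h1 = pretrain(Y, X, cfg, opt, seed=9)
        p2, h2 = pretrain(Y, X, cfg, opt, seed=9)
        assert h1.records == h2.records
        for a, b in zip(p1.adaptable_arrays(), p2.adaptable_arrays()):
            assert np.array_equal(a, b)

    def test_epochs_strictly_increase_within_fold(self):
        X, Y = _tiny_problem()
        cfg = PretrainConfig(folds=3, epoch_cap=15, layer_sizes=(12, 6, 5, 4))
        _, hist = pretrain(Y, X, cfg,
                           OptimizerConfig(learning_rate=5e-3, batch_size=16),
                           seed=1)
        for fold in range(3):
            epochs = [r["epoch"] for r in hist.records
                      if r["fold"] == fold and "event" not in r]
            assert epochs == sorted(set(epochs))


@pytest.fixture(scope="module")
def finetuned():
    spec = SyntheticSpec(n_source=300, n_target=120, n_targets=6,
                         n_bits=24, seed=5)
    source, target = generate(spec)
    cfg = PretrainConfig(folds=2, epoch_cap=10, layer_sizes=(24, 12, 10, 8))
    pre, _ = pretrain(source.labels, source.fingerprints, cfg,
                      OptimizerConfig(learning_rate=5e-3, batch_size=64),
                      seed=5)
    tuned, hist = finetune(
        pre, target.labels, target.fingerprints, FinetuneConfig(epochs=12),
        OptimizerConfig(learning_rate=5e-3, batch_size=32), seed=5,
    )
    return pre, tuned, hist


class TestFinetune:
    def test_capsule_linear_parameters_bitwise_frozen(self, finetuned):
        pre, tuned, _ = finetuned
        for a, b in zip(pre.capsule_linear_arrays(),
                        tuned.capsule_linear_arrays()):
            assert np.array_equal(a, b)

    def test_adaptable_parameters_change(self, finetuned):
        pre, tuned, _ = finetuned
        changed = [
            not np.array_equal(a, b)
            for a, b in zip(pre.adaptable_arrays(), tuned.adaptable_arrays())
        ]
        assert all(changed)

    def test_runs_exactly_configured_epochs(self, finetuned):
        _, _, hist = finetuned
        assert [r["epoch"] for r in hist.records] == list(range(1, 13))

    def test_zero_learning_rate_changes_only_running_stats(self):
        spec = SyntheticSpec(n_source=300, n_target=80, n_targets=6,
                             n_bits=24, seed=6)
        _, target = generate(spec)
        pre = init_parameters((24, 12, 10, 8), 6, np.random.default_rng(0))
        tuned, _ = finetune(
            pre, target.labels, target.fingerprints, FinetuneConfig(epochs=3),
            OptimizerConfig(learning_rate=0.0, batch_size=32), seed=0,
        )
        for a, b in zip(pre.adaptable_arrays(), tuned.adaptable_arrays()):
            assert np.array_equal(a, b)
        assert not np.array_equal(pre.capsules[0].running_mean,
                                  tuned.capsules[0].running_mean)

    def test_running_means_move_toward_shifted_input(self):
        """One train-mode batch pulls running means toward batch statistics."""
        params = init_parameters((8, 4, 3, 3), 2, np.random.default_rng(1))
        X = np.random.default_rng(2).random((32, 8)) + 10.0  # strong shift
        z = X @ params.capsules[0].W.T + params.capsules[0].b
        expected = 0.9 * params.capsules[0].running_mean + 0.1 * z.mean(axis=0)
        forward_batch(params, X, mode="train")
        assert np.allclose(params.capsules[0].running_mean, expected)

    def test_incompatible_target_count_rejected(self):
        params = init_parameters((8, 4, 3, 3), 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            finetune(params, np.zeros((10, 5), dtype=np.int8),
                     np.zeros((10, 8)), FinetuneConfig(),
                     OptimizerConfig(), seed=0)


class TestGridSearch:
    def test_grids_match_protocol(self):
        assert len(PRETRAIN_GRID) == 12
        assert {c["learning_rate"] for c in PRETRAIN_GRID} == {
            5e-2, 5e-3, 5e-4, 5e-5
        }
        assert {c["batch_size"] for c in PRETRAIN_GRID} == {256, 512, 1024}
        assert len(FINETUNE_GRID) == 6
        assert {c["batch_size"] for c in FINETUNE_GRID} == {32, 64, 128}

    def test_ranking_contract(self):
        scores = {"a": 0.7, "b": 0.9, "c": None}
        ranked = grid_search(lambda cfg: scores[cfg], ["a", "b", "c"])
        assert [r["config"] for r in ranked] == ["b", "a", "c"]
        assert [r["rank"] for r in ranked] == [1, 2, 3]

    def test_duplicate_configs_score_identically(self):
        X, Y = _tiny_problem()
        cfg = PretrainConfig(folds=2, epoch_cap=5, layer_sizes=(12, 6, 5, 4))

        def run(c):
            _, hist = pretrain(Y, X, cfg,
                               OptimizerConfig(**c), seed=4)
            return hist.best["val_auroc"]

        grid = [{"learning_rate": 5e-3, "batch_size": 16}] * 2
        ranked = grid_search(run, grid)
        assert ranked[0]["score"] == ranked[1]["score"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(lambda c: 0.0, [])


def test_history_container():
    h = TrainingHistory()
    h.log(fold=0, epoch=0, val_auroc=0.5)
    assert h.to_rows() == [{"fold": 0, "epoch": 0, "val_auroc": 0.5}]
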