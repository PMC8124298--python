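"""Pre-training and fine-tuning of the multitask network.

Pre-training runs random-split k-fold cross-validation (default 5 folds)
with all parameters trainable.  Micro-averaged AUROC on the held-out fold
is evaluated before training starts and then every 5 epochs; after 5
cumulative evaluations without improving the best score, training stops and
the best checkpoint is restored.  The returned model is the fold model with
the highest validation AUROC.

Fine-tuning freezes the capsule linear weights and biases exactly — they
are bitwise identical before and after — and updates only the batch-norm
affine parameters and the classifier head for a fixed 100 epochs on a
90:10 random split.  Batch-norm running statistics also adapt to the new
input distribution (the mechanism that transfers the model across the
source-to-target covariate shift); a switch can hold them fixed.

Both phases use Adam (β1=0.9, β2=0.999), weight decay 0.002 on the capsule
linear parameters only, and cost-weighted binary cross-entropy computed on
logits for numerical stability.  All randomness (splits, shuffles, init)
derives from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import xlogy

from . import balance
from .curation import LabelMatrix
from .evaluation import micro_auroc
from .model import (
    ModelParameters,
    backward_batch,
    forward_batch,
    init_parameters,
    predict_proba,
    sigmoid,
)

#: learning-rate x batch-size grid searched during pre-training
PRETRAIN_GRID = tuple(
    {"learning_rate": lr, "batch_size": bs}
    for lr, bs in product((5e-2, 5e-3, 5e-4, 5e-5), (256, 512, 1024))
)
#: grid searched during fine-tuning
FINETUNE_GRID = tuple(
    {"learning_rate": lr, "batch_size": bs}
    for lr, bs in product((5e-2, 5e-3), (32, 64, 128))
)


@dataclass
class OptimizerConfig:
    learning_rate: float = 5e-4
    batch_size: int = 256
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.002  # capsule linear parameters only

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be >=0 and batch_size >=1")


@dataclass
class PretrainConfig:
    folds: int = 5
    eval_every: int = 5
    patience: int = 5
    epoch_cap: int = 500
    layer_sizes: tuple = (2048, 2048, 1536, 1024)
    use_cost_weights: bool = True


@dataclass
class FinetuneConfig:
    epochs: int = 100
    split_ratio: float = 0.9
    update_running_stats: bool = True
    use_cost_weights: bool = True


@dataclass
class TrainingHistory:
    """Per-evaluation log and a pointer to the best checkpoint."""

    records: list = field(default_factory=list)
    best: dict = field(default_factory=dict)

    def log(self, **kw):
        self.records.append(kw)

    def to_rows(self):
        return list(self.records)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_bce_loss(probabilities, labels, costs) -> float:
    """Mean over all cells of cost * binary cross-entropy."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    c = np.asarray(costs, dtype=float)
    if not (p.shape == y.shape == c.shape):
        raise ValueError("probabilities, labels and costs must share a shape")
    bce = -(xlogy(y, p) + xlogy(1.0 - y, 1.0 - p))
    return float(np.mean(c * bce))


def _bce_with_logits(logits, labels, costs):
    """(loss, dloss/dlogits) with the stable log1p(exp) formulation."""
    z, y, c = logits, labels, costs
    per_cell = c * (np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    loss = float(per_cell.mean())
    dlogits = c * (sigmoid(z) - y) / z.size
    return loss, dlogits


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _Adam:
    """Adam over an explicit list of (array, decay) slots, updated in place."""

    def __init__(self, slots, cfg: OptimizerConfig):
        self.slots = slots  # list[(np.ndarray, bool apply_weight_decay)]
        self.cfg = cfg
        self.m = [np.zeros_like(a) for a, _ in slots]
        self.v = [np.zeros_like(a) for a, _ in slots]
        self.t = 0

    def step(self, grads):
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1 ** self.t
        bc2 = 1.0 - cfg.beta2 ** self.t
        for (param, decay), m, v, g in zip(self.slots, self.m, self.v, grads):
            if decay and cfg.weight_decay:
                g = g + cfg.weight_decay * param
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * g * g
            param -= cfg.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + 1e-8)


def _slots_and_grad_getter(params: ModelParameters, trainable: str):
    """Parameter slots + a function mapping backward grads to slot order."""
    slots, paths = [], []
    for i, cap in enumerate(params.capsules):
        if trainable == "all":
            slots += [(cap.W, True), (cap.b, True)]
            paths += [(i, "dW"), (i, "db")]
        slots += [(cap.gamma, False), (cap.beta, False)]
        paths += [(i, "dgamma"), (i, "dbeta")]
    slots += [(params.clf_W, False), (params.clf_b, False)]
    paths += [(None, "clf_W"), (None, "clf_b")]

    def get(grads):
        return [
            grads[key] if i is None else grads["capsules"][i][key]
            for i, key in paths
        ]

    return slots, get


def _train_one_epoch(params, X, Y, C, adam, get_grads, opt, rng,
                     update_running_stats=True):
    order = rng.permutation(len(X))
    losses = []
    for start in range(0, len(X), opt.batch_size):
        idx = order[start:start + opt.batch_size]  # last short batch kept
        logits, _, cache = forward_batch(
            params, X[idx], mode="train",
            update_running_stats=update_running_stats,
        )
        loss, dlogits = _bce_with_logits(logits, Y[idx], C[idx])
        adam.step(get_grads(backward_batch(params, cache, dlogits)))
        losses.append(loss)
    return float(np.mean(losses))


def _as_arrays(matrix, fingerprints):
    labels = matrix.labels if isinstance(matrix, LabelMatrix) else np.asarray(matrix)
    X = np.asarray(fingerprints, dtype=np.float64)
    if len(X) != len(labels):
        raise ValueError("fingerprints and labels are not aligned")
    return X, labels.astype(np.float64)


def _default_eval(params, X_val, Y_val):
    return micro_auroc(predict_proba(params, X_val), Y_val)


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def pretrain(
    matrix,
    fingerprints,
    config: PretrainConfig,
    opt: OptimizerConfig,
    seed: int,
    eval_metric=None,
) -> tuple[ModelParameters, TrainingHistory]:
    """K-fold pre-training with AUROC early stopping.

    ``eval_metric(params, X_val, Y_val) -> float`` defaults to held-out
    micro AUROC.  Per fold: evaluate at epoch 0, then every ``eval_every``
    epochs; after ``patience`` evaluations without a new best, stop and
    restore the best checkpoint (an epoch cap bounds the loop).  Returns the
    best fold's best checkpoint and the full history.
    """
    X, Y = _as_arrays(matrix, fingerprints)
    C = (balance.build_cost_matrix(Y.astype(np.int8))
         if config.use_cost_weights else np.ones_like(Y))
    evaluate = eval_metric if eval_metric is not None else _default_eval

    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    fold_of = split_rng.permutation(len(X)) % config.folds

    history = TrainingHistory()
    best_overall = (-np.inf, None)
    sizes = (X.shape[1],) + tuple(config.layer_sizes[1:])
    for fold in range(config.folds):
        fold_ss = np.random.SeedSequence(seed, spawn_key=(fold + 1,))
        init_rng, shuffle_rng = (
            np.random.default_rng(s) for s in fold_ss.spawn(2)
        )
        val = fold_of == fold
        params = init_parameters(sizes, Y.shape[1], rng=init_rng)
        slots, get_grads = _slots_and_grad_getter(params, "all")
        adam = _Adam(slots, opt)

        best_score, best_params, bad = -np.inf, params.copy(), 0
        score = evaluate(params, X[val], Y[val])
        history.log(fold=fold, epoch=0, train_loss=None, val_auroc=score)
        if score is not None:
            best_score, best_params = score, params.copy()

        epoch = 0
        while epoch < config.epoch_cap and bad < config.patience:
            epoch += 1
            loss = _train_one_epoch(
                params, X[~val], Y[~val], C[~val], adam, get_grads, opt,
                shuffle_rng,
            )
            if epoch % config.eval_every:
                continue
            score = evaluate(params, X[val], Y[val])
            history.log(fold=fold, epoch=epoch, train_loss=loss,
                        val_auroc=score)
            if score is not None and score > best_score:
                best_score, best_params, bad = score, params.copy(), 0
            else:
                bad += 1

        history.log(fold=fold, epoch=epoch, train_loss=None,
                    val_auroc=best_score, event="fold_best")
        if best_score > best_overall[0]:
            best_overall = (best_score, best_params)

    history.best = {"val_auroc": best_overall[0]}
    return best_overall[1], history


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def finetune(
    pretrained: ModelParameters,
    np_matrix,
    fingerprints,
    config: FinetuneConfig,
    opt: OptimizerConfig,
    seed: int,
) -> tuple[ModelParameters, TrainingHistory]:
    """Fixed-length fine-tuning with frozen capsule linear parameters.

    Trains for exactly ``config.epochs`` epochs on the 90% split; capsule
    linear weights/biases in the result are bitwise identical to the input.
    Batch-norm affine parameters, (optionally) running statistics, and the
    classifier head adapt.  The held-out 10% micro AUROC is logged per epoch.
    """
    X, Y = _as_arrays(np_matrix, fingerprints)
    if Y.shape[1] != pretrained.n_targets:
        raise ValueError(
            f"matrix has {Y.shape[1]} targets but the model predicts "
            f"{pretrained.n_targets}"
        )
    C = (balance.build_cost_matrix(Y.astype(np.int8))
         if config.use_cost_weights else np.ones_like(Y))

    ss = np.random.SeedSequence(seed, spawn_key=(101,))
    split_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    order = split_rng.permutation(len(X))
    n_train = int(round(config.split_ratio * len(X)))
    tr, va = order[:n_train], order[n_train:]

    params = pretrained.copy()
    slots, get_grads = _slots_and_grad_getter(params, "adapt")
    adam = _Adam(slots, opt)

    history = TrainingHistory()
    best = (-np.inf, params.copy())
    for epoch in range(1, config.epochs + 1):
        loss = _train_one_epoch(
            params, X[tr], Y[tr], C[tr], adam, get_grads, opt, shuffle_rng,
            update_running_stats=config.update_running_stats,
        )
        score = (
            micro_auroc(predict_proba(params, X[va]), Y[va]) if len(va) else None
        )
        history.log(fold=0, epoch=epoch, train_loss=loss, val_auroc=score)
        if score is not None and score > best[0]:
            best = (score, params.copy())

    history.best = {"val_auroc": best[0], "final_val_auroc": score,
                    "val_indices": va.tolist()}
    return params, history


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def grid_search(train_fn, grid, descending: bool = True) -> list:
    """Run ``train_fn(config) -> score`` over a grid; rank by score.

    Returns [{'config', 'score', 'rank'}] sorted best-first; None scores
    rank last.  Ties keep grid order (stable sort).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    results = [{"config": cfg, "score": train_fn(cfg)} for cfg in grid]
    sign = -1.0 if descending else 1.0
    ranked = sorted(
        results,
        key=lambda r: sign * r["score"] if r["score"] is not None else np.inf,
    )
    for rank, r in enumerate(ranked, start=1):
        r["rank"] = rank
    return ranked
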