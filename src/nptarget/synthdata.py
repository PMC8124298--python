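"""Synthetic fingerprint/label data with the structure the method assumes.

The generator emulates three statistical features of curated bioactivity
data without any chemistry: (i) sparse multilabel activity — most compounds
active on at most a couple of targets; (ii) strong class imbalance — a few
percent of cells positive; (iii) a source-to-target covariate shift — the
fine-tuning set draws its fingerprint bits at shifted frequencies while the
input-to-label relationship (a sparse linear-logistic "teacher") is shared.
That last property is exactly the regime batch-norm adaptation targets:
the inputs move, the concept does not.

Also here: the hand-written curation fixture (a small activity table with
its hand-derived curated output) and the two synthetic experiment designs
the package reproduces — the transfer-learning effect and the
cost-weighting ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import LabelMatrix, SanitizedCompound
from .evaluation import compute_metrics, confusion_at_cutoff, micro_auroc
from .model import predict_proba
from .train import (
    FinetuneConfig,
    OptimizerConfig,
    PretrainConfig,
    finetune,
    pretrain,
)


@dataclass
class SyntheticSpec:
    """Desk-scale defaults: small enough for CPU minutes, shaped like the
    curated data (hundreds of compounds per task, ~3% positive cells,
    most compounds with <=2 actives)."""

    n_source: int = 4000
    n_target: int = 500
    n_targets: int = 50
    n_bits: int = 256
    bit_density: float = 0.15
    shift_delta: float = 0.13
    positive_rate_goal: float = 0.03
    teacher_bits_per_task: int = 10
    teacher_weight_scale: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.bit_density < 1:
            raise ValueError("bit_density must be in (0, 1)")
        if not 0 < self.positive_rate_goal < 0.5:
            raise ValueError("positive_rate_goal must be in (0, 0.5)")
        if not 0 <= self.shift_delta < min(self.bit_density,
                                           1 - self.bit_density):
            raise ValueError(
                "shift_delta must keep bit probabilities inside (0, 1)"
            )


@dataclass
class SyntheticDataset:
    fingerprints: np.ndarray  # uint8 (n, n_bits)
    labels: np.ndarray  # int8 (n, n_targets)
    teacher: dict  # {'W': (n_targets, n_bits), 'b': (n_targets,)}
    provenance: dict = field(default_factory=dict)

    @property
    def positive_rate(self) -> float:
        return float(self.labels.mean())

    def as_label_matrix(self, prefix: str = "SYN") -> LabelMatrix:
        """Wrap labels in the curation container (synthetic row ids)."""
        compounds = [
            SanitizedCompound(f"{prefix}-{i:06d}", frozenset({f"{prefix}-{i:06d}"}))
            for i in range(len(self.labels))
        ]
        targets = [f"T{j:03d}" for j in range(self.labels.shape[1])]
        return LabelMatrix(compounds, targets, self.labels)

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.as_label_matrix().to_dir(out)
        np.savez(out / "fingerprints.npz", fingerprints=self.fingerprints,
                 teacher_W=self.teacher["W"], teacher_b=self.teacher["b"])
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )


def _calibrate_intercept(logits_no_b: np.ndarray, goal: float) -> float:
    """Bisect b so that mean sigmoid(logits + b) == goal on the sample."""
    lo, hi = -40.0, 40.0
    def rate(b):
        return float(np.mean(1.0 / (1.0 + np.exp(-(logits_no_b + b)))))
    if not rate(lo) <= goal <= rate(hi):
        raise ValueError(
            f"cannot calibrate intercept for positive rate {goal}"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if rate(mid) < goal:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _teacher_weights(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    W = np.zeros((spec.n_targets, spec.n_bits))
    for j in range(spec.n_targets):
        support = rng.choice(
            spec.n_bits, size=spec.teacher_bits_per_task, replace=False
        )
        W[j, support] = rng.normal(
            0.0, spec.teacher_weight_scale, size=spec.teacher_bits_per_task
        )
    return W


def _draw(X_bits, W, b, rng):
    probs = 1.0 / (1.0 + np.exp(-(X_bits.astype(float) @ W.T + b)))
    return (rng.random(probs.shape) < probs).astype(np.int8)


def generate(
    spec: SyntheticSpec, n_target_eval: int = 0
) -> tuple[SyntheticDataset, ...]:
    """Draw (source, target[, target_eval]) datasets sharing one teacher.

    Source bits ~ Bernoulli(bit_density); target bits ~ Bernoulli of the
    per-bit shifted probabilities (bit_density +/- shift_delta, random sign
    per bit) — covariate shift only.  Per-task intercepts are calibrated on
    the source sample so the realized positive rate lands within +/-20%
    relative of ``positive_rate_goal``.  ``n_target_eval > 0`` additionally
    draws an independent sample of that size from the target distribution
    (same teacher), useful as a low-variance evaluation set.
    """
    ss = np.random.SeedSequence(spec.seed)
    r_teacher, r_src, r_tgt, r_shift = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    W = _teacher_weights(spec, r_teacher)

    X_src = (r_src.random((spec.n_source, spec.n_bits))
             < spec.bit_density).astype(np.uint8)
    signs = r_shift.choice((-1.0, 1.0), size=spec.n_bits)
    p_tgt = np.clip(spec.bit_density + signs * spec.shift_delta, 0.01, 0.99)
    X_tgt = (r_tgt.random((spec.n_target, spec.n_bits)) < p_tgt).astype(np.uint8)

    base_logits = X_src.astype(float) @ W.T
    b = np.array([
        _calibrate_intercept(base_logits[:, j], spec.positive_rate_goal)
        for j in range(spec.n_targets)
    ])

    y_src = _draw(X_src, W, b, r_src)
    y_tgt = _draw(X_tgt, W, b, r_tgt)

    realized = float(y_src.mean())
    lo, hi = 0.8 * spec.positive_rate_goal, 1.2 * spec.positive_rate_goal
    if not lo <= realized <= hi:
        raise ValueError(
            f"calibration failed: realized source positive rate {realized:.4f} "
            f"outside [{lo:.4f}, {hi:.4f}]"
        )

    teacher = {"W": W, "b": b}
    prov = {"spec": asdict(spec)}
    out = [
        SyntheticDataset(X_src, y_src, teacher, {**prov, "role": "source"}),
        SyntheticDataset(X_tgt, y_tgt, teacher, {**prov, "role": "target"}),
    ]
    if n_target_eval > 0:
        r_eval = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(7,))
        )
        X_ev = (r_eval.random((n_target_eval, spec.n_bits))
                < p_tgt).astype(np.uint8)
        out.append(
            SyntheticDataset(X_ev, _draw(X_ev, W, b, r_eval), teacher,
                             {**prov, "role": "target_eval"})
        )
    return tuple(out)


def label_count_histogram(ds: SyntheticDataset) -> np.ndarray:
    """Counts of compounds by number of active targets (0..n_targets)."""
    counts = ds.labels.sum(axis=1)
    return np.bincount(counts, minlength=ds.labels.shape[1] + 1)


# ---------------------------------------------------------------------------
# hand-written curation fixture
# ---------------------------------------------------------------------------

def toy_curation_fixture():
    """A 23-record activity table with its hand-derived curated output.

    Exercises every curation rule: measurement averaging ([500, 2000] ->
    1250 -> inactive), the strict 1000 nM boundary (1000 -> inactive, 999 ->
    active), the element filter (selenium), conflicting duplicates (both
    removed), agreeing duplicates (merged), fixpoint pruning (an inactive-
    only target takes its only compound with it), the natural-product
    partition, and the >=10-active high-frequency target filter with a
    retained all-zero row.

    Returns (records DataFrame, natural-product SMILES list, expected dict)
    with expected rows keyed by canonical SMILES over expected['targets'].
    """
    rows = [
        # 10 natural products active on TA: exercise the min_active=10 bar
        *[(f"np{i:02d}", smi, "TA", "IC50", 500.0) for i, smi in enumerate(
            ["C", "CC", "CCC", "CCCC", "CCCCC",
             "CCO", "CCCO", "CCN", "CCCN", "CCCCN"], start=1)],
        # natural product active only on a low-frequency target
        ("np11", "OCCO", "TC", "Ki", 200.0),
        # two assays average to 1250 nM -> inactive -> row pruned
        ("ch01", "c1ccccc1", "TA", "IC50", 500.0),
        ("ch01", "c1ccccc1", "TA", "EC50", 2000.0),
        # exactly 1000 nM is inactive (strict threshold) -> row pruned
        ("ch02", "CCCl", "TA", "IC50", 1000.0),
        # 999 nM is active
        ("ch03", "CCBr", "TB", "IC50", 999.0),
        # disallowed element (Se)
        ("ch04", "CC[Se]CC", "TB", "IC50", 100.0),
        # same canonical structure, different active sets -> both removed
        ("ch05", "CC(=O)[O-].[Na+]", "TA", "IC50", 500.0),
        ("ch06", "CC(=O)O", "TB", "IC50", 500.0),
        # same canonical structure, same active set -> merged
        ("ch07", "OCCCC", "TA", "IC50", 100.0),
        ("ch08", "CCCCO", "TA", "IC50", 200.0),
        # stereocenter erased during sanitization
        ("ch09", "C[C@H](N)C(=O)O", "TA", "Kd", 50.0),
        ("ch09", "C[C@H](N)C(=O)O", "TB", "Ki", 300.0),
        # target TD has no actives: column pruned, then this row pruned
        ("ch10", "CCCCCC", "TD", "IC50", 5000.0),
    ]
    records = pd.DataFrame(
        rows, columns=["compound_id", "smiles", "target_id",
                       "activity_type", "value_nM"]
    )
    np_structures = ["C", "CC", "CCC", "CCCC", "CCCCC",
                     "CCO", "CCCO", "CCN", "CCCN", "CCCCN", "OCCO"]
    expected = {
        "targets": ["TA"],
        "np_rows": {smi: [1] for smi in np_structures[:10]} | {"OCCO": [0]},
        "pretrain_rows": {"CCBr": [0], "CCCCO": [1], "CC(N)C(=O)O": [1]},
        "report": {
            "input_records": 23,
            "invalid_records": 0,
            "unparsable_records": 0,
            "element_filter_records": 1,
            "surviving_records": 22,
            "conflict_structures_removed": 1,
            "pruned_rows": 3,
            "pruned_targets": 1,
        },
    }
    return records, np_structures, expected


# ---------------------------------------------------------------------------
# synthetic experiment designs
# ---------------------------------------------------------------------------

def _experiment_sizes(spec: SyntheticSpec) -> tuple:
    return (spec.n_bits, 128, 96, 64)


def run_transfer_experiment(
    n_seeds: int = 10,
    base_seed: int = 0,
    spec: SyntheticSpec | None = None,
    pretrain_config: PretrainConfig | None = None,
    pretrain_opt: OptimizerConfig | None = None,
    finetune_config: FinetuneConfig | None = None,
    finetune_opt: OptimizerConfig | None = None,
    n_eval: int = 2000,
) -> dict:
    """Does fine-tuning beat the pre-trained model under covariate shift?

    Per seed: generate (source, target), pre-train on source, fine-tune on
    the target set (90:10 split inside), and compare micro AUROC of the two
    models on an independent ``n_eval``-row sample from the target
    distribution (low-variance measurement of the same quantity as the
    small hold-out).  Returns per-seed scores and the win count.  Training
    sizes are scaled to desk scale (2 folds, short epoch cap, narrow
    capsules); the protocol — early stopping, freeze set, 100 fine-tune
    epochs, Adam settings — is the full one.
    """
    spec = spec if spec is not None else SyntheticSpec()
    p_cfg = pretrain_config or PretrainConfig(
        folds=2, epoch_cap=30, layer_sizes=_experiment_sizes(spec)
    )
    p_opt = pretrain_opt or OptimizerConfig(learning_rate=5e-3, batch_size=256)
    f_cfg = finetune_config or FinetuneConfig()
    f_opt = finetune_opt or OptimizerConfig(learning_rate=5e-3, batch_size=128)

    rows = []
    for i in range(n_seeds):
        seed = int((base_seed + 1000003 * i) % (2**31 - 1))
        source, target, target_eval = generate(
            replace(spec, seed=seed), n_target_eval=n_eval
        )
        pre, _ = pretrain(source.labels, source.fingerprints, p_cfg, p_opt,
                          seed=seed)
        tuned, _ = finetune(pre, target.labels, target.fingerprints,
                            f_cfg, f_opt, seed=seed)
        Xv = target_eval.fingerprints.astype(np.float64)
        Yv = target_eval.labels
        rows.append({
            "seed": seed,
            "pretrained_auroc": micro_auroc(predict_proba(pre, Xv), Yv),
            "finetuned_auroc": micro_auroc(predict_proba(tuned, Xv), Yv),
        })
    wins = sum(r["finetuned_auroc"] > r["pretrained_auroc"] for r in rows)
    return {"per_seed": rows, "wins": wins, "n_seeds": n_seeds}


def run_balance_experiment(
    n_seeds: int = 10,
    base_seed: int = 0,
    spec: SyntheticSpec | None = None,
    pretrain_config: PretrainConfig | None = None,
    opt: OptimizerConfig | None = None,
    cutoff: float = 0.5,
) -> dict:
    """Does cost weighting raise sensitivity on imbalanced data?

    Per seed: generate a source set, hold out 20%, train two otherwise
    identical models — with and without the selectivity cost weights — and
    compare sensitivity at the cutoff on the hold-out.
    """
    spec = spec if spec is not None else SyntheticSpec()
    base_cfg = pretrain_config or PretrainConfig(
        folds=2, epoch_cap=25, layer_sizes=_experiment_sizes(spec)
    )
    opt = opt or OptimizerConfig(learning_rate=5e-3, batch_size=256)

    rows = []
    for i in range(n_seeds):
        seed = int((base_seed + 2000003 * i) % (2**31 - 1))
        source, _ = generate(replace(spec, seed=seed))
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(source.labels))
        n_test = len(order) // 5
        test, tr = order[:n_test], order[n_test:]
        Xt, Yt = source.fingerprints[test], source.labels[test]

        result = {"seed": seed}
        for name, weighted in (("weighted", True), ("unweighted", False)):
            cfg = replace(base_cfg, use_cost_weights=weighted)
            params, _ = pretrain(source.labels[tr], source.fingerprints[tr],
                                 cfg, opt, seed=seed)
            cc = confusion_at_cutoff(predict_proba(params, Xt), Yt,
                                     cutoff=cutoff)
            result[f"se_{name}"] = compute_metrics(cc).SE
        rows.append(result)
    wins = sum(
        (r["se_weighted"] or 0.0) > (r["se_unweighted"] or 0.0) for r in rows
    )
    return {"per_seed": rows, "wins": wins, "n_seeds": n_seeds,
            "cutoff": cutoff}
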