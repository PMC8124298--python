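"""Three-capsule multitask MLP with batch normalization, in NumPy.

The network maps a folded binary fingerprint through three "capsules"
(linear -> batch norm -> leaky ReLU) into an embedding, then through a
linear classifier head whose sigmoid outputs are per-target activity
probabilities.  The last capsule's activation is the embedding space
(default 1024-dimensional); the head has one output per target (default
229 high-frequency natural-product targets).

Everything is explicit arrays so the fine-tuning freeze contract can be
stated exactly: capsule linear weights/biases are one parameter set, batch
norm affine parameters plus classifier weights/biases another, and batch
norm running statistics a third.

Batch norm follows the usual convention: training mode normalizes with
batch statistics (biased variance) and updates running statistics with
momentum 0.1 (running variance uses the unbiased estimate); eval mode uses
running statistics, making the forward map a pure function of (parameters,
input).  Leaky ReLU negative slope is 0.01; batch-norm epsilon 1e-5.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_LAYER_SIZES = (2048, 2048, 1536, 1024)
DEFAULT_N_TARGETS = 229
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
LEAKY_SLOPE = 0.01


@dataclass
class CapsuleParams:
    """One capsule block: linear + batch norm (affine + running stats)."""

    W: np.ndarray  # (out, in)
    b: np.ndarray  # (out,)
    gamma: np.ndarray  # (out,)
    beta: np.ndarray  # (out,)
    running_mean: np.ndarray  # (out,)
    running_var: np.ndarray  # (out,)

    def copy(self) -> "CapsuleParams":
        return CapsuleParams(*(a.copy() for a in self.arrays()))

    def arrays(self):
        return (self.W, self.b, self.gamma, self.beta,
                self.running_mean, self.running_var)


@dataclass
class ModelParameters:
    """Full parameter set: three capsules plus the classifier head."""

    capsules: list  # list[CapsuleParams], length 3
    clf_W: np.ndarray  # (n_targets, embed_size)
    clf_b: np.ndarray  # (n_targets,)
    meta: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.capsules[0].W.shape[1]

    @property
    def embed_size(self) -> int:
        return self.capsules[-1].W.shape[0]

    @property
    def n_targets(self) -> int:
        return self.clf_W.shape[0]

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            [c.copy() for c in self.capsules],
            self.clf_W.copy(),
            self.clf_b.copy(),
            dict(self.meta),
        )

    def capsule_linear_arrays(self):
        """The parameter set frozen during fine-tuning."""
        return [a for c in self.capsules for a in (c.W, c.b)]

    def adaptable_arrays(self):
        """Batch-norm affine + classifier: trainable during fine-tuning."""
        return [a for c in self.capsules for a in (c.gamma, c.beta)] + [
            self.clf_W, self.clf_b,
        ]


def init_parameters(
    layer_sizes=DEFAULT_LAYER_SIZES,
    n_targets: int = DEFAULT_N_TARGETS,
    rng: np.random.Generator | None = None,
) -> ModelParameters:
    """Fan-in-scaled uniform init; batch norm starts as the identity map."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(layer_sizes) != 4:
        raise ValueError("layer_sizes must be (input, h1, h2, embed)")
    capsules = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        capsules.append(
            CapsuleParams(
                W=rng.uniform(-bound, bound, size=(fan_out, fan_in)),
                b=rng.uniform(-bound, bound, size=fan_out),
                gamma=np.ones(fan_out),
                beta=np.zeros(fan_out),
                running_mean=np.zeros(fan_out),
                running_var=np.ones(fan_out),
            )
        )
    bound = 1.0 / np.sqrt(layer_sizes[-1])
    return ModelParameters(
        capsules,
        clf_W=rng.uniform(-bound, bound, size=(n_targets, layer_sizes[-1])),
        clf_b=rng.uniform(-bound, bound, size=n_targets),
        meta={"layer_sizes": list(layer_sizes), "n_targets": n_targets},
    )


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, LEAKY_SLOPE * x)


def forward_batch(
    params: ModelParameters,
    X: np.ndarray,
    mode: str = "eval",
    update_running_stats: bool = True,
):
    """Batched forward pass.

    Returns (logits, embedding, cache).  ``mode='train'`` normalizes with
    batch statistics and (by default) updates the running statistics in
    place; ``mode='eval'`` uses running statistics and mutates nothing.
    The cache holds intermediates for backpropagation.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.n_inputs:
        raise ValueError(
            f"input shape {X.shape} incompatible with {params.n_inputs} inputs"
        )
    cache = {"X": X, "capsules": []}
    h = X
    for cap in params.capsules:
        z = h @ cap.W.T + cap.b
        if mode == "train":
            mean = z.mean(axis=0)
            var = z.var(axis=0)  # biased, used for normalization
            if update_running_stats:
                n = z.shape[0]
                unbiased = var * n / max(n - 1, 1)
                cap.running_mean *= 1.0 - BN_MOMENTUM
                cap.running_mean += BN_MOMENTUM * mean
                cap.running_var *= 1.0 - BN_MOMENTUM
                cap.running_var += BN_MOMENTUM * unbiased
        else:
            mean = cap.running_mean
            var = cap.running_var
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        z_hat = (z - mean) * inv_std
        y = cap.gamma * z_hat + cap.beta
        a = _leaky_relu(y)
        cache["capsules"].append(
            {"h_in": h, "z": z, "z_hat": z_hat, "inv_std": inv_std, "y": y}
        )
        h = a
    logits = h @ params.clf_W.T + params.clf_b
    cache["embedding"] = h
    return logits, h, cache


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(params: ModelParameters, fp: np.ndarray, mode: str = "eval") -> np.ndarray:
    """Per-target activity probabilities for one fingerprint.

    In eval mode this is deterministic; probabilities lie strictly in (0,1).
    """
    logits, _, _ = forward_batch(params, np.atleast_2d(fp), mode=mode)
    return sigmoid(logits[0])


def predict_proba(params: ModelParameters, X: np.ndarray) -> np.ndarray:
    """Eval-mode probabilities for a batch of fingerprints."""
    logits, _, _ = forward_batch(params, X, mode="eval")
    return sigmoid(logits)


def extract_embedding(params: ModelParameters, fp: np.ndarray) -> np.ndarray:
    """Activation after the third capsule (eval mode) for one fingerprint."""
    _, emb, _ = forward_batch(params, np.atleast_2d(fp), mode="eval")
    return emb[0]


def extract_embeddings(params: ModelParameters, X: np.ndarray) -> np.ndarray:
    _, emb, _ = forward_batch(params, X, mode="eval")
    return emb


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def backward_batch(params: ModelParameters, cache: dict, dlogits: np.ndarray) -> dict:
    """Gradients of a scalar loss given d(loss)/d(logits).

    Returns a dict with keys 'capsules' (list of per-capsule dicts with dW,
    db, dgamma, dbeta) and 'clf_W', 'clf_b'.  Batch-norm backward uses the
    train-mode (batch statistics) graph.
    """
    emb = cache["embedding"]
    grads = {
        "clf_W": dlogits.T @ emb,
        "clf_b": dlogits.sum(axis=0),
        "capsules": [None] * len(params.capsules),
    }
    da = dlogits @ params.clf_W
    for i in range(len(params.capsules) - 1, -1, -1):
        cap = params.capsules[i]
        c = cache["capsules"][i]
        dy = da * np.where(c["y"] >= 0, 1.0, LEAKY_SLOPE)
        dgamma = (dy * c["z_hat"]).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dz_hat = dy * cap.gamma
        n = dz_hat.shape[0]
        # batch-norm backward (batch statistics)
        dz = (c["inv_std"] / n) * (
            n * dz_hat
            - dz_hat.sum(axis=0)
            - c["z_hat"] * (dz_hat * c["z_hat"]).sum(axis=0)
        )
        grads["capsules"][i] = {
            "dW": dz.T @ c["h_in"],
            "db": dz.sum(axis=0),
            "dgamma": dgamma,
            "dbeta": dbeta,
        }
        da = dz @ cap.W
    return grads


# ---------------------------------------------------------------------------
# prediction post-processing
# ---------------------------------------------------------------------------

def predict_targets(probabilities: np.ndarray, cutoff: float = 0.5) -> set:
    """Indexes with probability strictly above the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return set(np.flatnonzero(np.asarray(probabilities) > cutoff).tolist())


def top_k_targets(probabilities: np.ndarray, k: int) -> list:
    """Top-k target indexes by descending probability; ties -> lower index."""
    p = np.asarray(probabilities)
    if not 1 <= k <= p.size:
        raise ValueError(f"k={k} out of range 1..{p.size}")
    order = np.argsort(-p, kind="stable")  # stable: ties keep ascending index
    return order[:k].tolist()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: ModelParameters, path) -> None:
    """Single-archive checkpoint: all arrays plus a JSON header."""
    arrays = {"clf_W": params.clf_W, "clf_b": params.clf_b}
    for i, cap in enumerate(params.capsules):
        for name, arr in zip(
            ("W", "b", "gamma", "beta", "running_mean", "running_var"),
            cap.arrays(),
        ):
            arrays[f"capsule{i}_{name}"] = arr
    header = dict(params.meta)
    header.setdefault("layer_sizes",
                      [params.n_inputs] + [c.W.shape[0] for c in params.capsules])
    header.setdefault("n_targets", params.n_targets)
    arrays["header_json"] = np.frombuffer(
        json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with io.BytesIO() as buf:  # write via buffer so the file is atomic-ish
        np.savez(buf, **arrays)
        path.write_bytes(buf.getvalue())


def load_checkpoint(path) -> ModelParameters:
    with np.load(path) as data:
        header = json.loads(bytes(data["header_json"]).decode())
        capsules = []
        i = 0
        while f"capsule{i}_W" in data:
            capsules.append(
                CapsuleParams(
                    *(data[f"capsule{i}_{n}"]
                      for n in ("W", "b", "gamma", "beta",
                                "running_mean", "running_var"))
                )
            )
            i += 1
        return ModelParameters(capsules, data["clf_W"], data["clf_b"], header)
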