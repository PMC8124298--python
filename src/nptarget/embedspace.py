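"""Embedding-space analysis: variance-thresholded PCA then 2-D t-SNE.

The 1024-dimensional embeddings (last-capsule activations) of a 2% sample
of each dataset are first projected onto the smallest number of principal
components whose cumulative explained-variance ratio reaches 0.9, then
compressed to two dimensions with t-SNE (1000 iterations).  A nearest-
neighbor overlap statistic quantifies how much two tagged point clouds
share the projected space; it is an artifact-added numeric proxy for what
is otherwise a visual judgement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


@dataclass
class EmbeddingMatrix:
    """Embedding rows with a dataset tag per row (e.g. pretrain / np)."""

    values: np.ndarray  # (n, embed_size)
    tags: np.ndarray  # (n,) strings

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.tags = np.asarray(self.tags)
        if self.values.ndim != 2 or len(self.tags) != len(self.values):
            raise ValueError("values must be 2-D with one tag per row")


@dataclass
class Projection2D:
    coordinates: np.ndarray  # (n, 2)
    tags: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.coordinates[:, 0], "y": self.coordinates[:, 1],
             "tag": self.tags}
        )


def sample_fraction(
    matrix: EmbeddingMatrix, fraction: float = 0.02, seed: int = 0
) -> EmbeddingMatrix:
    """Uniform sample without replacement, ceil(fraction * n) per tag."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = []
    for tag in pd.unique(matrix.tags):
        idx = np.flatnonzero(matrix.tags == tag)
        k = math.ceil(fraction * len(idx))
        keep.append(rng.choice(idx, size=k, replace=False))
    keep = np.sort(np.concatenate(keep))
    return EmbeddingMatrix(matrix.values[keep], matrix.tags[keep])


def pca_to_variance(values: np.ndarray, threshold: float = 0.9):
    """Project onto the fewest components reaching the variance threshold.

    Centering only (no per-dimension standardization).  Returns
    (projected data of shape (n, k), k).
    """
    values = np.asarray(values, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(values) < 2:
        raise ValueError("need at least two rows")
    if np.allclose(values.var(axis=0), 0.0):
        raise ValueError("zero-variance data: no components to keep")
    pca = PCA(n_components=min(values.shape), svd_solver="full")
    projected = pca.fit_transform(values)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    return projected[:, :k], k


def tsne_2d(
    reduced: np.ndarray,
    iterations: int = 1000,
    seed: int = 0,
    perplexity: float = 30.0,
    tags=None,
) -> Projection2D:
    """2-D t-SNE with random (seeded) initialization.

    Requires more rows than the perplexity; reproducible for a fixed seed
    and pinned scikit-learn version.
    """
    reduced = np.asarray(reduced, dtype=float)
    if len(reduced) < perplexity + 1:
        raise ValueError(
            f"need more than perplexity+1={perplexity + 1:.0f} rows, "
            f"got {len(reduced)}"
        )
    coords = TSNE(
        n_components=2,
        max_iter=iterations,
        random_state=seed,
        perplexity=perplexity,
        init="random",
    ).fit_transform(reduced)
    if tags is None:
        tags = np.array(["all"] * len(reduced))
    return Projection2D(np.asarray(coords, dtype=float), np.asarray(tags))


def coverage_overlap(proj: Projection2D) -> dict:
    """Nearest-neighbor tag mixing per ordered tag pair.

    For tags (a, b): among points tagged a, the fraction whose nearest
    neighbor within the union of a- and b-points (self excluded, 2-D
    Euclidean) is tagged b.  Identical clouds give ~0.5; disjoint clouds 0.
    Pairs involving a singleton tag report None.
    """
    tags = pd.unique(proj.tags)
    if len(tags) < 2:
        raise ValueError("need at least two tags")
    out = {}
    for a in tags:
        for b in tags:
            if a == b:
                continue
            mask = (proj.tags == a) | (proj.tags == b)
            pts = proj.coordinates[mask]
            sub_tags = proj.tags[mask]
            if (sub_tags == a).sum() < 2 or (sub_tags == b).sum() < 1:
                out[(a, b)] = None
                continue
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            nn_tag = sub_tags[np.argmin(d2, axis=1)]
            a_rows = sub_tags == a
            out[(a, b)] = float(np.mean(nn_tag[a_rows] == b))
    return out
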