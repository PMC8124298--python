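"""Cost-sensitive loss weights for imbalanced multitask activity labels.

Most compounds are active on at most a couple of targets, so active cells
are rare.  Each compound's loss weights are set from its own label vector:
inactive positions get weight 1, and each active position gets N_i / N_a,
the ratio of the compound's inactive-target count to its active-target
count.  A compound with no active labels at all gets all-ones weights.
The more selective a compound (fewer actives), the larger the weight on
each active cell; across one row the active weights always sum to N_i.
"""

from __future__ import annotations

import warnings

import numpy as np

from .curation import LabelMatrix


def build_cost_vector(label: np.ndarray) -> np.ndarray:
    """Per-target loss weights for one compound's binary label vector."""
    label = np.asarray(label)
    if label.ndim != 1:
        raise ValueError("label must be a 1-D vector")
    if not np.isin(label, (0, 1)).all():
        raise ValueError("label entries must be 0 or 1")
    n_active = int(label.sum())
    cost = np.ones(label.shape[0], dtype=np.float64)
    if n_active == 0:
        return cost
    n_inactive = label.shape[0] - n_active
    if n_inactive == 0:
        warnings.warn(
            "compound active on every target: active costs are 0 "
            "(cannot occur after curation)",
            stacklevel=2,
        )
    cost[label == 1] = n_inactive / n_active
    return cost


def build_cost_matrix(matrix) -> np.ndarray:
    """Row-wise cost weights aligned to a label matrix.

    Accepts a LabelMatrix or a bare binary array; weights depend only on
    each compound's own row, so they are identical across training splits.
    """
    labels = matrix.labels if isinstance(matrix, LabelMatrix) else np.asarray(matrix)
    if labels.ndim != 2:
        raise ValueError("labels must be 2-D")
    return np.vstack([build_cost_vector(row) for row in labels]) if len(labels) \
        else np.ones_like(labels, dtype=np.float64)
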