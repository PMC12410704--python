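"""Independent brute-force oracles shared across tests.

These deliberately avoid the package's own fast implementations: AUC and the
DeLong structural components are computed by explicit enumeration over all
(positive, negative) pairs.
"""

from __future__ import annotations

import numpy as np


def psi_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """psi(x, y) for every (positive, negative) pair: 1 / 0.5 / 0."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return (pos > neg).astype(float) + 0.5 * (pos == neg)


def split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    return scores[labels], scores[~labels]


def brute_auc(scores, labels) -> float:
    pos, neg = split(scores, labels)
    return float(psi_matrix(pos, neg).mean())


def brute_components(scores, labels):
    """Per-positive and per-negative mean psi values (V10, V01)."""
    pos, neg = split(scores, labels)
    m = psi_matrix(pos, neg)
    return m.mean(axis=1), m.mean(axis=0)


def brute_delong_variance(scores, labels) -> float:
    v10, v01 = brute_components(scores, labels)
    s10 = np.var(v10, ddof=1) if len(v10) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(v10) + s01 / len(v01))
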