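"""Rasch partial credit model (PCM) mathematics.

For an item with effective category thresholds ``delta_i1..delta_iK`` the
probability of a person at ability ``theta`` scoring category ``k`` is

    P(X = k | theta) = exp( sum_{j<=k} (theta - delta_ij) ) / G,

where the empty sum for ``k = 0`` is zero and ``G`` normalises over the
``K + 1`` categories.  Expected score and item information (= conditional
response variance, which equals the derivative of the expected score in
theta) follow directly.  All items share unit discrimination.

Computations use log-sum-exp stabilisation and are safe for |theta| up to
at least 40 logits.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .item_bank import ItemParameters

__all__ = [
    "category_probabilities",
    "expected_score",
    "item_information",
    "sample_response",
]


def _cumulative_logits(theta: float, item: ItemParameters) -> np.ndarray:
    """Log-numerators c_k = sum_{j<=k}(theta - delta_ij), c_0 = 0."""
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    steps = theta - item.category_thresholds
    return np.concatenate(([0.0], np.cumsum(steps)))


def category_probabilities(theta: float, item: ItemParameters) -> np.ndarray:
    """PCM category probabilities P(X=k | theta) for k = 0..K.

    Returns a vector of length ``item.n_categories`` summing to 1.
    """
    return softmax(_cumulative_logits(theta, item))


def expected_score(theta: float, item: ItemParameters) -> float:
    """Model-expected score E[X | theta] = sum_k k * P(k); in (0, K)."""
    p = category_probabilities(theta, item)
    return float(np.arange(len(p)) @ p)


def item_information(theta: float, item: ItemParameters) -> float:
    """Item information at ``theta``: Var(X | theta) = E[X^2] - E[X]^2.

    Equals the first derivative of :func:`expected_score` with respect to
    theta, and is strictly positive for finite theta.
    """
    p = category_probabilities(theta, item)
    k = np.arange(len(p))
    mean = k @ p
    return float(k**2 @ p - mean**2)


def sample_response(
    theta: float, item: ItemParameters, rng: np.random.Generator
) -> int:
    """Draw one response category from the PCM at ``theta``.

    The caller supplies the seeded generator; no global state is touched.
    """
    p = category_probabilities(theta, item)
    return int(rng.choice(len(p), p=p))


def category_probability_matrix(thetas: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Vectorised :func:`category_probabilities`: rows = abilities.

    Returns an ``(n, K+1)`` matrix of category probabilities.
    """
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise ValueError("thetas must be finite")
    steps = thetas[:, None] - item.category_thresholds[None, :]
    cum = np.concatenate([np.zeros((len(thetas), 1)), np.cumsum(steps, axis=1)], axis=1)
    return softmax(cum, axis=1)


def sample_responses(
    thetas: np.ndarray, item: ItemParameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw one response per ability by inverse-CDF sampling (vectorised)."""
    p = category_probability_matrix(thetas, item)
    cdf = np.cumsum(p, axis=1)
    u = rng.random(len(cdf))
    return (u[:, None] > cdf[:, :-1]).sum(axis=1).astype(np.int64)
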