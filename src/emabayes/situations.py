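"""Categorical model of situation occupancy.

Each participant has an unknown probability vector over the K joint
situation categories in each test phase; records within a phase are
exchangeable, so the per-phase category counts are multinomial.  The model
parameterizes the T x K probability array by unconstrained logits through
a row-wise softmax (K logits per phase; the one redundant coordinate per
row is regularized by the population prior rather than removed).
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_softmax, softmax

from .frame import EmaDataset, EmaFrame

__all__ = [
    "situation_probs",
    "situation_logits",
    "counts_from_dataset",
    "situation_log_likelihood",
    "situation_loglik_grad",
    "conjugate_posterior_check",
]


def situation_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax: T x K logits -> T x K simplex rows."""
    return softmax(np.asarray(logits, dtype=float), axis=-1)


def situation_logits(u: np.ndarray) -> np.ndarray:
    """Centered log transform; right inverse of :func:`situation_probs`."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("logit parameterization needs strictly positive probabilities")
    lg = np.log(u)
    return lg - lg.mean(axis=-1, keepdims=True)


def counts_from_dataset(dataset: EmaDataset, frame: EmaFrame | None = None) -> dict[str, np.ndarray]:
    """Tabulate per-participant T x K situation counts.

    Cell index is row-major over the declared dimension order; the counts
    of each participant sum to that participant's record count.
    """
    frame = frame or dataset.frame
    T, K = frame.n_phases, frame.n_cells
    out: dict[str, np.ndarray] = {}
    for pid in dataset.participants:
        counts = np.zeros((T, K), dtype=np.int64)
        for rec in dataset.records_of(pid):
            t = frame.phase_index(rec.phase)
            k = frame.cell_index(rec.situation)
            counts[t, k] += 1
        out[pid] = counts
    return out


def situation_log_likelihood(counts: np.ndarray, u: np.ndarray) -> float:
    """Multinomial log-likelihood ``sum_tk counts[t,k] * log u[t,k]``.

    The combinatorial constant is omitted (it does not depend on u).
    Returns ``-inf`` when a positive count sits on a zero probability.
    """
    counts = np.asarray(counts, dtype=float)
    u = np.asarray(u, dtype=float)
    if counts.shape != u.shape:
        raise ValueError(f"shape mismatch: counts {counts.shape} vs u {u.shape}")
    with np.errstate(divide="ignore"):
        lg = np.log(u)
    bad = (counts > 0) & (u == 0)
    if np.any(bad):
        return float("-inf")
    return float(np.sum(np.where(counts > 0, counts * lg, 0.0)))


def situation_loglik_grad(counts, logits):
    """Multinomial log-likelihood in logit parameterization, with gradient.

    Vectorized over leading axes of ``logits``; ``counts`` broadcasts.
    Gradient per row is ``counts - R_t * softmax(logits)``.
    """
    counts = np.asarray(counts, dtype=float)
    logits = np.asarray(logits, dtype=float)
    logu = log_softmax(logits, axis=-1)
    loglik = np.sum(counts * logu, axis=(-2, -1))
    row_tot = counts.sum(axis=-1, keepdims=True)
    grad = counts - row_tot * np.exp(logu)
    return loglik, grad


def conjugate_posterior_check(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial posterior mean, ``(alpha + counts) / sum``.

    Closed-form oracle for the categorical block: with a Dirichlet(alpha)
    prior on each phase's probability vector and multinomial counts, the
    posterior mean is available exactly.  Used to validate sampled
    single-participant inference on small cases.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("concentration parameters must be positive")
    post = alpha + counts
    return np.squeeze(post / post.sum(axis=-1, keepdims=True))
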