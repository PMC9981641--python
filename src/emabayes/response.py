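"""Graded-response (cumulative) ordinal model.

Each ordinal rating of attribute *i* is generated by a continuous latent
variable with a standard logistic distribution located at the latent
attribute value ``theta``; the l-th response is observed when the latent
draw falls between consecutive response thresholds
``tau_{l-1} < Y <= tau_l``, with sentinels ``tau_0 = -inf`` and
``tau_L = +inf``.  Thresholds are participant- and attribute-specific but
shared across situations.

The latent scale is identified only up to a common shift of ``theta`` and
all thresholds; the restriction modes are

``"median-zero"``
    the median interior threshold is forced to zero (default), or
``"zero-mean-attribute"``
    the mean latent attribute value over cells is forced to zero.

Thresholds are parameterized by ``L`` unconstrained reals per attribute:
an overall location plus ``L - 1`` log-widths mapped through a softplus,
cumulated into a strictly increasing interior sequence.  Under
``median-zero`` the location coordinate is redundant (it cancels in the
median shift); that surplus degree of freedom is regularized by the
population prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ThresholdSet",
    "thresholds_from_raw",
    "response_prob",
    "ordinal_logpmf",
    "ordinal_loglik_grad",
    "shift_identifiability",
    "attribute_log_likelihood",
    "MIN_GAP",
]

#: minimum gap between consecutive thresholds, to avoid numerically fused
#: thresholds producing zero-probability categories
MIN_GAP = 1e-8

_MODES = ("median-zero", "zero-mean-attribute", "free")


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _log_logistic_cdf(x):
    """log F(x) for the standard logistic CDF, stable for large |x|."""
    return -_softplus(-x)


def _log1mexp(u):
    """log(1 - exp(u)) for u < 0, stable near both ends."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u > -np.log(2.0)
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(u[small]))
        out[~small] = np.log1p(-np.exp(u[~small]))
    return out


@dataclass(frozen=True)
class ThresholdSet:
    """Interior response thresholds of one attribute for one participant."""

    raw: np.ndarray  # L unconstrained parameters
    interior: np.ndarray  # L-1 strictly increasing thresholds
    mode: str = "median-zero"
    attribute: str | None = None

    @property
    def n_levels(self) -> int:
        return len(self.raw)


def raw_to_interior(raw: np.ndarray, mode: str = "median-zero") -> np.ndarray:
    """Map L unconstrained reals to L-1 strictly increasing thresholds.

    Vectorized over leading axes of ``raw``; the last axis holds the
    parameters (location, then L-1 log-widths).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] < 2:
        raise ValueError("need at least 2 raw parameters (>= 2 response levels)")
    if mode not in _MODES:
        raise ValueError(f"unknown identifiability mode {mode!r}")
    widths = _softplus(raw[..., 1:]) + MIN_GAP
    interior = raw[..., :1] + np.cumsum(widths, axis=-1)
    if mode == "median-zero":
        interior = interior - np.median(interior, axis=-1, keepdims=True)
    return interior


def raw_to_interior_vjp(raw: np.ndarray, dtau: np.ndarray, mode: str = "median-zero") -> np.ndarray:
    """Pull a gradient w.r.t. interior thresholds back to the raw parameters."""
    raw = np.asarray(raw, dtype=float)
    dtau = np.asarray(dtau, dtype=float)
    if mode == "median-zero":
        # tau = tau0 - sum_i m_i tau0_i  with m the median-averaging weights
        n = raw.shape[-1] - 1
        m = np.zeros(n)
        if n % 2:
            m[n // 2] = 1.0
        else:
            m[n // 2 - 1 : n // 2 + 1] = 0.5
        dtau0 = dtau - m * np.sum(dtau, axis=-1, keepdims=True)
    else:
        dtau0 = dtau
    # reverse cumulative sum: d/d width_j picks up every tau0_l with l >= j
    rev = np.cumsum(dtau0[..., ::-1], axis=-1)[..., ::-1]
    draw = np.empty_like(raw)
    draw[..., 0] = np.sum(dtau0, axis=-1)
    draw[..., 1:] = expit(raw[..., 1:]) * rev
    return draw


def thresholds_from_raw(
    raw: np.ndarray, mode: str = "median-zero", attribute: str | None = None
) -> ThresholdSet:
    """Construct a :class:`ThresholdSet` from unconstrained parameters."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("thresholds_from_raw expects a 1-D raw vector")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw threshold parameters must be finite")
    return ThresholdSet(raw=raw, interior=raw_to_interior(raw, mode), mode=mode, attribute=attribute)


def ordinal_logpmf(theta, interior):
    """Log response probabilities of the cumulative logistic model.

    Parameters
    ----------
    theta : array, shape (...,)
        Latent attribute locations.
    interior : array, shape (..., L-1) or (L-1,)
        Strictly increasing interior thresholds (broadcast against theta).

    Returns
    -------
    array, shape (..., L)
        ``log P(l) = log[F(tau_l - theta) - F(tau_{l-1} - theta)]`` with F
        the standard logistic CDF, computed in log space so it survives
        locations out to ``|theta| ~ 700``.
    """
    theta = np.asarray(theta, dtype=float)
    interior = np.asarray(interior, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    x = interior - theta[..., None]  # (..., L-1)
    logF = _log_logistic_cdf(x)
    logFc = _log_logistic_cdf(-x)
    L = x.shape[-1] + 1
    out = np.empty(x.shape[:-1] + (L,))
    out[..., 0] = logF[..., 0]
    out[..., L - 1] = logFc[..., L - 2]
    if L > 2:
        # F(b)-F(a) = F(b) * (1-F(a)) * (1 - exp(a-b)),  a < b
        out[..., 1 : L - 1] = (
            logF[..., 1:] + logFc[..., :-1] + _log1mexp(x[..., :-1] - x[..., 1:])
        )
    return out


def response_prob(theta, tau: ThresholdSet | np.ndarray) -> np.ndarray:
    """Probability vector over the L ordinal response categories.

    ``tau`` may be a :class:`ThresholdSet` or a bare interior-threshold
    array.  Vectorized over leading axes of ``theta``.
    """
    interior = tau.interior if isinstance(tau, ThresholdSet) else np.asarray(tau, float)
    return np.exp(ordinal_logpmf(theta, interior))


def ordinal_loglik_grad(counts, theta, interior):
    """Log-likelihood of rating counts and its analytic gradient.

    Parameters
    ----------
    counts : array, shape (..., C, L)
        Per-cell rating counts (cells C are phase x situation combinations).
    theta : array, shape (..., C)
        Latent locations per cell.
    interior : array, shape (..., L-1)
        Interior thresholds (shared across cells).

    Returns
    -------
    loglik : array, shape (...,)
    dtheta : array, shape (..., C)
    dtau : array, shape (..., L-1)
        Gradient with respect to the interior thresholds.
    """
    counts = np.asarray(counts, dtype=float)
    theta = np.asarray(theta, dtype=float)
    interior = np.asarray(interior, dtype=float)
    x = interior[..., None, :] - theta[..., :, None]  # (..., C, L-1)
    logP = ordinal_logpmf(theta, interior[..., None, :])  # (..., C, L)
    loglik = np.sum(counts * logP, axis=(-2, -1))
    # logistic pdf at the thresholds: f = F * (1-F)
    log_f = _log_logistic_cdf(x) + _log_logistic_cdf(-x)  # (..., C, L-1)
    # ratio_up[l] = f(tau_l - theta)/P(l) for l < L-1 ; ratio_lo[l] = f(tau_{l-1}-theta)/P(l)
    ru = np.zeros_like(logP)
    rl = np.zeros_like(logP)
    ru[..., :-1] = np.exp(log_f - logP[..., :-1])
    rl[..., 1:] = np.exp(log_f - logP[..., 1:])
    dtheta = np.sum(counts * (rl - ru), axis=-1)
    dtau = counts[..., :-1] * ru[..., :-1] - counts[..., 1:] * rl[..., 1:]
    dtau = np.sum(dtau, axis=-2)
    return loglik, dtheta, dtau


def shift_identifiability(theta, tau: ThresholdSet, mode: str = "median-zero"):
    """Apply the common-shift restriction to (theta, thresholds).

    Adding one constant to all locations and all thresholds leaves every
    response probability unchanged; this picks the representative with
    either a zero median threshold or a zero mean location.
    """
    theta = np.asarray(theta, dtype=float)
    if mode == "median-zero":
        c = np.median(tau.interior)
    elif mode == "zero-mean-attribute":
        c = float(np.mean(theta))
    else:
        raise ValueError(f"unknown identifiability mode {mode!r}")
    shifted = ThresholdSet(
        raw=tau.raw, interior=tau.interior - c, mode=mode, attribute=tau.attribute
    )
    return theta - c, shifted


def attribute_log_likelihood(counts, theta, tau: ThresholdSet | np.ndarray) -> float:
    """Sum of log response probabilities over observed rating counts.

    ``counts[c, l]`` is the number of level-``l+1`` ratings given in cell
    ``c``; missing ratings simply never appear in the counts.  Zero counts
    contribute nothing, so an empty table returns 0.0.
    """
    interior = tau.interior if isinstance(tau, ThresholdSet) else np.asarray(tau, float)
    counts = np.asarray(counts, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if counts.sum() == 0:
        return 0.0
    logP = ordinal_logpmf(theta, interior[..., None, :])
    return float(np.sum(counts * logP))
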