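"""Vectorized Hamiltonian Monte Carlo.

A plain HMC sampler (leapfrog integrator, identity mass matrix,
dual-averaging step-size adaptation during warm-up) evaluated for many
independent walkers at once: the target callable receives a (W, D) array
of positions and returns per-walker log densities and gradients.  In the
variational loop the walkers are all (participant, chain) combinations,
each targeting its own participant posterior, so one leapfrog step costs
a single stacked likelihood evaluation.

Samples are kept every iteration after warm-up; acceptance and divergence
counts are recorded per walker.  All randomness flows through the
supplied generator, so a fixed seed reproduces the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HmcDiagnostics", "hmc_sample"]

#: energy error treated as a divergent trajectory
DIVERGENCE_ENERGY = 1000.0


@dataclass
class HmcDiagnostics:
    """Per-walker sampling diagnostics of one HMC run."""

    accept_rate: np.ndarray  # (W,), post-warmup mean acceptance probability
    divergences: np.ndarray  # (W,), post-warmup divergent-trajectory counts
    step_size: np.ndarray  # (W,), step sizes used after adaptation
    n_samples: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def all_diverged(self) -> bool:
        return self.n_samples > 0 and bool(np.all(self.divergences >= self.n_samples))


class SamplerError(RuntimeError):
    """Raised when sampling fails on all chains."""


def _leapfrog(logp_grad, x, p, eps, n_steps):
    """Vectorized leapfrog; eps has shape (W, 1)."""
    lp, g = logp_grad(x)
    p = p + 0.5 * eps * g
    for step in range(n_steps):
        x = x + eps * p
        lp, g = logp_grad(x)
        if step < n_steps - 1:
            p = p + eps * g
    p = p + 0.5 * eps * g
    return x, p, lp


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    n_leapfrog: int = 10,
    target_accept: float = 0.8,
    step_size0: np.ndarray | float = 0.1,
    adapt: bool = True,
):
    """Run vectorized HMC from ``x0`` (W, D).

    Parameters
    ----------
    logp_grad
        Callable ``X (W, D) -> (logp (W,), grad (W, D))``.
    n_warmup, n_samples
        Adaptation iterations (discarded) and kept iterations.
    rng
        Generator driving momenta and accept decisions.
    n_leapfrog
        Leapfrog steps per trajectory.
    step_size0
        Initial step size, scalar or per-walker.

    Returns
    -------
    samples : (n_samples, W, D)
    logps : (n_samples, W) log densities of the kept positions
    x_last : (W, D) final positions (for warm-starting)
    diagnostics : HmcDiagnostics
    """
    x = np.array(x0, dtype=float)
    W, D = x.shape
    eps = np.broadcast_to(np.asarray(step_size0, float), (W,)).copy()
    # dual averaging state (Nesterov-style), per walker
    mu = np.log(10.0 * eps)
    log_eps_bar = np.log(eps)
    h_bar = np.zeros(W)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    lp, _ = logp_grad(x)
    if not np.all(np.isfinite(lp)):
        raise SamplerError("non-finite log density at the initial positions")
    accept_sum = np.zeros(W)
    divergences = np.zeros(W, dtype=int)
    samples = np.empty((n_samples, W, D))
    logps = np.empty((n_samples, W))
    total = n_warmup + n_samples
    for it in range(total):
        warm = it < n_warmup
        p = rng.standard_normal((W, D))
        h0 = -lp + 0.5 * np.sum(p**2, axis=1)
        x_new, p_new, lp_new = _leapfrog(logp_grad, x, p, eps[:, None], n_leapfrog)
        h1 = -lp_new + 0.5 * np.sum(p_new**2, axis=1)
        delta = h0 - h1
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        diverged = delta < -DIVERGENCE_ENERGY
        p_accept = np.exp(np.minimum(delta, 0.0))
        p_accept = np.where(diverged, 0.0, p_accept)
        accept = rng.random(W) < p_accept
        x = np.where(accept[:, None], x_new, x)
        lp = np.where(accept, lp_new, lp)
        if warm:
            if adapt:
                t = it + 1
                eta = 1.0 / (t + t0)
                h_bar = (1 - eta) * h_bar + eta * (target_accept - p_accept)
                log_eps = mu - np.sqrt(t) / gamma * h_bar
                w = t**-kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = np.exp(log_eps)
                if it == n_warmup - 1:
                    eps = np.exp(log_eps_bar)  # freeze at the averaged step size
        else:
            accept_sum += p_accept
            divergences += diverged.astype(int)
            samples[it - n_warmup] = x
            logps[it - n_warmup] = lp
    diag = HmcDiagnostics(
        accept_rate=accept_sum / max(n_samples, 1),
        divergences=divergences,
        step_size=eps.copy(),
        n_samples=n_samples,
    )
    if diag.all_diverged:
        raise SamplerError(
            f"all {W} chains diverged on every kept iteration "
            f"(step sizes {eps.min():.2e}..{eps.max():.2e})"
        )
    return samples, logps, x, diag
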