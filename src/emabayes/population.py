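"""Bayesian Gaussian-mixture population model over individual parameters.

The individual parameter vectors ``xi`` of all participants in one group
are treated as draws from a Gaussian mixture with diagonal-covariance
components.  The mixture is itself given a conjugate Bayesian treatment:
Dirichlet posterior over the component weights and, per component and
coordinate, a normal-gamma posterior over (mean, precision).  The fitted
mixture acts as the prior for every participant's parameters and as the
generator for population-level predictions.  The Bayesian fit exhibits the
usual Occam behaviour: components not supported by the data keep only
their small symmetric prior weight.

Each participant contributes total responsibility weight 1 to the
variational update regardless of how many posterior samples represent
them or how many EMA records they provided, so every participant counts
equally in the population estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = [
    "GmmHyper",
    "PopulationGMM",
    "init_population",
    "update_population",
    "expected_log_pdf",
    "expected_log_pdf_grad",
    "sample_random_individual",
    "sample_population_mean",
]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GmmHyper:
    """Weakly informative hyperparameters of the population prior.

    ``prior_scale`` sets the typical prior coordinate scale (logit units;
    broad relative to the unit-scale logistic latent variable).  The
    gamma rate is derived as ``prec_shape * prior_scale**2`` so the prior
    mean precision is ``1 / prior_scale**2``.
    """

    weight_conc: float = 1.0  # total Dirichlet concentration, split over components
    mean_scale: float = 1e-2  # precision-scaling kappa_0 of the mean prior
    prec_shape: float = 0.5  # gamma shape a_0 of the coordinate precisions
    prior_scale: float = 10.0  # typical prior std of a coordinate, logit units

    def __post_init__(self):
        for name in ("weight_conc", "mean_scale", "prec_shape", "prior_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")

    @property
    def prec_rate(self) -> float:
        return self.prec_shape * self.prior_scale**2


@dataclass(frozen=True)
class PopulationGMM:
    """Variational posterior over a diagonal Gaussian mixture on xi-space.

    Fields are the conjugate posterior parameters: Dirichlet
    concentrations ``alpha`` (M,), mean-precision scalings ``kappa`` (M,),
    mean locations ``m`` (M, D) and per-coordinate gamma shape/rate
    ``a``/``b`` (M, D).
    """

    alpha: np.ndarray
    kappa: np.ndarray
    m: np.ndarray
    a: np.ndarray
    b: np.ndarray
    hyper: GmmHyper
    alpha0: np.ndarray | None = None  # prior concentration per component

    def __post_init__(self):
        if self.alpha0 is None:
            object.__setattr__(
                self, "alpha0",
                np.full(len(self.alpha), self.hyper.weight_conc / len(self.alpha)),
            )
        if np.any(self.alpha <= 0) or np.any(self.kappa <= 0):
            raise ValueError("concentrations and mean scalings must be positive")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("precision shape/rate must be positive")

    @property
    def n_components(self) -> int:
        return len(self.alpha)

    @property
    def dim(self) -> int:
        return self.m.shape[1]

    @property
    def expected_weights(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def expected_precision(self) -> np.ndarray:
        return self.a / self.b

    def active_components(self, min_weight: float = 0.01) -> np.ndarray:
        """Indices of components whose expected weight exceeds ``min_weight``."""
        return np.flatnonzero(self.expected_weights >= min_weight)

    @property
    def evidence(self) -> np.ndarray:
        """Accumulated responsibility mass per component (in participants)."""
        return self.alpha - self.alpha0

    def prune(self, min_evidence: float = 0.5) -> "PopulationGMM":
        """Drop components supported by less than ``min_evidence``
        participants' worth of responsibility mass.

        Empty components carry only their symmetric prior share of the
        weight, and their mean posterior is essentially the (very broad)
        prior — keeping them would leak prior-scale dispersion into
        population-level predictions.  At least one component is always
        kept.  The criterion is the data evidence rather than the expected
        weight because the prior weight share does not vanish for small
        participant counts.
        """
        keep = np.flatnonzero(self.evidence >= min_evidence)
        if len(keep) == 0:
            keep = np.array([int(np.argmax(self.alpha))])
        if len(keep) == self.n_components:
            return self
        log.info(
            "pruning %d of %d mixture components (evidence < %g participants)",
            self.n_components - len(keep), self.n_components, min_evidence,
        )
        return replace(
            self, alpha=self.alpha[keep], kappa=self.kappa[keep],
            m=self.m[keep], a=self.a[keep], b=self.b[keep],
            alpha0=self.alpha0[keep],
        )


def init_population(
    D: int,
    M_max: int = 5,
    hyper: GmmHyper | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationGMM:
    """Symmetric weakly informative posterior-initialization.

    Component mean locations get a small jitter (from ``rng`` when given)
    so that identical components can differentiate during learning;
    without jitter a multi-component model would stay exactly symmetric
    forever.
    """
    if D < 1 or M_max < 1:
        raise ValueError("need D >= 1 and M_max >= 1")
    hyper = hyper or GmmHyper()
    alpha = np.full(M_max, hyper.weight_conc / M_max)
    kappa = np.full(M_max, hyper.mean_scale)
    m = np.zeros((M_max, D))
    if M_max > 1:
        jitter_rng = rng if rng is not None else np.random.default_rng(0)
        m += 0.05 * hyper.prior_scale * jitter_rng.standard_normal((M_max, D))
    a = np.full((M_max, D), hyper.prec_shape)
    b = np.full((M_max, D), hyper.prec_rate)
    return PopulationGMM(alpha=alpha, kappa=kappa, m=m, a=a, b=b, hyper=hyper)


def _expected_log_weights(pop: PopulationGMM) -> np.ndarray:
    return digamma(pop.alpha) - digamma(pop.alpha.sum())


def _expected_log_gauss(x: np.ndarray, pop: PopulationGMM) -> np.ndarray:
    """E[log N(x | mu_m, Lambda_m)] per component, shape (..., M)."""
    x = np.asarray(x, dtype=float)
    elog_prec = digamma(pop.a) - np.log(pop.b)  # (M, D)
    eprec = pop.a / pop.b
    diff = x[..., None, :] - pop.m  # (..., M, D)
    quad = np.sum(eprec * diff**2, axis=-1) + pop.dim / pop.kappa
    return 0.5 * (np.sum(elog_prec, axis=-1) - pop.dim * _LOG2PI - quad)


def expected_log_pdf(xi: np.ndarray, pop: PopulationGMM) -> np.ndarray:
    """Expected mixture log-density at ``xi`` under the parameter posterior.

    Computed as ``logsumexp_m(E[log w_m] + E[log N(xi | m)])`` — the form
    used as the (smooth, differentiable) prior term when sampling
    individual posteriors.  Vectorized over leading axes of ``xi``.
    """
    val, _ = expected_log_pdf_grad(xi, pop, with_grad=False)
    return val


def expected_log_pdf_grad(
    xi: np.ndarray, pop: PopulationGMM, with_grad: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """Expected mixture log-density and its gradient w.r.t. ``xi``."""
    xi = np.asarray(xi, dtype=float)
    comp = _expected_log_weights(pop) + _expected_log_gauss(xi, pop)  # (..., M)
    val = logsumexp(comp, axis=-1)
    if not with_grad:
        return val, None
    resp = np.exp(comp - val[..., None])  # (..., M)
    eprec = pop.a / pop.b
    diff = xi[..., None, :] - pop.m
    grad = -np.sum(resp[..., None] * eprec * diff, axis=-2)
    return val, grad


def responsibilities(x: np.ndarray, pop: PopulationGMM) -> np.ndarray:
    """Posterior component responsibilities for points ``x`` (..., D)."""
    comp = _expected_log_weights(pop) + _expected_log_gauss(x, pop)
    return np.exp(comp - logsumexp(comp, axis=-1, keepdims=True))


def update_population(
    xi_samples: list[np.ndarray], pop: PopulationGMM
) -> PopulationGMM:
    """One conjugate variational update of the population posterior.

    ``xi_samples[n]`` is the (S_n, D) posterior sample set of participant
    ``n``; every sample of participant ``n`` carries weight ``1/S_n`` so
    each participant contributes total weight 1.  Responsibilities are
    evaluated under the current ``pop``; the prior is taken from
    ``pop.hyper``.
    """
    if not xi_samples or any(s.shape[0] == 0 for s in xi_samples):
        raise ValueError("need at least one sample per participant")
    D, M = pop.dim, pop.n_components
    hyper = pop.hyper
    X = np.vstack([np.atleast_2d(s) for s in xi_samples])  # (S_tot, D)
    w = np.concatenate(
        [np.full(len(np.atleast_2d(s)), 1.0 / len(np.atleast_2d(s))) for s in xi_samples]
    )
    r = responsibilities(X, pop) * w[:, None]  # (S_tot, M)
    N_m = r.sum(axis=0)  # (M,)
    # weighted first and second moments per component
    sum_x = r.T @ X  # (M, D)
    sum_x2 = r.T @ X**2
    eps = 1e-12
    xbar = sum_x / (N_m[:, None] + eps)
    scatter = sum_x2 - N_m[:, None] * xbar**2  # within-component scatter
    if np.all(scatter <= 0) and len(X) > len(xi_samples):
        log.warning("degenerate sample sets (zero variance); prior regularization only")
    scatter = np.maximum(scatter, 0.0)
    kappa0 = hyper.mean_scale
    alpha = pop.alpha0 + N_m
    kappa = kappa0 + N_m
    m = (kappa0 * 0.0 + N_m[:, None] * xbar) / kappa[:, None]
    a = hyper.prec_shape + 0.5 * np.broadcast_to(N_m[:, None], (M, D)).copy()
    b = hyper.prec_rate + 0.5 * (
        scatter + (kappa0 * N_m / kappa)[:, None] * xbar**2
    )
    return replace(pop, alpha=alpha, kappa=kappa, m=m, a=a, b=b)


def _draw_parameters(pop: PopulationGMM, n: int, rng: np.random.Generator):
    """Draw (weights, means, precisions) from the parameter posterior."""
    w = rng.dirichlet(pop.alpha, size=n)  # (n, M)
    lam = rng.gamma(shape=pop.a, scale=1.0 / pop.b, size=(n,) + pop.a.shape)
    mu = pop.m + rng.standard_normal((n,) + pop.m.shape) / np.sqrt(
        pop.kappa[:, None] * lam
    )
    return w, mu, lam


def sample_random_individual(
    pop: PopulationGMM, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Hierarchical draws of xi for unseen random individuals.

    For each of the ``n`` draws: mixture parameters from their posterior,
    then a component, then ``xi`` from that component.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w, mu, lam = _draw_parameters(pop, n, rng)
    cum = np.cumsum(w, axis=1)
    comp = (rng.random(n)[:, None] > cum).sum(axis=1)
    idx = np.arange(n)
    return mu[idx, comp] + rng.standard_normal((n, pop.dim)) / np.sqrt(lam[idx, comp])


def sample_population_mean(
    pop: PopulationGMM, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Posterior draws of the mixture mean ``sum_m w_m mu_m``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w, mu, _ = _draw_parameters(pop, n, rng)
    return np.sum(w[..., None] * mu, axis=1)
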