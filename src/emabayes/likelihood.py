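"""Individual parameter vector and the joint EMA log-likelihood.

A participant's parameter vector ``xi`` concatenates three blocks:

1. situation logits, ``T * K`` (K logits per phase);
2. regression effects, ``P`` per attribute, ``I * P`` in total;
3. raw threshold parameters, ``L_i`` per attribute.

``D = T*K + I*P + sum_i L_i``.  The likelihood of all EMA records of one
participant is the sum of the multinomial situation term and the
graded-response terms of every attribute, after mapping the blocks through
softmax, the regression design and the threshold transform.  Missing
ratings contribute nothing.

Evaluation is *stacked*: all participants share the frame, so their count
tables stack into dense arrays and the likelihood (with analytic
gradient) is evaluated for many (participant, chain) parameter vectors at
once — this is what keeps the alternating variational loop fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix, EffectSpec, design_matrix
from .frame import EmaDataset, EmaFrame
from .response import ordinal_loglik_grad, raw_to_interior, raw_to_interior_vjp
from .situations import counts_from_dataset, situation_loglik_grad

__all__ = ["ParamBlocks", "IndividualParams", "param_dimension", "StackedLikelihood",
           "total_log_likelihood"]


@dataclass(frozen=True)
class ParamBlocks:
    """Index map of the three blocks inside a parameter vector."""

    frame: EmaFrame
    spec: EffectSpec
    n_effect_params: int  # P, per attribute

    @property
    def T(self) -> int:
        return self.frame.n_phases

    @property
    def K(self) -> int:
        return self.frame.n_cells

    @property
    def attributes(self) -> list[str]:
        return list(self.frame.attributes)

    @property
    def situation_slice(self) -> slice:
        return slice(0, self.T * self.K)

    def effect_slice(self, attribute: str) -> slice:
        i = self.attributes.index(attribute)
        start = self.T * self.K + i * self.n_effect_params
        return slice(start, start + self.n_effect_params)

    def threshold_slice(self, attribute: str) -> slice:
        start = self.T * self.K + len(self.attributes) * self.n_effect_params
        for a, L in self.frame.attribute_levels.items():
            if a == attribute:
                return slice(start, start + L)
            start += L
        raise KeyError(attribute)

    @property
    def dim(self) -> int:
        return (
            self.T * self.K
            + len(self.attributes) * self.n_effect_params
            + sum(self.frame.attribute_levels.values())
        )

    def breakdown(self) -> dict[str, int]:
        return {
            "situation": self.T * self.K,
            "effects": len(self.attributes) * self.n_effect_params,
            "thresholds": sum(self.frame.attribute_levels.values()),
        }


@dataclass(frozen=True)
class IndividualParams:
    """One participant's parameter vector with typed block access."""

    xi: np.ndarray
    blocks: ParamBlocks

    def __post_init__(self):
        if self.xi.shape != (self.blocks.dim,):
            raise ValueError(
                f"xi has shape {self.xi.shape}, expected ({self.blocks.dim},)"
            )

    @property
    def situation_logits(self) -> np.ndarray:
        return self.xi[self.blocks.situation_slice].reshape(self.blocks.T, self.blocks.K)

    def effects(self, attribute: str) -> np.ndarray:
        return self.xi[self.blocks.effect_slice(attribute)]

    def raw_thresholds(self, attribute: str) -> np.ndarray:
        return self.xi[self.blocks.threshold_slice(attribute)]


def param_dimension(frame: EmaFrame, spec: EffectSpec | None = None):
    """Total parameter count D per participant, with the per-block breakdown.

    Returns ``(D, breakdown)`` where breakdown maps
    ``situation / effects / thresholds`` to their addends
    ``T*K``, ``I*P`` and ``sum_i L_i``.
    """
    spec = spec or EffectSpec.saturated(frame)
    design = design_matrix(spec, frame)
    blocks = ParamBlocks(frame=frame, spec=spec, n_effect_params=design.n_params)
    return blocks.dim, blocks.breakdown()


class StackedLikelihood:
    """Joint EMA log-likelihood of all participants, vectorized.

    Parameters
    ----------
    dataset, frame
        Validated data and the study design.
    spec
        Effect specification (defaults to the saturated phase x situation
        interaction).
    mode
        Identifiability restriction: ``"median-zero"`` restricts the
        thresholds inside the likelihood; ``"zero-mean-attribute"`` centers
        the latent locations over cells instead.
    """

    def __init__(
        self,
        dataset: EmaDataset,
        frame: EmaFrame | None = None,
        spec: EffectSpec | None = None,
        mode: str = "median-zero",
    ):
        frame = frame or dataset.frame
        spec = spec or EffectSpec.saturated(frame)
        spec.validate(frame)
        if mode not in ("median-zero", "zero-mean-attribute"):
            raise ValueError(f"unknown identifiability mode {mode!r}")
        self.frame = frame
        self.spec = spec
        self.mode = mode
        self.design: DesignMatrix = design_matrix(spec, frame)
        self.blocks = ParamBlocks(frame=frame, spec=spec, n_effect_params=self.design.n_params)
        self.participants = dataset.participants
        self.groups = {p: dataset.group_of(p) for p in self.participants}
        T, K = frame.n_phases, frame.n_cells
        sit = counts_from_dataset(dataset, frame)
        self.sit_counts = np.stack([sit[p] for p in self.participants]).astype(float)
        # per attribute: (N, T*K, L) rating counts over (cell, level)
        self.attr_counts: dict[str, np.ndarray] = {}
        for attr, L in frame.attribute_levels.items():
            counts = np.zeros((len(self.participants), T * K, L))
            for n, pid in enumerate(self.participants):
                for rec in dataset.records_of(pid):
                    v = rec.ratings.get(attr)
                    if v is None:
                        continue
                    t = frame.phase_index(rec.phase)
                    k = frame.cell_index(rec.situation)
                    counts[n, t * K + k, v - 1] += 1
            self.attr_counts[attr] = counts

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def dim(self) -> int:
        return self.blocks.dim

    # -- evaluation -----------------------------------------------------------

    def loglik_grad(self, X: np.ndarray):
        """Log-likelihood and gradient for stacked parameter vectors.

        ``X`` has shape (N, C, D): C parameter vectors (chains) per
        participant, participants in ``self.participants`` order.
        Returns ``(loglik (N, C), grad (N, C, D))``.
        """
        X = np.asarray(X, dtype=float)
        N, C, D = X.shape
        if N != self.n_participants or D != self.dim:
            raise ValueError(f"X has shape {X.shape}, expected ({self.n_participants}, C, {self.dim})")
        b = self.blocks
        T, K = b.T, b.K
        grad = np.zeros_like(X)
        logits = X[..., b.situation_slice].reshape(N, C, T, K)
        ll, g = situation_loglik_grad(self.sit_counts[:, None], logits)
        if not np.all(np.isfinite(ll)):
            raise FloatingPointError("non-finite situation log-likelihood")
        grad[..., b.situation_slice] = g.reshape(N, C, T * K)
        total = ll
        thr_mode = "median-zero" if self.mode == "median-zero" else "free"
        for attr in b.attributes:
            counts = self.attr_counts[attr][:, None]  # (N, 1, T*K, L)
            esl, tsl = b.effect_slice(attr), b.threshold_slice(attr)
            beta = X[..., esl]
            theta = beta @ self.design.matrix.T  # (N, C, T*K)
            if self.mode == "zero-mean-attribute":
                theta = theta - theta.mean(axis=-1, keepdims=True)
            raw = X[..., tsl]
            interior = raw_to_interior(raw, thr_mode)
            ll_a, dtheta, dtau = ordinal_loglik_grad(counts, theta, interior)
            if not np.all(np.isfinite(ll_a)):
                raise FloatingPointError(
                    f"non-finite log-likelihood in attribute block {attr!r}"
                )
            total = total + ll_a
            if self.mode == "zero-mean-attribute":
                dtheta = dtheta - dtheta.mean(axis=-1, keepdims=True)
            grad[..., esl] = dtheta @ self.design.matrix
            grad[..., tsl] = raw_to_interior_vjp(raw, dtau, thr_mode)
        return total, grad

    def loglik(self, X: np.ndarray) -> np.ndarray:
        return self.loglik_grad(X)[0]

    def single(self, pid: str):
        """(loglik, grad) closure over one participant's D-vector."""
        n = self.participants.index(pid)

        def fn(xi: np.ndarray):
            ll, g = self._eval_one(n, xi)
            return ll, g

        return fn

    def _eval_one(self, n: int, xi: np.ndarray):
        xi = np.asarray(xi, dtype=float)
        sub = _SubsetView(self, [n])
        ll, g = sub.loglik_grad(xi[None, None])
        return float(ll[0, 0]), g[0, 0]


class _SubsetView:
    """Restriction of a StackedLikelihood to a subset of participants."""

    def __init__(self, parent: StackedLikelihood, idx: list[int]):
        self.blocks = parent.blocks
        self.design = parent.design
        self.mode = parent.mode
        self.frame = parent.frame
        self.participants = [parent.participants[i] for i in idx]
        self.sit_counts = parent.sit_counts[idx]
        self.attr_counts = {a: c[idx] for a, c in parent.attr_counts.items()}
        self.dim = parent.dim
        self.n_participants = len(idx)
        self.loglik_grad = StackedLikelihood.loglik_grad.__get__(self)


def total_log_likelihood(
    xi: np.ndarray | IndividualParams,
    dataset: EmaDataset,
    participant_id: str,
    spec: EffectSpec | None = None,
    mode: str = "median-zero",
):
    """Joint log-likelihood of one participant's records, with gradient.

    Convenience wrapper assembling a (tiny) stacked evaluation for a
    single participant; returns ``(loglik, grad)``.
    """
    if isinstance(xi, IndividualParams):
        xi = xi.xi
    lik = StackedLikelihood(dataset, spec=spec, mode=mode)
    if participant_id not in lik.participants:
        raise KeyError(participant_id)
    n = lik.participants.index(participant_id)
    return lik._eval_one(n, xi)
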