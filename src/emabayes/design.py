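"""Ordinal-regression design layer.

The latent attribute location of a participant varies over the
``T x K`` (phase x joint-situation) cells through a linear map
``theta = X beta`` where ``X`` is a cell-indicator design matrix built
from *effect terms*.  A term is a subset of the factors
``{"phase"} | situation dimensions``: singletons are main effects, larger
subsets interactions.  Cell-indicator coding is used throughout — each
term contributes one column per category combination of its factors, with
no reference level dropped; the resulting rank deficiency of
main-effect models is regularized by the population prior, and reported
effects are contrasts, which are identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frame import ConfigurationError, EmaFrame

__all__ = ["EffectSpec", "DesignMatrix", "design_matrix", "theta_from_effects"]

PHASE = "phase"


@dataclass(frozen=True)
class EffectSpec:
    """Ordered list of effect terms, each a tuple of factor names."""

    terms: tuple[tuple[str, ...], ...]

    def __init__(self, terms: Sequence[Sequence[str] | str]):
        norm = []
        for term in terms:
            if isinstance(term, str):
                term = [f.strip() for f in term.replace("*", "+").split("+") if f.strip()]
            t = tuple(term)
            if not t:
                raise ConfigurationError("empty effect term")
            if len(set(t)) != len(t):
                raise ConfigurationError(f"repeated factor within term {t}")
            norm.append(t)
        if not norm:
            raise ConfigurationError("effect specification needs at least one term")
        if len(set(norm)) != len(norm):
            raise ConfigurationError("duplicate effect terms")
        object.__setattr__(self, "terms", tuple(norm))

    @classmethod
    def saturated(cls, frame: EmaFrame) -> "EffectSpec":
        """The default: one term interacting phase with all situation dimensions."""
        return cls([(PHASE, *frame.situation_dims)])

    def validate(self, frame: EmaFrame) -> None:
        for term in self.terms:
            for f in term:
                if f != PHASE and f not in frame.situation_dims:
                    raise ConfigurationError(
                        f"effect term {term} names unknown factor {f!r}"
                    )

    def __str__(self) -> str:
        return " + ".join("*".join(t) for t in self.terms)


@dataclass(frozen=True)
class DesignMatrix:
    """(T*K) x P indicator matrix mapping effect parameters to cell locations."""

    matrix: np.ndarray
    column_labels: tuple[str, ...]
    term_slices: dict[tuple[str, ...], slice] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def _factor_levels(frame: EmaFrame) -> dict[str, tuple[str, ...]]:
    levels = {PHASE: frame.phases}
    levels.update(frame.situation_dims)
    return levels


def design_matrix(spec: EffectSpec, frame: EmaFrame) -> DesignMatrix:
    """Build the cell-indicator design for an effect specification.

    Rows enumerate (phase, joint situation cell) combinations row-major in
    the declared order; each row carries exactly one 1 per term.
    """
    spec.validate(frame)
    levels = _factor_levels(frame)
    T, K = frame.n_phases, frame.n_cells
    # per-row level index of each factor
    cell_tuples = frame.cell_labels()
    dim_names = list(frame.situation_dims)
    row_levels: dict[str, np.ndarray] = {}
    t_idx = np.repeat(np.arange(T), K)
    row_levels[PHASE] = t_idx
    for j, dim in enumerate(dim_names):
        per_cell = np.array(
            [frame.situation_dims[dim].index(cell[j]) for cell in cell_tuples]
        )
        row_levels[dim] = np.tile(per_cell, T)
    blocks = []
    labels: list[str] = []
    term_slices: dict[tuple[str, ...], slice] = {}
    start = 0
    for term in spec.terms:
        sizes = [len(levels[f]) for f in term]
        p = int(np.prod(sizes))
        col = np.zeros(T * K, dtype=np.int64)
        for f, size in zip(term, sizes):
            col = col * size + row_levels[f]
        block = np.zeros((T * K, p))
        block[np.arange(T * K), col] = 1.0
        blocks.append(block)
        for combo in np.ndindex(*sizes):
            labels.append(
                "*".join(f"{f}={levels[f][i]}" for f, i in zip(term, combo))
            )
        term_slices[term] = slice(start, start + p)
        start += p
    matrix = np.hstack(blocks)
    return DesignMatrix(matrix=matrix, column_labels=tuple(labels), term_slices=term_slices)


def theta_from_effects(beta: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Latent locations over all T*K cells, ``theta = X beta``.

    Vectorized over leading axes of ``beta`` (last axis must be P).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[-1] != design.n_params:
        raise ValueError(
            f"beta has {beta.shape[-1]} entries, design expects {design.n_params}"
        )
    theta = beta @ design.matrix.T
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite latent locations")
    return theta
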