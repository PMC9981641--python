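"""Predictive distributions, credibility probabilities, and reporting.

All reported quantities are computed by pushing posterior draws of the
individual parameter vector through the model maps (softmax for situation
probabilities, the regression design for latent attribute locations, the
monotone threshold transform), at one of three inference levels:

``"random_individual"``
    hierarchical draws of an unseen member of the population,
``"population_mean"``
    posterior draws of the population mixture mean,
``"participant:<id>"``
    the stored posterior sample set of one participant.

Credibility of a (joint) set of inequalities is the fraction of draws
satisfying all of them simultaneously — the joint evaluation already
accounts for multiplicity, so no further correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frame import EmaDataset
from .population import sample_population_mean, sample_random_individual
from .response import ordinal_logpmf, raw_to_interior

__all__ = [
    "PredictiveResult",
    "Hypothesis",
    "CredibilityResult",
    "predict",
    "credibility",
    "posterior_predictive_counts",
    "save_results",
]

DEFAULT_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)
LEVELS = ("random_individual", "population_mean")


# -- draws ------------------------------------------------------------------


def _resolve_group(results, group: str | None) -> str:
    if group is not None:
        if group not in results.populations:
            raise KeyError(f"unknown group {group!r}")
        return group
    if len(results.populations) == 1:
        return next(iter(results.populations))
    raise ValueError(
        f"several groups fitted ({list(results.populations)}); specify one"
    )


def level_draws(results, level: str, n_draws: int = 2000,
                seed: int | None = None, group: str | None = None) -> np.ndarray:
    """Posterior xi draws (n, D) appropriate for an inference level."""
    if level.startswith("participant:"):
        pid = level.split(":", 1)[1]
        if pid not in results.samples:
            raise KeyError(f"unknown participant {pid!r}")
        s = results.samples[pid]
        if s.size == 0:
            raise ValueError(f"empty sample store for participant {pid!r}")
        return s
    pop = results.populations[_resolve_group(results, group)]
    rng = np.random.default_rng(seed)
    if level == "random_individual":
        return sample_random_individual(pop, n_draws, rng)
    if level == "population_mean":
        return sample_population_mean(pop, n_draws, rng)
    raise ValueError(f"unknown inference level {level!r}")


def _situation_draws(results, xi: np.ndarray) -> np.ndarray:
    """(n, T, K) situation-probability draws."""
    from scipy.special import softmax

    b = results.blocks
    logits = xi[:, b.situation_slice].reshape(len(xi), b.T, b.K)
    return softmax(logits, axis=-1)


def _attribute_draws(results, xi: np.ndarray, attr: str):
    """(theta (n, T*K), interior (n, L-1)) draws for one attribute."""
    b = results.blocks
    theta = xi[:, b.effect_slice(attr)] @ results.design.matrix.T
    if results.mode == "zero-mean-attribute":
        theta = theta - theta.mean(axis=-1, keepdims=True)
    thr_mode = "median-zero" if results.mode == "median-zero" else "free"
    interior = raw_to_interior(xi[:, b.threshold_slice(attr)], thr_mode)
    return theta, interior


# -- percentile tables -------------------------------------------------------


@dataclass
class PredictiveResult:
    """Percentile table plus the underlying draws for one target."""

    level: str
    target: str
    table: pd.DataFrame
    samples: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PredictiveResult {self.target} @ {self.level}, n={len(self.samples)}>"


def _percentile_table(draws: np.ndarray, index, percentiles=DEFAULT_PERCENTILES):
    q = np.percentile(draws, percentiles, axis=0).T
    return pd.DataFrame(q, index=index, columns=[f"p{p:g}" for p in percentiles])


def _row_index(results):
    cells = results.frame.cell_names()
    return pd.MultiIndex.from_product(
        [results.frame.phases, cells], names=["phase", "situation"]
    )


def predict(results, level: str = "population_mean", targets=None,
            n_draws: int = 2000, seed: int | None = None,
            group: str | None = None,
            percentiles: Sequence[float] = DEFAULT_PERCENTILES) -> dict[str, PredictiveResult]:
    """Percentile tables for situation probabilities, attribute locations
    and response thresholds at one inference level.

    ``targets`` selects among ``"situations"``, ``"attribute:<name>"`` and
    ``"thresholds:<name>"``; by default everything is reported.
    """
    xi = level_draws(results, level, n_draws, seed, group)
    frame = results.frame
    wanted = set(targets) if targets is not None else None

    def take(name):
        return wanted is None or name in wanted

    out: dict[str, PredictiveResult] = {}
    if take("situations"):
        u = _situation_draws(results, xi)
        flat = u.reshape(len(xi), -1)
        out["situations"] = PredictiveResult(
            level, "situations", _percentile_table(flat, _row_index(results), percentiles), u
        )
    for attr in frame.attributes:
        theta, interior = None, None
        if take(f"attribute:{attr}"):
            theta, interior = _attribute_draws(results, xi, attr)
            out[f"attribute:{attr}"] = PredictiveResult(
                level, f"attribute:{attr}",
                _percentile_table(theta, _row_index(results), percentiles), theta,
            )
        if take(f"thresholds:{attr}"):
            if interior is None:
                _, interior = _attribute_draws(results, xi, attr)
            idx = [f"tau_{j + 1}" for j in range(interior.shape[1])]
            out[f"thresholds:{attr}"] = PredictiveResult(
                level, f"thresholds:{attr}",
                _percentile_table(interior, idx, percentiles), interior,
            )
    return out


# -- credibility -------------------------------------------------------------


@dataclass(frozen=True)
class Hypothesis:
    """One pairwise inequality: value(smaller) < value(larger).

    ``kind`` is ``"attribute"`` (latent location; ``name`` is the
    attribute) or ``"situation"`` (cell probability; ``name`` ignored).
    Cell selectors are ``(phase, category, category, ...)`` in declared
    dimension order; a ``"*"`` entry averages the latent location (or sums
    the probability) over that dimension's categories.
    """

    kind: str
    name: str | None
    smaller: tuple
    larger: tuple


@dataclass
class CredibilityResult:
    probability: float
    mcse: float
    n_draws: int
    marginals: list[float]

    def __repr__(self) -> str:  # pragma: no cover
        return f"P(joint) = {self.probability:.3f} +- {self.mcse:.3f} (n={self.n_draws})"


def _cell_weights(frame, selector: tuple, average: bool) -> tuple[int, np.ndarray]:
    """(phase index, weight vector over K cells) for a selector."""
    phase, *cats = selector
    t = frame.phase_index(phase)
    dims = list(frame.situation_dims)
    if len(cats) != len(dims):
        raise ValueError(
            f"selector {selector} must name all {len(dims)} situation dimension(s)"
        )
    mask = np.ones(frame.n_cells, dtype=bool)
    for j, (dim, cat) in enumerate(zip(dims, cats)):
        if cat == "*":
            continue
        col = np.array([cell[j] == cat for cell in frame.cell_labels()])
        if not col.any():
            raise ValueError(f"unknown category {cat!r} in dimension {dim!r}")
        mask &= col
    w = mask.astype(float)
    if average:
        w /= w.sum()
    return t, w


def _hypothesis_values(results, xi: np.ndarray, hyp: Hypothesis):
    frame = results.frame
    K = frame.n_cells
    if hyp.kind == "attribute":
        theta, _ = _attribute_draws(results, xi, hyp.name)
        vals = []
        for sel in (hyp.smaller, hyp.larger):
            t, w = _cell_weights(frame, sel, average=True)
            vals.append(theta[:, t * K : (t + 1) * K] @ w)
        return vals
    if hyp.kind == "situation":
        u = _situation_draws(results, xi)
        vals = []
        for sel in (hyp.smaller, hyp.larger):
            t, w = _cell_weights(frame, sel, average=False)
            vals.append(u[:, t] @ w)
        return vals
    raise ValueError(f"unknown hypothesis kind {hyp.kind!r}")


def credibility(results, level: str, hypotheses: Sequence[Hypothesis],
                n_draws: int = 2000, seed: int | None = None,
                group: str | None = None) -> CredibilityResult:
    """Joint posterior probability that all inequalities hold.

    Returns the fraction of level-appropriate draws satisfying every
    hypothesis simultaneously, with its Monte-Carlo standard error and
    the per-hypothesis marginal probabilities.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    xi = level_draws(results, level, n_draws, seed, group)
    n = len(xi)
    joint = np.ones(n, dtype=bool)
    marginals = []
    for hyp in hypotheses:
        lo, hi = _hypothesis_values(results, xi, hyp)
        sat = lo < hi
        marginals.append(float(sat.mean()))
        joint &= sat
    p = float(joint.mean())
    return CredibilityResult(
        probability=p,
        mcse=float(np.sqrt(max(p * (1 - p), 1e-12) / n)),
        n_draws=n,
        marginals=marginals,
    )


# -- posterior predictive checks --------------------------------------------


def posterior_predictive_counts(results, dataset: EmaDataset,
                                n_draws: int = 200,
                                seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Observed response counts with model-predicted 95% credible intervals.

    For each posterior draw, rating counts are simulated conditional on
    each observed record's (phase, situation) cell, summed over
    participants, and summarized per (phase, response level).  Interval
    bounds are integer counts.
    """
    if dataset is None:
        raise ValueError("posterior_predictive_counts needs the fitted dataset")
    frame = results.frame
    rng = np.random.default_rng(seed)
    T, K = frame.n_phases, frame.n_cells
    S = min([n_draws] + [len(results.samples[p]) for p in results.participants])
    out: dict[str, pd.DataFrame] = {}
    for attr, scale in frame.attributes.items():
        L = len(scale)
        observed = np.zeros((T, L))
        simulated = np.zeros((S, T, L))
        any_data = False
        for pid in results.participants:
            cnt = np.zeros((T * K, L))
            for rec in dataset.records_of(pid):
                v = rec.ratings.get(attr)
                if v is None:
                    continue
                t = frame.phase_index(rec.phase)
                k = frame.cell_index(rec.situation)
                cnt[t * K + k, v - 1] += 1
            m = cnt.sum(axis=1)  # records with a rating, per cell
            if m.sum() == 0:
                continue
            any_data = True
            observed += cnt.reshape(T, K, L).sum(axis=1)
            xi = results.samples[pid][:S]
            theta, interior = _attribute_draws(results, xi, attr)
            probs = np.exp(ordinal_logpmf(theta, interior[:, None, :]))  # (S, T*K, L)
            for c in np.flatnonzero(m):
                draws = np.array(
                    [rng.multinomial(int(m[c]), probs[s, c]) for s in range(S)]
                )
                simulated[:, c // K] += draws
        if not any_data:
            out[attr] = pd.DataFrame(
                columns=["observed", "lo2.5", "hi97.5"],
                index=pd.MultiIndex.from_arrays([[], []], names=["phase", "response"]),
            )
            continue
        lo = np.percentile(simulated, 2.5, axis=0, method="lower")
        hi = np.percentile(simulated, 97.5, axis=0, method="higher")
        idx = pd.MultiIndex.from_product(
            [frame.phases, scale], names=["phase", "response"]
        )
        out[attr] = pd.DataFrame(
            {
                "observed": observed.reshape(-1).astype(int),
                "lo2.5": lo.reshape(-1).astype(int),
                "hi97.5": hi.reshape(-1).astype(int),
            },
            index=idx,
        )
    return out


# -- saving ------------------------------------------------------------------

_TABLE_FORMATS = {"csv", "tsv"}
_FIGURE_FORMATS = {"png", "pdf", "svg"}


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def save_results(results: dict, directory, formats: Sequence[str] = ("csv",)) -> list[Path]:
    """Write percentile tables (and optionally figures) to ``directory``.

    ``results`` maps level -> {target -> PredictiveResult}.  File names
    are deterministic functions of level and target.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - _TABLE_FORMATS - _FIGURE_FORMATS
    if unknown:
        raise ValueError(f"unknown output format(s): {sorted(unknown)}")
    written: list[Path] = []
    for level, targets in results.items():
        for target, pr in targets.items():
            stem = f"{_safe(level)}__{_safe(target)}"
            if "csv" in formats:
                path = directory / f"{stem}.csv"
                pr.table.to_csv(path)
                written.append(path)
            if "tsv" in formats:
                path = directory / f"{stem}.tsv"
                pr.table.to_csv(path, sep="\t")
                written.append(path)
            for fmt in sorted(formats & _FIGURE_FORMATS):
                path = directory / f"{stem}.{fmt}"
                _plot_result(pr, targets, path)
                written.append(path)
    return written


def _plot_result(pr: PredictiveResult, siblings: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = pr.table
    x = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(tab)), 4))
    ax.vlines(x, tab["p2.5"], tab["p97.5"], color="0.4", lw=1.2, label="95% CI")
    ax.plot(x, tab["p50"], "o", color="C0", label="median")
    ax.plot(x, tab["p25"], "_", color="C0", ms=10)
    ax.plot(x, tab["p75"], "_", color="C0", ms=10)
    # attribute plots get the median response thresholds as horizontal guides
    if pr.target.startswith("attribute:"):
        tkey = "thresholds:" + pr.target.split(":", 1)[1]
        if tkey in siblings:
            for tau in siblings[tkey].table["p50"]:
                ax.axhline(tau, color="0.8", lw=0.7, zorder=0)
    labels = [
        "/".join(str(v) for v in ix) if isinstance(ix, tuple) else str(ix)
        for ix in tab.index
    ]
    ax.set_xticks(x, labels, rotation=45, ha="right", fontsize=8)
    ax.set_title(f"{pr.target} ({pr.level})")
    ax.set_ylabel("latent scale (logit units)"
                  if not pr.target.startswith("situations") else "probability")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
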