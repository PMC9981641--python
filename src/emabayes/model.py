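"""The hierarchical EMA model and its fitted results.

`EmaModel` couples a validated :class:`~emabayes.frame.EmaDataset` with an
effect specification and identifiability mode; ``fit()`` runs the
alternating variational learning loop —

1. sample each participant's posterior over ``xi`` (likelihood times the
   expected population log-density) with Hamiltonian Monte Carlo, all
   participants and chains stacked into one vectorized run;
2. conjugately update the per-group Gaussian-mixture population posterior
   from the participant sample sets (each participant with total weight 1);

— until the objective proxy (mean sampled log joint per participant)
stabilizes, the iteration limit is reached, or the time limit expires.
The returned :class:`EmaResults` carries the participant sample stores,
the population posteriors, the convergence trace and a settings snapshot,
and exposes predictive summaries, credibility calculations, diagnostics
and serialization.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .design import EffectSpec
from .frame import EmaDataset, EmaFrame
from .likelihood import StackedLikelihood, param_dimension
from .population import (
    GmmHyper,
    PopulationGMM,
    expected_log_pdf_grad,
    init_population,
    update_population,
)
from .sampler import hmc_sample

__all__ = ["EmaModel", "EmaResults", "learn"]

log = logging.getLogger(__name__)


class EmaModel:
    """Hierarchical Bayesian model of one EMA study.

    Parameters
    ----------
    dataset
        Validated records for all participants.
    effects
        Ordinal-regression effect specification; defaults to the saturated
        phase x situation interaction.
    mode
        Identifiability restriction, ``"median-zero"`` (default) or
        ``"zero-mean-attribute"``.
    """

    def __init__(
        self,
        dataset: EmaDataset,
        effects: EffectSpec | None = None,
        mode: str = "median-zero",
    ):
        if dataset.n_participants == 0:
            raise ValueError("empty dataset")
        self.dataset = dataset
        self.frame = dataset.frame
        self.effects = effects or EffectSpec.saturated(self.frame)
        self.mode = mode
        self.likelihood = StackedLikelihood(dataset, spec=self.effects, mode=mode)
        self.blocks = self.likelihood.blocks
        self.design = self.likelihood.design

    @classmethod
    def from_directory(
        cls, directory, frame: EmaFrame, effects: EffectSpec | None = None, **kw
    ) -> "EmaModel":
        from .io import load_dataset

        return cls(load_dataset(directory, frame), effects=effects, **kw)

    @property
    def param_dim(self) -> int:
        return self.blocks.dim

    def param_breakdown(self) -> dict[str, int]:
        return self.blocks.breakdown()

    # -- initialization -------------------------------------------------------

    def _initial_xi(self) -> np.ndarray:
        """Moment-matched starting points, one D-vector per participant."""
        lik = self.likelihood
        b = self.blocks
        N = lik.n_participants
        xi0 = np.zeros((N, b.dim))
        counts = lik.sit_counts  # (N, T, K)
        logits = np.log(counts + 0.5)
        logits -= logits.mean(axis=-1, keepdims=True)
        xi0[:, b.situation_slice] = logits.reshape(N, -1)
        for attr, L in self.frame.attribute_levels.items():
            sl = b.threshold_slice(attr)
            spacing = 4.0 / max(L - 2, 1)
            raw = np.full(L, np.log(np.expm1(spacing)))
            raw[0] = -spacing * (L - 1) / 2.0
            xi0[:, sl] = raw
        return xi0

    # -- learning -------------------------------------------------------------

    def fit(
        self,
        M_max: int = 5,
        n_chains: int = 4,
        n_kept: int = 100,
        n_warmup: int = 100,
        max_iter: int = 100,
        tol: float = 1e-5,
        patience: int = 3,
        max_minutes: float | None = None,
        seed: int | None = None,
        n_leapfrog: int = 10,
        hyper: GmmHyper | None = None,
    ) -> "EmaResults":
        """Run the alternating variational learning loop.

        ``seed`` governs every source of randomness (initial jitter, HMC
        momenta, accept decisions, component-jitter of the population
        initialization); re-running with the same seed reproduces the
        convergence trace exactly.
        """
        t_start = time.monotonic()
        rng = np.random.default_rng(seed)
        lik = self.likelihood
        N, D, C = lik.n_participants, lik.dim, n_chains
        if N == 1:
            log.warning(
                "single participant: population posterior will stay prior-dominated"
            )
        hyper = hyper or GmmHyper()
        group_idx: dict[str, np.ndarray] = {}
        for g in self.frame.groups:
            idx = np.array(
                [i for i, p in enumerate(lik.participants) if lik.groups[p] == g]
            )
            if len(idx):
                group_idx[g] = idx
        pops = {
            g: init_population(D, M_max, hyper, rng=rng) for g in group_idx
        }

        X = self._initial_xi()[:, None, :] + 0.05 * rng.standard_normal((N, C, D))

        def logp_grad(Xflat):
            Xr = Xflat.reshape(N, C, D)
            ll, g = lik.loglik_grad(Xr)
            for grp, idx in group_idx.items():
                val, gr = expected_log_pdf_grad(Xr[idx], pops[grp])
                ll[idx] += val
                g[idx] += gr
            return ll.reshape(N * C), g.reshape(N * C, D)

        Xflat = X.reshape(N * C, D)
        eps: np.ndarray | float = 0.1
        trace: list[float] = []
        diag_last = None
        streak = 0
        converged = False
        partial = False
        samples_by_pid: dict[str, np.ndarray] = {}
        it = 0
        for it in range(1, max_iter + 1):
            warm = n_warmup if it == 1 else max(10, n_warmup // 5)
            samples, logps, Xflat, diag_last = hmc_sample(
                logp_grad, Xflat, warm, n_kept, rng,
                n_leapfrog=n_leapfrog, step_size0=eps,
            )
            eps = diag_last.step_size
            # (S, N*C, D) -> per participant (S*C, D)
            per_part = (
                samples.reshape(-1, N, C, D).transpose(1, 0, 2, 3).reshape(N, -1, D)
            )
            samples_by_pid = {
                pid: per_part[i] for i, pid in enumerate(lik.participants)
            }
            for grp, idx in group_idx.items():
                pops[grp] = update_population([per_part[i] for i in idx], pops[grp])
            # objective proxy: per-participant mean sampled log joint
            obj = float(logps.reshape(-1, N, C).mean(axis=(0, 2)).mean())
            if trace:
                rel = abs(obj - trace[-1]) / (1.0 + abs(obj))
                streak = streak + 1 if rel < tol else 0
            trace.append(obj)
            log.info("iteration %d: objective %.4f", it, obj)
            if streak >= patience:
                converged = True
                break
            if max_minutes is not None and (time.monotonic() - t_start) > 60 * max_minutes:
                partial = True
                log.warning("time limit reached after %d iterations; partial fit", it)
                break
        if not trace:
            raise RuntimeError("time limit reached before the first full iteration")
        pops = {g: pop.prune() for g, pop in pops.items()}

        settings = {
            "M_max": M_max, "n_chains": n_chains, "n_kept": n_kept,
            "n_warmup": n_warmup, "max_iter": max_iter, "tol": tol,
            "patience": patience, "max_minutes": max_minutes, "seed": seed,
            "n_leapfrog": n_leapfrog, "mode": self.mode,
            "effects": str(self.effects),
        }
        return EmaResults(
            frame=self.frame,
            effects=self.effects,
            mode=self.mode,
            design=self.design,
            blocks=self.blocks,
            participants=list(lik.participants),
            participant_groups=dict(lik.groups),
            samples=samples_by_pid,
            populations=pops,
            trace=trace,
            converged=converged,
            partial=partial,
            settings=settings,
            diagnostics={
                "accept_rate": float(np.mean(diag_last.accept_rate)),
                "divergence_rate": float(np.mean(diag_last.divergences)) / max(n_kept, 1),
                "iterations": it,
            },
            dataset=self.dataset,
        )


def learn(
    dataset: EmaDataset,
    frame: EmaFrame | None = None,
    spec: EffectSpec | None = None,
    **options,
) -> "EmaResults":
    """Functional entry point: build an :class:`EmaModel` and fit it."""
    if frame is not None and frame is not dataset.frame:
        dataset = EmaDataset(frame, list(dataset))
    mode = options.pop("mode", "median-zero")
    return EmaModel(dataset, effects=spec, mode=mode).fit(**options)


@dataclass
class EmaResults:
    """Fitted hierarchical EMA model.

    Carries the per-participant posterior sample stores over ``xi``, the
    per-group population posteriors, the convergence trace and the exact
    settings of the run.  Predictive summaries are produced at three
    levels: ``"random_individual"``, ``"population_mean"`` and
    ``"participant:<id>"``.
    """

    frame: EmaFrame
    effects: EffectSpec
    mode: str
    design: object
    blocks: object
    participants: list[str]
    participant_groups: dict[str, str]
    samples: dict[str, np.ndarray]
    populations: dict[str, PopulationGMM]
    trace: list[float]
    converged: bool
    partial: bool
    settings: dict
    diagnostics: dict = field(default_factory=dict)
    dataset: EmaDataset | None = None

    @property
    def param_dim(self) -> int:
        return self.blocks.dim

    # -- predictive API (delegated) ------------------------------------------

    def predict(self, level: str = "population_mean", targets=None, n_draws: int = 2000,
                seed: int | None = None, group: str | None = None):
        from . import predictive

        return predictive.predict(self, level, targets=targets, n_draws=n_draws,
                                  seed=seed, group=group)

    def credibility(self, hypotheses, level: str = "population_mean",
                    n_draws: int = 2000, seed: int | None = None,
                    group: str | None = None):
        from . import predictive

        return predictive.credibility(self, level, hypotheses, n_draws=n_draws,
                                      seed=seed, group=group)

    def posterior_predictive_counts(self, dataset: EmaDataset | None = None,
                                    n_draws: int = 200, seed: int | None = None):
        from . import predictive

        return predictive.posterior_predictive_counts(
            self, dataset or self.dataset, n_draws=n_draws, seed=seed
        )

    def save(self, directory, formats=("csv",), **kw):
        from . import predictive

        results = {}
        for level in ["random_individual", "population_mean"]:
            results[level] = self.predict(level, **kw)
        return predictive.save_results(results, directory, formats=formats)

    def summary(self, n_draws: int = 2000, seed: int | None = 0) -> str:
        """Plain-text summary of the fit and population-mean estimates."""
        from . import predictive

        lines = [
            "Hierarchical Bayesian EMA model",
            "=" * 46,
            f"participants: {len(self.participants)}   groups: {list(self.populations)}",
            f"phases: {list(self.frame.phases)}   situation cells K={self.frame.n_cells}",
            f"effects: {self.effects}   identifiability: {self.mode}",
            f"parameters per participant: D={self.param_dim} "
            f"{self.blocks.breakdown()}",
            f"iterations: {len(self.trace)}   converged: {self.converged}"
            + ("   [partial: time limit]" if self.partial else ""),
            f"mean HMC acceptance: {self.diagnostics.get('accept_rate', float('nan')):.2f}",
            "",
            "Population-mean posterior percentiles (latent logit scale)",
            "-" * 46,
        ]
        res = predictive.predict(self, "population_mean", n_draws=n_draws, seed=seed)
        for name, pr in res.items():
            lines.append(f"[{name}]")
            lines.append(pr.table.round(3).to_string())
            lines.append("")
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    def save_fit(self, directory) -> Path:
        """Serialize the fitted model (samples + populations + manifest)."""
        directory = Path(directory)
        (directory / "samples").mkdir(parents=True, exist_ok=True)
        manifest = {
            "frame": self.frame.to_config(),
            "effects": [list(t) for t in self.effects.terms],
            "mode": self.mode,
            "participants": self.participants,
            "participant_groups": self.participant_groups,
            "trace": [float(x) for x in self.trace],
            "converged": bool(self.converged),
            "partial": bool(self.partial),
            "settings": self.settings,
            "diagnostics": self.diagnostics,
        }
        with open(directory / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        for pid, s in self.samples.items():
            np.savetxt(directory / "samples" / f"{pid}.csv", s, delimiter=",")
        for grp, pop in self.populations.items():
            payload = {
                "alpha0": pop.alpha0.tolist(),
                "alpha": pop.alpha.tolist(),
                "kappa": pop.kappa.tolist(),
                "m": pop.m.tolist(),
                "a": pop.a.tolist(),
                "b": pop.b.tolist(),
                "hyper": {
                    "weight_conc": pop.hyper.weight_conc,
                    "mean_scale": pop.hyper.mean_scale,
                    "prec_shape": pop.hyper.prec_shape,
                    "prior_scale": pop.hyper.prior_scale,
                },
            }
            with open(directory / f"population_{grp}.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(payload, fh)
        return directory

    @classmethod
    def load_fit(cls, directory) -> "EmaResults":
        directory = Path(directory)
        with open(directory / "manifest.yaml", "r", encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh)
        frame = EmaFrame.from_config(manifest["frame"])
        effects = EffectSpec(manifest["effects"])
        from .design import design_matrix
        from .likelihood import ParamBlocks

        design = design_matrix(effects, frame)
        blocks = ParamBlocks(frame=frame, spec=effects, n_effect_params=design.n_params)
        samples = {}
        for pid in manifest["participants"]:
            s = np.loadtxt(directory / "samples" / f"{pid}.csv", delimiter=",", ndmin=2)
            samples[pid] = s
        populations = {}
        for f in sorted(directory.glob("population_*.yaml")):
            grp = f.stem[len("population_"):]
            with open(f, "r", encoding="utf-8") as fh:
                p = yaml.safe_load(fh)
            populations[grp] = PopulationGMM(
                alpha=np.array(p["alpha"]), kappa=np.array(p["kappa"]),
                m=np.array(p["m"]), a=np.array(p["a"]), b=np.array(p["b"]),
                hyper=GmmHyper(**p["hyper"]),
                alpha0=np.array(p["alpha0"]) if "alpha0" in p else None,
            )
        return cls(
            frame=frame, effects=effects, mode=manifest["mode"], design=design,
            blocks=blocks, participants=list(manifest["participants"]),
            participant_groups=dict(manifest["participant_groups"]),
            samples=samples, populations=populations,
            trace=list(manifest["trace"]), converged=manifest["converged"],
            partial=manifest["partial"], settings=manifest["settings"],
            diagnostics=manifest.get("diagnostics", {}), dataset=None,
        )
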