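"""Metropolis Monte Carlo refinement of microscopic pKa's and binding free
energies against macroscopic observables.

Targets are either bound fractions over a (pH, free Zn2+) grid — as
measured by a binding assay — or metal-free microstate probability
distributions over a pH ladder, as sampled by constant-pH simulations.
Each MC step perturbs every free microscopic parameter with an independent
uniform draw (residues constrained to a tie group share one draw and stay
exactly equal), re-projects the potential graph so the trial model is
thermodynamically consistent, and accepts with the Metropolis criterion
P = min(1, exp(-dRMSD / r)) at a small fictional temperature r.  A
zero-temperature variant (accept only improvements, stop once a trailing
window sees no acceptance) is used to calibrate RMSD cutoffs.

Because binding isotherms alone under-determine the microscopic model,
refinement is meaningful only as a correction of physically sensible
starting values; a run that cannot reach its cutoff is returned flagged,
never silently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import ProtonationEdge, SiteModel

#: default RMSD convergence cutoffs keyed by (target kind, site label)
DEFAULT_CUTOFFS = {
    ("cphmd", "A"): 0.0382,
    ("cphmd", "B"): 0.0447,
    ("mst", "A"): 0.0760,
    ("mst", "B"): 0.0995,
}


# ---------------------------------------------------------------------------
# Targets


@dataclass
class BoundFractionTarget:
    """Bound fractions on a list of (pH, free Zn2+) conditions."""

    ph: np.ndarray
    zn_molar: np.ndarray
    values: np.ndarray
    kind: str = field(default="mst", init=False)

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float).ravel()
        self.zn_molar = np.asarray(self.zn_molar, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not (self.ph.size == self.zn_molar.size == self.values.size):
            raise ValueError("ph, zn_molar and values must have equal length")
        if self.ph.size == 0:
            raise ValueError("target grid is empty")
        if np.any((self.values < -1e-9) | (self.values > 1 + 1e-9)):
            raise ValueError("bound fractions must lie in [0, 1]")


@dataclass
class MicrostateTarget:
    """Metal-free protonation-state distributions over a pH ladder.

    ``probs`` has shape (n_ph, 2^R) with rows summing to 1 (states indexed
    little-endian in residue order).
    """

    ph: np.ndarray
    probs: np.ndarray
    x_molar: float = 1e-20
    kind: str = field(default="cphmd", init=False)

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float).ravel()
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[0] != self.ph.size:
            raise ValueError("one probability row per pH required")
        if self.ph.size == 0:
            raise ValueError("target grid is empty")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


InferenceTarget = Union[BoundFractionTarget, MicrostateTarget]


def _model_observable(model: SiteModel, target: InferenceTarget) -> np.ndarray:
    if isinstance(target, BoundFractionTarget):
        return model.bound_fractions(target.ph, target.zn_molar)
    n_states = 1 << model.n_residues
    if target.probs.shape[1] != n_states:
        raise ValueError(
            f"target has {target.probs.shape[1]} states per pH but the model "
            f"enumerates {n_states}"
        )
    return model.unbound_distributions(target.ph, target.x_molar).ravel()


def _target_values(target: InferenceTarget) -> np.ndarray:
    if isinstance(target, BoundFractionTarget):
        return target.values
    return target.probs.ravel()


def rmsd_objective(model: SiteModel, target: InferenceTarget) -> float:
    """Root-mean-square deviation between computed and target observables.

    Microstate targets concatenate all state probabilities over all pH
    points; every entry is weighted equally.
    """
    diff = _model_observable(model, target) - _target_values(target)
    return float(np.sqrt(np.mean(diff * diff)))


# ---------------------------------------------------------------------------
# Free-parameter space with tie constraints


def _tie_permutations(model: SiteModel):
    """Composite name-permutations generated by the model's tie groups."""
    groups: Dict[str, List[str]] = {}
    for r in model.residues:
        if r.tie_group:
            groups.setdefault(r.tie_group, []).append(r.name)
    per_group = []
    for members in groups.values():
        per_group.append([dict(zip(members, p)) for p in itertools.permutations(members)])
    perms = []
    for combo in itertools.product(*per_group) if per_group else [()]:
        mapping = {}
        for d in combo:
            mapping.update(d)
        perms.append(mapping)
    return perms or [{}]


def _edge_signature(edge, mapping):
    rename = lambda n: mapping.get(n, n)
    ctx = tuple(sorted((rename(k), v) for k, v in edge.context))
    if isinstance(edge, ProtonationEdge):
        return ("p", rename(edge.residue), bool(edge.zn_bound), ctx)
    return ("b", ctx)


class ParameterSpace:
    """Free parameters of a site model under its tie constraints.

    Edges whose signatures map onto each other under a permutation of
    tie-group members form one equivalence class sharing a single free
    parameter; a proposal perturbs each class with one draw, so tied
    residues remain exactly equal after every update.
    """

    def __init__(self, model: SiteModel, symmetrize: bool = False, atol: float = 1e-9):
        self.model = model
        perms = _tie_permutations(model)
        canon: Dict[tuple, int] = {}
        classes: List[List[int]] = []
        for k, e in enumerate(model.edges):
            key = min(_edge_signature(e, m) for m in perms)
            if key not in canon:
                canon[key] = len(classes)
                classes.append([])
            classes[canon[key]].append(k)
        self.classes = classes
        self.kinds = tuple(
            "pka" if isinstance(model.edges[c[0]], ProtonationEdge) else "dg0"
            for c in classes
        )
        raw = model.edge_values
        init = np.empty(len(classes))
        for ci, members in enumerate(classes):
            vals = raw[members]
            if np.ptp(vals) > atol:
                if not symmetrize:
                    raise ValueError(
                        f"tie-constrained parameters differ within a class "
                        f"(spread {np.ptp(vals):.3g}); pass symmetrize=True to "
                        f"average them"
                    )
            init[ci] = vals.mean()
        self.initial = init
        self.names = tuple(self._class_name(c[0]) for c in classes)

    def _class_name(self, edge_index: int) -> str:
        e = self.model.edges[edge_index]
        ctx = ",".join(f"{k}={v}" for k, v in e.context)
        if isinstance(e, ProtonationEdge):
            branch = "Zn" if e.zn_bound else "apo"
            return f"pKa({e.residue}|{ctx}|{branch})"
        return f"dG0({ctx})"

    @property
    def n_free(self) -> int:
        return len(self.classes)

    def _edge_values(self, theta: np.ndarray) -> np.ndarray:
        values = np.empty(len(self.model.edges))
        for ci, members in enumerate(self.classes):
            values[members] = theta[ci]
        return values

    def build(self, theta: np.ndarray) -> SiteModel:
        """Model with class parameters theta, consistency re-projected."""
        return self.model.with_edge_values(self._edge_values(theta))


class _FastObjective:
    """Vectorized RMSD evaluation reusing the cached graph factorization.

    Equivalent to ``rmsd_objective(space.build(theta), target)`` but skips
    rebuilding edge dataclasses: raw intrinsic edge values (-ln10 * pKa or
    dG0) are projected to potentials directly and the observable field
    matrix over the target grid is precomputed once.
    """

    def __init__(self, space: ParameterSpace, target: InferenceTarget):
        from .model import LN10

        model = space.model
        self.space = space
        self._pka_sign = np.array(
            [
                -LN10 if isinstance(e, ProtonationEdge) else 1.0
                for e in model.edges
            ]
        )
        self._projector = model._projector
        n_prot = model._n_protons
        half = 1 << model.n_residues
        if isinstance(target, BoundFractionTarget):
            self._micro = False
            self._field = (
                n_prot[:, None] * LN10 * target.ph[None, :]
                - model._zn_flag[:, None] * np.log(target.zn_molar)[None, :]
            )
            self._half = half
        else:
            if target.probs.shape[1] != half:
                raise ValueError(
                    f"target has {target.probs.shape[1]} states per pH but "
                    f"the model enumerates {half}"
                )
            self._micro = True
            self._field = n_prot[:half, None] * LN10 * target.ph[None, :]
            self._half = half
        self._y = _target_values(target)

    def __call__(self, theta: np.ndarray) -> float:
        from scipy.special import logsumexp

        raw = self.space._edge_values(theta) * self._pka_sign
        g = self._projector.project(raw)
        if self._micro:
            G = g[: self._half, None] + self._field
            obs = np.exp(-G - logsumexp(-G, axis=0)[None, :]).T.ravel()
        else:
            G = g[:, None] + self._field
            obs = np.exp(
                logsumexp(-G[self._half :], axis=0) - logsumexp(-G, axis=0)
            )
        d = obs - self._y
        return float(np.sqrt(np.mean(d * d)))


def propose(
    theta: np.ndarray,
    rng: np.random.Generator,
    kinds: Sequence[str],
    step_pka: float = 0.2,
    step_dg: float = 0.2,
) -> np.ndarray:
    """Uniform perturbation of every free parameter.

    Each class receives one independent draw from U(-step, +step) with the
    half-width chosen by parameter kind (pKa units or kBT).
    """
    steps = np.where(np.asarray(kinds) == "pka", step_pka, step_dg)
    return theta + rng.uniform(-1.0, 1.0, size=len(theta)) * steps


# ---------------------------------------------------------------------------
# MC driver


@dataclass
class MCConfig:
    """Settings of the Metropolis refinement.

    ``mode`` is "finite" (Metropolis at fictional temperature ``r``,
    running until the RMSD drops below ``cutoff``) or "zero" (accept only
    improvements, stop once no proposal was accepted within the trailing
    ``stall_window`` steps).  Step half-widths are 0.2 pKa units / 0.2 kBT.
    """

    mode: str = "finite"
    r: float = 1e-4
    step_pka: float = 0.2
    step_dg: float = 0.2
    cutoff: float = DEFAULT_CUTOFFS[("mst", "A")]
    max_steps: int = 2000
    stall_window: int = 100
    n_runs: int = 50
    seed: int = 0
    symmetrize: bool = False

    def __post_init__(self):
        if self.mode not in ("finite", "zero"):
            raise ValueError(f"mode must be 'finite' or 'zero', got {self.mode!r}")
        if self.mode == "finite" and self.r <= 0:
            raise ValueError("fictional temperature r must be positive")
        if self.cutoff <= 0:
            raise ValueError("RMSD cutoff must be positive")


@dataclass
class MCResult:
    """One refinement run: final free parameters and diagnostics."""

    theta: np.ndarray
    names: Tuple[str, ...]
    rmsd: float
    initial_rmsd: float
    accepted: np.ndarray
    rmsd_trace: np.ndarray
    steps: int
    converged: bool
    seed: Optional[int] = None

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if self.accepted.size else 0.0


def mc_minimize(
    model: SiteModel,
    target: InferenceTarget,
    config: MCConfig,
    rng: Optional[np.random.Generator] = None,
    space: Optional[ParameterSpace] = None,
) -> MCResult:
    """Single Metropolis run from the supplied (consistent) initial model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if space is None:
        space = ParameterSpace(model, symmetrize=config.symmetrize)
    objective = _FastObjective(space, target)
    theta = space.initial.copy()
    rmsd = objective(theta)
    initial_rmsd = rmsd
    accepted: List[bool] = []
    trace: List[float] = [rmsd]
    since_accept = 0
    steps = 0
    while steps < config.max_steps:
        if config.mode == "finite" and rmsd <= config.cutoff:
            break
        if config.mode == "zero" and since_accept >= config.stall_window:
            break
        trial = propose(theta, rng, space.kinds, config.step_pka, config.step_dg)
        trial_rmsd = objective(trial)
        d = trial_rmsd - rmsd
        if config.mode == "zero":
            ok = d < 0
        else:
            ok = d < 0 or rng.random() < math.exp(-d / config.r)
        if ok:
            theta, rmsd = trial, trial_rmsd
            since_accept = 0
        else:
            since_accept += 1
        accepted.append(ok)
        trace.append(rmsd)
        steps += 1
    converged = rmsd <= config.cutoff
    return MCResult(
        theta=theta,
        names=space.names,
        rmsd=rmsd,
        initial_rmsd=initial_rmsd,
        accepted=np.array(accepted, dtype=bool),
        rmsd_trace=np.array(trace),
        steps=steps,
        converged=converged,
    )


@dataclass
class RunEnsemble:
    """Results of independent MC runs plus the shared parameter space."""

    results: List[MCResult]
    space: ParameterSpace

    def __post_init__(self):
        if not self.results:
            raise ValueError("ensemble needs at least one run")

    @property
    def thetas(self) -> np.ndarray:
        return np.vstack([r.theta for r in self.results])

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.results)


def run_ensemble(
    model: SiteModel, target: InferenceTarget, config: MCConfig
) -> RunEnsemble:
    """Independent runs with sub-seeds derived from config.seed."""
    space = ParameterSpace(model, symmetrize=config.symmetrize)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    results = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        res = mc_minimize(model, target, config, rng=rng, space=space)
        res.seed = i
        results.append(res)
    return RunEnsemble(results, space)


def aggregate_runs(ensemble: RunEnsemble) -> pd.DataFrame:
    """Per-parameter ensemble mean and standard deviation (n-1 denominator).

    The spread is a variability indicator over independent runs, not a
    rigorous statistical error.
    """
    th = ensemble.thetas
    mean = th.mean(axis=0)
    sd = th.std(axis=0, ddof=1) if th.shape[0] > 1 else np.zeros(th.shape[1])
    return pd.DataFrame(
        {
            "parameter": ensemble.space.names,
            "kind": ensemble.space.kinds,
            "mean": mean,
            "sd": sd,
            "n_runs": th.shape[0],
            "n_converged": ensemble.n_converged,
        }
    )


# ---------------------------------------------------------------------------
# Estimator facade


class MicrostateInference(BaseEstimator):
    """Refine a microstate model against bound-fraction data (sklearn API).

    Parameters mirror :class:`MCConfig`; ``initial_model`` supplies the
    starting microscopic parameters (physically sensible initialization is
    required — isotherms alone do not determine the microscopic model).

    ``fit(X, y)`` takes ``X`` of shape (n, 2) with columns (pH, free Zn2+
    molar) and ``y`` the measured bound fractions.  Use
    :meth:`fit_microstates` for simulation-style distribution targets.

    Fitted attributes: ``ensemble_``, ``summary_`` (parameter, mean, sd),
    ``model_`` (ensemble-mean-parameter model), ``n_converged_``,
    ``param_names_``.
    """

    def __init__(
        self,
        initial_model: Optional[SiteModel] = None,
        mode: str = "finite",
        r: float = 1e-4,
        step_pka: float = 0.2,
        step_dg: float = 0.2,
        cutoff: float = DEFAULT_CUTOFFS[("mst", "A")],
        max_steps: int = 2000,
        stall_window: int = 100,
        n_runs: int = 50,
        random_state: int = 0,
        symmetrize: bool = False,
    ):
        self.initial_model = initial_model
        self.mode = mode
        self.r = r
        self.step_pka = step_pka
        self.step_dg = step_dg
        self.cutoff = cutoff
        self.max_steps = max_steps
        self.stall_window = stall_window
        self.n_runs = n_runs
        self.random_state = random_state
        self.symmetrize = symmetrize

    def _config(self) -> MCConfig:
        return MCConfig(
            mode=self.mode,
            r=self.r,
            step_pka=self.step_pka,
            step_dg=self.step_dg,
            cutoff=self.cutoff,
            max_steps=self.max_steps,
            stall_window=self.stall_window,
            n_runs=self.n_runs,
            seed=self.random_state,
            symmetrize=self.symmetrize,
        )

    def _fit_target(self, target: InferenceTarget):
        if self.initial_model is None:
            raise ValueError("initial_model is required")
        ensemble = run_ensemble(self.initial_model, target, self._config())
        self.ensemble_ = ensemble
        self.summary_ = aggregate_runs(ensemble)
        self.param_names_ = ensemble.space.names
        self.n_converged_ = ensemble.n_converged
        self.model_ = ensemble.space.build(
            np.asarray(self.summary_["mean"].to_numpy())
        )
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (pH, free Zn2+ molar)")
        target = BoundFractionTarget(X[:, 0], X[:, 1], np.asarray(y, dtype=float))
        return self._fit_target(target)

    def fit_microstates(self, ph, probs, x_molar: float = 1e-20):
        return self._fit_target(MicrostateTarget(ph, probs, x_molar))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.array(
            [self.model_.bound_fraction(p, x) for p, x in X]
        )
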