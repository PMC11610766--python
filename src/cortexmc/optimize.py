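"""Differential-evolution selection of optimal wavelength combinations.

The task: pick ``k`` wavelengths out of the 601-point 1-nm grid on
400-1000 nm that minimize the quantification error of the modified
Beer-Lambert inversion under instrument noise.  The cost of a candidate set
is the root-mean-square error (in M) between the noisy concentration-change
estimates and the ground truth, summed over the chromophore subset (joint
mode) or taken for a single target chromophore (separate mode).

Candidates are continuous k-vectors rounded onto the wavelength grid inside
the cost function; sets that collapse below the number of chromophores
after deduplication, or whose design is numerically rank-deficient, receive
a large finite penalty instead of an exception.  A single noise realization
(common random numbers) is shared across all candidate evaluations of one
optimization so the comparison between sets is consistent and the optimum
reproducible.  An exhaustive search over small restricted grids provides
the ground-truth optimum for validation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .quantify import (ActivationModel, MBLLSystem, NoiseModel,
                       attenuation_change, mbll_solve, rmse)
from .spectra import ExtinctionLibrary

__all__ = [
    "LITERATURE_CONFIGS",
    "QuantificationContext",
    "OptimizationProblem",
    "OptimizationResult",
    "cost_function",
    "optimize_de",
    "exhaustive_search",
    "run_separate_mode",
    "evaluate_config",
]

#: published wavelength sets used as comparison configurations (nm)
LITERATURE_CONFIGS: dict[str, tuple[int, ...]] = {
    "bouchard": (470, 530),
    "white": (470, 530, 590, 625),
    "bale": tuple(range(780, 901)),          # broadband, 121 wavelengths
    "arifler": (784, 800, 818, 835, 851, 868, 881, 894),
    "separate_hemoglobin": (468, 482, 610, 753, 814, 907),
    "separate_oxcco": (608, 650, 661, 672, 820, 865),
}

_PENALTY = 10.0  # M; far above any achievable RMSE sum


@dataclass
class QuantificationContext:
    """Rest/activity reflectance and rest path-length spectra on a 1-nm grid.

    The spectra are pooled over the evaluated pixel region (or belong to a
    single pixel); ``activation`` carries the ground-truth concentration
    changes the errors are measured against.
    """

    wavelengths: np.ndarray          # 1-nm grid, nm
    phi_rest: np.ndarray
    phi_activity: np.ndarray
    pathlength_mm: np.ndarray
    lib: ExtinctionLibrary
    activation: ActivationModel = field(default_factory=ActivationModel)

    def __post_init__(self):
        n = self.wavelengths.size
        for name in ("phi_rest", "phi_activity", "pathlength_mm"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} does not match the wavelength grid")

    def sample(self, wavelengths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.wavelengths, np.asarray(wavelengths))
        if not np.allclose(self.wavelengths[idx], wavelengths):
            raise ValueError("requested wavelengths are not on the context grid")
        return (self.phi_rest[idx], self.phi_activity[idx],
                self.pathlength_mm[idx])


@dataclass(frozen=True)
class OptimizationProblem:
    """What to optimize: k wavelengths for a chromophore subset.

    ``mode='joint'`` sums the per-chromophore RMSEs of the whole subset;
    ``mode='separate'`` scores only ``target`` (which must be in the
    subset).  ``allowed_wavelengths`` restricts candidates to a sub-grid
    (used by the exhaustive cross-check); by default the full 1-nm grid of
    the context is allowed.
    """

    k: int
    chromophores: tuple[str, ...]
    mode: str = "joint"
    target: str | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    bounds: tuple[float, float] = (400.0, 1000.0)
    allowed_wavelengths: tuple[float, ...] | None = None
    popsize: int = 15
    maxiter: int = 200
    tol: float = 1e-8
    de_seed: int = 0

    def __post_init__(self):
        if self.k < len(self.chromophores):
            raise ValueError("k must be >= the number of chromophores")
        if self.mode not in ("joint", "separate"):
            raise ValueError("mode must be 'joint' or 'separate'")
        if self.mode == "separate":
            if self.target is None or self.target not in self.chromophores:
                raise ValueError("separate mode needs a target in the subset")


@dataclass
class OptimizationResult:
    wavelengths: tuple[float, ...]
    cost_M: float
    rmse_uM: dict[str, float]
    n_evaluations: int
    converged: bool
    de_seed: int
    noise_seed: int
    target: str | None = None


def _snap(candidate, problem: OptimizationProblem,
          context: QuantificationContext) -> np.ndarray:
    """Round a continuous candidate onto the allowed wavelength grid."""
    cand = np.clip(np.asarray(candidate, dtype=float),
                   problem.bounds[0], problem.bounds[1])
    if problem.allowed_wavelengths is not None:
        grid = np.asarray(problem.allowed_wavelengths, dtype=float)
        idx = np.abs(cand[:, None] - grid[None, :]).argmin(axis=1)
        cand = grid[idx]
    else:
        cand = np.round(cand)
        lo = context.wavelengths.min()
        hi = context.wavelengths.max()
        cand = np.clip(cand, lo, hi)
    return np.unique(cand)


def _shared_normals(problem: OptimizationProblem) -> np.ndarray:
    rng = np.random.default_rng(problem.noise.seed)
    return rng.standard_normal((problem.noise.n_noise, problem.k, 2))


def _evaluate(wavelengths: np.ndarray, problem: OptimizationProblem,
              context: QuantificationContext,
              normals: np.ndarray) -> tuple[float, dict[str, float]]:
    phi_r, phi_a, L = context.sample(wavelengths)
    system = MBLLSystem.build(wavelengths, L, context.lib, problem.chromophores)
    if np.linalg.matrix_rank(system.matrix) < len(problem.chromophores):
        return _PENALTY, {}
    dA = attenuation_change(phi_r, phi_a, problem.noise,
                            normals=normals[:, :wavelengths.size, :])
    dc = mbll_solve(dA, system)
    gt = context.activation.ground_truth_M(problem.chromophores)
    err = rmse(dc, gt)
    per_chrom = {c: float(err[i] * 1e6)
                 for i, c in enumerate(problem.chromophores)}
    if problem.mode == "separate":
        cost = float(err[problem.chromophores.index(problem.target)])
    else:
        cost = float(err.sum())
    return cost, per_chrom


def cost_function(candidate, problem: OptimizationProblem,
                  context: QuantificationContext,
                  normals: np.ndarray | None = None) -> float:
    """Cost (RMSE in M) of a candidate wavelength vector.

    Wavelength order is irrelevant; candidates that collapse below k
    distinct wavelengths after grid rounding are penalized (the caller
    asked for k usable spectral bands).
    """
    if normals is None:
        normals = _shared_normals(problem)
    lam = _snap(candidate, problem, context)
    if lam.size < max(problem.k, len(problem.chromophores)):
        return _PENALTY
    cost, _ = _evaluate(lam, problem, context, normals)
    return cost


def optimize_de(problem: OptimizationProblem,
                context: QuantificationContext) -> OptimizationResult:
    """Differential evolution over k continuous wavelengths."""
    normals = _shared_normals(problem)
    n_eval = 0

    def f(x):
        nonlocal n_eval
        n_eval += 1
        return cost_function(x, problem, context, normals)

    res = differential_evolution(
        f, bounds=[problem.bounds] * problem.k,
        seed=problem.de_seed, popsize=problem.popsize,
        maxiter=problem.maxiter, tol=problem.tol, polish=False)
    best = _snap(res.x, problem, context)
    cost, per_chrom = _evaluate(best, problem, context, normals)
    return OptimizationResult(
        wavelengths=tuple(float(w) for w in np.sort(best)),
        cost_M=cost, rmse_uM=per_chrom, n_evaluations=n_eval,
        converged=bool(res.success), de_seed=problem.de_seed,
        noise_seed=problem.noise.seed, target=problem.target)


def exhaustive_search(problem: OptimizationProblem,
                      context: QuantificationContext,
                      grid: Sequence[float],
                      max_combinations: int = 200_000) -> OptimizationResult:
    """True optimum over all k-combinations of a restricted grid."""
    grid = np.asarray(sorted(grid), dtype=float)
    from math import comb
    n_comb = comb(grid.size, problem.k)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed the cap of {max_combinations}; "
            f"use differential evolution instead")
    normals = _shared_normals(problem)
    best_cost = np.inf
    best_set: tuple[float, ...] = ()
    best_per: dict[str, float] = {}
    n_eval = 0
    for combo in itertools.combinations(grid, problem.k):
        lam = np.asarray(combo)
        cost, per = _evaluate(lam, problem, context, normals)
        n_eval += 1
        if cost < best_cost:
            best_cost, best_set, best_per = cost, combo, per
    return OptimizationResult(
        wavelengths=tuple(float(w) for w in best_set),
        cost_M=float(best_cost), rmse_uM=best_per, n_evaluations=n_eval,
        converged=True, de_seed=problem.de_seed,
        noise_seed=problem.noise.seed, target=problem.target)


def run_separate_mode(k: int, context: QuantificationContext,
                      noise: NoiseModel | None = None,
                      de_seed: int = 0) -> dict[str, OptimizationResult]:
    """Optimize one wavelength set per chromophore target.

    The hemoglobins share a two-chromophore inversion scored on the sum of
    both errors; each cytochrome target is scored on its own error with
    {HbO2, Hb, target} in the design.
    """
    noise = noise or NoiseModel()
    out: dict[str, OptimizationResult] = {}
    hem = OptimizationProblem(k=k, chromophores=("HbO2", "Hb"), mode="joint",
                              noise=noise, de_seed=de_seed)
    res = optimize_de(hem, context)
    out["HbO2"] = res
    out["Hb"] = res
    for target in ("oxCCO", "oxCytb", "oxCytc"):
        prob = OptimizationProblem(
            k=k, chromophores=("HbO2", "Hb", target), mode="separate",
            target=target, noise=noise, de_seed=de_seed)
        out[target] = optimize_de(prob, context)
    return out


def evaluate_config(wavelengths: Sequence[float] | str,
                    context: QuantificationContext,
                    chromophores: Sequence[str],
                    noise: NoiseModel | None = None) -> dict[str, float]:
    """Per-chromophore RMSE (uM) of a fixed wavelength configuration.

    ``wavelengths`` may be a named literature configuration or an explicit
    list on the context grid.
    """
    if isinstance(wavelengths, str):
        wavelengths = LITERATURE_CONFIGS[wavelengths]
    lam = np.asarray(sorted(wavelengths), dtype=float)
    noise = noise or NoiseModel()
    problem = OptimizationProblem(
        k=lam.size, chromophores=tuple(chromophores), noise=noise)
    normals = _shared_normals(problem)
    _, per_chrom = _evaluate(lam, problem, context, normals)
    if not per_chrom:
        raise np.linalg.LinAlgError("rank-deficient configuration")
    return per_chrom
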