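"""Dominant-wavelet selection.

Three stages pick the wavelet subset that enters the fuzzy model:

1. :func:`ols_rank` -- classical forward orthogonal least squares (modified
   Gram-Schmidt).  The linear input regressors are *forced* terms,
   orthogonalised first; every lattice candidate is then greedily ranked by
   its error-reduction ratio (ERR), the fraction of residual energy it
   explains after the terms already in the model.
2. :func:`choose_wavelet_count` -- for n = 1..N_max, fit linear regressors +
   the top-n ranked wavelets by least squares on a chronological training
   split and evaluate RMSE on the held-out validation tail; the n with the
   smallest validation RMSE wins (smallest n on ties).
3. :func:`ga_refine` -- an integer-chromosome genetic algorithm searches for
   an n-subset of the lattice with lower validation RMSE, seeded with the
   OLS choice; elitism guarantees the result is never worse than the seed.

There is deliberately no intercept column: the model output is a pure linear
combination of regressors and wavelet responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAConfig",
    "SelectionConfig",
    "ols_rank",
    "ls_fit",
    "choose_wavelet_count",
    "ga_refine",
]


@dataclass
class GAConfig:
    """Genetic-algorithm settings for wavelet-subset refinement."""

    population_size: int = 1000
    generations: int = 40
    tolerance: float = 1e-5
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/n per gene
    tournament_size: int = 3
    patience: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("GA population must be at least 2")
        if self.generations < 1:
            raise ValueError("GA needs at least one generation")


@dataclass
class SelectionConfig:
    """Settings for the whole dominant-wavelet selection stage."""

    scale_range: tuple[int, int] = (-4, 4)
    max_centers_per_scale: int = 100
    max_terms: int = 40
    validation_fraction: float = 0.2
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")


def ls_fit(F: np.ndarray, C: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of ``y`` on ``[F | C]``; returns (coef, residual vector)."""
    X = np.hstack([F, C]) if C.size else np.asarray(F)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, y - X @ coef


def ols_rank(
    candidates: np.ndarray,
    forced: np.ndarray,
    y: np.ndarray,
    max_terms: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward OLS ranking of candidate columns with forced regressors.

    Parameters
    ----------
    candidates : (N, K) candidate columns (wavelet responses).
    forced : (N, m) columns always in the model (linear regressors); may have
        zero columns.
    y : (N,) target.
    max_terms : stop after ranking this many candidates (default: all).

    Returns
    -------
    order : int array of candidate indices in greedy selection order.
    errs : error-reduction ratio of each selected term, measured against the
        residual energy remaining after the forced columns.

    Ties are broken toward the lower candidate index; all-zero candidate
    columns (after orthogonalisation, numerically degenerate ones too) are
    skipped with a warning.
    """
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    F = np.asarray(forced, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = np.asarray(y, dtype=float).ravel()
    N, K = C.shape
    if np.var(y) == 0.0:
        raise ValueError("target has zero variance")
    if max_terms is None:
        max_terms = K
    max_terms = min(max_terms, K)

    # Orthogonalise the forced columns (MGS) and deflate y and the candidates.
    y_res = y.copy()
    W = C.copy()
    for j in range(F.shape[1]):
        q = F[:, j].copy()
        # re-orthogonalise against previously processed forced columns
        for jj in range(j):
            qq = F[:, jj]
            nq = qq @ qq
            if nq > 0:
                q -= (qq @ q) / nq * qq
        F[:, j] = q
        nq = q @ q
        if nq <= 1e-14 * N:
            continue
        y_res -= (q @ y_res) / nq * q
        W -= np.outer(q, (q @ W) / nq)

    denom = float(y_res @ y_res)
    if denom <= 1e-20 * float(y @ y):
        # forced columns already explain y to machine precision: ranking
        # candidates against pure rounding noise would select junk terms
        return np.arange(0), np.zeros(0)

    col_norm0 = np.sqrt(np.einsum("ij,ij->j", C, C))
    alive = col_norm0 > 1e-12
    if not alive.all():
        warnings.warn(
            f"{int((~alive).sum())} all-zero candidate column(s) skipped", stacklevel=2
        )

    order: list[int] = []
    errs: list[float] = []
    for _ in range(max_terms):
        norms = np.einsum("ij,ij->j", W, W)
        ok = alive & (norms > 1e-12 * np.maximum(col_norm0, 1.0) ** 2)
        if not ok.any():
            break
        proj = W.T @ y_res
        score = np.where(ok, proj ** 2 / np.where(ok, norms, 1.0), -np.inf)
        k = int(np.argmax(score))  # argmax takes the first max -> lowest index on ties
        if not np.isfinite(score[k]) or score[k] <= 0.0:
            # no candidate reduces the residual further
            if score[k] < 0.0 or not np.isfinite(score[k]):
                break
        order.append(k)
        errs.append(float(score[k] / denom))
        q = W[:, k].copy()
        nq = norms[k]
        alive[k] = False
        y_res -= (q @ y_res) / nq * q
        W -= np.outer(q, (q @ W) / nq)
        W[:, k] = 0.0
    return np.asarray(order, dtype=int), np.asarray(errs)


def _val_split(N: int, validation_fraction: float) -> int:
    n_val = max(1, int(round(N * validation_fraction)))
    n_train = N - n_val
    if n_train < 1:
        raise ValueError("training split is empty")
    return n_train


def choose_wavelet_count(
    C: np.ndarray,
    F: np.ndarray,
    y: np.ndarray,
    order: np.ndarray,
    max_terms: int,
    validation_fraction: float = 0.2,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Pick the wavelet count minimising validation RMSE over nested prefixes.

    The data is split chronologically: the last ``validation_fraction`` of
    rows is the validation tail (time-series convention, no shuffling).
    Returns ``(n_star, selected_indices, rmse_curve)`` where ``rmse_curve[n-1]``
    is the validation RMSE with the top-n wavelets.
    """
    order = np.asarray(order, dtype=int)
    if max_terms > order.size:
        warnings.warn(
            f"max_terms={max_terms} exceeds the {order.size} ranked candidates; clamped",
            stacklevel=2,
        )
        max_terms = order.size
    if max_terms == 0:
        return 0, order[:0], np.zeros(0)
    N = y.shape[0]
    n_train = _val_split(N, validation_fraction)
    Ftr, Fva = F[:n_train], F[n_train:]
    ytr, yva = y[:n_train], y[n_train:]
    curve = np.empty(max_terms)
    for n in range(1, max_terms + 1):
        cols = order[:n]
        coef, _ = ls_fit(Ftr, C[:n_train, cols], ytr)
        pred = np.hstack([Fva, C[n_train:, cols]]) @ coef
        curve[n - 1] = float(np.sqrt(np.mean((yva - pred) ** 2)))
    # smallest n on ties, where "tie" tolerates floating-point noise
    thresh = curve.min() + 1e-12 + 1e-9 * abs(curve.min())
    n_star = int(np.nonzero(curve <= thresh)[0][0]) + 1
    return n_star, order[:n_star].copy(), curve


def _subset_fitness(cols, C, F, y, n_train, cache):
    key = tuple(sorted(int(c) for c in cols))
    hit = cache.get(key)
    if hit is not None:
        return hit
    coef, _ = ls_fit(F[:n_train], C[:n_train, list(key)], y[:n_train])
    pred = np.hstack([F[n_train:], C[n_train:, list(key)]]) @ coef
    val = float(np.sqrt(np.mean((y[n_train:] - pred) ** 2)))
    if not np.isfinite(val):
        val = np.inf
    cache[key] = val
    return val


def _repair(chrom: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Resample duplicate genes so the chromosome is a set of distinct indices."""
    seen = set()
    for i in range(chrom.size):
        g = int(chrom[i])
        while g in seen:
            g = int(rng.integers(0, K))
        seen.add(g)
        chrom[i] = g
    return chrom


def ga_refine(
    initial_indices: np.ndarray,
    C: np.ndarray,
    F: np.ndarray,
    y: np.ndarray,
    config: GAConfig,
    validation_fraction: float = 0.2,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """GA refinement of an n-subset of lattice candidates.

    Chromosome = n distinct candidate indices; fitness = validation RMSE of
    the least-squares fit with forced linear regressors (same chronological
    split as :func:`choose_wavelet_count`).  The population is seeded with
    the OLS selection and elitism keeps the best-so-far, so the returned
    subset is never worse than the initial one.

    Returns ``(best_indices, best_fitness, best_fitness_trace)``.
    """
    initial = np.asarray(initial_indices, dtype=int)
    n = initial.size
    K = C.shape[1]
    if n == 0:
        return initial, np.inf, np.zeros(0)
    if n > K:
        raise ValueError("subset size exceeds lattice size")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_train = _val_split(y.shape[0], validation_fraction)
    cache: dict[tuple, float] = {}
    fit = lambda ch: _subset_fitness(ch, C, F, y, n_train, cache)

    pop_size = config.population_size
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n
    pop = np.empty((pop_size, n), dtype=int)
    pop[0] = initial
    for i in range(1, pop_size):
        ch = initial.copy()
        flip = rng.random(n) < 0.5
        ch[flip] = rng.integers(0, K, size=int(flip.sum()))
        pop[i] = _repair(ch, K, rng)
    fitness = np.array([fit(ch) for ch in pop])

    best_i = int(np.argmin(fitness))
    best, best_f = pop[best_i].copy(), float(fitness[best_i])
    trace = [best_f]
    stall = 0
    for _ in range(config.generations):
        new_pop = np.empty_like(pop)
        new_pop[0] = best  # elitism
        for i in range(1, pop_size):
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, pop_size, size=config.tournament_size)
                parents.append(pop[idx[np.argmin(fitness[idx])]])
            p1, p2 = parents
            if rng.random() < config.crossover_rate:
                mask = rng.random(n) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mmask = rng.random(n) < mut
            if mmask.any():
                child = child.copy()
                child[mmask] = rng.integers(0, K, size=int(mmask.sum()))
            new_pop[i] = _repair(np.asarray(child, dtype=int).copy(), K, rng)
        pop = new_pop
        fitness = np.array([fit(ch) for ch in pop])
        gi = int(np.argmin(fitness))
        if fitness[gi] < best_f:
            improvement = best_f - float(fitness[gi])
            best, best_f = pop[gi].copy(), float(fitness[gi])
            stall = 0 if improvement >= config.tolerance else stall + 1
        else:
            stall += 1
        trace.append(best_f)
        if stall >= config.patience:
            break
    return np.sort(best), best_f, np.asarray(trace)
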