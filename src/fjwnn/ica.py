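"""Imperialist competitive algorithm (ICA) over a box-constrained real vector.

A population of "countries" (candidate solutions) is split into empires: the
best ``n_imperialists`` countries become imperialists, the rest colonies
allocated in proportion to imperialist power.  Each iteration:

* assimilation -- every colony moves toward its imperialist by a uniformly
  random step per dimension scaled by the assimilation coefficient;
* revolution  -- with a fixed probability a colony has a fraction of its
  genes re-randomised uniformly inside the box;
* exchange    -- a colony that becomes cheaper than its imperialist swaps
  roles with it;
* competition -- the weakest colony of the weakest empire (by total cost:
  imperialist cost plus a fraction of the mean colony cost) is handed to a
  probabilistically chosen stronger empire; an empire left with no colonies
  is absorbed.

The best imperialist cost is tracked per iteration; it is non-increasing.
Non-finite costs are treated as +inf so such candidates are never kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ICAConfig", "ica_optimize", "ICAResult"]


@dataclass
class ICAConfig:
    """Hyperparameters of the imperialist competitive algorithm."""

    max_iterations: int = 60
    population: int = 500
    n_imperialists: int = 5
    selection_pressure: float = 1.0
    assimilation_coeff: float = 1.5
    revolution_prob: float = 0.5
    revolution_rate: float = 0.3
    colonies_mean_cost_coeff: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if not self.population > self.n_imperialists >= 1:
            raise ValueError("population must exceed n_imperialists >= 1")


@dataclass
class ICAResult:
    x: np.ndarray
    cost: float
    trace: np.ndarray
    n_evaluations: int


def _safe_cost(fn, x) -> float:
    c = fn(x)
    return float(c) if np.isfinite(c) else np.inf


def ica_optimize(
    cost_fn,
    lo: np.ndarray,
    hi: np.ndarray,
    config: ICAConfig,
    seed: int | np.random.Generator | None = None,
    init_population: np.ndarray | None = None,
) -> ICAResult:
    """Minimise ``cost_fn`` over the box ``[lo, hi]``.

    ``init_population`` optionally supplies starting countries (rows); missing
    rows are drawn uniformly in the box.  Fully reproducible given a seed.
    """
    lo = np.asarray(lo, dtype=float).ravel()
    hi = np.asarray(hi, dtype=float).ravel()
    d = lo.size
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_pop = config.population
    pop = lo + (hi - lo) * rng.random((n_pop, d))
    if init_population is not None:
        init_population = np.atleast_2d(np.asarray(init_population, dtype=float))
        k = min(n_pop, init_population.shape[0])
        pop[:k] = np.clip(init_population[:k], lo, hi)
    costs = np.array([_safe_cost(cost_fn, x) for x in pop])
    n_eval = n_pop

    order = np.argsort(costs, kind="stable")
    pop, costs = pop[order], costs[order]
    n_imp = config.n_imperialists
    imp_x, imp_c = pop[:n_imp].copy(), costs[:n_imp].copy()
    col_x, col_c = pop[n_imp:].copy(), costs[n_imp:].copy()

    # Allocate colonies proportionally to normalised imperialist power.
    finite_max = imp_c[np.isfinite(imp_c)].max() if np.any(np.isfinite(imp_c)) else 1.0
    base = np.where(np.isfinite(imp_c), imp_c, finite_max)
    power = np.abs(base - base.max()) ** config.selection_pressure
    if power.sum() <= 0:
        power = np.ones(n_imp)
    share = power / power.sum()
    n_col = col_x.shape[0]
    counts = np.floor(share * n_col).astype(int)
    while counts.sum() < n_col:
        counts[int(np.argmax(share))] += 1
        share = share * 0.999  # spread remainder deterministically
    owner = np.repeat(np.arange(n_imp), counts)[:n_col]
    rng.shuffle(owner)

    best_x = imp_x[int(np.argmin(imp_c))].copy()
    best_c = float(imp_c.min())
    trace = [best_c]
    alive = list(range(n_imp))

    n_rev_genes = max(1, int(np.ceil(config.revolution_rate * d)))
    for _ in range(config.max_iterations):
        # --- assimilation + revolution, colony by colony (vectorised in d)
        beta = config.assimilation_coeff
        step = beta * rng.random(col_x.shape)
        col_x = col_x + step * (imp_x[owner] - col_x)
        rev = rng.random(n_col) < config.revolution_prob
        for i in np.nonzero(rev)[0]:
            genes = rng.choice(d, size=n_rev_genes, replace=False)
            col_x[i, genes] = lo[genes] + (hi[genes] - lo[genes]) * rng.random(n_rev_genes)
        np.clip(col_x, lo, hi, out=col_x)
        col_c = np.array([_safe_cost(cost_fn, x) for x in col_x])
        n_eval += n_col

        # --- colony/imperialist exchange
        for e in alive:
            mine = np.nonzero(owner == e)[0]
            if mine.size == 0:
                continue
            j = mine[int(np.argmin(col_c[mine]))]
            if col_c[j] < imp_c[e]:
                imp_x[e], col_x[j] = col_x[j].copy(), imp_x[e].copy()
                imp_c[e], col_c[j] = col_c[j], imp_c[e]

        # --- imperialistic competition
        if len(alive) > 1:
            totals = {}
            for e in alive:
                mine = np.nonzero(owner == e)[0]
                mean_col = float(np.mean(col_c[mine])) if mine.size else 0.0
                if not np.isfinite(mean_col):
                    mean_col = np.nanmax(col_c[np.isfinite(col_c)]) if np.any(np.isfinite(col_c)) else 0.0
                totals[e] = imp_c[e] + config.colonies_mean_cost_coeff * mean_col
            weakest = max(alive, key=lambda e: totals[e])
            mine = np.nonzero(owner == weakest)[0]
            others = [e for e in alive if e != weakest]
            tvals = np.array([totals[e] for e in others])
            norm = tvals - tvals.max()
            p = np.abs(norm)
            p = p / p.sum() if p.sum() > 0 else np.full(len(others), 1.0 / len(others))
            winner = others[int(np.argmax(p - rng.random(len(others))))]
            if mine.size > 0:
                j = mine[int(np.argmax(col_c[mine]))]
                owner[j] = winner
            else:
                # empire collapsed: its imperialist becomes a colony of the winner
                col_x = np.vstack([col_x, imp_x[weakest][None, :]])
                col_c = np.append(col_c, imp_c[weakest])
                owner = np.append(owner, winner)
                n_col += 1
                alive.remove(weakest)

        i_best = int(np.argmin(imp_c[alive]))
        e_best = alive[i_best]
        if imp_c[e_best] < best_c:
            best_c = float(imp_c[e_best])
            best_x = imp_x[e_best].copy()
        trace.append(best_c)

    return ICAResult(x=best_x, cost=best_c, trace=np.asarray(trace), n_evaluations=n_eval)
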