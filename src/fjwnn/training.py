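"""Hybrid training: least-squares consequents nested inside ICA.

The unknowns split into two groups, learned by different methods:

* membership means/std-devs, rule weights ``v`` and antecedent codes are
  encoded in a flat real genome and optimised by the imperialist
  competitive algorithm (:mod:`fjwnn.ica`);
* all sub-JWNN consequent weights are solved in closed form by a single
  joint linear least squares at *every* cost evaluation -- once firings and
  rule weights are fixed, the defuzzified output is linear in all consequent
  weights, so one global solve is exact.

The ICA cost is the training RMSE of that nested fit (a validation-cost
switch is provided).  After ICA converges, rules with weight below the
pruning threshold are removed and the consequents are re-solved on the
surviving rules.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .dataset import Dataset
from .ica import ICAConfig, ica_optimize
from .rules import FIRING_GUARD, SU_MIN, FuzzyRule, FuzzyRuleSystem
from .selection import SelectionConfig, choose_wavelet_count, ga_refine, ols_rank
from .wavelets import build_lattice

__all__ = [
    "InitConfig",
    "GenomeSpec",
    "decode_genome",
    "solve_consequent_ls",
    "fit_fjwnn",
    "FitReport",
]

logger = logging.getLogger(__name__)

# genome box constraints (normalised input units)
MU_LO, MU_HI = -0.5, 1.5
SU_HI = 2.0


@dataclass
class InitConfig:
    """Initial genome values: membership means drawn uniformly on the
    normalised input range, fixed initial std-dev, rule weight and
    antecedent code."""

    init_su: float = 0.2
    init_rule_weight: float = 0.7
    init_antecedent_code: int = 1
    mu_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if not self.init_su > 0:
            raise ValueError("initial membership std-dev must be positive")


@dataclass
class GenomeSpec:
    """Layout of the flat genome: mu block, su block, v block, code block."""

    m: int
    n_a: int

    @property
    def length(self) -> int:
        return 2 * self.m * self.n_a + self.n_a + self.n_a * self.m

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        mn = self.m * self.n_a
        lo = np.concatenate([
            np.full(mn, MU_LO), np.full(mn, SU_MIN),
            np.zeros(self.n_a), np.zeros(self.n_a * self.m),
        ])
        hi = np.concatenate([
            np.full(mn, MU_HI), np.full(mn, SU_HI),
            np.ones(self.n_a), np.full(self.n_a * self.m, self.n_a + 1 - 1e-9),
        ])
        return lo, hi

    def initial_population(
        self, size: int, init: InitConfig, rng: np.random.Generator
    ) -> np.ndarray:
        mn = self.m * self.n_a
        a, b = init.mu_range
        pop = np.empty((size, self.length))
        pop[:, :mn] = a + (b - a) * rng.random((size, mn))
        pop[:, mn:2 * mn] = init.init_su
        pop[:, 2 * mn:2 * mn + self.n_a] = init.init_rule_weight
        # code gene g decodes as floor(g); centre it inside its integer cell
        pop[:, 2 * mn + self.n_a:] = init.init_antecedent_code + 0.5
        return pop


def decode_genome(
    genome: np.ndarray, spec: GenomeSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decode a flat genome into (mu, su, v, codes).

    mu is unclamped, su clamped to >= SU_MIN, v clipped to [0, 1] and each
    antecedent code is the floor of its real gene clamped into {0..n_a}.
    Returns mu, su with shape (m, n_a), v with shape (n_a,), codes with
    shape (n_a, m).
    """
    genome = np.asarray(genome, dtype=float).ravel()
    if genome.size != spec.length:
        raise ValueError(f"genome length {genome.size} != expected {spec.length}")
    m, n_a = spec.m, spec.n_a
    mn = m * n_a
    mu = genome[:mn].reshape(m, n_a)
    su = np.maximum(genome[mn:2 * mn].reshape(m, n_a), SU_MIN)
    v = np.clip(genome[2 * mn:2 * mn + n_a], 0.0, 1.0)
    codes = np.clip(np.floor(genome[2 * mn + n_a:]), 0, n_a).astype(int).reshape(n_a, m)
    return mu, su, v, codes


def _firings(Xn, mu, su, codes) -> np.ndarray:
    """(N, n_a) firing strengths from decoded genome blocks."""
    N, m = Xn.shape
    n_a = codes.shape[0]
    # log-membership tensor, (N, m, n_a)
    z = (Xn[:, :, None] - mu[None, :, :]) / su[None, :, :]
    logM = -0.5 * z * z
    out = np.ones((N, n_a))
    for l in range(n_a):
        part = np.nonzero(codes[l] > 0)[0]
        if part.size == 0:
            continue
        acc = logM[np.arange(N)[:, None], part[None, :], (codes[l, part] - 1)[None, :]]
        out[:, l] = np.exp(acc.sum(axis=1) / part.size)
    return out


def _normalise_firings(mu_f: np.ndarray) -> np.ndarray:
    tot = mu_f.sum(axis=1)
    r = mu_f.shape[1]
    return np.where(
        tot[:, None] > FIRING_GUARD, mu_f / np.maximum(tot, FIRING_GUARD)[:, None], 1.0 / r
    )


def solve_consequent_ls(
    Phi_groups: list[np.ndarray],
    Ulin: np.ndarray,
    scaled_firings: np.ndarray,
    y: np.ndarray,
    warn_rank: bool = False,
    fast: bool = False,
    ridge: float = 0.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Joint least squares for every rule's consequent weights.

    ``Phi_groups[l]`` holds rule ``l``'s wavelet response columns (may have
    zero columns); ``Ulin`` the raw linear regressors (each rule's
    consequent keeps all of them); ``scaled_firings[:, l] = v_l * mubar_l``
    is the factor multiplying rule ``l``'s consequent in the model output.
    Returns the per-rule weight vectors (wavelet weights then linear
    weights) and the fitted values.  Rank-deficient systems get the
    minimum-norm solution.
    """
    N, m = Ulin.shape
    r = len(Phi_groups)
    widths = [g.shape[1] + m for g in Phi_groups]
    P = int(sum(widths))
    A = np.empty((N, P))
    off = 0
    for l, G in enumerate(Phi_groups):
        s = scaled_firings[:, l][:, None]
        k = G.shape[1]
        if k:
            A[:, off:off + k] = G * s
        A[:, off + k:off + k + m] = Ulin * s
        off += k + m
    if not np.any(np.abs(A) > 0):
        raise ValueError("all-zero design matrix: no rule can contribute")
    if fast:
        # Normal-equations path for the inner optimisation loop: a tiny
        # relative ridge keeps the Cholesky factorisation defined on the
        # collinear designs that metaheuristic genomes routinely produce.
        G = A.T @ A
        b = A.T @ y
        G.flat[:: P + 1] += 1e-10 * (np.trace(G) / P + 1.0)
        try:
            w = sla.cho_solve(sla.cho_factor(G, check_finite=False), b, check_finite=False)
        except np.linalg.LinAlgError:
            w, *_ = sla.lstsq(A, y, cond=1e-8, lapack_driver="gelsd", check_finite=False)
        fitted = A @ w
        weights = []
        off = 0
        for wdt in widths:
            weights.append(w[off:off + wdt].copy())
            off += wdt
        return weights, fitted
    # Equilibrate columns and truncate small singular values: a rule that
    # barely fires on the training data contributes near-zero columns, and
    # an untruncated solve can hand those columns enormous weights that
    # explode wherever the rule does fire.  Solving in the equilibrated
    # space with a conditioning cutoff keeps all weights data-scaled.
    col = np.sqrt(np.einsum("ij,ij->j", A, A))
    big = col.max()
    keep = col > 1e-6 * max(big, 1.0)
    w = np.zeros(P)
    if keep.any():
        An = A[:, keep] / col[keep]
        wn, _, rank, _ = sla.lstsq(An, y, cond=1e-8, lapack_driver="gelsd", check_finite=False)
        if warn_rank and (rank < int(keep.sum()) or not keep.all()):
            warnings.warn(
                f"rank-deficient consequent system (rank {rank} of {P}); "
                "minimum-norm solution used",
                stacklevel=2,
            )
        if ridge > 0.0:
            G = An.T @ An
            G.flat[:: G.shape[0] + 1] += ridge * np.trace(G) / G.shape[0]
            wn = np.linalg.solve(G, An.T @ y)
        w[keep] = wn / col[keep]
    fitted = A @ w
    weights = []
    off = 0
    for wdt in widths:
        weights.append(w[off:off + wdt].copy())
        off += wdt
    return weights, fitted


class _FitCore:
    """Precomputed state for fast nested-LS cost evaluations.

    ``Xn`` (normalised inputs) drives memberships/firings; ``Ulin`` (raw
    inputs) supplies the linear consequent columns.
    """

    def __init__(self, Xn, Ulin, y, Phi_groups, spec: GenomeSpec, n_train_cost=None):
        self.Xn = Xn
        self.Ulin = Ulin
        self.y = y
        self.Phi_groups = Phi_groups
        self.spec = spec
        # validation-cost switch: LS on [:n], score on [n:]
        self.n_train_cost = n_train_cost

    def cost(self, genome) -> float:
        mu, su, v, codes = decode_genome(genome, self.spec)
        fir = _firings(self.Xn, mu, su, codes)
        s = _normalise_firings(fir) * v[None, :]
        try:
            if self.n_train_cost is None:
                _, fitted = solve_consequent_ls(self.Phi_groups, self.Ulin, s, self.y, fast=True)
                res = self.y - fitted
            else:
                n = self.n_train_cost
                Pg = [G[:n] for G in self.Phi_groups]
                weights, _ = solve_consequent_ls(Pg, self.Ulin[:n], s[:n], self.y[:n], fast=True)
                pred = np.zeros(self.y.size - n)
                off_groups = [G[n:] for G in self.Phi_groups]
                for l, (G, w) in enumerate(zip(off_groups, weights)):
                    k = G.shape[1]
                    eta = self.Ulin[n:] @ w[k:]
                    if k:
                        eta = eta + G @ w[:k]
                    pred += s[n:, l] * eta
                res = self.y[n:] - pred
        except ValueError:
            return np.inf
        out = float(np.sqrt(np.mean(res ** 2)))
        return out if np.isfinite(out) else np.inf


@dataclass
class FitReport:
    """Diagnostics produced by :func:`fit_fjwnn`."""

    cost_trace: np.ndarray
    ga_trace: np.ndarray
    validation_curve: np.ndarray
    ols_errs: np.ndarray
    selected_indices: np.ndarray
    n_rules: int
    n_parameters: int
    train_rmse: float
    seeds: dict = field(default_factory=dict)


def fit_fjwnn(
    dataset: Dataset,
    selection: SelectionConfig | None = None,
    ica: ICAConfig | None = None,
    init: InitConfig | None = None,
    seed: int = 0,
    cost_on: str = "train",
    prune_threshold: float = 0.05,
) -> tuple[FuzzyRuleSystem, FitReport]:
    """Run the full identification pipeline on a dataset.

    normalise -> build lattice -> OLS ranking -> validation count choice ->
    GA subset refinement -> scale grouping -> ICA over membership/rule-weight
    /antecedent genome with nested LS consequents -> prune -> final LS.
    """
    selection = selection or SelectionConfig()
    ica = ica or ICAConfig()
    init = init or InitConfig()
    if cost_on not in ("train", "validation"):
        raise ValueError("cost_on must be 'train' or 'validation'")

    ss = np.random.SeedSequence(seed)
    s_lat, s_ga, s_ica = [np.random.default_rng(c) for c in ss.spawn(3)]
    logger.info("fit start: seed=%d N=%d m=%d", seed, dataset.n, dataset.m)
    t0 = time.perf_counter()

    U, y = dataset.U, dataset.y
    lo = U.min(axis=0)
    hi = U.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Xn = (U - lo) / span
    N, m = Xn.shape

    # --- dominant-wavelet selection
    lattice = build_lattice(
        Xn, selection.scale_range, selection.max_centers_per_scale, s_lat
    )
    C = lattice.responses(Xn)
    max_terms = min(selection.max_terms, len(lattice))
    order, errs = ols_rank(C, U.copy(), y, max_terms=max_terms)
    n_star, sel, curve = choose_wavelet_count(
        C, U, y, order, min(max_terms, order.size), selection.validation_fraction
    )
    logger.info(
        "selection: lattice=%d ranked=%d n_star=%d [%.2fs]",
        len(lattice), order.size, n_star, time.perf_counter() - t0,
    )
    t0 = time.perf_counter()
    if sel.size:
        sel, _, ga_trace = ga_refine(
            sel, C, U, y, selection.ga, selection.validation_fraction, s_ga
        )
    else:
        ga_trace = np.zeros(0)
    logger.info("ga refine: subset=%d [%.2fs]", sel.size, time.perf_counter() - t0)
    t0 = time.perf_counter()

    # --- scale grouping -> rule skeleton
    if sel.size:
        scales = np.array([lattice.wavelets[i].a for i in sel])
        uniq = np.unique(scales)
        group_idx = [sel[scales == a] for a in uniq]
        group_wavelets = [[lattice.wavelets[i] for i in g] for g in group_idx]
        Phi_groups = [C[:, g] for g in group_idx]
        group_scales = [int(a) for a in uniq]
    else:
        # nothing beats the linear regressors: a single linear global rule
        group_wavelets = [[]]
        Phi_groups = [np.empty((N, 0))]
        group_scales = [0]
    n_a = len(group_wavelets)

    # --- ICA over the antecedent/rule-weight genome with nested LS
    spec = GenomeSpec(m=m, n_a=n_a)
    glo, ghi = spec.bounds()
    n_train_cost = None
    if cost_on == "validation":
        n_train_cost = N - max(1, int(round(N * selection.validation_fraction)))
    core = _FitCore(Xn, U, y, Phi_groups, spec, n_train_cost)
    init_pop = spec.initial_population(ica.population, init, s_ica)
    result = ica_optimize(core.cost, glo, ghi, ica, seed=s_ica, init_population=init_pop)
    logger.info(
        "ica: evals=%d best_cost=%.4g [%.2fs]",
        result.n_evaluations, result.cost, time.perf_counter() - t0,
    )

    # --- decode best genome, prune, final LS on survivors
    mu, su, v, codes = decode_genome(result.x, spec)
    # A rule that essentially never fires on the training data has an
    # unidentifiable consequent (near-zero design columns) and undefined
    # behaviour wherever it does fire later; such dead rules are removed
    # together with the weight-threshold pruning.
    fir_all = _normalise_firings(_firings(Xn, mu, su, codes))
    supported = fir_all.max(axis=0) >= 1e-3
    keep = np.nonzero((v >= prune_threshold) & supported)[0]
    if keep.size == 0:
        cand = np.nonzero(supported)[0]
        keep = np.array([int(cand[np.argmax(v[cand])]) if cand.size else int(np.argmax(v))])
        warnings.warn(
            "every rule weight fell below the pruning threshold; "
            "keeping the strongest rule",
            stacklevel=2,
        )
    # recompute firings restricted to surviving rules
    fir = _firings(Xn, mu, su, codes[keep])
    s_fir = _normalise_firings(fir) * v[keep][None, :]
    kept_groups = [Phi_groups[i] for i in keep]

    def build_system(weights):
        rules = [
            FuzzyRule(
                a=group_scales[i],
                wavelets=group_wavelets[i],
                w=weights[j],
                ca=codes[i],
                v=float(v[i]),
            )
            for j, i in enumerate(keep)
        ]
        return FuzzyRuleSystem(
            rules=rules,
            mf_mu=mu,
            mf_su=su,
            prune_threshold=prune_threshold,
            ph=dataset.ph,
            norm_lo=lo,
            norm_hi=hi,
            n_a=n_a,
        )

    # Stability probe: a solve whose residual is exact on the training
    # points can still spike between them when weakly-firing rules carry
    # inflated weights (their fine-scale wavelets are unconstrained off the
    # sample).  Probe the blended prediction on jittered copies of the
    # training inputs and escalate a ridge until it stays data-scaled.
    probe_rng = np.random.default_rng(ss.spawn(1)[0])
    jitter = 0.02 * (hi - lo)
    probes = np.vstack([
        U + probe_rng.uniform(-1.0, 1.0, size=U.shape) * jitter for _ in range(2)
    ])
    y_scale = float(np.max(np.abs(y))) or 1.0
    system = None
    for lam in (0.0, 1e-8, 1e-6, 1e-4, 1e-2):
        weights, fitted = solve_consequent_ls(
            kept_groups, U, s_fir, y, warn_rank=(lam == 0.0), ridge=lam
        )
        system = build_system(weights)
        if float(np.max(np.abs(system.predict(probes)))) <= 5.0 * y_scale:
            break
    else:
        warnings.warn(
            "prediction stayed off-scale on probe points at the strongest "
            "ridge level",
            stacklevel=2,
        )
    train_rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    report = FitReport(
        cost_trace=result.trace,
        ga_trace=ga_trace,
        validation_curve=curve,
        ols_errs=errs,
        selected_indices=sel,
        n_rules=system.n_rules,
        n_parameters=system.n_parameters,
        train_rmse=train_rmse,
        seeds={"seed": seed},
    )
    return system, report
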