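"""Fuzzy rule base: scale-grouped sub-JWNN consequents, Gaussian memberships,
geometric-mean firing, rule-weight pruning and defuzzified prediction.

Each fuzzy rule corresponds to one *scale group* of the selected dominant
wavelets: all wavelets with the same integer scale share a rule, whose
consequent (a "sub jump wavelet neural network") is a linear combination of
those wavelet responses plus all linear input regressors.  The antecedent of
rule ``l`` is encoded by integer codes ``ca[l, i]`` in {0..n_a}: 0 means
input ``i`` plays no role in the rule, a nonzero code selects one of the
``n_a`` Gaussian membership functions in input ``i``'s pool.  The firing
strength is the geometric mean of the participating memberships, and the
model output is the rule-weighted, firing-normalised blend of the sub-JWNN
outputs.

Rules whose learned weight ``v`` falls below the pruning threshold are
removed outright; the firing normalisation is then recomputed over the
survivors only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .wavelets import Wavelet, response_matrix

__all__ = [
    "MembershipFunction",
    "FuzzyRule",
    "FuzzyRuleSystem",
    "EmptyModelError",
    "membership",
    "group_by_scale",
    "prune_rule_weights",
]

SU_MIN = 1e-3  # lower clamp on membership std-dev (normalised input units)
FIRING_GUARD = 1e-12


class EmptyModelError(ValueError):
    """Raised when pruning removes every rule or prediction is attempted on
    a model with no surviving rules."""


@dataclass
class MembershipFunction:
    """Gaussian membership exp(-((u-mu)/su)^2 / 2)."""

    mu: float
    su: float

    def __post_init__(self):
        if not self.su > 0:
            raise ValueError("membership std-dev must be positive")

    def __call__(self, u: float) -> float:
        return membership(self, u)


def membership(mf: MembershipFunction, u) -> float:
    """Evaluate one Gaussian membership at ``u``."""
    z = (np.asarray(u, dtype=float) - mf.mu) / mf.su
    out = np.exp(-0.5 * z * z)
    return float(out) if np.isscalar(u) or np.ndim(u) == 0 else out


def prune_rule_weights(v, threshold: float = 0.05) -> np.ndarray:
    """Zero every rule weight below ``threshold`` (rule induction pruning).

    Raises :class:`EmptyModelError` if no rule survives.
    """
    v = np.asarray(v, dtype=float)
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    out = np.where(v < threshold, 0.0, v)
    if not np.any(out > 0.0):
        raise EmptyModelError("all rule weights fall below the pruning threshold")
    return out


def group_by_scale(wavelets: list[Wavelet]) -> list[list[Wavelet]]:
    """Partition selected wavelets by scale, groups in ascending scale order."""
    if not wavelets:
        raise ValueError("cannot group an empty wavelet selection")
    scales = sorted({w.a for w in wavelets})
    return [[w for w in wavelets if w.a == a] for a in scales]


@dataclass
class FuzzyRule:
    """One fuzzy rule: a scale group of wavelets plus antecedent structure.

    ``w`` stacks the ``n_l`` wavelet weights followed by the ``m`` linear
    regressor weights; ``ca`` holds the antecedent codes; ``v`` in [0, 1] is
    the learned rule weight used for induction/pruning.
    """

    a: int
    wavelets: list[Wavelet]
    w: np.ndarray
    ca: np.ndarray
    v: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.ca = np.asarray(self.ca, dtype=int).ravel()
        if any(wv.a != self.a for wv in self.wavelets):
            raise ValueError("all wavelets in a rule must share its scale")
        if not 0.0 <= self.v <= 1.0:
            raise ValueError("rule weight must lie in [0, 1]")

    @property
    def n_wavelets(self) -> int:
        return len(self.wavelets)

    def subjwnn_output(self, U, U_wavelet=None) -> float:
        """Consequent output: sum_j w_j phi_j(U) + sum_j w_uj u_j.

        ``U_wavelet`` optionally supplies a separately scaled copy of the
        input for the wavelet terms (the rule system evaluates wavelets on
        normalised inputs while the linear part uses the raw regressors);
        by default the same vector feeds both.
        """
        U = np.atleast_1d(np.asarray(U, dtype=float))
        Uw = U if U_wavelet is None else np.atleast_1d(np.asarray(U_wavelet, dtype=float))
        m = U.size
        if self.w.size != self.n_wavelets + m:
            raise ValueError("weight vector length does not match rule structure")
        val = float(self.w[self.n_wavelets:] @ U)
        if self.wavelets:
            phi = response_matrix(self.wavelets, Uw[None, :])[0]
            val += float(self.w[: self.n_wavelets] @ phi)
        return val


@dataclass
class FuzzyRuleSystem:
    """A complete rule base with membership pools and normalisation.

    ``mf_mu``/``mf_su`` are (m, n_a) pools: input ``i`` owns ``n_a``
    Gaussian membership functions, one per rule slot; antecedent codes index
    into these pools (1-based; 0 = input excluded).  ``norm_lo``/``norm_hi``
    hold the min-max normalisation of raw inputs to [0, 1] learned from the
    training data; prediction applies it before any membership or wavelet
    evaluation.
    """

    rules: list[FuzzyRule]
    mf_mu: np.ndarray
    mf_su: np.ndarray
    prune_threshold: float = 0.05
    ph: int = 0
    norm_lo: np.ndarray | None = None
    norm_hi: np.ndarray | None = None
    n_a: int = field(default=0)

    def __post_init__(self):
        self.mf_mu = np.atleast_2d(np.asarray(self.mf_mu, dtype=float))
        self.mf_su = np.atleast_2d(np.asarray(self.mf_su, dtype=float))
        if self.n_a == 0:
            self.n_a = self.mf_mu.shape[1]
        if np.any(self.mf_su < SU_MIN):
            self.mf_su = np.maximum(self.mf_su, SU_MIN)
        for r in self.rules:
            if np.any(r.ca < 0) or np.any(r.ca > self.n_a):
                raise ValueError("antecedent code outside {0..n_a}")

    # ------------------------------------------------------------ structure
    @property
    def m(self) -> int:
        return self.mf_mu.shape[0]

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def normalise(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.norm_lo is None:
            return X
        span = np.where(self.norm_hi - self.norm_lo > 0, self.norm_hi - self.norm_lo, 1.0)
        return (X - self.norm_lo) / span

    # -------------------------------------------------------------- firing
    def firing_strengths(self, Xn: np.ndarray) -> np.ndarray:
        """(N, r) matrix of rule firing strengths on *normalised* inputs.

        Rule firing = geometric mean of the participating memberships; a
        rule with no participating inputs fires at 1 everywhere (a global
        rule) so that the convention keeps it usable.
        """
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        N = Xn.shape[0]
        out = np.ones((N, self.n_rules))
        for li, rule in enumerate(self.rules):
            part = np.nonzero(rule.ca > 0)[0]
            if part.size == 0:
                continue
            logs = np.zeros(N)
            for i in part:
                k = rule.ca[i] - 1
                z = (Xn[:, i] - self.mf_mu[i, k]) / self.mf_su[i, k]
                logs += -0.5 * z * z
            out[:, li] = np.exp(logs / part.size)
        return out

    def subjwnn_outputs(self, Xn: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
        """(N, r) matrix of sub-JWNN consequent outputs.

        Wavelet terms are evaluated on the normalised inputs ``Xn``; the
        linear terms use the raw regressors ``X`` (defaults to ``Xn`` when
        no separate raw matrix is given).
        """
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        X = Xn if X is None else np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((Xn.shape[0], self.n_rules))
        for li, rule in enumerate(self.rules):
            val = X @ rule.w[rule.n_wavelets:]
            if rule.wavelets:
                val = val + response_matrix(rule.wavelets, Xn) @ rule.w[: rule.n_wavelets]
            out[:, li] = val
        return out

    # ------------------------------------------------------------- predict
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Defuzzified prediction for raw inputs ``X`` (N, m) -> (N,).

        yhat = sum_l v_l * mubar_l * eta_l over surviving rules, where
        mubar normalises firings across the surviving rules.  If the total
        firing underflows, the rules are blended with equal weights.
        """
        if self.n_rules == 0:
            raise EmptyModelError("no surviving rules")
        v = np.array([r.v for r in self.rules])
        active = np.nonzero(v > 0.0)[0]
        if active.size == 0:
            raise EmptyModelError("every rule has zero weight")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = self.normalise(X)
        # zero-weight rules are pruned by definition: they contribute nothing
        # and are excluded from the firing normalisation
        mu = self.firing_strengths(Xn)[:, active]
        eta = self.subjwnn_outputs(Xn, X)[:, active]
        tot = mu.sum(axis=1)
        mubar = np.where(
            tot[:, None] > FIRING_GUARD, mu / np.maximum(tot, FIRING_GUARD)[:, None],
            1.0 / active.size,
        )
        return (mubar * eta) @ v[active]

    def predict_one(self, U) -> float:
        return float(self.predict(np.atleast_2d(U))[0])

    # -------------------------------------------------------------- pruning
    def pruned(self) -> "FuzzyRuleSystem":
        """Return a copy with every rule of weight v < threshold removed."""
        keep = [r for r in self.rules if r.v >= self.prune_threshold]
        if not keep:
            raise EmptyModelError(
                "all rule weights fall below the pruning threshold"
            )
        return FuzzyRuleSystem(
            rules=keep,
            mf_mu=self.mf_mu.copy(),
            mf_su=self.mf_su.copy(),
            prune_threshold=self.prune_threshold,
            ph=self.ph,
            norm_lo=None if self.norm_lo is None else self.norm_lo.copy(),
            norm_hi=None if self.norm_hi is None else self.norm_hi.copy(),
            n_a=self.n_a,
        )

    # ---------------------------------------------------------- accounting
    @property
    def n_parameters(self) -> int:
        """Parameter count: consequent weights, participating-membership
        (mu, su) pairs, and one weight per surviving rule."""
        nw = sum(r.w.size for r in self.rules)
        n_mf = 2 * sum(int(np.count_nonzero(r.ca)) for r in self.rules)
        return nw + n_mf + self.n_rules

    # ------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "prune_threshold": self.prune_threshold,
            "ph": self.ph,
            "mf_mu": self.mf_mu.tolist(),
            "mf_su": self.mf_su.tolist(),
            "norm_lo": None if self.norm_lo is None else self.norm_lo.tolist(),
            "norm_hi": None if self.norm_hi is None else self.norm_hi.tolist(),
            "rules": [
                {
                    "a": r.a,
                    "shifts": [list(w.b) for w in r.wavelets],
                    "w": r.w.tolist(),
                    "ca": r.ca.tolist(),
                    "v": r.v,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyRuleSystem":
        rules = [
            FuzzyRule(
                a=int(rd["a"]),
                wavelets=[Wavelet(a=int(rd["a"]), b=tuple(b)) for b in rd["shifts"]],
                w=np.asarray(rd["w"], dtype=float),
                ca=np.asarray(rd["ca"], dtype=int),
                v=float(rd["v"]),
            )
            for rd in d["rules"]
        ]
        return cls(
            rules=rules,
            mf_mu=np.asarray(d["mf_mu"], dtype=float),
            mf_su=np.asarray(d["mf_su"], dtype=float),
            prune_threshold=float(d["prune_threshold"]),
            ph=int(d["ph"]),
            norm_lo=None if d["norm_lo"] is None else np.asarray(d["norm_lo"], dtype=float),
            norm_hi=None if d["norm_hi"] is None else np.asarray(d["norm_hi"], dtype=float),
            n_a=int(d["n_a"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FuzzyRuleSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
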