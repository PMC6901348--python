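"""Model/Results interface for fuzzy jump wavelet neural network fitting.

:class:`FJWNN` is constructed from data (arrays, a :class:`~fjwnn.dataset.Dataset`
or a DataFrame) together with the configuration bundles; calling
:meth:`FJWNN.fit` runs the full identification pipeline and returns a
:class:`FJWNNResults` carrying the fitted rule base, diagnostics and a
``summary()`` table.  Prediction and evaluation hang off the results object.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .dataset import Dataset
from .ica import ICAConfig
from .rules import FuzzyRuleSystem
from .selection import SelectionConfig
from .training import FitReport, InitConfig, fit_fjwnn

__all__ = ["FJWNN", "FJWNNResults"]


class FJWNN:
    """Fuzzy jump wavelet neural network identification model.

    Parameters
    ----------
    data : Dataset or (U, y) pair
        Training data: regressor matrix and aligned target.
    selection : SelectionConfig, optional
        Wavelet lattice / OLS / GA settings.
    ica : ICAConfig, optional
        Imperialist-competitive-algorithm settings for the antecedent,
        membership and rule-weight genome.
    init : InitConfig, optional
        Genome initialisation (membership std-dev 0.2, rule weight 0.7,
        antecedent codes 1, means uniformly random).
    prune_threshold : float
        Rule weights below this are pruned after training (default 0.05).
    cost_on : {"train", "validation"}
        Which RMSE the ICA minimises (training RMSE by default).

    Examples
    --------
    >>> model = FJWNN((U, y))
    >>> res = model.fit(seed=0)
    >>> yhat = res.predict(U_test)
    """

    def __init__(
        self,
        data,
        selection: SelectionConfig | None = None,
        ica: ICAConfig | None = None,
        init: InitConfig | None = None,
        prune_threshold: float = 0.05,
        cost_on: str = "train",
    ):
        if isinstance(data, Dataset):
            self.dataset = data
        elif isinstance(data, pd.DataFrame):
            self.dataset = Dataset.from_dataframe(data)
        else:
            U, y = data
            self.dataset = Dataset(U=np.asarray(U), y=np.asarray(y))
        self.selection = selection or SelectionConfig()
        self.ica = ica or ICAConfig()
        self.init = init or InitConfig()
        self.prune_threshold = prune_threshold
        self.cost_on = cost_on

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, target: str | None = None, ph: int = 0, **kwargs
    ) -> "FJWNN":
        return cls(Dataset.from_dataframe(df, target=target, ph=ph), **kwargs)

    @classmethod
    def from_csv(cls, path, target: str | None = None, ph: int = 0, **kwargs) -> "FJWNN":
        return cls(Dataset.from_csv(path, target=target, ph=ph), **kwargs)

    def fit(self, seed: int = 0) -> "FJWNNResults":
        """Run selection + hybrid ICA/LS training; reproducible given seed."""
        system, report = fit_fjwnn(
            self.dataset,
            selection=self.selection,
            ica=self.ica,
            init=self.init,
            seed=seed,
            cost_on=self.cost_on,
            prune_threshold=self.prune_threshold,
        )
        return FJWNNResults(self, system, report)


class FJWNNResults:
    """Fitted FJWNN: rule base, diagnostics and evaluation helpers."""

    def __init__(self, model: FJWNN, system: FuzzyRuleSystem, report: FitReport):
        self.model = model
        self.system = system
        self.report = report

    # --------------------------------------------------------- prediction
    def predict(self, X=None) -> np.ndarray:
        """Predict targets for raw regressors ``X`` (training data if None)."""
        if X is None:
            X = self.model.dataset.U
        elif isinstance(X, Dataset):
            X = X.U
        elif isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.system.predict(np.asarray(X, dtype=float))

    def evaluate(self, dataset: Dataset) -> dict:
        """Standard metric bundle on a dataset."""
        yhat = self.predict(dataset.U)
        y = dataset.y
        return {
            "rmse": _metrics.rmse(y, yhat),
            "rrse": _metrics.rrse(y, yhat),
            "rel_err_pct": _metrics.rel_err_pct(y, yhat),
            "vaf_pct": _metrics.vaf_pct(y, yhat),
            "n": int(y.size),
        }

    # -------------------------------------------------------- diagnostics
    @property
    def n_rules(self) -> int:
        return self.report.n_rules

    @property
    def n_parameters(self) -> int:
        return self.report.n_parameters

    @property
    def train_rmse(self) -> float:
        return self.report.train_rmse

    @property
    def cost_trace(self) -> np.ndarray:
        return self.report.cost_trace

    def summary(self) -> str:
        """Plain-text fit summary."""
        ds = self.model.dataset
        lines = [
            "Fuzzy Jump Wavelet Neural Network Results",
            "=" * 57,
            f"{'No. observations:':<28}{ds.n:>10}",
            f"{'No. regressors:':<28}{ds.m:>10}",
            f"{'Prediction horizon:':<28}{ds.ph:>10}",
            f"{'Rules (after pruning):':<28}{self.n_rules:>10}",
            f"{'Model parameters:':<28}{self.n_parameters:>10}",
            f"{'Selected wavelets:':<28}{int(self.report.selected_indices.size):>10}",
            f"{'Training RMSE:':<28}{self.train_rmse:>10.3e}",
            f"{'Final ICA cost:':<28}{self.report.cost_trace[-1]:>10.3e}",
            "-" * 57,
            f"{'rule':>4} {'scale':>6} {'wavelets':>9} {'weight v':>9}  antecedent codes",
        ]
        for i, r in enumerate(self.system.rules):
            codes = ",".join(str(c) for c in r.ca)
            lines.append(
                f"{i + 1:>4} {r.a:>6} {r.n_wavelets:>9} {r.v:>9.4f}  [{codes}]"
            )
        lines.append("=" * 57)
        return "\n".join(lines)

    # ------------------------------------------------------ serialisation
    def save(self, path) -> None:
        """Serialise the fitted system + config echo + diagnostics to JSON."""
        payload = {
            "system": self.system.to_dict(),
            "config": {
                "selection": _cfg_dict(self.model.selection),
                "ica": asdict(self.model.ica),
                "init": asdict(self.model.init),
                "prune_threshold": self.model.prune_threshold,
                "cost_on": self.model.cost_on,
            },
            "report": {
                "n_rules": self.report.n_rules,
                "n_parameters": self.report.n_parameters,
                "train_rmse": self.report.train_rmse,
                "cost_trace": self.report.cost_trace.tolist(),
                "validation_curve": self.report.validation_curve.tolist(),
                "seeds": self.report.seeds,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load_system(path) -> FuzzyRuleSystem:
        """Load just the predictive rule system from a saved results file."""
        with open(path) as fh:
            payload = json.load(fh)
        return FuzzyRuleSystem.from_dict(payload["system"])


def _cfg_dict(cfg: SelectionConfig) -> dict:
    d = asdict(cfg)
    d["scale_range"] = list(d["scale_range"])
    return d
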