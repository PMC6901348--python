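"""Regressor/target containers and delimited-text I/O.

A :class:`Dataset` holds the regressor matrix ``U`` (one column per input
regressor), the target vector ``y`` and the prediction horizon ``ph``: row
``i`` of ``U`` is time-aligned with the target ``ph`` steps ahead, so a model
maps ``U[i]`` to ``y[i]`` where ``y[i]`` is the measurement at time
``t_i + ph``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Time-aligned regressor matrix and target vector.

    Parameters
    ----------
    U : ndarray, shape (N, m)
        Input regressors, one column per regressor.
    y : ndarray, shape (N,)
        Target values, aligned so that row ``i`` of ``U`` predicts ``y[i]``
        at horizon ``ph``.
    ph : int
        Non-negative prediction horizon (0 = one-step / nowcast alignment,
        already baked into the row alignment).
    column_names : list of str, optional
        Regressor labels; autogenerated as ``u1..um`` when omitted.
    """

    U: np.ndarray
    y: np.ndarray
    ph: int = 0
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.U.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"U has {self.U.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if self.U.shape[0] < 1 or self.U.shape[1] < 1:
            raise ValueError("dataset needs at least one row and one regressor")
        if self.ph < 0:
            raise ValueError("prediction horizon must be non-negative")
        if not np.all(np.isfinite(self.U)) or not np.all(np.isfinite(self.y)):
            raise ValueError("dataset contains non-finite values")
        if not self.column_names:
            self.column_names = [f"u{j + 1}" for j in range(self.m)]
        if len(self.column_names) != self.m:
            raise ValueError("column_names length does not match U columns")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.U.shape[1]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, target: str | None = None, ph: int = 0
    ) -> "Dataset":
        """Build a dataset from a DataFrame; ``target`` defaults to the last column."""
        if target is None:
            target = df.columns[-1]
        regs = [c for c in df.columns if c != target]
        return cls(
            U=df[regs].to_numpy(dtype=float),
            y=df[target].to_numpy(dtype=float),
            ph=ph,
            column_names=list(regs),
        )

    @classmethod
    def from_csv(cls, path, target: str | None = None, ph: int = 0) -> "Dataset":
        """Read a delimited text file (header row; last column = target by default)."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls.from_dataframe(df, target=target, ph=ph)

    def to_dataframe(self, target_name: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.U, columns=self.column_names)
        df[target_name] = self.y
        return df

    def to_csv(self, path, target_name: str = "y") -> None:
        self.to_dataframe(target_name).to_csv(path, index=False)

    def split(self, n_first: int) -> tuple["Dataset", "Dataset"]:
        """Split chronologically into the first ``n_first`` rows and the rest."""
        if not 0 < n_first < self.n:
            raise ValueError("split point must be strictly inside the dataset")
        return (
            Dataset(self.U[:n_first], self.y[:n_first], self.ph, list(self.column_names)),
            Dataset(self.U[n_first:], self.y[n_first:], self.ph, list(self.column_names)),
        )
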