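"""Goodness-of-fit metrics for identification experiments.

All metrics compare a measured output ``y`` with a model prediction ``yhat``:

* ``rmse``        -- root mean square error, sqrt(sum((y-yhat)^2)/n).
* ``rrse``        -- root relative squared error, the residual norm relative
                     to the deviation of ``y`` from its mean:
                     sqrt(sum((y-yhat)^2) / sum((y-ybar)^2)).
* ``rel_err_pct`` -- percent residual norm relative to the RMS of ``y``:
                     100*sqrt(sum((y-yhat)^2) / sum(y^2)).
* ``vaf_pct``     -- percent variance accounted for:
                     100*(1 - var(y-yhat)/var(y)), population variances.

``rrse`` and ``rel_err_pct`` are reported in square-root form, consistent
with their names and with how comparable identification studies tabulate
them; the squared variants are exposed separately as ``rse`` and
``rel_sq_err_pct``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "rrse", "rse", "rel_err_pct", "rel_sq_err_pct", "vaf_pct"]


def _check(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rse(y, yhat) -> float:
    """Relative squared error (no square root): sum((y-yhat)^2)/sum((y-ybar)^2)."""
    y, yhat = _check(y, yhat)
    denom = float(np.sum((y - np.mean(y)) ** 2))
    if denom == 0.0:
        raise ValueError("target is constant; relative error undefined")
    return float(np.sum((y - yhat) ** 2) / denom)


def rrse(y, yhat) -> float:
    """Root relative squared error."""
    return float(np.sqrt(rse(y, yhat)))


def rel_sq_err_pct(y, yhat) -> float:
    """Percent squared error relative to the output power: 100*sum((y-yhat)^2)/sum(y^2)."""
    y, yhat = _check(y, yhat)
    denom = float(np.sum(y ** 2))
    if denom == 0.0:
        raise ValueError("target has zero power; relative error undefined")
    return float(100.0 * np.sum((y - yhat) ** 2) / denom)


def rel_err_pct(y, yhat) -> float:
    """Percent root error relative to the output RMS."""
    return float(np.sqrt(rel_sq_err_pct(y, yhat) / 100.0) * 100.0)


def vaf_pct(y, yhat) -> float:
    """Percent variance accounted for (population variance convention)."""
    y, yhat = _check(y, yhat)
    vy = float(np.var(y))
    if vy == 0.0:
        raise ValueError("target is constant; VAF undefined")
    return float(100.0 * (1.0 - np.var(y - yhat) / vy))
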