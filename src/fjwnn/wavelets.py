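"""Mexican-hat mother wavelet, dyadic scaled/shifted variants and the
candidate lattice.

The multi-dimensional Mexican hat

    phi(U) = (m - ||U||^2) * exp(-||U||^2 / 2)

is the mother wavelet; a candidate basis function at integer scale ``a`` and
shift vector ``B`` responds as

    phi_{a,B}(U) = 2^(-a*m/2) * phi(2^a * U - B),

i.e. the standard dyadic frame normalisation multiplying the scaled/shifted
mother wavelet.  The amplitude factor is immaterial to the fitted model (it
is absorbed by the learned least-squares weights) but keeps responses on a
comparable numeric footing across scales.

The lattice is a finite dictionary of such candidates.  Shifts are centred
on (subsampled) training rows, ``B = 2^a * c``, so that every candidate peaks
on the support of the data; a full tensor grid of shifts would be
exponentially large in the input dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "mother_wavelet",
    "wavelet_response",
    "response_matrix",
    "Wavelet",
    "WaveletLattice",
    "build_lattice",
]


def mother_wavelet(U) -> float:
    """Evaluate the m-dimensional Mexican hat ``(m - ||U||^2) exp(-||U||^2/2)``.

    ``U`` is a single input-regressor vector; its length is the dimension m.
    """
    U = np.atleast_1d(np.asarray(U, dtype=float))
    if not np.all(np.isfinite(U)):
        raise ValueError("mother wavelet input must be finite")
    r2 = float(U @ U)
    return (U.size - r2) * np.exp(-r2 / 2.0)


@dataclass(frozen=True)
class Wavelet:
    """A dyadic scaled/shifted Mexican-hat variant: integer scale ``a`` and
    real shift vector ``b`` (one entry per input regressor)."""

    a: int
    b: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))

    @property
    def m(self) -> int:
        return len(self.b)


def wavelet_response(w: Wavelet, U) -> float:
    """Response ``2^(-a*m/2) * phi(2^a U - b)`` of one candidate at one point."""
    U = np.atleast_1d(np.asarray(U, dtype=float))
    if U.size != w.m:
        raise ValueError(f"input has dimension {U.size}, wavelet expects {w.m}")
    z = (2.0 ** w.a) * U - np.asarray(w.b)
    return 2.0 ** (-w.a * w.m / 2.0) * mother_wavelet(z)


def response_matrix(wavelets: list[Wavelet], X: np.ndarray) -> np.ndarray:
    """Vectorised responses of a wavelet list on an (N, m) point matrix.

    Returns an (N, K) matrix, one column per wavelet.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, m = X.shape
    K = len(wavelets)
    out = np.empty((N, K))
    for k, w in enumerate(wavelets):
        if w.m != m:
            raise ValueError("wavelet dimension does not match data")
        z = (2.0 ** w.a) * X - np.asarray(w.b)[None, :]
        r2 = np.einsum("ij,ij->i", z, z)
        out[:, k] = 2.0 ** (-w.a * m / 2.0) * (m - r2) * np.exp(-r2 / 2.0)
    return out


@dataclass
class WaveletLattice:
    """Ordered candidate dictionary of wavelets over an integer scale range."""

    wavelets: list[Wavelet]
    m: int
    scale_range: tuple[int, int]

    def __post_init__(self):
        lo, hi = self.scale_range
        seen = set()
        for w in self.wavelets:
            if not lo <= w.a <= hi:
                raise ValueError(f"wavelet scale {w.a} outside range {self.scale_range}")
            if w.m != self.m:
                raise ValueError("wavelet dimension mismatch in lattice")
            key = (w.a, w.b)
            if key in seen:
                raise ValueError("duplicate (scale, shift) in lattice")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.wavelets)

    def responses(self, X: np.ndarray) -> np.ndarray:
        return response_matrix(self.wavelets, X)


def build_lattice(
    X: np.ndarray,
    scale_range: tuple[int, int] = (-4, 4),
    max_centers_per_scale: int = 100,
    seed: int | np.random.Generator = 0,
) -> WaveletLattice:
    """Construct the candidate lattice from (normalised) training points.

    For each integer scale ``a`` in ``scale_range`` a subsample of at most
    ``max_centers_per_scale`` distinct training rows ``c`` becomes candidate
    shifts ``B = 2^a * c``, so each candidate peaks exactly on a data point.
    Deterministic for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("cannot build a lattice from an empty training set")
    lo, hi = int(scale_range[0]), int(scale_range[1])
    if hi < lo:
        raise ValueError("empty scale range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.unique(X, axis=0)
    wavelets: list[Wavelet] = []
    seen: set[tuple] = set()
    for a in range(lo, hi + 1):
        if centers.shape[0] > max_centers_per_scale:
            idx = rng.choice(centers.shape[0], size=max_centers_per_scale, replace=False)
            idx.sort()
            sub = centers[idx]
        else:
            sub = centers
        for c in sub:
            b = tuple((2.0 ** a) * c)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            wavelets.append(Wavelet(a=a, b=b))
    return WaveletLattice(wavelets=wavelets, m=X.shape[1], scale_range=(lo, hi))
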