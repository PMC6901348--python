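"""Benchmark data generators and loaders for identification experiments.

Covers the standard test problems used to exercise the model:

* a piecewise single-variable function approximated from uniformly sampled
  pairs on [-10, 10];
* five discrete-time nonlinear plants with different nonlinearity
  structures, driven by random training inputs and deterministic sinusoidal
  test inputs;
* the Mackey-Glass chaotic delay differential equation at several delays,
  optionally corrupted by uniform additive noise at a requested SNR;
* the Box-Jenkins gas-furnace record (external two-column text file);
* a synthetic surface-EMG envelope -> elbow torque generator emulating
  isometric flexion/extension ramp trials with four muscles, plus a loader
  for per-trial CSV files in the same layout.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .dataset import Dataset

__all__ = [
    "piecewise_fn",
    "gen_example1",
    "PlantSpec",
    "simulate_plant",
    "train_input",
    "test_input",
    "plant_regressor_lags",
    "MGConfig",
    "simulate_mackey_glass",
    "add_noise",
    "make_regressors",
    "mackey_glass_dataset",
    "plant_dataset",
    "load_gas_furnace",
    "EMGSynthConfig",
    "gen_synthetic_emg",
    "load_emg_trials",
]


# --------------------------------------------------------------------------
# piecewise single-variable function
# --------------------------------------------------------------------------
def piecewise_fn(x):
    """Three-branch test function on [-10, 10].

    f(x) = -2.186x - 12.864                       for -10 <= x < -2
           4.246x                                  for  -2 <= x <  0
           10 exp(-0.05x) - 0.5 sin((0.03x+0.7)x)  for   0 <= x <= 10
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -10) or np.any(x > 10):
        raise ValueError("piecewise function is defined on [-10, 10]")
    out = np.where(
        x < -2,
        -2.186 * x - 12.864,
        np.where(x < 0, 4.246 * x, 10.0 * np.exp(-0.05 * x) - 0.5 * np.sin((0.03 * x + 0.7) * x)),
    )
    return float(out) if np.ndim(x) == 0 else out


def gen_example1(n: int = 200, seed: int | np.random.Generator = 0) -> Dataset:
    """n input-output pairs with x ~ Uniform[-10, 10], y = piecewise_fn(x)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(-10.0, 10.0, size=n)
    return Dataset(U=x[:, None], y=piecewise_fn(x), ph=0, column_names=["x"])


# --------------------------------------------------------------------------
# discrete-time nonlinear plants
# --------------------------------------------------------------------------
PLANT_IDS = ("2-1", "2-2", "2-3", "2-4", "2-5")

#: regressor lags per plant: (output lags, input lags); row k predicts y(k)
plant_regressor_lags = {
    "2-1": ((1, 2), (2, 3, 4)),
    "2-2": ((1, 2), (0,)),
    "2-3": ((1, 2), (0,)),
    "2-4": ((1,), (1,)),
    "2-5": ((1, 2, 3), (1, 2)),
}


@dataclass
class PlantSpec:
    """Which benchmark plant to simulate (zero initial conditions)."""

    plant_id: str

    def __post_init__(self):
        if self.plant_id not in PLANT_IDS:
            raise ValueError(f"unknown plant id {self.plant_id!r}; choose from {PLANT_IDS}")


def simulate_plant(spec: PlantSpec | str, u: np.ndarray) -> np.ndarray:
    """Run a plant's difference equation over input ``u`` from zero state.

    Returns y with y[k] computed from the recursion at step k; y[k] = 0 for
    k before the maximum delay is reachable (zero initial conditions).
    """
    pid = spec.plant_id if isinstance(spec, PlantSpec) else PlantSpec(spec).plant_id
    u = np.asarray(u, dtype=float).ravel()
    n = u.size
    y = np.zeros(n)

    def yv(k):
        return y[k] if k >= 0 else 0.0

    def uv(k):
        return u[k] if k >= 0 else 0.0

    for k in range(n):
        if pid == "2-1":
            y[k] = (
                0.72 * yv(k - 1)
                + 0.025 * yv(k - 2) * uv(k - 2)
                + 0.01 * uv(k - 3) ** 2
                + 0.2 * uv(k - 4)
            )
        elif pid == "2-2":
            y[k] = (
                0.3 * yv(k - 1)
                + 0.6 * yv(k - 2)
                + 0.6 * np.sin(np.pi * uv(k))
                + 0.3 * np.sin(3 * np.pi * uv(k))
                + 0.1 * np.sin(5 * np.pi * uv(k))
            )
        elif pid == "2-3":
            y1, y2 = yv(k - 1), yv(k - 2)
            y[k] = (
                y1 * y2 * (y1 + 0.5) * (y2 - 1.0) / (1.0 + y1 ** 2 + y2 ** 2)
                + uv(k)
            )
        elif pid == "2-4":
            y1, u1 = yv(k - 1), uv(k - 1)
            y[k] = y1 * (y1 + 0.3) / (1.0 + y1 ** 2) + u1 * (u1 + 0.8) * (u1 - 0.5)
        else:  # 2-5 (Narendra-type plant; the additive input drive is part of
            # the canonical recursion -- without it the zero-state output is
            # identically zero and the identification task is degenerate)
            y1, y2, y3 = yv(k - 1), yv(k - 2), yv(k - 3)
            y[k] = (
                y1 * y2 * y3 * uv(k - 2) * (y3 - 1.0) + uv(k - 1)
            ) / (1.0 + y2 ** 2 + y3 ** 2)
        if not np.isfinite(y[k]) or abs(y[k]) > 1e6:
            raise FloatingPointError(
                f"plant {pid} diverged at step {k} (y={y[k]!r})"
            )
    return y


def train_input(plant_id: str, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Training excitation: plant 2-1 gets 900 steps (first 450 iid
    Uniform[-2,2], remainder 1.05 sin(pi k / 45)); the others get 1000 iid
    Uniform[-1,1] steps."""
    PlantSpec(plant_id)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if plant_id == "2-1":
        u = np.empty(900)
        u[:450] = rng.uniform(-2.0, 2.0, size=450)
        k = np.arange(450, 900)
        u[450:] = 1.05 * np.sin(np.pi * k / 45.0)
        return u
    return rng.uniform(-1.0, 1.0, size=1000)


def test_input(plant_id: str) -> np.ndarray:
    """Deterministic test excitation for each plant."""
    PlantSpec(plant_id)
    if plant_id == "2-1":
        k = np.arange(1, 1001, dtype=float)
        u = np.where(
            k <= 250,
            np.sin(np.pi * k / 25.0),
            np.where(
                k <= 500,
                1.0,
                np.where(
                    k <= 750,
                    -1.0,
                    0.3 * np.sin(np.pi * k / 25.0)
                    + 0.1 * np.sin(np.pi * k / 32.0)
                    + 0.6 * np.sin(np.pi * k / 10.0),
                ),
            ),
        )
        return u
    k = np.arange(1, 601, dtype=float)
    return np.where(
        k <= 250,
        np.sin(2 * np.pi * k / 250.0),
        0.8 * np.sin(2 * np.pi * k / 250.0) + 0.2 * np.sin(2 * np.pi * k / 25.0),
    )


# --------------------------------------------------------------------------
# Mackey-Glass chaotic delay differential equation
# --------------------------------------------------------------------------
@dataclass
class MGConfig:
    """Mackey-Glass integration settings.

    dx/dt = 0.2 x(t - tau) / (1 + x(t - tau)^10) - 0.1 x(t),
    with x(0) = x0 and x(t) = 0 for t < 0; integrated by fixed-step RK4 with
    linear interpolation of the delayed state and sampled at unit times.
    """

    tau: float = 17.0
    x0: float = 1.2
    dt: float = 0.1
    n_points: int = 1200
    history: float = 0.0  # value of x(t) for t < 0
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.tau < 0 or self.dt <= 0:
            raise ValueError("tau must be >= 0 and dt > 0")


def _mg_rhs(x, x_tau):
    return 0.2 * x_tau / (1.0 + x_tau ** 10) - 0.1 * x


def simulate_mackey_glass(config: MGConfig) -> np.ndarray:
    """Integrate the delay equation; returns ``n_points`` samples at t = 0..n-1.

    If ``snr_db`` is set, zero-mean uniform noise at that empirical SNR is
    added to the sampled series (seeded).
    """
    cfg = config
    dt = cfg.dt
    steps_per_unit = int(round(1.0 / dt))
    if abs(steps_per_unit * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide the unit sampling interval")
    n_steps = (cfg.n_points - 1) * steps_per_unit
    hist = np.empty(n_steps + 1)
    hist[0] = cfg.x0

    def delayed(t):
        # x(t - tau) with x = 0 for negative times, linear interpolation on the grid
        td = t - cfg.tau
        if td < 0:
            return cfg.history
        g = td / dt
        i = int(g)
        if i >= n_steps:
            return hist[n_steps]
        frac = g - i
        return hist[i] * (1.0 - frac) + hist[i + 1] * frac if frac > 0 else hist[i]

    for i in range(n_steps):
        t = i * dt
        x = hist[i]
        k1 = _mg_rhs(x, delayed(t))
        k2 = _mg_rhs(x + 0.5 * dt * k1, delayed(t + 0.5 * dt))
        k3 = _mg_rhs(x + 0.5 * dt * k2, delayed(t + 0.5 * dt))
        k4 = _mg_rhs(x + dt * k3, delayed(t + dt))
        hist[i + 1] = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(hist[i + 1]) or abs(hist[i + 1]) > 1e6:
            raise FloatingPointError(f"Mackey-Glass integration diverged at step {i}")

    series = hist[::steps_per_unit].copy()
    if cfg.snr_db is not None:
        series = add_noise(series, cfg.snr_db, cfg.seed)
    return series


def add_noise(series: np.ndarray, snr_db: float | None, seed: int | np.random.Generator = 0):
    """Add zero-mean uniform noise scaled to the requested empirical SNR (dB)."""
    series = np.asarray(series, dtype=float)
    if snr_db is None:
        return series.copy()
    p_sig = float(np.mean(series ** 2))
    if p_sig == 0.0:
        raise ValueError("cannot scale noise against a zero-power signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.uniform(-1.0, 1.0, size=series.shape)
    p_noise_target = p_sig / (10.0 ** (snr_db / 10.0))
    raw *= np.sqrt(p_noise_target / np.mean(raw ** 2))
    return series + raw


def make_regressors(
    data, lags, ph: int = 0, target: str | None = None, names: list[str] | None = None
) -> Dataset:
    """Delay-embed series into a regressor dataset.

    Parameters
    ----------
    data : 1-D array or dict of named 1-D arrays
        The source series.  A bare array is treated as ``{"x": data}`` with
        the target defaulting to ``"x"``.
    lags : list of (name, lag) pairs, or list of ints for a bare array
        Each pair contributes the regressor ``name(t - lag)``.
    ph : int
        Prediction horizon: row t carries regressors at their lags and the
        target value at time t + ph.
    target : str
        Which series is the target (default: the only/first one).

    Rows run over every t for which all lags and the target are in range.
    """
    if not isinstance(data, dict):
        data = {"x": np.asarray(data, dtype=float).ravel()}
        lags = [("x", int(l)) for l in lags]
        target = target or "x"
    else:
        data = {k: np.asarray(v, dtype=float).ravel() for k, v in data.items()}
        target = target or next(iter(data))
    n = len(data[target])
    for k, v in data.items():
        if v.size != n:
            raise ValueError("all series must have equal length")
    max_lag = max(l for _, l in lags)
    if any(l < 0 for _, l in lags):
        raise ValueError("lags must be non-negative")
    t0, t1 = max_lag, n - ph  # rows t in [t0, t1)
    if t1 <= t0:
        raise ValueError("series too short for the requested lags and horizon")
    t = np.arange(t0, t1)
    U = np.column_stack([data[k][t - l] for k, l in lags])
    y = data[target][t + ph]
    cols = names or [f"{k}(t-{l})" if l else f"{k}(t)" for k, l in lags]
    return Dataset(U=U, y=y, ph=ph, column_names=cols)


def mackey_glass_dataset(
    tau: float = 17.0,
    snr_db: float | None = None,
    seed: int = 0,
    window: tuple[int, int] = (124, 1123),
    n_train: int = 500,
    target: str = "noisy",
) -> tuple[Dataset, Dataset]:
    """Standard Mackey-Glass prediction task: regressors
    [x(t-6), x(t-12), x(t-18), x(t-24)] -> x(t) over the identification
    window, first ``n_train`` retained points for training.

    For noisy variants (``snr_db`` set) the regressors are always built from
    the observed (noisy) series; ``target`` chooses whether errors are
    scored against the ``"noisy"`` observations (the default -- they are
    what a real sensor delivers) or the underlying ``"clean"`` series.
    """
    if target not in ("noisy", "clean"):
        raise ValueError("target must be 'noisy' or 'clean'")
    clean = simulate_mackey_glass(MGConfig(tau=tau, seed=seed))
    series = add_noise(clean, snr_db, seed) if snr_db is not None else clean
    t = np.arange(window[0], window[1] + 1)
    lags = (6, 12, 18, 24)
    U = np.column_stack([series[t - l] for l in lags])
    y = series[t] if target == "noisy" else clean[t]
    ds = Dataset(
        U=U, y=y, ph=0, column_names=[f"x(t-{l})" for l in lags]
    )
    return ds.split(n_train)


def plant_dataset(plant_id: str, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Train/test datasets for a benchmark plant under its standard protocol.

    Training uses the random excitation (seeded), testing the deterministic
    sinusoidal signal; regressors follow the plant's own difference-equation
    arguments (series-parallel, measured past outputs).
    """
    ylags, ulags = plant_regressor_lags[plant_id]
    u_tr = train_input(plant_id, seed)
    y_tr = simulate_plant(plant_id, u_tr)
    u_te = test_input(plant_id)
    y_te = simulate_plant(plant_id, u_te)
    lags = [("y", l) for l in ylags] + [("u", l) for l in ulags]
    train = make_regressors({"y": y_tr, "u": u_tr}, lags, ph=0, target="y")
    test = make_regressors({"y": y_te, "u": u_te}, lags, ph=0, target="y")
    return train, test


# --------------------------------------------------------------------------
# Box-Jenkins gas furnace
# --------------------------------------------------------------------------
def load_gas_furnace(path) -> tuple[Dataset, Dataset]:
    """Load the 296-sample gas-furnace record and build its standard task.

    The file must hold two columns (gas flow rate u, CO2 concentration y),
    whitespace- or comma-delimited, no header.  Regressors are
    y(k-1), y(k-2), y(k-3), u(k), u(k-1), u(k-2) -> y(k); the 296 samples
    are split into equal first/second halves for train/test.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                vals = [float(p) for p in parts if p]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {ln}: {line!r}") from exc
            if len(vals) != 2:
                raise ValueError(
                    f"{path}: line {ln} has {len(vals)} columns, expected 2"
                )
            rows.append(vals)
    arr = np.asarray(rows, dtype=float)
    if arr.shape[0] != 296:
        warnings.warn(
            f"expected 296 gas-furnace rows, found {arr.shape[0]}; proceeding",
            stacklevel=2,
        )
    u, y = arr[:, 0], arr[:, 1]
    lags = [("y", 1), ("y", 2), ("y", 3), ("u", 0), ("u", 1), ("u", 2)]
    ds = make_regressors({"y": y, "u": u}, lags, ph=0, target="y")
    return ds.split(ds.n // 2)


# --------------------------------------------------------------------------
# synthetic EMG-envelope -> torque trials
# --------------------------------------------------------------------------
EMG_MUSCLES = ("BB", "BR", "TBL", "TBM")  # two elbow flexors, two extensors


@dataclass
class EMGSynthConfig:
    """Synthetic isometric flexion/extension ramp trial.

    Emulates the layout of envelope-level elbow-torque recordings: a
    triangular torque demand alternating between +/- ``mvc_percent`` of a
    nominal maximum voluntary contraction over four ramps, four rectified
    low-pass-filtered envelope channels (flexors BB/BR driven by positive
    torque demand, extensors TBL/TBM by negative demand), a mild monotone
    nonlinearity between drive and torque contribution, inter-muscle
    crosstalk, and additive measurement noise.
    """

    n_samples: int = 796
    mvc_percent: float = 50.0
    n_muscles: int = 4
    gains: tuple[float, ...] = (1.0, 0.7, 1.1, 0.8)
    nonlinearity: float = 1.0  # exponent on the normalised drive (1 = linear)
    noise_level: float = 0.02  # envelope-relative additive noise std
    crosstalk: float = 0.05
    torque_mvc: float = 60.0  # nominal MVC torque, N*m
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_muscles != 4:
            raise ValueError("the synthetic protocol uses exactly 4 muscles")


def _triangle_ramps(n: int, n_ramps: int = 4) -> np.ndarray:
    """Alternating flexion/extension triangular demand in [-1, 1]:
    0 -> +1 -> 0 -> -1 -> 0 per ramp pair."""
    t = np.linspace(0.0, n_ramps, n, endpoint=False)
    phase = t % 2.0
    tri = np.where(phase < 1.0, 1.0 - np.abs(2.0 * phase - 1.0), -(1.0 - np.abs(2.0 * (phase - 1.0) - 1.0)))
    return tri


def gen_synthetic_emg(config: EMGSynthConfig) -> Dataset:
    """Generate one synthetic trial: 4 envelope regressors -> torque target.

    The clean envelope of muscle ``j`` is its gain times its activation
    drive (flexors follow positive torque demand, extensors negative);
    multiplicative envelope fluctuation -- smoothed rectified noise, the
    hallmark of real sEMG envelopes -- enters scaled by ``noise_level``,
    as does additive torque measurement noise.  Torque is a monotone power
    of the demand times the nominal MVC torque, so with ``noise_level=0``,
    ``crosstalk=0`` and ``nonlinearity=1`` the torque is an exact linear
    combination of the four envelopes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    demand = _triangle_ramps(n) * (cfg.mvc_percent / 100.0)
    flex_drive = np.maximum(demand, 0.0)
    ext_drive = np.maximum(-demand, 0.0)
    drives = np.column_stack([flex_drive, flex_drive, ext_drive, ext_drive])

    env = drives * np.asarray(cfg.gains)[None, :]
    if cfg.noise_level > 0:
        # 1 Hz-equivalent 4th-order low-pass on rectified noise
        fs = n / 25.0  # trials last ~25 s
        b, a = butter(4, min(1.0 / (fs / 2.0), 0.99))
        for j in range(4):
            carrier = filtfilt(b, a, np.abs(rng.standard_normal(n)))
            carrier = carrier / max(np.mean(carrier), 1e-12) - 1.0
            env[:, j] = env[:, j] * (1.0 + cfg.noise_level * 5.0 * carrier)
        env = np.maximum(env, 0.0)
    if cfg.crosstalk > 0:
        mix = np.full((4, 4), cfg.crosstalk) + (1 - cfg.crosstalk) * np.eye(4)
        env = env @ mix.T

    # torque: monotone (possibly nonlinear) function of the signed demand
    signed = np.sign(demand) * np.abs(demand) ** cfg.nonlinearity
    torque = cfg.torque_mvc * signed
    if cfg.noise_level > 0:
        torque = torque + cfg.noise_level * cfg.torque_mvc * 0.05 * rng.standard_normal(n)
    return Dataset(U=env, y=torque, ph=0, column_names=list(EMG_MUSCLES))


def load_emg_trials(path) -> list[dict]:
    """Load per-trial envelope/torque CSVs from a directory or a single file.

    Each trial CSV must hold the columns BB, BR, TBL, TBM and torque.  Trial
    tags (participant, %MVC) are parsed from filenames matching
    ``*S<participant>*_<mvc>mvc*.csv`` when present.  Returns a list of
    ``{"dataset": Dataset, "participant": str|None, "mvc": int|None,
    "path": str}`` records.
    """
    p = Path(path)
    files = sorted(p.glob("*.csv")) if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no trial CSVs found under {path}")
    trials = []
    for f in files:
        df = pd.read_csv(f)
        missing = [c for c in (*EMG_MUSCLES, "torque") if c not in df.columns]
        if missing:
            raise ValueError(f"{f}: missing column(s) {missing}")
        ds = Dataset(
            U=df[list(EMG_MUSCLES)].to_numpy(dtype=float),
            y=df["torque"].to_numpy(dtype=float),
            ph=0,
            column_names=list(EMG_MUSCLES),
        )
        m_part = re.search(r"S(\d+)", f.stem)
        m_mvc = re.search(r"(\d+)\s*mvc", f.stem, flags=re.IGNORECASE)
        trials.append(
            {
                "dataset": ds,
                "participant": m_part.group(1) if m_part else None,
                "mvc": int(m_mvc.group(1)) if m_mvc else None,
                "path": str(f),
            }
        )
    return trials
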