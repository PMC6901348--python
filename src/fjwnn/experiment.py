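"""Multi-seed experiment runner.

An experiment fits the model R times with consecutive seeds on one of the
named benchmark protocols (or user-supplied train/test datasets), evaluates
train/test metrics per run, and aggregates mean +/- std tables together with
rule/parameter counts.  Per-run failures are recorded and skipped so partial
results survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset
from .ica import ICAConfig
from .model import FJWNN
from .selection import SelectionConfig
from .training import InitConfig

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "benchmark_splits",
    "validate_report",
    "BENCHMARK_NAMES",
]

BENCHMARK_NAMES = (
    "example1",
    "plant2-1",
    "plant2-2",
    "plant2-3",
    "plant2-4",
    "plant2-5",
    "mackey-glass",
    "emg-synth",
)


def benchmark_splits(name: str, seed: int = 0, **kwargs) -> tuple[Dataset, Dataset]:
    """Train/test datasets for a named benchmark protocol.

    ``example1`` draws an independent test sample of the same size as the
    training sample; plants use their deterministic sinusoidal test inputs;
    ``mackey-glass`` accepts ``tau``/``snr_db``; ``emg-synth`` splits one
    synthetic trial chronologically 60/40 (ramp coverage in both parts).
    """
    from . import benchmarks as B

    if name == "example1":
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
        train = B.gen_example1(kwargs.get("n", 200), rng)
        test = B.gen_example1(kwargs.get("n", 200), rng)
        return train, test
    if name.startswith("plant"):
        return B.plant_dataset(name[len("plant"):], seed=seed)
    if name == "mackey-glass":
        return B.mackey_glass_dataset(
            tau=kwargs.get("tau", 17.0),
            snr_db=kwargs.get("snr_db"),
            seed=seed,
            target=kwargs.get("target", "noisy"),
        )
    if name == "emg-synth":
        cfg = B.EMGSynthConfig(seed=seed, **{
            k: v for k, v in kwargs.items() if k in B.EMGSynthConfig.__dataclass_fields__ and k != "seed"
        })
        ds = B.gen_synthetic_emg(cfg)
        return ds.split(int(ds.n * 0.6))
    raise ValueError(f"unknown benchmark {name!r}; choose from {BENCHMARK_NAMES}")


@dataclass
class ExperimentConfig:
    """A repeated-fit experiment specification."""

    benchmark: str
    runs: int = 10
    base_seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ica: ICAConfig = field(default_factory=ICAConfig)
    init: InitConfig = field(default_factory=InitConfig)
    benchmark_kwargs: dict = field(default_factory=dict)
    regenerate_data_per_run: bool = True
    output_dir: str | None = None

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("need at least one run")


METRIC_KEYS = ("rmse", "rrse", "rel_err_pct", "vaf_pct")


def validate_report(report: dict) -> None:
    """Check a report dict against the expected schema; raises ValueError.

    The schema is structural: required keys, value types, and mean/std
    aggregate entries for every metric on both splits.
    """
    def need(d, key, typ, where):
        if key not in d:
            raise ValueError(f"report{where} missing key {key!r}")
        if not isinstance(d[key], typ):
            raise ValueError(f"report{where}[{key!r}] has type {type(d[key]).__name__}")

    need(report, "benchmark", str, "")
    for k in ("runs_requested", "runs_completed", "base_seed"):
        need(report, k, int, "")
    need(report, "failures", list, "")
    need(report, "per_run", list, "")
    need(report, "aggregate", dict, "")
    for split in ("train", "test"):
        need(report["aggregate"], split, dict, "['aggregate']")
        for metric in METRIC_KEYS:
            need(report["aggregate"][split], metric, dict, f"['aggregate']['{split}']")
            for stat in ("mean", "std"):
                need(
                    report["aggregate"][split][metric], stat, (int, float),
                    f"['aggregate']['{split}']['{metric}']",
                )
    for rec in report["per_run"]:
        for k in ("seed", "n_rules", "n_parameters"):
            need(rec, k, int, "['per_run'][i]")
        for split in ("train", "test"):
            need(rec, split, dict, "['per_run'][i]")


def run_experiment(
    config: ExperimentConfig,
    data: tuple[Dataset, Dataset] | None = None,
) -> dict:
    """Fit R models with seeds base_seed..base_seed+R-1 and aggregate metrics.

    ``data`` overrides the named benchmark with explicit (train, test)
    datasets.  Returns the report dict; if ``output_dir`` is set, also writes
    ``report.json``, ``metrics.csv`` and per-run model files there.
    """
    cfg = config
    runs = []
    failures = []
    for r in range(cfg.runs):
        seed = cfg.base_seed + r
        try:
            if data is not None:
                train, test = data
            else:
                data_seed = seed if cfg.regenerate_data_per_run else cfg.base_seed
                train, test = benchmark_splits(cfg.benchmark, data_seed, **cfg.benchmark_kwargs)
            model = FJWNN(train, selection=cfg.selection, ica=cfg.ica, init=cfg.init)
            res = model.fit(seed=seed)
            rec = {
                "seed": seed,
                "train": res.evaluate(train),
                "test": res.evaluate(test),
                "n_rules": res.n_rules,
                "n_parameters": res.n_parameters,
            }
            runs.append((rec, res))
        except Exception as exc:  # noqa: BLE001 - partial results must survive
            failures.append({"seed": seed, "error": f"{type(exc).__name__}: {exc}"})
    if not runs:
        raise RuntimeError(f"all {cfg.runs} runs failed: {failures}")

    def agg(values):
        values = np.asarray(values, dtype=float)
        return {
            "mean": float(values.mean()),
            "std": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        }

    report = {
        "benchmark": cfg.benchmark,
        "runs_requested": cfg.runs,
        "runs_completed": len(runs),
        "base_seed": cfg.base_seed,
        "failures": failures,
        "per_run": [rec for rec, _ in runs],
        "aggregate": {
            split: {k: agg([rec[split][k] for rec, _ in runs]) for k in METRIC_KEYS}
            for split in ("train", "test")
        },
    }
    report["aggregate"]["n_rules"] = agg([rec["n_rules"] for rec, _ in runs])
    report["aggregate"]["n_parameters"] = agg([rec["n_parameters"] for rec, _ in runs])

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        rows = []
        for rec, _ in runs:
            row = {"seed": rec["seed"], "n_rules": rec["n_rules"], "n_parameters": rec["n_parameters"]}
            for split in ("train", "test"):
                for k in METRIC_KEYS:
                    row[f"{split}_{k}"] = rec[split][k]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        for rec, res in runs:
            res.save(out / f"model_run{rec['seed']}.json")
    return report
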