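"""Scenario orchestration: clean/missing protocols, sweeps and the headline run.

Three train/test scenarios are compared:

* ``clean_clean`` — no masking anywhere (the ceiling);
* ``clean_missing`` — the *traditional* protocol: train on clean data, test
  on data with missing-at-random rows;
* ``missing_missing`` — the *proposed* protocol: induce the same missing
  rate in the training data too (independent masks), so the model learns the
  feature distribution it will face at test time. No imputation is performed
  at any point; robustness comes entirely from train-time corruption.

Every run threads one integer seed through mask draws, noise and classifier
fitting, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classification import CASES, Model, ModelConfig, ScenarioResult, evaluate, train
from .features import apply_feature_fill, build_feature_table, fit_feature_fill
from .io_formats import SensorSeries
from .missingness import induce_mar
from .synthetic_signals import build_simulated_dataset
from .windowing import WindowConfig, segment

logger = logging.getLogger(__name__)

#: Missing-rate grids: benchmark datasets tolerate only a few percent, the
#: synthetic waveforms are probed much harder.
BENCHMARK_RATES = (0.02, 0.03, 0.05, 0.07, 0.08, 0.10)
SYNTHETIC_RATES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

#: Window configuration of the synthetic three-waveform experiment: short
#: (sub-period) windows with a dense slide, so windowed statistics vary with
#: waveform phase and each window carries few enough samples for induced
#: missingness to bite.
SYNTHETIC_WINDOW = WindowConfig(window_s=0.3, slide_s=0.1)
SYNTHETIC_TRAIN_FRACTION = 0.8


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [_child_seed(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _mask_series(
    series_list: Sequence[SensorSeries], rate: float, seed: int
) -> list[SensorSeries]:
    seeds = _spawn_seeds(seed, len(series_list))
    return [induce_mar(s, rate, sd) for s, sd in zip(series_list, seeds)]


def featurize(
    series_list: Sequence[SensorSeries], window_config: WindowConfig
) -> pd.DataFrame:
    """Segment each series and stack the per-window feature rows."""
    tables = []
    for s in series_list:
        windows = segment(s, window_config)
        tables.append(
            build_feature_table(
                windows, s.channels, min_valid_samples=window_config.min_valid_samples
            )
        )
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def run_scenario(
    train_series: Sequence[SensorSeries],
    test_series: Sequence[SensorSeries],
    case: str,
    missing_rate: float,
    window_config: WindowConfig | None = None,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    train_rate: float | None = None,
) -> ScenarioResult:
    """Mask per the case, then segment -> featurize -> train -> evaluate.

    ``train_rate`` overrides the training-side missing rate of the proposed
    protocol (default: same rate as the test side). Train and test masks are
    always drawn with independent seeds.
    """
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    window_config = window_config or WindowConfig()
    model_config = model_config or ModelConfig()
    train_mask_seed, test_mask_seed, model_seed = _spawn_seeds(seed, 3)

    if case == "missing_missing":
        rate_tr = missing_rate if train_rate is None else train_rate
        train_series = _mask_series(train_series, rate_tr, train_mask_seed)
    if case in ("clean_missing", "missing_missing"):
        test_series = _mask_series(test_series, missing_rate, test_mask_seed)

    train_feats = featurize(train_series, window_config)
    test_feats = featurize(test_series, window_config)
    fill = fit_feature_fill(train_feats)
    model = train(apply_feature_fill(train_feats, fill), replace(model_config, seed=model_seed))
    result = evaluate(model, apply_feature_fill(test_feats, fill))
    return replace(
        result,
        case=case,
        missing_rate=missing_rate,
        window_s=window_config.window_s,
        slide_s=window_config.slide_s,
        seed=seed,
    )


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian grid of scenario cells to evaluate."""

    missing_rates: tuple[float, ...] = BENCHMARK_RATES
    window_sizes: tuple[float, ...] = (1.0,)
    slides: tuple[float | None, ...] = (None,)  # None -> window/2
    classifiers: tuple[str, ...] = ("random_forest",)
    cases: tuple[str, ...] = ("clean_missing", "missing_missing")
    n_seeds: int = 1
    base_seed: int = 0
    min_valid_samples: int = 4

    def __post_init__(self) -> None:
        for r in self.missing_rates:
            if not 0 <= r < 1:
                raise ValueError(f"missing rate {r} outside [0, 1)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    def cells(self):
        return itertools.product(
            self.cases,
            self.missing_rates,
            self.window_sizes,
            self.slides,
            self.classifiers,
            range(self.n_seeds),
        )


_SWEEP_KEY = ["case", "missing_rate", "window_s", "slide_s", "classifier", "seed_index"]


def sweep(
    spec: SweepSpec,
    train_series: Sequence[SensorSeries],
    test_series: Sequence[SensorSeries],
    checkpoint: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full Cartesian product of scenario cells.

    One result row per cell with its seed recorded; failed cells are logged
    and marked ``status="failed"`` while the sweep continues. With a
    ``checkpoint`` path, completed cells are reloaded and skipped, making the
    sweep resumable.
    """
    done = pd.DataFrame()
    if checkpoint is not None and Path(checkpoint).exists():
        done = pd.read_csv(checkpoint)
    rows = [] if done.empty else done.to_dict("records")
    done_keys = (
        set(map(tuple, done[_SWEEP_KEY].itertuples(index=False))) if not done.empty else set()
    )
    for cell_index, (case, rate, window_s, slide_s, clf, seed_idx) in enumerate(spec.cells()):
        slide_val = slide_s if slide_s is not None else window_s / 2
        key = (case, rate, window_s, slide_val, clf, seed_idx)
        if key in done_keys:
            continue
        cell_seed = _child_seed(np.random.SeedSequence([spec.base_seed, cell_index]))
        row = dict(zip(_SWEEP_KEY, key))
        row["seed"] = cell_seed
        try:
            result = run_scenario(
                train_series,
                test_series,
                case,
                rate,
                WindowConfig(window_s, slide_val, spec.min_valid_samples),
                ModelConfig(kind=clf),
                seed=cell_seed,
            )
            row.update(accuracy=result.accuracy, n_windows=result.n_windows, status="ok")
        except Exception:  # noqa: BLE001 -- partial failure must not kill the sweep
            logger.exception("sweep cell %s failed", key)
            row.update(accuracy=np.nan, n_windows=0, status="failed")
        rows.append(row)
        if checkpoint is not None:
            pd.DataFrame(rows).to_csv(checkpoint, index=False)
    return pd.DataFrame(rows)


def synthetic_series(
    n_per_class: int = 400,
    train_fraction: float = SYNTHETIC_TRAIN_FRACTION,
    seed: int = 0,
    spec_overrides: dict | None = None,
) -> tuple[list[SensorSeries], list[SensorSeries]]:
    """The simulated three-waveform dataset as train/test SensorSeries lists."""
    train_ls, test_ls = build_simulated_dataset(
        n_per_class=n_per_class,
        train_fraction=train_fraction,
        seed=seed,
        spec_overrides=spec_overrides,
    )

    def convert(ls_list):
        out = []
        for ls in ls_list:
            fs = None
            if len(ls.timestamps) > 1:
                fs = 1.0 / float(ls.timestamps[1] - ls.timestamps[0])
            out.append(ls.to_sensor_series(sampling_rate=fs))
        return out

    return convert(train_ls), convert(test_ls)


@dataclass
class HeadlineResult:
    """Outcome of the traditional-vs-proposed comparison over a rate grid.

    ``best_rate`` is the missing rate with the largest seed-averaged
    (proposed - traditional) accuracy gap; ``traditional_accuracy`` and
    ``proposed_accuracy`` are the seed-averaged accuracies at that rate.
    ``table`` holds every (rate, replicate, protocol, accuracy) cell.
    """

    best_rate: float
    traditional_accuracy: float
    proposed_accuracy: float
    table: pd.DataFrame

    def rate_means(self) -> pd.DataFrame:
        return (
            self.table.pivot_table(
                index="missing_rate", columns="protocol", values="accuracy", aggfunc="mean"
            )
        )


def headline_comparison(
    rates: Sequence[float] = SYNTHETIC_RATES,
    n_seeds: int = 10,
    seed: int = 0,
    n_per_class: int = 400,
    train_fraction: float = SYNTHETIC_TRAIN_FRACTION,
    window_config: WindowConfig | None = None,
    model_config: ModelConfig | None = None,
    spec_overrides: dict | None = None,
) -> HeadlineResult:
    """Seed-averaged traditional vs proposed accuracy per missing rate.

    Per replicate the synthetic dataset is regenerated with fresh noise, the
    clean (traditional) model is fitted once and evaluated against
    independently masked test data at every rate, and a proposed model is
    fitted per rate on masked training data. Reusing the clean model across
    rates is exact: neither it nor its feature-fill values depend on the test
    mask.
    """
    rates = list(rates)
    if not rates:
        raise ValueError("rates must be non-empty")
    window_config = window_config or SYNTHETIC_WINDOW
    model_config = model_config or ModelConfig()
    rows = []
    rep_seqs = np.random.SeedSequence(seed).spawn(n_seeds)
    for rep, rep_seq in enumerate(rep_seqs):
        data_seed, clean_model_seed, mask_root = (_child_seed(c) for c in rep_seq.spawn(3))
        train_series, test_series = synthetic_series(
            n_per_class=n_per_class,
            train_fraction=train_fraction,
            seed=data_seed,
            spec_overrides=spec_overrides,
        )
        clean_train_feats = featurize(train_series, window_config)
        clean_fill = fit_feature_fill(clean_train_feats)
        clean_model = train(
            apply_feature_fill(clean_train_feats, clean_fill),
            replace(model_config, seed=clean_model_seed),
        )
        rate_seeds = _spawn_seeds(mask_root, 3 * len(rates))
        for j, rate in enumerate(rates):
            trad_test_seed, prop_seed_a, prop_seed_b = rate_seeds[3 * j : 3 * j + 3]
            # traditional: clean model, masked test
            masked_test = _mask_series(test_series, rate, trad_test_seed)
            trad = evaluate(
                clean_model, apply_feature_fill(featurize(masked_test, window_config), clean_fill)
            )
            rows.append(
                dict(missing_rate=rate, replicate=rep, protocol="traditional",
                     accuracy=trad.accuracy, n_windows=trad.n_windows)
            )
            # proposed: mask train and test independently at the same rate
            prop_train = _mask_series(train_series, rate, prop_seed_a)
            prop_feats = featurize(prop_train, window_config)
            prop_fill = fit_feature_fill(prop_feats)
            prop_model = train(
                apply_feature_fill(prop_feats, prop_fill),
                replace(model_config, seed=prop_seed_a),
            )
            prop_test = _mask_series(test_series, rate, prop_seed_b)
            prop = evaluate(
                prop_model, apply_feature_fill(featurize(prop_test, window_config), prop_fill)
            )
            rows.append(
                dict(missing_rate=rate, replicate=rep, protocol="proposed",
                     accuracy=prop.accuracy, n_windows=prop.n_windows)
            )
    table = pd.DataFrame(rows)
    means = table.pivot_table(
        index="missing_rate", columns="protocol", values="accuracy", aggfunc="mean"
    )
    gap = means["proposed"] - means["traditional"]
    best_rate = float(gap.idxmax())
    return HeadlineResult(
        best_rate=best_rate,
        traditional_accuracy=float(means.loc[best_rate, "traditional"]),
        proposed_accuracy=float(means.loc[best_rate, "proposed"]),
        table=table,
    )


def write_manifest(path: str | Path, config: dict) -> None:
    """Record the run configuration, seeds and code version next to results."""
    manifest = {"actigap_version": __version__, **config}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def plot_accuracy_vs_rate(table: pd.DataFrame, path: str | Path | None = None):
    """Accuracy-vs-missing-rate curves per protocol (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = table.pivot_table(
        index="missing_rate", columns="protocol", values="accuracy", aggfunc="mean"
    )
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for protocol in means.columns:
        ax.plot(means.index * 100, means[protocol] * 100, marker="o", label=protocol)
    ax.set_xlabel("missing rate (%)")
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
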