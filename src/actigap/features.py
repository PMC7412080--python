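"""Windowed statistical features tolerant of missing rows.

Seven statistics per axis — mean, variance, skewness, kurtosis, max, min and
MAD — giving 21 features for tri-axial data (7 for single-channel). Each
statistic is computed over the window's valid (non-missing) rows only, so the
feature of a masked window equals the feature of the explicitly-subsetted
valid subsequence; missing rows never enter the arithmetic and are never
imputed at the signal level.

Conventions, followed exactly as defined:

* variance is the population form (divide by n);
* skewness is the adjusted sample form ``n/((n-1)(n-2)) * sum(((x-mean)/S)^3)``
  with S the sample standard deviation (divide by n-1);
* kurtosis is the adjusted excess form
  ``n(n+1)/((n-1)(n-2)(n-3)) * sum(((x-mean)/S)^4) - 3(n-1)^2/((n-2)(n-3))``
  (0 for a large normal sample);
* MAD is the mean absolute deviation about the median:
  ``sum(|x_i - M|)/n`` with M the sample median.

A statistic whose preconditions fail (too few valid samples, zero spread) is
flagged *undefined* rather than propagated as NaN arithmetic; how undefined
entries are filled before classification is a policy decision made on
training data only (see :func:`fit_feature_fill`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windowing import Window, DEFAULT_MIN_VALID

#: Statistic names in table order (stat-major across axes).
STAT_NAMES = ("mean", "var", "skew", "kurt", "max", "min", "mad")

#: Metadata columns of a feature table; everything else is a feature.
METADATA_COLUMNS = ("subject", "start", "label")


class UndefinedFeatureError(ValueError):
    """A statistic's preconditions are not met on the valid subsample."""


def _valid_1d(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise UndefinedFeatureError("no valid samples")
    return v


def mean(values) -> float:
    """Arithmetic mean over the valid samples."""
    return float(np.mean(_valid_1d(values)))


def variance(values) -> float:
    """Population variance E[(X - mean)^2] (divide by n)."""
    return float(np.var(_valid_1d(values)))


def _sample_sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1))


def skewness(values) -> float:
    """Adjusted sample skewness; requires n >= 3 and positive spread."""
    v = _valid_1d(values)
    n = v.size
    if n < 3:
        raise UndefinedFeatureError(f"skewness needs >= 3 samples, got {n}")
    s = _sample_sd(v)
    if s == 0:
        raise UndefinedFeatureError("skewness undefined for zero spread")
    z = (v - v.mean()) / s
    return float(n / ((n - 1) * (n - 2)) * np.sum(z**3))


def kurtosis(values) -> float:
    """Adjusted excess kurtosis; requires n >= 4 and positive spread."""
    v = _valid_1d(values)
    n = v.size
    if n < 4:
        raise UndefinedFeatureError(f"kurtosis needs >= 4 samples, got {n}")
    s = _sample_sd(v)
    if s == 0:
        raise UndefinedFeatureError("kurtosis undefined for zero spread")
    z = (v - v.mean()) / s
    term = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * np.sum(z**4)
    return float(term - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


def mad(values) -> float:
    """Mean absolute deviation about the median: sum(|x_i - M|)/n."""
    v = _valid_1d(values)
    return float(np.mean(np.abs(v - np.median(v))))


_STAT_FUNCS = {
    "mean": mean,
    "var": variance,
    "skew": skewness,
    "kurt": kurtosis,
    "max": lambda v: float(np.max(_valid_1d(v))),
    "min": lambda v: float(np.min(_valid_1d(v))),
    "mad": mad,
}


def feature_names(channels: tuple[str, ...]) -> list[str]:
    """Feature column names in table order: each statistic across all axes."""
    return [f"{stat}_{ch}" for stat in STAT_NAMES for ch in channels]


@dataclass
class FeatureVector:
    """The per-window statistics with per-entry validity flags.

    ``values`` holds NaN where the statistic is undefined; ``defined`` marks
    which entries are usable. Order matches :func:`feature_names`.
    """

    names: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def extract_features(
    window: Window,
    channels: tuple[str, ...] | None = None,
    min_valid_samples: int = DEFAULT_MIN_VALID,
    include_median: bool = False,
) -> FeatureVector:
    """Compute the per-axis statistics of a window over its valid rows only.

    A window with fewer than ``min_valid_samples`` valid rows yields an
    all-undefined vector. ``include_median`` appends the plain median per
    axis as extra columns (off by default).
    """
    if channels is None:
        channels = tuple(f"c{i}" for i in range(window.values.shape[1]))
    names = tuple(feature_names(channels))
    if include_median:
        names = names + tuple(f"median_{ch}" for ch in channels)
    n_feat = len(names)
    values = np.full(n_feat, np.nan)
    defined = np.zeros(n_feat, dtype=bool)
    if window.n_valid >= min_valid_samples:
        valid = window.valid_values()
        stats = list(STAT_NAMES) + (["median"] if include_median else [])
        i = 0
        for stat in stats:
            func = _STAT_FUNCS.get(stat, lambda v: float(np.median(_valid_1d(v))))
            for c in range(len(channels)):
                try:
                    values[i] = func(valid[:, c])
                    defined[i] = True
                except UndefinedFeatureError:
                    pass
                i += 1
    return FeatureVector(names=names, values=values, defined=defined)


def build_feature_table(
    windows,
    channels: tuple[str, ...],
    min_valid_samples: int = DEFAULT_MIN_VALID,
    include_median: bool = False,
) -> pd.DataFrame:
    """One row per window: subject, window start, label, then the features.

    Undefined statistics appear as NaN; fill them with
    :func:`fit_feature_fill` / :func:`apply_feature_fill` before training.
    """
    rows = []
    names: tuple[str, ...] | None = None
    for w in windows:
        fv = extract_features(
            w, channels, min_valid_samples=min_valid_samples, include_median=include_median
        )
        names = fv.names
        rows.append([w.subject_id, w.start, w.label, *fv.values])
    if names is None:
        names = tuple(feature_names(channels))
    return pd.DataFrame(rows, columns=[*METADATA_COLUMNS, *names])


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def fit_feature_fill(train_table: pd.DataFrame) -> pd.Series:
    """Per-feature fill values: the training-set median of each defined column.

    Computed once on training data and frozen, so applying it to test data
    leaks nothing; a column undefined everywhere falls back to 0.
    """
    cols = feature_columns(train_table)
    fill = train_table[cols].median(skipna=True)
    return fill.fillna(0.0)


def apply_feature_fill(table: pd.DataFrame, fill: pd.Series) -> pd.DataFrame:
    """Replace undefined (NaN) feature entries with the frozen fill values."""
    out = table.copy()
    out[fill.index] = out[fill.index].fillna(fill)
    return out
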