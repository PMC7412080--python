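"""Overlapping fixed-duration window segmentation of (possibly gappy) series.

Windows are timestamp-driven, half-open ``[start, start + window_s)``,
anchored at the first timestamp of each recording and advanced by
``slide_s``; the same physical boundaries therefore result at any sampling
rate. Masked rows stay inside their window (they occupy time) but are not
counted as valid samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SensorSeries

#: Default minimum number of valid (non-missing) samples for a usable window.
DEFAULT_MIN_VALID = 4

_EPS = 1e-9


@dataclass(frozen=True)
class WindowConfig:
    """Window duration, slide and validity threshold.

    ``slide_s`` defaults to ``window_s / 2`` (50% overlap). A slide larger
    than the window leaves unsampled gaps and triggers a warning.
    """

    window_s: float = 1.0
    slide_s: float | None = None
    min_valid_samples: int = DEFAULT_MIN_VALID

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.slide_s is None:
            object.__setattr__(self, "slide_s", self.window_s / 2)
        if self.slide_s <= 0:
            raise ValueError("slide_s must be > 0")
        if self.slide_s > self.window_s:
            warnings.warn(
                f"slide_s={self.slide_s} > window_s={self.window_s}: "
                "windows will leave gaps between them",
                stacklevel=2,
            )


@dataclass
class Window:
    """One time-bounded slice of a series with its majority activity label."""

    start: float
    end: float
    timestamps: np.ndarray
    values: np.ndarray  # (n_samples_in_window, n_channels)
    missing: np.ndarray  # bool per row
    label: object
    subject_id: str | None = None

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_valid(self) -> int:
        return int(np.sum(~self.missing))

    def valid_values(self) -> np.ndarray:
        """Channel values of the non-missing rows only."""
        return self.values[~self.missing]


def _majority_label(labels: np.ndarray) -> object:
    """Modal label; ties broken by earliest appearance in the window."""
    first_pos: dict = {}
    counts: dict = {}
    for i, lab in enumerate(labels):
        if lab not in counts:
            counts[lab] = 0
            first_pos[lab] = i
        counts[lab] += 1
    if not counts:
        return None
    return max(counts, key=lambda lab: (counts[lab], -first_pos[lab]))


def segment(series: SensorSeries, config: WindowConfig) -> list[Window]:
    """Cut ``series`` into windows of ``config.window_s`` advanced by ``config.slide_s``.

    The number of windows is ``floor((T - window_s) / slide_s) + 1`` for total
    duration ``T >= window_s`` (T = last - first timestamp plus one nominal
    sample period), else 0. Each window's label is the modal per-row label.
    """
    if series.n == 0:
        return []
    t0 = series.timestamps[0]
    T = series.duration
    if T + _EPS < config.window_s:
        return []
    n_windows = int(math.floor((T - config.window_s) / config.slide_s + _EPS)) + 1
    windows = []
    for i in range(n_windows):
        start = t0 + i * config.slide_s
        end = start + config.window_s
        lo = np.searchsorted(series.timestamps, start - _EPS, side="left")
        hi = np.searchsorted(series.timestamps, end - _EPS, side="left")
        sl = slice(lo, hi)
        windows.append(
            Window(
                start=float(start),
                end=float(end),
                timestamps=series.timestamps[sl],
                values=series.values[sl],
                missing=series.row_missing[sl],
                label=_majority_label(series.labels[sl]),
                subject_id=series.subject_id,
            )
        )
    return windows
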