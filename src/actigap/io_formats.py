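"""Readers and writers for the two benchmark accelerometer CSV dialects.

Two dialects are supported:

* HASC-style: ``timestamp,x,y,z`` rows (seconds; variable 10-100 Hz sampling),
  with the activity label carried per file (segmented mode) or in a separate
  label-interval track (sequential mode).
* Single-chest-style: ``sample_index,x,y,z,label`` rows at a nominal 52 Hz,
  with numeric labels 1-7 (0 marks unlabeled rows, which are dropped).

Missing cells are serialized as the literal token ``NA`` and represented in
memory as an explicit per-row missingness flag, never a sentinel value.

Conventions: timestamps are seconds; windows downstream use half-open
``[start, end)`` intervals anchored at each recording's first timestamp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: The six HASC activity classes.
HASC_LABELS = ("stay", "walk", "jog", "skip", "stUp", "stDown")

#: Numeric label -> class name for the single chest-mounted accelerometer set.
CHEST_LABELS = {
    1: "working_at_computer",
    2: "standup_walk_stairs",
    3: "standing",
    4: "walking",
    5: "going_updown_stairs",
    6: "walking_talking",
    7: "talking_standing",
}

CHEST_SAMPLING_RATE = 52.0


class FormatError(ValueError):
    """Raised for malformed sensor CSV content; message names file and line."""


@dataclass
class SensorSeries:
    """A timestamped multi-channel signal with explicit per-row missingness.

    Attributes
    ----------
    timestamps : ndarray of float
        Sample times in seconds, non-decreasing.
    values : ndarray, shape (n, n_channels)
        Channel values; rows flagged missing hold NaN.
    channels : tuple of str
        Channel names, e.g. ``("x", "y", "z")``.
    row_missing : ndarray of bool
        True where the whole row (all channels) is absent.
    labels : ndarray of object
        Per-row activity labels (a per-file label is broadcast to all rows).
    subject_id : str or None
        Subject/recording identifier used for leave-one-person-out splits.
    sampling_rate : float or None
        Nominal sampling rate in Hz; None if unknown/variable.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...] = ("x", "y", "z")
    row_missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        n = self.timestamps.shape[0]
        if self.values.shape[0] != n:
            raise ValueError("values and timestamps length mismatch")
        if len(self.channels) != self.values.shape[1]:
            raise ValueError("channel names do not match value columns")
        if self.row_missing is None:
            self.row_missing = np.all(np.isnan(self.values), axis=1) if n else np.zeros(0, bool)
        self.row_missing = np.asarray(self.row_missing, dtype=bool)
        if self.row_missing.shape[0] != n:
            raise ValueError("row_missing length mismatch")
        if self.labels is None:
            self.labels = np.full(n, None, dtype=object)
        elif np.ndim(self.labels) == 0:
            self.labels = np.full(n, self.labels, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != n:
            raise ValueError("labels length mismatch")
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @property
    def n(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        """Total recorded duration: last - first timestamp plus one nominal period."""
        if self.n == 0:
            return 0.0
        return self.timestamps[-1] - self.timestamps[0] + self.nominal_period

    @property
    def nominal_period(self) -> float:
        """Nominal inter-sample period (1/fs, or the median gap if fs unknown)."""
        if self.sampling_rate:
            return 1.0 / self.sampling_rate
        if self.n > 1:
            return float(np.median(np.diff(self.timestamps)))
        return 0.0

    def copy(self) -> "SensorSeries":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            values=self.values.copy(),
            row_missing=self.row_missing.copy(),
            labels=self.labels.copy(),
        )


def _parse_float(token: str, path: Path, line_no: int, col: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{line_no}: non-numeric, non-{NA_TOKEN} value {token!r} in column {col}"
        ) from None


def _read_rows(path: Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rows.append((line_no, [tok.strip() for tok in line.split(",")]))
    return rows


def _sidecar_label(path: Path) -> str:
    """Read the activity label from a HASC-style ``<stem>.meta`` sidecar file."""
    meta = path.with_suffix(".meta")
    if not meta.exists():
        raise FormatError(
            f"{path}: segmented mode needs an explicit label= or a {meta.name} sidecar"
        )
    for line in meta.read_text().splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            if key.strip().lower() in ("activity", "terminalactivity"):
                return value.strip()
    raise FormatError(f"{meta}: no 'Activity:' entry found")


def read_hasc(
    path: str | Path,
    mode: str = "segmented",
    label: str | None = None,
    label_track: str | Path | None = None,
    subject_id: str | None = None,
    validate_labels: bool = True,
) -> SensorSeries:
    """Read a HASC-dialect CSV (``timestamp,x,y,z``) into a :class:`SensorSeries`.

    Parameters
    ----------
    mode : {"segmented", "sequential"}
        Segmented files hold one activity; the label comes from ``label`` or a
        ``.meta`` sidecar. Sequential files hold several activities in a row;
        per-row labels come from ``label_track``, a ``start,end,label`` CSV of
        half-open intervals in the file's own time coordinates.
    validate_labels
        If True, labels must be among the six HASC activity classes.
    """
    path = Path(path)
    if mode not in ("segmented", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = _read_rows(path)
    ts, vals, miss = [], [], []
    prev_t = -np.inf
    prev_line = 0
    for line_no, toks in rows:
        if len(toks) != 4:
            raise FormatError(f"{path}:{line_no}: expected 4 columns, got {len(toks)}")
        t = _parse_float(toks[0], path, line_no, "timestamp")
        if t < prev_t:
            raise FormatError(
                f"{path}:{line_no}: timestamp {t} decreases from line {prev_line}"
            )
        prev_t, prev_line = t, line_no
        na = [tok == NA_TOKEN for tok in toks[1:]]
        if all(na):
            vals.append([np.nan] * 3)
            miss.append(True)
        elif any(na):
            raise FormatError(
                f"{path}:{line_no}: partial {NA_TOKEN} row (a missing timestep "
                "loses all channels)"
            )
        else:
            vals.append([_parse_float(toks[1 + i], path, line_no, c) for i, c in enumerate("xyz")])
            miss.append(False)
        ts.append(t)

    ts_arr = np.array(ts, dtype=float)
    labels: np.ndarray | str | None
    if mode == "segmented":
        labels = label if label is not None else _sidecar_label(path)
    else:
        if label_track is None:
            raise FormatError(f"{path}: sequential mode requires a label_track file")
        labels = _labels_from_track(Path(label_track), ts_arr)
    series = SensorSeries(
        timestamps=ts_arr,
        values=np.array(vals, dtype=float).reshape(-1, 3),
        channels=("x", "y", "z"),
        row_missing=np.array(miss, dtype=bool),
        labels=labels,
        subject_id=subject_id or path.stem,
    )
    if validate_labels:
        seen = {l for l in series.labels if l is not None}
        unknown = seen - set(HASC_LABELS)
        if unknown:
            raise FormatError(f"{path}: unknown HASC label(s) {sorted(unknown)}")
    return series


def _labels_from_track(track_path: Path, timestamps: np.ndarray) -> np.ndarray:
    """Assign per-row labels from a ``start,end,label`` interval CSV (half-open)."""
    labels = np.full(timestamps.shape[0], None, dtype=object)
    for line_no, toks in _read_rows(track_path):
        if toks and toks[0].lower() == "start":  # optional header
            continue
        if len(toks) != 3:
            raise FormatError(f"{track_path}:{line_no}: expected start,end,label")
        start = _parse_float(toks[0], track_path, line_no, "start")
        end = _parse_float(toks[1], track_path, line_no, "end")
        labels[(timestamps >= start) & (timestamps < end)] = toks[2]
    n_unlabeled = int(np.sum([l is None for l in labels]))
    if n_unlabeled:
        logger.info("%s: %d rows outside labeled intervals", track_path, n_unlabeled)
    return labels


def read_chest(path: str | Path, subject_id: str | None = None) -> SensorSeries:
    """Read a single-chest-dialect CSV (``index,x,y,z,label`` at 52 Hz).

    Timestamps are synthesized as ``sample_index / 52`` seconds. Rows with
    label 0 (unlabeled) are dropped with a logged count; labels outside 0-7
    are a parse error.
    """
    path = Path(path)
    ts, vals, miss, labels = [], [], [], []
    n_dropped = 0
    for line_no, toks in _read_rows(path):
        if len(toks) != 5:
            raise FormatError(f"{path}:{line_no}: expected 5 columns, got {len(toks)}")
        idx = _parse_float(toks[0], path, line_no, "index")
        lab_tok = toks[4]
        try:
            lab = int(float(lab_tok))
        except ValueError:
            raise FormatError(f"{path}:{line_no}: non-integer label {lab_tok!r}") from None
        if lab == 0:
            n_dropped += 1
            continue
        if lab not in CHEST_LABELS:
            raise FormatError(f"{path}:{line_no}: label {lab} outside 1-7")
        na = [tok == NA_TOKEN for tok in toks[1:4]]
        if all(na):
            vals.append([np.nan] * 3)
            miss.append(True)
        elif any(na):
            raise FormatError(f"{path}:{line_no}: partial {NA_TOKEN} row")
        else:
            vals.append(
                [_parse_float(toks[1 + i], path, line_no, c) for i, c in enumerate("xyz")]
            )
            miss.append(False)
        ts.append(idx / CHEST_SAMPLING_RATE)
        labels.append(CHEST_LABELS[lab])
    if n_dropped:
        logger.info("%s: dropped %d unlabeled (label-0) rows", path, n_dropped)
    return SensorSeries(
        timestamps=np.array(ts, dtype=float),
        values=np.array(vals, dtype=float).reshape(-1, 3),
        channels=("x", "y", "z"),
        row_missing=np.array(miss, dtype=bool),
        labels=np.array(labels, dtype=object),
        subject_id=subject_id or path.stem,
        sampling_rate=CHEST_SAMPLING_RATE,
    )


def read_simulated(path: str | Path, subject_id: str | None = None) -> SensorSeries:
    """Read a single-channel synthetic CSV (``timestamp,value,label`` rows)."""
    path = Path(path)
    ts, vals, miss, labels = [], [], [], []
    for line_no, toks in _read_rows(path):
        if len(toks) != 3:
            raise FormatError(f"{path}:{line_no}: expected 3 columns, got {len(toks)}")
        t = _parse_float(toks[0], path, line_no, "timestamp")
        if toks[1] == NA_TOKEN:
            vals.append(np.nan)
            miss.append(True)
        else:
            vals.append(_parse_float(toks[1], path, line_no, "value"))
            miss.append(False)
        ts.append(t)
        labels.append(toks[2])
    return SensorSeries(
        timestamps=np.array(ts, dtype=float),
        values=np.array(vals, dtype=float).reshape(-1, 1),
        channels=("a",),
        row_missing=np.array(miss, dtype=bool),
        labels=np.array(labels, dtype=object),
        subject_id=subject_id or path.stem,
    )


def _format_number(x: float) -> str:
    """Canonical minimal decimal representation (round-trips exactly)."""
    return repr(float(x))


def write_csv(series: SensorSeries, path: str | Path, include_label: bool = False) -> None:
    """Write ``timestamp,<channels>[,label]`` rows; missing rows as ``NA`` tokens.

    The writer emits a canonical minimal float representation, so
    write -> read -> write is byte-identical.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(series.n):
            cells = [_format_number(series.timestamps[i])]
            if series.row_missing[i]:
                cells += [NA_TOKEN] * len(series.channels)
            else:
                cells += [_format_number(v) for v in series.values[i]]
            if include_label:
                cells.append(str(series.labels[i]))
            fh.write(",".join(cells) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature/result table as CSV with ``NA`` missing tokens."""
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def series_from_frame(
    df: pd.DataFrame,
    channels: Sequence[str] = ("x", "y", "z"),
    **kwargs,
) -> SensorSeries:
    """Build a :class:`SensorSeries` from a DataFrame with timestamp + channels."""
    vals = df[list(channels)].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=object) if "label" in df else None
    return SensorSeries(
        timestamps=df["timestamp"].to_numpy(dtype=float),
        values=vals,
        channels=tuple(channels),
        labels=labels,
        **kwargs,
    )
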