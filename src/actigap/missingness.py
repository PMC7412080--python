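"""Missing-at-random (MAR) mask induction and timestamp-gap diagnostics.

MAR here means the probability that a row is masked does not depend on the
(unobserved) signal values: masked rows are chosen by a uniform random draw
without replacement over row positions. A masked timestep loses all channels
simultaneously ("NA" in serialized form); no imputation is ever performed.

The gap diagnostics recover a missing-sample ratio from received timestamps
alone: on a stream with nominal period p, an inter-sample gap of k*p implies
k-1 consecutively dropped samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SensorSeries

#: Gaps beyond this many nominal periods are pooled as "long outage" and
#: excluded from MAR ratios (complete loss is a different mechanism).
MAX_GAP_MULTIPLE = 5


@dataclass(frozen=True)
class MissingMask:
    """A concrete draw of masked row indices for one series.

    ``len(masked_indices) == round(rate * n_total)`` (banker's rounding),
    indices unique and uniform over ``range(n_total)``.
    """

    masked_indices: np.ndarray
    rate: float
    n_total: int
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.masked_indices, dtype=np.intp)
        object.__setattr__(self, "masked_indices", idx)
        if idx.size != len(np.unique(idx)):
            raise ValueError("masked indices must be unique")
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_total):
            raise ValueError("masked indices out of range")
        expected = int(np.round(self.rate * self.n_total))
        if idx.size != expected:
            raise ValueError(f"mask size {idx.size} != round(rate*n) = {expected}")

    @classmethod
    def draw(cls, n_total: int, rate: float, seed: int) -> "MissingMask":
        """Draw ``round(rate * n_total)`` row indices uniformly without replacement."""
        if not 0 <= rate < 1:
            raise ValueError(f"rate must be in [0, 1); got {rate}")
        if n_total < 1:
            raise ValueError("n_total must be >= 1")
        n_mask = int(np.round(rate * n_total))
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n_total, size=n_mask, replace=False))
        return cls(masked_indices=idx, rate=rate, n_total=n_total, seed=seed)


def induce_mar(series: SensorSeries, rate: float, seed: int) -> SensorSeries:
    """Mask exactly ``round(rate * n)`` whole rows of ``series`` at random.

    Unmasked rows are unchanged (timestamps are always retained); masked rows
    get ``row_missing=True`` and NaN channel values. Returns a new series.
    """
    if series.n == 0:
        raise ValueError("series is empty")
    mask = MissingMask.draw(series.n, rate, seed)
    out = series.copy()
    out.row_missing[mask.masked_indices] = True
    out.values[mask.masked_indices, :] = np.nan
    return out


def missing_rate(series: SensorSeries) -> float:
    """Fraction of fully-missing rows."""
    if series.n == 0:
        raise ValueError("series is empty")
    return float(series.row_missing.mean())


@dataclass
class GapReport:
    """Histogram of inter-sample gaps at multiples of the nominal period.

    Attributes
    ----------
    histogram : dict[int, int]
        Count of gaps at each multiple k (1..MAX_GAP_MULTIPLE) of the nominal
        period, within ``jitter_tolerance``.
    per_bin_missing_ratio : dict[int, float]
        For each k, the fraction of the (reconstructed) stream lost to gaps in
        that bin: ``(k-1) * count[k] / (received + implied_missing)``.
    n_irregular : int
        Gaps not within tolerance of any integer multiple of the period.
    n_long_outage : int
        Gaps at multiples beyond MAX_GAP_MULTIPLE, excluded from MAR ratios.
    nominal_period : float
        In the same time units as the input timestamps (e.g. milliseconds).
    jitter_tolerance : float
    n_received : int
        Number of samples actually present.
    """

    histogram: dict[int, int]
    per_bin_missing_ratio: dict[int, float]
    n_irregular: int
    n_long_outage: int
    nominal_period: float
    jitter_tolerance: float
    n_received: int

    @property
    def implied_missing(self) -> int:
        """Total dropped samples implied by gaps at multiples 2..MAX_GAP_MULTIPLE."""
        return sum((k - 1) * c for k, c in self.histogram.items())

    @property
    def overall_missing_ratio(self) -> float:
        """Implied missing fraction of the reconstructed stream."""
        total = self.n_received + self.implied_missing
        return self.implied_missing / total if total else 0.0


def gap_histogram(
    timestamps: np.ndarray,
    nominal_period: float,
    jitter_tolerance: float | None = None,
) -> GapReport:
    """Bin consecutive timestamp gaps at multiples of the nominal period.

    Each gap is assigned to the nearest integer multiple k of
    ``nominal_period`` when within ``jitter_tolerance`` (default 10% of the
    period); k > MAX_GAP_MULTIPLE counts as a long outage, anything else as
    irregular. A gap at multiple k implies k-1 consecutive missing samples.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if nominal_period <= 0:
        raise ValueError("nominal_period must be > 0")
    if timestamps.size > 1 and np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if jitter_tolerance is None:
        jitter_tolerance = 0.1 * nominal_period

    gaps = np.diff(timestamps)
    k_star = np.round(gaps / nominal_period).astype(int)
    within = np.abs(gaps - k_star * nominal_period) <= jitter_tolerance
    regular = within & (k_star >= 1) & (k_star <= MAX_GAP_MULTIPLE)
    long_outage = within & (k_star > MAX_GAP_MULTIPLE)

    histogram = {
        int(k): int(np.sum(k_star[regular] == k)) for k in np.unique(k_star[regular])
    }
    n_received = timestamps.size
    implied = sum((k - 1) * c for k, c in histogram.items())
    denom = n_received + implied
    ratios = {k: ((k - 1) * c / denom if denom else 0.0) for k, c in histogram.items()}
    return GapReport(
        histogram=histogram,
        per_bin_missing_ratio=ratios,
        n_irregular=int(np.sum(~within | (within & (k_star < 1)))),
        n_long_outage=int(np.sum(long_outage)),
        nominal_period=float(nominal_period),
        jitter_tolerance=float(jitter_tolerance),
        n_received=n_received,
    )
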