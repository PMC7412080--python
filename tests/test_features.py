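"""Statistic definitions, their printed-form conventions, and NA tolerance.

The independent oracle for the adjusted skewness/kurtosis forms is
scipy.stats with bias=False; variance is checked against the population
formula directly and MAD against an explicit mean-|x - median| evaluation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from actigap import features
from actigap.features import (
    UndefinedFeatureError,
    apply_feature_fill,
    build_feature_table,
    extract_features,
    feature_names,
    fit_feature_fill,
    kurtosis,
    mad,
    mean,
    skewness,
    variance,
)
from actigap.io_formats import SensorSeries
from actigap.missingness import induce_mar
from actigap.windowing import Window, WindowConfig, segment

from conftest import make_triaxial_series


def make_window(values, missing=None, label="walk"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n = values.shape[0]
    missing = np.zeros(n, bool) if missing is None else np.asarray(missing, bool)
    return Window(
        start=0.0,
        end=1.0,
        timestamps=np.arange(n, dtype=float),
        values=values,
        missing=missing,
        label=label,
    )


class TestScalarStatistics:
    @pytest.mark.parametrize(
        "func,data,expected",
        [
            (mean, [1, 2, 3], 2.0),
            (variance, [1, 2, 3], 2 / 3),  # population divisor n
            (variance, [5, 5, 5], 0.0),
            (skewness, [1, 2, 3], 0.0),  # symmetric sample
            (skewness, [0, 0, 0, 1], 2.0),  # frozen brute-force value
            (kurtosis, [-1, -1, 1, 1], -6.0),  # frozen brute-force value
            (mad, [1, 2, 3, 4, 5], 1.2),  # (2+1+0+1+2)/5 about the median 3
            (mad, [7, 7, 7], 0.0),
        ],
    )
    def test_pinned_values(self, func, data, expected):
        assert func(data) == pytest.approx(expected, abs=1e-12)

    def test_skewness_is_odd(self, rng):
        x = rng.normal(size=30)
        assert skewness(-x) == pytest.approx(-skewness(x), rel=1e-12)

    def test_kurtosis_scale_invariant(self, rng):
        x = rng.normal(size=25)
        for c in (-3.0, 0.5, 10.0):
            assert kurtosis(c * x) == pytest.approx(kurtosis(x), rel=1e-9)

    def test_mad_translation_invariant(self, rng):
        x = rng.normal(size=17)
        assert mad(x + 123.4) == pytest.approx(mad(x), abs=1e-9)

    def test_excess_kurtosis_of_large_normal_sample_is_zero(self):
        x = np.random.default_rng(7).normal(size=100_000)
        assert abs(kurtosis(x)) < 0.1

    @pytest.mark.parametrize(
        "func,data",
        [
            (mean, []),
            (variance, []),
            (skewness, [1, 2]),  # n < 3
            (skewness, [4, 4, 4]),  # zero spread
            (kurtosis, [1, 2, 3]),  # n < 4
            (kurtosis, [2, 2, 2, 2]),  # zero spread
            (mad, []),
        ],
    )
    def test_preconditions_raise(self, func, data):
        with pytest.raises(UndefinedFeatureError):
            func(data)

    def test_matches_independent_oracle_on_random_vectors(self, rng):
        """All five statistics agree with scipy/numpy forms to 1e-10 relative."""
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            x = rng.normal(scale=rng.uniform(0.1, 10), size=n)
            assert mean(x) == pytest.approx(np.mean(x), rel=1e-10)
            assert variance(x) == pytest.approx(np.var(x), rel=1e-10)
            assert skewness(x) == pytest.approx(sps.skew(x, bias=False), rel=1e-10)
            assert kurtosis(x) == pytest.approx(sps.kurtosis(x, bias=False), rel=1e-10)
            assert mad(x) == pytest.approx(np.mean(np.abs(x - np.median(x))), rel=1e-10)


class TestExtractFeatures:
    def test_layout_is_stat_major_and_21_wide_for_triaxial(self):
        names = feature_names(("x", "y", "z"))
        assert len(names) == 21
        assert names[:6] == ["mean_x", "mean_y", "mean_z", "var_x", "var_y", "var_z"]
        assert names[-3:] == ["mad_x", "mad_y", "mad_z"]
        assert len(feature_names(("a",))) == 7

    def test_empty_mask_identity(self, rng):
        vals = rng.normal(size=(40, 3))
        clean = make_window(vals)
        masked0 = make_window(vals, missing=np.zeros(40, bool))
        np.testing.assert_array_equal(
            extract_features(clean, ("x", "y", "z")).values,
            extract_features(masked0, ("x", "y", "z")).values,
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_masking_equivalence(self, seed):
        """Features of a masked window equal features of the valid subsequence."""
        r = np.random.default_rng(seed)
        n = int(r.integers(8, 60))
        vals = r.normal(size=(n, 3))
        missing = r.random(n) < r.uniform(0, 0.6)
        w_masked = make_window(vals, missing=missing)
        w_subset = make_window(vals[~missing])
        got = extract_features(w_masked, ("x", "y", "z"))
        want = extract_features(w_subset, ("x", "y", "z"))
        np.testing.assert_array_equal(got.values, want.values)
        np.testing.assert_array_equal(got.defined, want.defined)

    def test_all_missing_window_is_all_undefined(self):
        w = make_window(np.full((10, 3), np.nan), missing=np.ones(10, bool))
        fv = extract_features(w, ("x", "y", "z"))
        assert not fv.defined.any()
        assert np.isnan(fv.values).all()

    def test_min_valid_gate(self, rng):
        vals = rng.normal(size=(10, 3))
        missing = np.array([True] * 7 + [False] * 3)
        fv = extract_features(make_window(vals, missing), ("x", "y", "z"), min_valid_samples=4)
        assert not fv.defined.any()

    def test_min_max_bracket_mean(self, rng):
        fv = extract_features(make_window(rng.normal(size=(30, 3))), ("x", "y", "z"))
        d = fv.as_dict()
        for ax in "xyz":
            assert d[f"min_{ax}"] <= d[f"mean_{ax}"] <= d[f"max_{ax}"]
            assert d[f"var_{ax}"] >= 0 and d[f"mad_{ax}"] >= 0

    def test_optional_median_columns(self, rng):
        fv = extract_features(
            make_window(rng.normal(size=(20, 3))), ("x", "y", "z"), include_median=True
        )
        assert len(fv.names) == 24 and fv.names[-1] == "median_z"


class TestFeatureTable:
    def test_masked_series_features_match_subset_oracle(self):
        series = make_triaxial_series(n=500, seed=3)
        masked = induce_mar(series, 0.3, seed=9)
        config = WindowConfig(window_s=2.0, slide_s=2.0)
        for w in segment(masked, config):
            fv = extract_features(w, series.channels)
            sub = extract_features(make_window(w.values[~w.missing]), series.channels)
            np.testing.assert_array_equal(fv.values, sub.values)

    def test_table_shape_and_fill_policy(self):
        series = make_triaxial_series(n=400, seed=5)
        heavy = induce_mar(series, 0.9, seed=1)
        windows = segment(heavy, WindowConfig(window_s=1.0))
        table = build_feature_table(windows, series.channels)
        assert table.shape[1] == 21 + 3  # 21 features + subject/start/label
        assert table.isna().any().any()  # heavy masking leaves undefined cells
        fill = fit_feature_fill(table)
        filled = apply_feature_fill(table, fill)
        assert not filled[features.feature_columns(filled)].isna().any().any()
        # the fill is frozen: applying it twice changes nothing further
        np.testing.assert_array_equal(
            filled.to_numpy(), apply_feature_fill(filled, fill).to_numpy()
        )
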