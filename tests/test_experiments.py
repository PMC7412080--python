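"""Scenario orchestration: case semantics, sweeps, and the headline run."""

import numpy as np
import pandas as pd
import pytest

from actigap.classification import ModelConfig
from actigap.experiments import (
    SYNTHETIC_WINDOW,
    SweepSpec,
    headline_comparison,
    run_scenario,
    sweep,
    synthetic_series,
)
from actigap.windowing import WindowConfig

FAST_RF = ModelConfig(n_trees=50)


@pytest.fixture(scope="module")
def small_synthetic():
    return synthetic_series(n_per_class=200, seed=5)


class TestRunScenario:
    def test_clean_case_reaches_perfect_accuracy(self, small_synthetic):
        train_s, test_s = small_synthetic
        res = run_scenario(
            train_s, test_s, "clean_clean", 0.0, SYNTHETIC_WINDOW, FAST_RF, seed=1
        )
        assert res.accuracy == 1.0

    def test_zero_rate_makes_all_cases_identical(self, small_synthetic):
        train_s, test_s = small_synthetic
        accs = {
            case: run_scenario(
                train_s, test_s, case, 0.0, SYNTHETIC_WINDOW, FAST_RF, seed=3
            ).accuracy
            for case in ("clean_clean", "clean_missing", "missing_missing")
        }
        assert len(set(accs.values())) == 1

    def test_unknown_case_rejected(self, small_synthetic):
        train_s, test_s = small_synthetic
        with pytest.raises(ValueError, match="unknown case"):
            run_scenario(train_s, test_s, "missing_clean", 0.1)

    def test_deterministic_given_seed(self, small_synthetic):
        train_s, test_s = small_synthetic
        a = run_scenario(train_s, test_s, "missing_missing", 0.3, SYNTHETIC_WINDOW, FAST_RF, seed=11)
        b = run_scenario(train_s, test_s, "missing_missing", 0.3, SYNTHETIC_WINDOW, FAST_RF, seed=11)
        assert a.accuracy == b.accuracy
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_train_rate_override(self, small_synthetic):
        train_s, test_s = small_synthetic
        res = run_scenario(
            train_s, test_s, "missing_missing", 0.4,
            SYNTHETIC_WINDOW, FAST_RF, seed=2, train_rate=0.0,
        )
        # override with a clean training side must match the traditional case
        trad = run_scenario(
            train_s, test_s, "clean_missing", 0.4, SYNTHETIC_WINDOW, FAST_RF, seed=2
        )
        assert res.accuracy == trad.accuracy


class TestSweep:
    def test_cartesian_product_row_count(self, small_synthetic):
        train_s, test_s = small_synthetic
        spec = SweepSpec(
            missing_rates=(0.1, 0.3),
            window_sizes=(0.3, 0.5),
            slides=(0.1,),
            classifiers=("random_forest",),
            cases=("clean_missing", "missing_missing"),
            n_seeds=1,
        )
        table = sweep(spec, train_s, test_s)
        assert len(table) == 8
        assert set(table["status"]) == {"ok"}
        assert "seed" in table.columns

    def test_repeat_with_same_seeds_is_identical(self, small_synthetic):
        train_s, test_s = small_synthetic
        spec = SweepSpec(missing_rates=(0.2,), window_sizes=(0.3,), slides=(0.1,), n_seeds=2)
        a = sweep(spec, train_s, test_s)
        b = sweep(spec, train_s, test_s)
        pd.testing.assert_frame_equal(a, b)

    def test_checkpoint_resume_skips_done_cells(self, small_synthetic, tmp_path):
        train_s, test_s = small_synthetic
        spec = SweepSpec(missing_rates=(0.1, 0.2), window_sizes=(0.3,), slides=(0.1,))
        ckpt = tmp_path / "sweep.csv"
        full = sweep(spec, train_s, test_s, checkpoint=ckpt)
        resumed = sweep(spec, train_s, test_s, checkpoint=ckpt)
        assert len(resumed) == len(full)
        np.testing.assert_allclose(resumed["accuracy"], full["accuracy"])

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(missing_rates=(1.2,))


def test_larger_windows_are_not_worse_under_missing_data():
    """On average over rates and seeds, longer windows absorb missing rows
    better than short ones (more class information per window)."""
    import numpy as np
    from actigap.classification import ModelConfig
    from actigap.experiments import run_scenario

    means = {}
    for w in (0.3, 0.9):
        vals = []
        for seed in range(4):
            tr, te = synthetic_series(seed=seed)
            for rate in (0.3, 0.4, 0.5):
                res = run_scenario(
                    tr, te, "clean_missing", rate,
                    WindowConfig(w, 0.1), ModelConfig(n_trees=200), seed=seed,
                )
                vals.append(res.accuracy)
        means[w] = np.mean(vals)
    assert means[0.9] >= means[0.3]


class TestHeadlineComparison:
    @pytest.fixture(scope="class")
    def quick_headline(self):
        return headline_comparison(
            rates=(0.0, 0.4), n_seeds=3, seed=7, n_per_class=200, model_config=FAST_RF
        )

    def test_proposed_at_least_traditional_at_max_gap(self, quick_headline):
        assert quick_headline.proposed_accuracy >= quick_headline.traditional_accuracy

    def test_zero_rate_gap_is_negligible(self, quick_headline):
        means = quick_headline.rate_means()
        gap0 = means.loc[0.0, "proposed"] - means.loc[0.0, "traditional"]
        assert abs(gap0) < 0.05

    def test_table_covers_full_grid(self, quick_headline):
        t = quick_headline.table
        assert set(t["protocol"]) == {"traditional", "proposed"}
        assert len(t) == 2 * 2 * 3  # rates x protocols x replicates

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            headline_comparison(rates=())
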