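import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import nodclass as nc
from nodclass.data_model_io import NODULE_CONDITIONS
from nodclass.differential_expression import (
    FLAG_DEGENERATE,
    NormalizationError,
    bh_adjust,
    normalize,
)
from nodclass.differential_expression import test_condition as one_sample_test
from conftest import make_dataset


def _single_condition_dataset(replicates):
    """Dataset with one probe whose WT4 replicates are given; other
    conditions zero-filled."""
    n = len(replicates)
    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in NODULE_CONDITIONS for r in range(n)],
        names=["condition", "replicate"],
    )
    row = list(replicates) + [0.0] * (len(NODULE_CONDITIONS) - 1) * n
    mat = pd.DataFrame([row], index=pd.Index(["P0"], name="probe"), columns=cols)
    return nc.ExpressionDataset(values=mat, panel="nodule")


class TestNormalize:
    def test_shifts_by_column_median(self):
        sim = nc.default_nodule_config(n_per_class=3, noise_sd=0.1, seed=0)
        ds, _ = nc.generate_nodule_dataset(sim)
        col = ds.values.columns[0]
        ds.values[col] += 0.3
        before_median = ds.values[col].median()
        out = normalize(ds)
        assert out.values[col].median() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            out.values[col], ds.values[col] - before_median
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        sim = nc.default_nodule_config(n_per_class=2, noise_sd=0.3, seed=seed)
        ds, _ = nc.generate_nodule_dataset(sim)
        once = normalize(ds)
        twice = normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_na_column_rejected(self):
        sim = nc.default_nodule_config(n_per_class=2, noise_sd=0.1, seed=0)
        ds, _ = nc.generate_nodule_dataset(sim)
        ds.values[ds.values.columns[0]] = np.nan
        with pytest.raises(NormalizationError):
            normalize(ds)


class TestTestCondition:
    def test_constant_replicates_flagged_degenerate(self):
        ds = _single_condition_dataset([1.0, 1.0, 1.0, 1.0])
        res = one_sample_test(ds, "WT4")
        assert res.loc["P0", "mean_log2"] == 1.0
        assert res.loc["P0", "flag"] == FLAG_DEGENERATE
        assert res.loc["P0", "p_raw"] == 0.0

    def test_closed_form_t_on_four_points(self):
        # replicate log2 ratios averaging 0.84 -> linear ratio 2^0.84 ~ 1.79,
        # the kind of modest induction the 1.5 threshold is meant to keep
        reps = [0.84, 0.80, 0.88, 0.84]
        ds = _single_condition_dataset(reps)
        res = one_sample_test(ds, "WT4")
        assert res.loc["P0", "mean_log2"] == pytest.approx(0.84)
        assert 2 ** res.loc["P0", "mean_log2"] == pytest.approx(1.79, abs=0.01)
        t = np.mean(reps) / (np.std(reps, ddof=1) / 2)
        expected_p = 2 * stats.t.sf(abs(t), df=3)
        assert res.loc["P0", "p_raw"] == pytest.approx(expected_p, rel=1e-12)

    def test_symmetric_replicates_give_p_one(self):
        ds = _single_condition_dataset([-0.5, 0.5, -0.5, 0.5])
        res = one_sample_test(ds, "WT4")
        assert res.loc["P0", "p_raw"] == pytest.approx(1.0)

    def test_missing_replicates_flagged_untestable(self):
        ds = _single_condition_dataset([0.5, np.nan, np.nan, np.nan])
        res = one_sample_test(ds, "WT4")
        assert res.loc["P0", "flag"] == "untestable"


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_nan_propagates_without_counting(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 60))
    def test_matches_statsmodels(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


class TestCallRegulation:
    def test_modest_induction_called_up(self):
        # linear ratio ~1.79 with tiny adjusted p -> up
        ds = make_dataset({"P0": [0.84, 0, 0, 0, 0, 0, 0]}, n_reps=4)
        calls = nc.call_regulation(ds)
        assert calls.call.loc["P0", "WT4"] == "up"
        assert calls.ratio.loc["P0", "WT4"] == pytest.approx(1.79, abs=0.01)

    def test_flat_probe_called_none_everywhere(self):
        ds = make_dataset({"P0": [0.0] * 7}, n_reps=4)
        calls = nc.call_regulation(ds)
        assert (calls.call.loc["P0"] == "none").all()

    def test_thresholds_are_inclusive(self):
        # exact boundary: ratio 1.5, adjusted p == alpha -> still called up
        config = nc.AnalysisConfig()
        ratio = pd.DataFrame({"WT4": [1.5]}, index=["P0"])
        p_adj = pd.DataFrame({"WT4": [config.alpha]}, index=["P0"])
        up = (ratio >= config.ratio_threshold) & (p_adj <= config.alpha)
        assert bool(up.iloc[0, 0])
        # and through the full caller, with noise-free replicates at log2(1.5)
        ds = make_dataset({"P0": [np.log2(1.5), 0, 0, 0, 0, 0, 0]}, n_reps=4)
        ds.values.loc["P0", "WT4"] = np.log2(1.5)  # exact, degenerate variance
        calls = nc.call_regulation(ds)
        assert calls.call.loc["P0", "WT4"] == "up"

    def test_call_invariant_holds_on_random_data(self, rng):
        sim = nc.default_nodule_config(n_per_class=5, noise_sd=0.4, seed=11)
        ds, _ = nc.generate_nodule_dataset(sim)
        cfg = nc.AnalysisConfig()
        calls = nc.call_regulation(ds, cfg)
        up = calls.call == "up"
        down = calls.call == "down"
        assert (calls.ratio[up].stack() >= cfg.ratio_threshold).all()
        assert (calls.p_adj[up].stack() <= cfg.alpha).all()
        assert (calls.ratio[down].stack() <= 1 / cfg.ratio_threshold).all()
        assert (calls.p_adj[down].stack() <= cfg.alpha).all()

    def test_raising_replicates_never_flips_up_to_down(self):
        ds = make_dataset({"P0": [0.7, 0, 0, 0, 0, 0, 0],
                           "P1": [0.2, 0, 0, 0, 0, 0, 0]}, n_reps=4)
        before = nc.call_regulation(ds).call.loc["P0", "WT4"]
        raised = ds.values.copy()
        raised.loc["P0", "WT4"] = raised.loc["P0", "WT4"].to_numpy() + 1.0
        ds2 = nc.ExpressionDataset(values=raised, panel="nodule")
        after = nc.call_regulation(ds2).call.loc["P0", "WT4"]
        order = {"down": 0, "none": 1, "up": 2}
        assert order[after] >= order[before]

    def test_pooled_adjustment_mode(self):
        sim = nc.default_nodule_config(n_per_class=3, noise_sd=0.2, seed=5)
        ds, _ = nc.generate_nodule_dataset(sim)
        pooled = nc.call_regulation(ds, nc.AnalysisConfig(pooled_adjust=True))
        flat = pooled.p_raw.to_numpy().ravel()
        expected = bh_adjust(flat).reshape(pooled.p_adj.shape)
        np.testing.assert_allclose(pooled.p_adj.to_numpy(), expected)
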