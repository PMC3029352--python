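"""Normalisation, one-sample t-tests, BH adjustment and up/none/down calls.

Each array already encodes log2(sample/control), so every nodule condition is
one contrast against zero: a one-sample two-sided t-test on the replicate log2
ratios.  P-values are adjusted per condition with the Benjamini-Hochberg
step-up procedure; a probe is called up when its mean linear ratio is at least
``ratio_threshold`` (default 1.5) and its adjusted p is at most ``alpha``
(default 0.05), both bounds inclusive, and symmetrically down at
``1/ratio_threshold``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import AnalysisConfig, ExpressionDataset, RegulationCallTable

FLAG_DEGENERATE = "degenerate"
FLAG_UNTESTABLE = "untestable"


class NormalizationError(ValueError):
    """A sample column cannot be median-centred (all values missing)."""


def normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Median-centre every sample column (idempotent).

    Subtracts each column's median so that within-sample ordering is
    unchanged and each column has median zero.
    """
    values = dataset.values
    if values.notna().sum(axis=0).eq(0).any():
        bad = [c for c in values.columns if values[c].notna().sum() == 0]
        raise NormalizationError(f"all-NA sample columns: {bad}")
    centred = values - values.median(axis=0, skipna=True)
    return ExpressionDataset(values=centred, panel=dataset.panel, annotations=dataset.annotations)


def test_condition(dataset: ExpressionDataset, condition: str) -> pd.DataFrame:
    """One-sample two-sided t-test of a condition's replicates against 0.

    Returns a frame indexed by probe with columns ``mean_log2``, ``p_raw``
    and ``flag``.  Zero replicate variance with a nonzero mean yields the
    limit p of 0 and a 'degenerate' flag; fewer than two non-missing
    replicates yields an 'untestable' flag (the caller forces call=none).
    """
    reps = dataset.replicates(condition)
    arr = reps.to_numpy(dtype=float)
    n = np.sum(~np.isnan(arr), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=1)
        sd = np.nanstd(arr, axis=1, ddof=1)

    p = np.full(arr.shape[0], np.nan)
    flag = np.full(arr.shape[0], "", dtype=object)

    untestable = n < 2
    flag[untestable] = FLAG_UNTESTABLE

    testable = ~untestable
    degenerate = testable & (sd == 0)
    flag[degenerate] = FLAG_DEGENERATE
    p[degenerate & (mean != 0)] = 0.0
    p[degenerate & (mean == 0)] = 1.0

    regular = testable & (sd > 0)
    if regular.any():
        t = mean[regular] / (sd[regular] / np.sqrt(n[regular]))
        p[regular] = 2 * stats.t.sf(np.abs(t), df=n[regular] - 1)

    return pd.DataFrame(
        {"mean_log2": mean, "p_raw": p, "flag": flag}, index=reps.index
    )


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest down (running minimum), cap at 1.  Missing entries propagate as
    NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        scaled = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        res = np.empty(m)
        res[order] = adj
        out[mask] = res
    return out


def call_regulation(
    dataset: ExpressionDataset, config: AnalysisConfig | None = None
) -> RegulationCallTable:
    """Test every probe in every condition and call up/none/down.

    BH runs within each condition across all probes (each condition is one
    contrast); set ``config.pooled_adjust`` to pool the 7 contrasts instead.
    Threshold bounds are inclusive: ratio exactly at ``ratio_threshold`` with
    adjusted p exactly at ``alpha`` is called.
    """
    config = config or AnalysisConfig()
    conditions = [c for c in dataset.conditions if c != "CTRL"]

    stats_frames = {c: test_condition(dataset, c) for c in conditions}
    mean = pd.DataFrame({c: stats_frames[c]["mean_log2"] for c in conditions})
    p_raw = pd.DataFrame({c: stats_frames[c]["p_raw"] for c in conditions})
    flags = pd.DataFrame({c: stats_frames[c]["flag"] for c in conditions})

    if config.pooled_adjust:
        flat = bh_adjust(p_raw.to_numpy().ravel())
        p_adj = pd.DataFrame(
            flat.reshape(p_raw.shape), index=p_raw.index, columns=p_raw.columns
        )
    else:
        p_adj = pd.DataFrame(
            {c: bh_adjust(p_raw[c].to_numpy()) for c in conditions}, index=p_raw.index
        )

    ratio = np.power(2.0, mean)
    up = (ratio >= config.ratio_threshold) & (p_adj <= config.alpha)
    down = (ratio <= 1.0 / config.ratio_threshold) & (p_adj <= config.alpha)
    untestable = flags == FLAG_UNTESTABLE
    call = pd.DataFrame("none", index=ratio.index, columns=ratio.columns)
    call = call.mask(up & ~untestable, "up").mask(down & ~untestable, "down")

    return RegulationCallTable(
        call=call, ratio=ratio, p_raw=p_raw, p_adj=p_adj, flags=flags
    )
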