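import numpy as np
import pandas as pd
import pytest

import nodclass as nc
from nodclass.census_reporting import (
    class_census,
    load_published_census,
    load_published_families,
    opposite_regulation_families,
    pairwise_overlap,
    per_condition_counts,
    percent,
    unique_up_fraction,
)

from test_concordance import make_calls

CONDS = ["WT4", "WT10", "WT14", "NN"]


class TestPercent:
    @pytest.mark.parametrize(
        "n,d,expected",
        [(334, 2050, 16), (62, 192, 32), (110, 2050, 5), (5, 192, 3),
         (0, 192, 0), (14, 2050, 1)],
    )
    def test_published_percentage_cells(self, n, d, expected):
        assert percent(n, d) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent(1, 200) == 1   # 0.5 -> 1
        assert percent(-1, 200) == -1

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestPerConditionCounts:
    def test_toy_table(self):
        calls = make_calls(
            {"P0": ["up", "none", "none", "none"],
             "P1": ["up", "down", "none", "none"],
             "P2": ["down", "none", "none", "none"]}
        )
        counts = per_condition_counts(calls)
        assert counts.loc["WT4", "n_up"] == 2 and counts.loc["WT4", "n_down"] == 1

    def test_matches_brute_force(self, rng):
        labels = np.array(["up", "none", "down"])
        rows = {f"P{i}": list(labels[rng.integers(0, 3, 4)]) for i in range(40)}
        counts = per_condition_counts(make_calls(rows))
        for k, cond in enumerate(CONDS):
            assert counts.loc[cond, "n_up"] == sum(r[k] == "up" for r in rows.values())
            assert counts.loc[cond, "n_down"] == sum(r[k] == "down" for r in rows.values())


class TestUniqueUpFraction:
    def test_examples(self):
        calls = make_calls(
            {"only_wt4": ["up", "none", "none", "none"],
             "both": ["none", "up", "up", "none"]}
        )
        frac = unique_up_fraction(calls)
        assert frac["WT4"] == 1.0
        assert frac["WT10"] == 0.0 and frac["WT14"] == 0.0
        assert np.isnan(frac["NN"])

    def test_matches_brute_force(self, rng):
        labels = np.array(["up", "none", "down"])
        rows = {f"P{i}": list(labels[rng.integers(0, 3, 4)]) for i in range(60)}
        frac = unique_up_fraction(make_calls(rows))
        for k, cond in enumerate(CONDS):
            ups = [p for p, r in rows.items() if r[k] == "up"]
            unique = [p for p in ups if sum(x == "up" for x in rows[p]) == 1]
            if ups:
                assert frac[cond] == pytest.approx(len(unique) / len(ups))
            else:
                assert np.isnan(frac[cond])


class TestClassCensus:
    def test_partition_and_percentages_on_synthetic_data(self, noise_free_run):
        dataset, truth, calls, assignment = noise_free_run
        report = class_census(assignment, dataset.annotations)
        assert report.class_counts.sum() == len(calls.de_probes())
        for label in report.pct_up_genes.index:
            assert report.pct_up_genes[label] == percent(
                report.class_counts[label], report.total_up
            )
        assert report.regulator_counts.sum() <= report.class_counts.sum()

    def test_unannotated_probes_excluded_from_family_tallies_only(self, noise_free_run):
        dataset, _, _, assignment = noise_free_run
        partial = dataset.annotations.iloc[:-20]
        report = class_census(assignment, partial)
        assert "unannotated_probes" in report.metadata
        full = class_census(assignment, dataset.annotations)
        assert (report.class_counts == full.class_counts).all()

    def test_family_induced_sum_equals_up_regulators(self, noise_free_run):
        dataset, _, _, assignment = noise_free_run
        report = class_census(assignment, dataset.annotations)
        assert report.family_table["induced_genes"].sum() == report.total_up_regulators


class TestPublishedTables:
    def test_census_fixture_checksums(self):
        census = load_published_census()
        assert census["n_probes"].sum() == 3437
        up = census.drop(index="repressed")
        assert up["n_probes"].sum() == 2050
        assert up["n_regulators"].sum() == 192

    def test_printed_percentages_reproduce_from_counts(self):
        census = load_published_census()
        up = census.drop(index="repressed")
        for label, row in up.iterrows():
            if not np.isnan(row["pct_up"]):
                assert percent(row["n_probes"], 2050) == row["pct_up"], label
            if not np.isnan(row["pct_regulators"]):
                assert percent(row["n_regulators"], 192) == row["pct_regulators"], label

    def test_family_fixture_checksum(self):
        families = load_published_families()
        assert len(families) == 35
        assert families["induced_genes"].sum() == 192


class TestPairwiseOverlap:
    def test_disjoint_and_identical_conditions(self):
        calls = make_calls(
            {"P0": ["up", "none", "none", "none"],
             "P1": ["none", "up", "up", "none"]}
        )
        overlap = pairwise_overlap(calls)["up"]
        assert overlap.loc["WT4", "WT10"] == 0
        assert overlap.loc["WT10", "WT14"] == 1
        assert overlap.loc["WT4", "WT4"] == 1

    def test_matches_brute_force_set_intersections(self, rng):
        labels = np.array(["up", "none", "down"])
        rows = {f"P{i}": list(labels[rng.integers(0, 3, 4)]) for i in range(40)}
        calls = make_calls(rows)
        overlap = pairwise_overlap(calls)
        for direction in ("up", "down"):
            for i, ci in enumerate(CONDS):
                for j, cj in enumerate(CONDS):
                    expected = sum(
                        1 for r in rows.values() if r[i] == direction and r[j] == direction
                    )
                    assert overlap[direction].loc[ci, cj] == expected
            assert (overlap[direction] == overlap[direction].T).all().all()


class TestOppositeRegulationFamilies:
    def test_detects_families_with_both_signs(self):
        calls = make_calls(
            {"P0": ["up", "none", "none", "none"],
             "P1": ["down", "none", "none", "none"],
             "P2": ["up", "none", "none", "none"]}
        )
        ann = pd.DataFrame(
            {"family": ["F1", "F1", "F2"]}, index=["P0", "P1", "P2"]
        )
        out = opposite_regulation_families(calls, ann)
        assert list(out["family"]) == ["F1"]
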