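"""Feature grouping, filling, quality scoring, mass relations and
normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_run, make_table
from metabocompare.chem import MassTolerance
from metabocompare.features import (
    FeatureTable,
    FillParams,
    GroupingParams,
    annotate_mass_relations,
    fill_missing,
    group_features,
    normalize_to_reference,
    peak_quality,
)
from metabocompare.rawdata import detect_peaks


def peak_row(mz, rt, maxo=1e5, area=None):
    return {
        "mz": mz, "mzmin": mz - 0.0005, "mzmax": mz + 0.0005,
        "rt": rt, "rtmin": rt - 8, "rtmax": rt + 8,
        "area": area if area is not None else maxo * 7.5, "maxo": maxo, "sn": 50.0,
    }


def peaks_df(rows):
    return pd.DataFrame(rows)


class TestGrouping:
    def test_same_compound_in_all_samples_is_one_feature(self):
        peaks = {
            "a": peaks_df([peak_row(185.1183, 300.0, 1e5)]),
            "b": peaks_df([peak_row(185.1185, 300.5, 2e5)]),
            "c": peaks_df([peak_row(185.1184, 299.8, 3e5)]),
        }
        table = group_features(peaks, {"a": "g", "b": "g", "c": "g"})
        assert len(table) == 1
        assert table.df[["a", "b", "c"]].notna().all(axis=None)
        assert table.df.iloc[0]["mz"] == pytest.approx(185.1184, abs=1e-4)

    def test_isomers_separated_by_rt_clustering(self):
        peaks = {
            "a": peaks_df([peak_row(185.1183, 300.0), peak_row(185.1183, 330.0)]),
            "b": peaks_df([peak_row(185.1184, 300.4), peak_row(185.1184, 330.5)]),
        }
        table = group_features(peaks, {"a": "g", "b": "g"}, GroupingParams(bw=2.0))
        assert len(table) == 2
        assert sorted(table.df["rt"].round(0)) == [300.0, 330.0]

    def test_minfrac_drops_rare_features(self):
        samples = [f"s{i}" for i in range(6)]
        peaks = {s: peaks_df([]) for s in samples}
        peaks["s0"] = peaks_df([peak_row(200.0, 100.0)])
        table = group_features(
            peaks, {s: "g" for s in samples}, GroupingParams(minfrac=0.2)
        )
        assert len(table) == 0  # 1/6 < 0.2

    def test_minfrac_satisfied_within_one_group(self):
        # 2/2 blanks is enough even though 0/4 elsewhere
        peaks = {
            "w1": peaks_df([]), "w2": peaks_df([]), "w3": peaks_df([]), "w4": peaks_df([]),
            "bl1": peaks_df([peak_row(200.0, 100.0)]),
            "bl2": peaks_df([peak_row(200.0005, 100.3)]),
        }
        groups = {"w1": "wt", "w2": "wt", "w3": "wt", "w4": "wt", "bl1": "blank", "bl2": "blank"}
        table = group_features(peaks, groups, GroupingParams(minfrac=0.5))
        assert len(table) == 1

    def test_duplicate_peaks_keep_max_intensity(self):
        peaks = {
            "a": peaks_df([peak_row(200.0, 100.0, maxo=1e5), peak_row(200.0002, 100.5, maxo=3e5)]),
            "b": peaks_df([peak_row(200.0001, 100.2, maxo=2e5)]),
        }
        table = group_features(peaks, {"a": "g", "b": "g"})
        assert len(table) == 1
        assert table.df.iloc[0]["a"] == 3e5

    def test_sample_order_permutation_invariant(self):
        rows = [peak_row(200.0 + i, 100.0 + 10 * i) for i in range(5)]
        peaks = {"a": peaks_df(rows), "b": peaks_df(rows[:3]), "c": peaks_df(rows[1:])}
        groups = {"a": "g", "b": "g", "c": "g"}
        t1 = group_features(peaks, groups)
        t2 = group_features({k: peaks[k] for k in ["c", "a", "b"]}, groups)
        cols = ["mz", "rt", "a", "b", "c"]
        pd.testing.assert_frame_equal(
            t1.df[cols].reset_index(drop=True), t2.df[cols].reset_index(drop=True)
        )


class TestFill:
    @pytest.fixture
    def detected_and_runs(self):
        compounds = [(300.0, 200.0, 3.0, 1e5)]
        runs = {
            s: gaussian_run(compounds, rt_range=(150, 260), sample_id=s, group="g",
                            min_intensity=1.0)
            for s in ("a", "b", "c")
        }
        peaks = {
            "a": peaks_df([peak_row(300.0, 200.0, 1e5)]),
            "b": peaks_df([peak_row(300.0, 200.0, 1e5)]),
            "c": peaks_df([]),  # detection "missed" sample c
        }
        table = group_features(peaks, {"a": "g", "b": "g", "c": "g"})
        return table, runs

    def test_fill_recovers_present_signal(self, detected_and_runs):
        table, runs = detected_and_runs
        filled = fill_missing(table, runs)
        assert filled.df.iloc[0]["c"] == pytest.approx(1e5, rel=0.05)
        assert filled.df.iloc[0]["filled_samples"] == "c"

    def test_fill_zero_when_no_signal(self, detected_and_runs):
        table, runs = detected_and_runs
        runs["c"] = gaussian_run([], rt_range=(150, 260), sample_id="c", group="g")
        filled = fill_missing(table, runs)
        assert filled.df.iloc[0]["c"] == 0.0
        assert "c" in filled.df.iloc[0]["filled_samples"]

    def test_fill_idempotent_and_preserves_detected(self, detected_and_runs):
        table, runs = detected_and_runs
        once = fill_missing(table, runs)
        twice = fill_missing(once, runs)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert once.df.iloc[0]["a"] == table.df.iloc[0]["a"]

    def test_missing_run_is_an_error_naming_the_sample(self, detected_and_runs):
        table, runs = detected_and_runs
        del runs["c"]
        with pytest.raises(KeyError, match="c"):
            fill_missing(table, runs)


class TestPeakQuality:
    def test_clean_gaussian_scores_high(self):
        runs = {"a": gaussian_run([(300.0, 200.0, 3.0, 1e5)], rt_range=(150, 260),
                                  sample_id="a", min_intensity=1.0)}
        table = make_table({"a": [1e5]}, {"a": "g"}, mz=[300.0], rt=[200.0])
        scored = peak_quality(table, runs)
        assert scored.df.iloc[0]["quality"] > 0.95

    def test_noise_scores_low_in_expectation(self):
        rng = np.random.default_rng(21)
        n = 40
        # dense random signal: every scan carries several centroids inside
        # each feature's EIC window, so windows are pure noise traces
        runs = {
            "a": gaussian_run([], rt_range=(0, 500), sample_id="a", noise_rng=rng,
                              noise_per_scan=800, noise_mz_range=(100, 500),
                              noise_scale=1000.0)
        }
        mz = np.linspace(110, 490, n)
        table = make_table({"a": np.full(n, 1e3)}, {"a": "g"}, mz=mz,
                           rt=np.linspace(50, 450, n))
        scored = peak_quality(table, runs, tol=MassTolerance(0.5, "da"))
        assert scored.df["quality"].mean() < 0.5

    def test_too_few_points_score_zero(self):
        runs = {"a": gaussian_run([(300.0, 200.0, 3.0, 1e5)], rt_range=(150, 260),
                                  sample_id="a", interval=30.0)}
        table = make_table({"a": [1e5]}, {"a": "g"}, mz=[300.0], rt=[200.0])
        scored = peak_quality(table, runs)
        assert scored.df.iloc[0]["quality"] == 0.0


class TestMassRelations:
    def test_methylene_homologs_linked(self):
        table = make_table(
            {"a": [1.0, 1.0]}, {"a": "g"}, mz=[185.1183, 199.1339], rt=[300.0, 301.0]
        )
        annotated, edges = annotate_mass_relations(table)
        assert len(edges) == 1
        assert edges.iloc[0]["name"] == "CH2"
        assert "CH2" in annotated.df.iloc[0]["relations"]

    def test_isotope_partner_linked(self):
        table = make_table(
            {"a": [1.0, 0.3]}, {"a": "g"}, mz=[185.1183, 186.1217], rt=[300.0, 300.2]
        )
        _, edges = annotate_mass_relations(table)
        assert list(edges["name"]) == ["13C"]

    def test_coelution_required(self):
        table = make_table(
            {"a": [1.0, 1.0]}, {"a": "g"}, mz=[185.1183, 199.1339], rt=[300.0, 340.0]
        )
        _, edges = annotate_mass_relations(table, rt_tol=3.0)
        assert len(edges) == 0


class TestNormalization:
    def test_division_by_reference(self):
        table = make_table(
            {"s1": [2.0, 10.0], "s2": [4.0, 10.0]}, {"s1": "g", "s2": "g"},
            index=["ref", "f1"],
        )
        normed = normalize_to_reference(table, "ref")
        assert list(normed.df.loc["f1", ["s1", "s2"]]) == [5.0, 2.5]
        assert list(normed.df.loc["ref", ["s1", "s2"]]) == [1.0, 1.0]

    def test_zero_reference_errors_naming_sample(self):
        table = make_table(
            {"s1": [2.0, 10.0], "s2": [0.0, 10.0]}, {"s1": "g", "s2": "g"},
            index=["ref", "f1"],
        )
        with pytest.raises(ValueError, match="s2"):
            normalize_to_reference(table, "ref")


class TestEndToEndGrouping:
    def test_planted_features_group_without_splits_or_merges(self):
        rng = np.random.default_rng(17)
        n = 25
        mzs = np.linspace(150, 750, n) + rng.uniform(-0.01, 0.01, n)
        rts = np.linspace(60, 540, n)
        compounds = [(m, r, 3.0, 5e5) for m, r in zip(mzs, rts)]
        runs = {
            s: gaussian_run(compounds, sample_id=s, group="g", min_intensity=1.0)
            for s in ("a", "b", "c")
        }
        peaks = {s: detect_peaks(r) for s, r in runs.items()}
        table = group_features(peaks, {s: "g" for s in runs})
        assert len(table) == n
        assert table.df[["a", "b", "c"]].notna().all(axis=None)


class TestTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = make_table({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, {"s1": "a", "s2": "b"})
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path, {"s1": "a", "s2": "b"})
        pd.testing.assert_frame_equal(back.df[["mz", "rt", "s1", "s2"]],
                                      table.df[["mz", "rt", "s1", "s2"]],
                                      check_names=False)

    def test_metaboanalyst_layout(self, tmp_path):
        table = make_table({"s1": [1.0], "s2": [2.0]}, {"s1": "wt", "s2": "mut"})
        path = tmp_path / "ma.csv"
        table.to_metaboanalyst_csv(path)
        out = pd.read_csv(path, index_col="Sample")
        assert list(out["Label"]) == ["wt", "mut"]
        assert out.shape == (2, 2)  # samples x (Label + 1 feature)
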