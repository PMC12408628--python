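"""Imaging QC chain: outlier masking, aggregation, normalization, NZV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioprofiler import profiles as prof
from cardioprofiler.design import CYTOPLASM_AREA
from cardioprofiler.profiles import (
    aggregate_replicates,
    build_feature_mask,
    filter_near_zero_variance,
    flag_area_outliers,
    flag_outliers,
    normalize_to_vehicle,
    viability_percent_change,
)


class TestMadOutliers:
    def test_identical_values_never_flagged(self):
        assert flag_outliers([5.0] * 20).n_flagged == 0

    def test_hand_computed_example(self):
        # median 11, MAD 1, |50-11|/1 = 39 > 3 → only the 50 is flagged
        mask = flag_outliers([10, 12, 11, 10, 11, 50])
        assert mask.median == 11 and mask.mad == 1
        assert list(mask.flags) == [False] * 5 + [True]

    def test_mad_zero_rule_applies_even_with_an_extreme_value(self):
        # MAD([1,1,1,1,100]) = 0: the stated rule flags nothing
        assert flag_outliers([1, 1, 1, 1, 100]).n_flagged == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            flag_outliers([])

    def test_nan_values_never_flagged(self):
        mask = flag_outliers([10, 11, 12, np.nan, 400])
        assert not mask.flags[3] and mask.flags[4]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=50),
        a=st.floats(0.01, 100.0),
        b=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, values, a, b):
        base = flag_outliers(values).flags
        mapped = flag_outliers([a * v + b for v in values]).flags
        assert list(base) == list(mapped)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=40))
    def test_matches_brute_force(self, values):
        x = np.array(values)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            expected = [False] * len(x)
        else:
            expected = [abs(v - med) / mad > 3 for v in x]
        assert list(flag_outliers(values).flags) == expected

    def test_per_dataset_grouping(self):
        cells = pd.DataFrame(
            {
                "line": ["A"] * 6 + ["B"] * 6,
                CYTOPLASM_AREA: [10, 12, 11, 10, 11, 50] + [50, 52, 51, 50, 51, 10],
            }
        )
        flags = flag_area_outliers(cells)
        # the 50 is an outlier in line A but normal in line B (and vice versa)
        assert flags.tolist() == [False] * 5 + [True] + [False] * 5 + [True]


def _cells_df(rows):
    cols = ["line", "plate", "well", "compound", "concentration_uM", "replicate",
            "f1", "f2"]
    return pd.DataFrame(rows, columns=cols)


class TestAggregation:
    def test_median_per_replicate_well(self):
        rows = [("A", "p", "w1", "drug", 1.0, 1, v, 2 * v) for v in (1.0, 2.0, 9.0)]
        profiles, undet = aggregate_replicates(_cells_df(rows))
        assert profiles.loc[0, "f1"] == 2.0 and profiles.loc[0, "f2"] == 4.0
        assert profiles.loc[0, "n_cells"] == 3
        assert undet == []

    def test_outlier_cell_removed_before_median(self):
        rows = [("A", "p", "w1", "drug", 1.0, 1, v, 1.0) for v in range(1, 102)]
        flags = pd.Series([False] * 100 + [True])
        clean, _ = aggregate_replicates(_cells_df(rows))
        masked, _ = aggregate_replicates(_cells_df(rows), flags)
        assert masked.loc[0, "f1"] == 50.5  # median of 1..100
        assert clean.loc[0, "f1"] == 51.0

    def test_all_missing_feature_reported_undetectable(self):
        rows = [("A", "p", "w1", "drug", 1.0, 1, np.nan, 1.0) for _ in range(5)]
        rows += [("A", "p", "w2", "DMSO", 0.0, 1, 1.0, 1.0) for _ in range(5)]
        _, undet = aggregate_replicates(_cells_df(rows))
        assert undet == ["f1"]

    def test_fully_flagged_well_dropped_with_warning(self):
        rows = [("A", "p", "w1", "drug", 1.0, 1, 1.0, 1.0) for _ in range(3)]
        rows += [("A", "p", "w2", "drug", 1.0, 2, 1.0, 1.0) for _ in range(3)]
        flags = pd.Series([True] * 3 + [False] * 3)
        with pytest.warns(UserWarning, match="dropped"):
            profiles, _ = aggregate_replicates(_cells_df(rows), flags)
        assert len(profiles) == 1


class TestVehicleNormalization:
    def _profiles(self):
        rows = [
            # two vehicle wells and one treated well on the same plate
            ("A", "p1", "v1", "DMSO", 0.0, 1, 1, 10.0, 5.0),
            ("A", "p1", "v2", "DMSO", 0.0, 2, 1, 20.0, 5.0),
            ("A", "p1", "t1", "drug", 1.0, 1, 1, 30.0, 10.0),
        ]
        return pd.DataFrame(
            rows,
            columns=["line", "plate", "well", "compound", "concentration_uM",
                     "replicate", "n_cells", "f1", "f2"],
        )

    def test_fold_change_against_vehicle_median(self):
        out, zero = normalize_to_vehicle(self._profiles())
        # vehicle median: f1=15, f2=5
        assert out.loc[2, "f1"] == pytest.approx(2.0)
        assert out.loc[2, "f2"] == pytest.approx(2.0)
        assert zero == []

    def test_vehicle_replicate_equal_to_median_maps_to_one(self):
        p = self._profiles()
        p.loc[1, "f1"] = 10.0  # both vehicles identical → each equals the median
        out, _ = normalize_to_vehicle(p)
        assert out.loc[0, "f1"] == pytest.approx(1.0)
        assert out.loc[0, "f2"] == pytest.approx(1.0)

    def test_zero_vehicle_feature_dropped_not_infinite(self):
        p = self._profiles()
        p.loc[[0, 1], "f2"] = 0.0
        out, zero = normalize_to_vehicle(p)
        assert zero == ["f2"]
        assert np.isnan(out.loc[2, "f2"])
        assert out.loc[2, "f1"] == pytest.approx(2.0)  # other features unaffected

    def test_missing_vehicle_stratum_raises(self):
        p = self._profiles()
        p["compound"] = "drug"
        with pytest.raises(ValueError, match="vehicle"):
            normalize_to_vehicle(p)


class TestNearZeroVariance:
    def test_constant_dropped(self):
        m = pd.DataFrame({"c": np.ones(100), "x": np.arange(100.0)})
        drop = filter_near_zero_variance(m)
        assert drop["c"] and not drop["x"]

    def test_96_4_dropped_95_5_kept(self):
        m = pd.DataFrame(
            {
                "dropme": [0.0] * 96 + [1.0] * 4,  # ratio 24 > 19, 2% unique
                "keepme": [0.0] * 95 + [1.0] * 5,  # ratio 19, not > 19
            }
        )
        drop = filter_near_zero_variance(m)
        assert bool(drop["dropme"]) and not bool(drop["keepme"])

    def test_unique_fraction_condition_required(self):
        # high ratio but many unique values → kept
        vals = np.concatenate([np.zeros(80), np.arange(1, 21, dtype=float)])
        drop = filter_near_zero_variance(pd.DataFrame({"x": vals}))
        assert not bool(drop["x"])

    def test_rounding_to_8_significant_digits(self):
        base = np.ones(100) * (1 / 3)
        base[:50] += 1e-12  # spurious uniqueness below 8 significant digits
        drop = filter_near_zero_variance(pd.DataFrame({"x": base}))
        assert bool(drop["x"])

    def test_idempotent_on_filtered_output(self, tiny_cells):
        cells, _ = tiny_cells
        profiles, undet = aggregate_replicates(cells, flag_area_outliers(cells))
        norm, zero = normalize_to_vehicle(profiles)
        feats = [c for c in profiles.columns if c not in prof.PROFILE_KEYS + ["n_cells"]]
        cand = [f for f in feats if f not in set(undet) | set(zero)]
        drop1 = filter_near_zero_variance(norm[cand])
        kept = [f for f in cand if not drop1[f]]
        drop2 = filter_near_zero_variance(norm[kept])
        assert not drop2.any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(10, 50))
        vals = data.draw(
            st.lists(st.sampled_from([0.0, 1.0, 2.0, 3.0]), min_size=n, max_size=n)
        )
        m = pd.DataFrame({"x": vals})
        _, counts = np.unique(vals, return_counts=True)
        counts = sorted(counts, reverse=True)
        if len(counts) == 1:
            expected = True
        else:
            expected = (counts[0] / counts[1] > 19) and (len(counts) / n < 0.10)
        assert bool(filter_near_zero_variance(m)["x"]) == expected


def test_feature_mask_single_status_with_precedence():
    mask = build_feature_mask(
        ["a", "b", "c", "d"],
        nzv_drop=pd.Series({"b": True, "c": True}),
        undetectable=["c"],
        zero_vehicle=["d"],
    )
    assert mask.status.to_dict() == {
        "a": "kept", "b": "near_zero_variance", "c": "undetectable", "d": "zero_vehicle"
    }
    assert mask.kept == ["a"]


class TestViability:
    def test_no_change(self):
        assert viability_percent_change([100, 100], [100, 100]) == pytest.approx(0.0)

    def test_doxorubicin_like_67_percent_loss(self):
        assert viability_percent_change([660], [2000]) == pytest.approx(-67.0)

    def test_amiodarone_like_31_percent_loss(self):
        assert viability_percent_change([1380], [2000]) == pytest.approx(-31.0)

    def test_zero_vehicle_mean_raises(self):
        with pytest.raises(ValueError):
            viability_percent_change([10], [0])
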