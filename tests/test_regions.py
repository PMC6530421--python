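"""Regional comparisons: region assignment, the delta (L1 histogram)
statistic, chromosome summaries and length fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourpoint.core import CoCProfile, RecombinationProfile
from fourpoint.io import GeneticMap
from fourpoint.regions import (
    assign_regions,
    chromosome_summaries,
    delta_statistic,
    difference_ratios,
    length_fit,
    region_values,
    ChromosomeSummary,
)
from fourpoint.scan import ScanRecord


def map_span(lg="1", lo=0.0, hi=90.0):
    return GeneticMap(
        pd.DataFrame(
            {
                "name": [f"{lg}a", f"{lg}b"],
                "linkage_group": [lg, lg],
                "position_cM": [lo, hi],
                "seg_type": ["hk_hk", "hk_hk"],
            }
        )
    )


def record(lg, mid, c4, method="em"):
    return ScanRecord(
        lg=lg,
        markers=(f"{lg}_{mid}a", f"{lg}_{mid}b", f"{lg}_{mid}c", f"{lg}_{mid}d"),
        positions=(mid - 1.5, mid - 0.5, mid + 0.5, mid + 1.5),
        r=RecombinationProfile(0.1, 0.1, 0.1, 0.18, 0.18, 0.244),
        coc=CoCProfile(1.0, 1.0, 1.0, c4),
        method=method,
        n_used=400,
    )


class TestAssignRegions:
    def test_thirds_of_ninety(self):
        gmap = map_span()
        assert assign_regions(gmap, "1", [10.0, 45.0, 89.0]) == [
            "NO.1", "NO.2", "NO.3",
        ]

    def test_boundary_belongs_to_next_region(self):
        assert assign_regions(map_span(), "1", [30.0]) == ["NO.2"]
        assert assign_regions(map_span(), "1", [90.0]) == ["NO.3"]  # closed end

    def test_single_region(self):
        assert assign_regions(map_span(), "1", [10.0, 80.0], k=1) == ["NO.1", "NO.1"]

    def test_absent_lg(self):
        with pytest.raises(KeyError):
            assign_regions(map_span(), "9", [1.0])


class TestDeltaStatistic:
    def test_identical_distributions_give_zero(self):
        vals = [0.5, 1.0, 1.5, 2.0]
        assert delta_statistic(vals, list(vals)).delta == 0.0

    def test_disjoint_supports_give_two(self):
        cmp = delta_statistic([0.0, 0.1, 0.2], [5.0, 5.1, 5.2])
        assert cmp.delta == pytest.approx(2.0)

    def test_half_overlap_example(self):
        # histograms (1, 0) vs (0.5, 0.5) on explicit shared edges
        cmp = delta_statistic([0.25, 0.25], [0.25, 0.75], bins=np.array([0.0, 0.5, 1.0]))
        assert cmp.delta == pytest.approx(1.0)
        assert cmp.p1.tolist() == [1.0, 0.0]
        assert cmp.p2.tolist() == [0.5, 0.5]

    def test_empty_region_is_absent_not_zero(self):
        with pytest.raises(ValueError, match="empty region"):
            delta_statistic([], [1.0])
        with pytest.raises(ValueError, match="empty region"):
            delta_statistic([float("nan")], [1.0])

    @given(
        st.lists(st.floats(0, 10), min_size=1, max_size=30),
        st.lists(st.floats(0, 10), min_size=1, max_size=30),
    )
    @settings(max_examples=80, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        d_ab = delta_statistic(a, b).delta
        d_ba = delta_statistic(b, a).delta
        assert 0.0 <= d_ab <= 2.0 + 1e-12
        assert d_ab == pytest.approx(d_ba)

    def test_triangle_inequality_on_shared_bins(self, rng):
        edges = np.linspace(0, 1, 11)
        for _ in range(50):
            a, b, c = (rng.uniform(0, 1, size=rng.integers(2, 20)) for _ in range(3))
            d = {
                key: delta_statistic(x, y, bins=edges).delta
                for key, (x, y) in {
                    "ab": (a, b), "bc": (b, c), "ac": (a, c)
                }.items()
            }
            assert d["ac"] <= d["ab"] + d["bc"] + 1e-12

    def test_unnormalized_reading(self):
        cmp = delta_statistic(
            [0.25, 0.25], [0.75], bins=np.array([0.0, 0.5, 1.0]), normalized=False
        )
        assert cmp.delta == pytest.approx(3.0)  # |2-0| + |0-1|


class TestDifferenceRatios:
    def make_scan(self, c4_by_region):
        gmap = map_span()
        records = []
        for region, mids in (("NO.1", [5, 15, 25]), ("NO.2", [35, 45, 55]),
                             ("NO.3", [65, 75, 85])):
            for m in mids:
                records.append(record("1", float(m), c4_by_region[region]))
        return gmap, records

    def test_identical_regions_give_zero_triple(self):
        gmap, records = self.make_scan({"NO.1": 1.0, "NO.2": 1.0, "NO.3": 1.0})
        out = difference_ratios(records, gmap)["1"]
        assert list(out.values()) == [0.0, 0.0, 0.0]

    def test_disjoint_middle_region(self):
        gmap, records = self.make_scan({"NO.1": 1.0, "NO.2": 9.0, "NO.3": 1.0})
        out = difference_ratios(records, gmap)["1"]
        assert out["NO.1-NO.2"] == pytest.approx(2.0)
        assert out["NO.2-NO.3"] == pytest.approx(2.0)
        assert out["NO.1-NO.3"] == pytest.approx(0.0)

    def test_empty_region_flagged_absent(self):
        gmap = map_span()
        records = [record("1", 5.0, 1.0), record("1", 80.0, 1.0)]
        out = difference_ratios(records, gmap)["1"]
        assert np.isnan(out["NO.1-NO.2"])
        assert out["NO.1-NO.3"] == 0.0

    def test_every_window_in_exactly_one_region(self):
        gmap, records = self.make_scan({"NO.1": 1.0, "NO.2": 2.0, "NO.3": 3.0})
        vals = region_values(records, gmap, lg="1")
        assert sum(len(v) for v in vals.values()) == len(records)


class TestChromosomeSummaries:
    def test_single_window_group(self):
        gmap = map_span()
        [summ] = chromosome_summaries([record("1", 45.0, 2.5)], gmap)
        assert summ.mean_C == summ.median_C == 2.5
        assert summ.iqr_C == 0.0 and summ.length_cM == 90.0

    def test_quartiles_by_linear_interpolation(self):
        gmap = map_span()
        records = [record("1", m, v) for m, v in zip((5, 25, 45, 65), (1, 2, 3, 4))]
        [summ] = chromosome_summaries(records, gmap)
        # type-7 convention: q1 = 1.75, q3 = 3.25 (midpoint convention would
        # give 1.5 / 3.5 — the choice matters and is declared)
        assert summ.median_C == 2.5
        assert summ.q1 == pytest.approx(1.75)
        assert summ.q3 == pytest.approx(3.25)
        assert summ.iqr_C == pytest.approx(1.5)
        assert summ.q1 <= summ.median_C <= summ.q3

    def test_invariant_to_window_order(self):
        gmap = map_span()
        records = [record("1", m, v) for m, v in zip((5, 25, 45, 65), (4, 1, 3, 2))]
        a = chromosome_summaries(records, gmap)
        b = chromosome_summaries(records[::-1], gmap)
        assert a == b

    def test_undefined_values_excluded_and_counted(self):
        gmap = map_span()
        records = [record("1", 5.0, 1.0), record("1", 45.0, float("nan"))]
        [summ] = chromosome_summaries(records, gmap)
        assert summ.mean_C == 1.0
        assert summ.n_undefined == 1


class TestLengthFit:
    def make_summaries(self, xs, ys):
        return [
            ChromosomeSummary(
                lg=str(i + 1), length_cM=float(x), mean_C=float(y),
                median_C=float(y), q1=float(y), q3=float(y),
                min=float(y), max=float(y), n_windows=1, n_undefined=0,
            )
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_exact_line_recovered(self):
        summ = self.make_summaries([100, 200, 300, 400, 500, 600],
                                   [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fits = length_fit(summ, group_a=["1", "2", "3"])
        for grp in fits.values():
            assert grp["slope"] == pytest.approx(0.01)
            assert grp["adj_r_squared"] == pytest.approx(1.0)

    def test_perturbed_point_matches_closed_form_ols(self):
        xs = [100.0, 200.0, 300.0, 400.0]
        ys = [1.0, 2.0, 3.0, 4.5]
        summ = self.make_summaries(xs + [10, 20, 30], ys + [0.1, 0.2, 0.3])
        fits = length_fit(summ, group_a=["1", "2", "3", "4"])
        x, y = np.array(xs), np.array(ys)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fits["a"]["slope"] == pytest.approx(slope)
        assert fits["a"]["adj_r_squared"] < 1.0

    def test_excluded_lg_absent_from_both_groups(self):
        summ = self.make_summaries([100, 200, 300, 400, 500, 600, 700],
                                   [1, 2, 3, 4, 5, 6, 99])
        fits = length_fit(summ, group_a=["1", "2", "3"], exclude=["7"])
        assert "7" not in fits["a"]["lgs"] + fits["b"]["lgs"]

    def test_small_group_rejected(self):
        summ = self.make_summaries([100, 200, 300, 400], [1, 2, 3, 4])
        with pytest.raises(ValueError, match=">= 3"):
            length_fit(summ, group_a=["1"])
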