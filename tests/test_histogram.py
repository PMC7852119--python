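import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molsetcomp import histogram as H
from molsetcomp.compare import Comparator, ComparisonResult, PairMetric


def result_from_values(values, name="test_metric"):
    metrics = [
        PairMetric(i, v if v is not None else math.nan, v is not None)
        for i, v in enumerate(values)
    ]
    return ComparisonResult(Comparator(name, "similarity"), metrics)


class TestBuildHistogram:
    def test_two_bins_last_closed(self):
        h = H.build_histogram(result_from_values([0, 0.2, 0.5, 1.0]), n_bins=2,
                              lower=0, upper=1)
        assert h.counts == [2, 2]  # 0.5 and 1.0 in the upper bin

    def test_defaults_ten_bins_spanning_min_max(self):
        vals = [0.05 * i for i in range(21)]
        h = H.build_histogram(result_from_values(vals))
        assert h.n_bins == 10
        assert h.borders[0] == min(vals) and h.borders[-1] == max(vals)
        assert sum(h.counts) == len(vals)

    def test_degenerate_all_equal_expands_range(self):
        h = H.build_histogram(result_from_values([0.7] * 5))
        assert h.borders[0] == pytest.approx(0.2)
        assert h.borders[-1] == pytest.approx(1.2)
        assert sum(h.counts) == 5 and h.n_out_of_range == 0

    def test_out_of_range_counted_separately(self):
        h = H.build_histogram(result_from_values([0.1, 0.5, 0.9, 1.5, -0.2]),
                              n_bins=2, lower=0, upper=1)
        assert sum(h.counts) == 3 and h.n_out_of_range == 2

    def test_undefined_values_excluded(self):
        h = H.build_histogram(result_from_values([0.2, None, 0.8]))
        assert h.total == 2

    def test_usage_errors(self):
        res = result_from_values([0.1, 0.9])
        with pytest.raises(H.HistogramUsageError):
            H.build_histogram(res, lower=1, upper=0)
        with pytest.raises(H.HistogramUsageError):
            H.build_histogram(res, n_bins=0)
        with pytest.raises(H.HistogramUsageError):
            H.build_histogram(result_from_values([None, None]))

    def test_upper_border_labels(self):
        h = H.build_histogram(result_from_values([0, 1]), n_bins=2, lower=0, upper=1)
        assert h.labels == ["0.5", "1"]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=80),
        st.integers(1, 12),
    )
    def test_conservation_property(self, values, n_bins):
        res = result_from_values(values)
        h = H.build_histogram(res, n_bins=n_bins)
        assert sum(h.counts) + h.n_out_of_range == len(values)
        assert sum(h.percents) + 100.0 * h.n_out_of_range / h.total == pytest.approx(100.0)


class TestCustomBorders:
    def test_half_open_rule(self):
        h = H.set_custom_borders(result_from_values([0.4, 0.5]), [0, 0.5, 1])
        assert h.counts == [1, 1]  # 0.5 opens the second bin

    def test_single_bin(self):
        h = H.set_custom_borders(result_from_values([0.1, 0.9, 2.0]), [0, 1])
        assert h.counts == [2] and h.n_out_of_range == 1

    def test_non_increasing_borders_identified(self):
        with pytest.raises(H.HistogramUsageError, match="1,2"):
            H.set_custom_borders(result_from_values([0.1]), [0, 0.5, 0.5, 1])

    def test_refinement_merge_consistency(self):
        rng = random.Random(13)
        values = [rng.uniform(0, 1) for _ in range(300)]
        res = result_from_values(values)
        fine = H.build_histogram(res, n_bins=10, lower=0, upper=1)
        merged_borders = fine.borders[::2]  # merge adjacent bin pairs
        coarse = H.set_custom_borders(res, merged_borders)
        merged_counts = [
            fine.counts[i] + fine.counts[i + 1] for i in range(0, 10, 2)
        ]
        assert coarse.counts == merged_counts


class TestDrilldown:
    def _setup(self):
        values = [0.1, 0.2, 0.8, 0.9, 0.15]
        res = result_from_values(values)
        h = H.build_histogram(res, n_bins=2, lower=0, upper=1)

        class P:
            def __init__(self, i):
                self.original = type("R", (), {"raw": f"orig{i}"})()
                self.predicted = type("R", (), {"raw": f"pred{i}"})()

        pairs = [P(i) for i in range(len(values))]
        return res, h, pairs

    def test_listing_contents_in_pair_order(self):
        res, h, pairs = self._setup()
        listing = H.drilldown(h, 0, pairs, result=res)
        assert [row[0] for row in listing] == [0, 1, 4]
        assert listing[0][1] == "orig0" and listing[0][3] == 0.1

    def test_sum_over_bins_equals_counts(self):
        res, h, pairs = self._setup()
        total = sum(len(H.drilldown(h, k, pairs, result=res)) for k in range(h.n_bins))
        assert total == sum(h.counts)

    def test_empty_bin_empty_listing(self):
        res = result_from_values([0.05])
        h = H.build_histogram(res, n_bins=2, lower=0, upper=1)
        assert H.drilldown(h, 1, [], result=res) == []

    def test_bin_index_out_of_range(self):
        res, h, pairs = self._setup()
        with pytest.raises(H.HistogramUsageError):
            H.drilldown(h, 5, pairs, result=res)

    def test_max_pairs_truncation(self):
        res, h, pairs = self._setup()
        listing = H.drilldown(h, 0, pairs, result=res, max_pairs=2)
        assert len(listing) == 2


class TestExport:
    def test_csv_round_trip(self, tmp_path):
        res = result_from_values([0.1, 0.4, 0.9, 0.9])
        h = H.build_histogram(res, n_bins=3, lower=0, upper=1)
        p = tmp_path / "h.csv"
        H.export_table(h, p, fmt="csv")
        back = H.read_table_csv(p)
        assert back["counts"] == h.counts
        assert back["borders"] == pytest.approx(h.borders)

    def test_json_includes_out_of_range(self, tmp_path):
        import json

        res = result_from_values([0.5, 2.0])
        h = H.build_histogram(res, n_bins=2, lower=0, upper=1)
        p = tmp_path / "h.json"
        H.export_table(h, p, fmt="json")
        doc = json.loads(p.read_text())
        assert doc["n_out_of_range"] == 1
        # percents recomputable from counts
        for c, pct in zip(doc["counts"], doc["percents"]):
            assert pct == pytest.approx(100.0 * c / h.total, abs=1e-9)

    def test_svg_chart_contains_bars(self, tmp_path):
        res = result_from_values([0.2, 0.8])
        h = H.build_histogram(res, n_bins=2, lower=0, upper=1)
        p = tmp_path / "h.svg"
        H.export_chart(h, p, fmt="svg", bar_frequency_labels=True)
        svg = p.read_text()
        assert svg.count("<g id=\"patch_") >= 2  # two bar patches + canvas

    @pytest.mark.parametrize("fmt", ["png", "jpeg", "pdf"])
    def test_binary_chart_formats_render(self, tmp_path, fmt):
        res = result_from_values([0.2, 0.8])
        h = H.build_histogram(res, n_bins=2, lower=0, upper=1)
        p = tmp_path / f"h.{fmt}"
        H.export_chart(h, p, fmt=fmt)
        assert p.stat().st_size > 0

    def test_unsupported_format(self, tmp_path):
        res = result_from_values([0.2])
        h = H.build_histogram(res, n_bins=1, lower=0, upper=1)
        with pytest.raises(H.HistogramUsageError):
            H.export_chart(h, tmp_path / "h.bmp", fmt="bmp")
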