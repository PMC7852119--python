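"""Frequency histograms over per-pair metric values.

Binning conventions, pinned once and used everywhere:

* bins are half-open ``[b_i, b_{i+1})`` with the last bin closed on both
  sides, so the maximum value is always counted;
* the default configuration is 10 equal-width bins spanning the minimum and
  maximum of the defined metric values;
* values outside the configured borders are not clamped into the edge bins;
  they are tallied separately as ``n_out_of_range`` so that
  ``sum(counts) + n_out_of_range`` always equals the number of defined
  metric values;
* an all-equal value vector would give a zero-width default range; it is
  expanded to ``value ± 0.5`` instead (constant vectors are routine, e.g.
  an equality comparison of a perfect prediction run);
* default bin labels show the bin's upper border.

Each bin also remembers which pair indices fell into it, which is what the
drill-down listing exports.
"""

from __future__ import annotations

import csv
import json
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .compare import ComparisonResult, SavedPair

DEFAULT_N_BINS = 10
CHART_FORMATS = ("png", "jpeg", "pdf", "svg")
_CSV_HEADER = ["bin_lower", "bin_upper", "count", "percent", "label"]


@dataclass
class Histogram:
    comparator_name: str
    borders: list[float]  # strictly increasing, len == n_bins + 1
    counts: list[int]
    bin_members: list[list[int]]  # pair indices per bin
    n_out_of_range: int
    label_mode: str = "upper_border"  # or "interval"

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts) + self.n_out_of_range

    @property
    def percents(self) -> list[float]:
        total = self.total
        if total == 0:
            return [0.0] * self.n_bins
        return [100.0 * c / total for c in self.counts]

    @property
    def labels(self) -> list[str]:
        if self.label_mode == "interval":
            return [
                f"[{self.borders[i]:g}, {self.borders[i + 1]:g}{']' if i == self.n_bins - 1 else ')'}"
                for i in range(self.n_bins)
            ]
        return [f"{b:g}" for b in self.borders[1:]]


class HistogramUsageError(ValueError):
    pass


def _validate_borders(borders: Sequence[float]) -> list[float]:
    if len(borders) < 2:
        raise HistogramUsageError("at least 2 borders are required")
    for i in range(len(borders) - 1):
        if not borders[i] < borders[i + 1]:
            raise HistogramUsageError(
                f"borders must be strictly increasing; offending pair at "
                f"positions {i},{i + 1}: {borders[i]!r} >= {borders[i + 1]!r}"
            )
    return [float(b) for b in borders]


def _bin_values(
    result: ComparisonResult, borders: list[float], label_mode: str
) -> Histogram:
    n_bins = len(borders) - 1
    counts = [0] * n_bins
    members: list[list[int]] = [[] for _ in range(n_bins)]
    out = 0
    lo, hi = borders[0], borders[-1]
    for m in result.metrics:
        if not m.defined:
            continue
        v = m.value
        if v < lo or v > hi:
            out += 1
            continue
        if v == hi:  # last bin is closed above
            k = n_bins - 1
        else:
            k = bisect_right(borders, v) - 1
        counts[k] += 1
        members[k].append(m.pair_index)
    return Histogram(result.comparator.name, borders, counts, members, out, label_mode)


def build_histogram(
    result: ComparisonResult,
    n_bins: Optional[int] = None,
    lower: Optional[float] = None,
    upper: Optional[float] = None,
    label_mode: str = "upper_border",
) -> Histogram:
    """Equal-width histogram; defaults: 10 bins spanning [min, max]."""
    vals = result.defined_values()
    if not vals:
        raise HistogramUsageError(
            f"no defined metric values for {result.comparator.name}; cannot bin"
        )
    if n_bins is None:
        n_bins = DEFAULT_N_BINS
    if n_bins < 1:
        raise HistogramUsageError(f"n_bins must be >= 1, got {n_bins}")
    lo = min(vals) if lower is None else float(lower)
    hi = max(vals) if upper is None else float(upper)

    def spaced(a: float, b: float) -> list[float]:
        return [a + (b - a) * i / n_bins for i in range(n_bins)] + [b]

    borders = spaced(lo, hi)
    degenerate = any(borders[i] >= borders[i + 1] for i in range(n_bins))
    if degenerate and lower is None and upper is None:
        # all-equal (or numerically indistinguishable) values: widen to +-0.5
        mid = (lo + hi) / 2
        borders = spaced(mid - 0.5, mid + 0.5)
    if not lo <= hi:
        raise HistogramUsageError(f"lower border must be < upper border ({lo} >= {hi})")
    return _bin_values(result, _validate_borders(borders), label_mode)


def set_custom_borders(
    result: ComparisonResult,
    borders: Sequence[float],
    label_mode: str = "upper_border",
) -> Histogram:
    """Histogram with arbitrary (possibly unequal-width) bin borders."""
    return _bin_values(result, _validate_borders(borders), label_mode)


def drilldown(
    h: Histogram,
    bin_index: int,
    pairs: Sequence,
    metrics_by_index: Optional[dict[int, float]] = None,
    result: Optional[ComparisonResult] = None,
    max_pairs: Optional[int] = None,
) -> list[tuple[int, str, str, float]]:
    """Listing of (pair_index, original raw, predicted raw, metric value)
    for every pair in one bin, in pair order.

    ``pairs`` may be a :class:`~molsetcomp.molio.PairedSet` or the pair list
    of a loaded results document.  ``max_pairs`` truncates the listing.
    """
    if not 0 <= bin_index < h.n_bins:
        raise HistogramUsageError(
            f"bin index {bin_index} out of range 0..{h.n_bins - 1}"
        )
    if metrics_by_index is None:
        if result is None:
            raise HistogramUsageError("provide metrics_by_index or result")
        metrics_by_index = {m.pair_index: m.value for m in result.metrics if m.defined}
    plist = getattr(pairs, "pairs", pairs)
    listing = []
    for idx in h.bin_members[bin_index]:
        p = plist[idx]
        if isinstance(p, SavedPair):
            orig, pred = p.original_raw, p.predicted_raw
        else:
            orig, pred = p.original.raw, p.predicted.raw
        listing.append((idx, orig, pred, metrics_by_index[idx]))
        if max_pairs is not None and len(listing) >= max_pairs:
            break
    return listing


def write_drilldown(listing: list[tuple[int, str, str, float]], path: str | Path,
                    truncated: bool = False) -> None:
    """Export a drill-down listing as a tab-separated molecule-pair file."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("pair_index\toriginal\tpredicted\tvalue\n")
        for idx, orig, pred, val in listing:
            fh.write(f"{idx}\t{orig}\t{pred}\t{val:.9g}\n")
        if truncated:
            fh.write("# truncated\n")


# ---------------------------------------------------------------------------
# export


def export_chart(
    h: Histogram,
    path: str | Path,
    fmt: Optional[str] = None,
    bar_frequency_labels: bool = False,
    y_axis_range: Optional[tuple[float, float]] = None,
    percent: bool = False,
    dpi: int = 150,
) -> None:
    """Render the histogram as a bar chart (PNG, JPEG, PDF or SVG).

    Vector formats (PDF/SVG) scale without rasterisation.  Bar geometry
    follows the bin borders, so unequal-width custom bins render with
    proportional widths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "png"
    fmt = {"jpg": "jpeg"}.get(fmt, fmt)
    if fmt not in CHART_FORMATS:
        raise HistogramUsageError(
            f"unsupported chart format {fmt!r}; choose one of {', '.join(CHART_FORMATS)}"
        )
    heights = h.percents if percent else h.counts
    lefts = h.borders[:-1]
    widths = [h.borders[i + 1] - h.borders[i] for i in range(h.n_bins)]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.bar(lefts, heights, width=widths, align="edge", edgecolor="black",
           color="#4878a8")
    ax.set_xticks(h.borders[1:])
    ax.set_xticklabels(h.labels if h.label_mode == "upper_border"
                       else [f"{b:g}" for b in h.borders[1:]])
    ax.set_xlabel("metric value (bin upper border)")
    ax.set_ylabel("molecule pairs [%]" if percent else "molecule pairs")
    ax.set_title(h.comparator_name)
    if y_axis_range is not None:
        ax.set_ylim(*y_axis_range)
    if bar_frequency_labels:
        for left, width, height, count in zip(lefts, widths, heights, h.counts):
            label = f"{height:.1f}" if percent else str(count)
            ax.annotate(label, (left + width / 2, height),
                        ha="center", va="bottom", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, format=fmt, dpi=dpi)
    plt.close(fig)


def export_table(h: Histogram, path: str | Path, fmt: str = "csv") -> None:
    """Serialise borders, counts, percents and labels as CSV or JSON."""
    path = Path(path)
    if fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER)
            for i in range(h.n_bins):
                w.writerow([
                    repr(h.borders[i]), repr(h.borders[i + 1]),
                    h.counts[i], f"{h.percents[i]:.1f}", h.labels[i],
                ])
        return
    if fmt == "json":
        doc = {
            "comparator": h.comparator_name,
            "borders": h.borders,
            "counts": h.counts,
            "percents": h.percents,
            "labels": h.labels,
            "n_out_of_range": h.n_out_of_range,
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    raise HistogramUsageError(f"unsupported table format {fmt!r} (csv or json)")


def read_table_csv(path: str | Path) -> dict:
    """Read back a CSV table written by :func:`export_table`."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.DictReader(fh))
    return {
        "borders": [float(rows[0]["bin_lower"])] + [float(r["bin_upper"]) for r in rows],
        "counts": [int(r["count"]) for r in rows],
        "percents": [float(r["percent"]) for r in rows],
        "labels": [r["label"] for r in rows],
    }
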