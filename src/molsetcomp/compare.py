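"""Per-pair metric evaluation over a positionally paired molecule set.

Two metric modes exist, mirroring how prediction quality is assessed:

* ``similarity`` — Tanimoto-family fingerprint comparisons, LINGO, and the
  canonical-form equality check; values in [0, 1], evaluated directly on
  the pair;
* ``abs_difference`` — every numerical descriptor; the metric is
  ``|d(original) - d(predicted)|``.

Both are symmetric in the pair members, so swapping the two input files
leaves every result unchanged.  Invalid pairs (a parse failure or blank
line on either side) and undefined descriptor cases are carried through as
``defined=False`` metrics: the metric vector always has one slot per file
line, which is what makes drill-down listings traceable back to the input.

Per-molecule work (fingerprints, descriptor values) is memoised by
canonical form, so a molecule appearing on many lines is only analysed
once.  Evaluation may be chunked over a thread pool; chunk boundaries are
deterministic and results are reassembled in pair order, so the output is
identical for every thread count.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import descriptors as desc_mod
from . import fingerprints as fp_mod
from .molgraph import MolGraph, canonical_form
from .molio import MoleculePair, PairedSet

RESULTS_FORMAT = "molsetcomp-results"
RESULTS_VERSION = 1

SIMILARITY_COMPARATORS = (
    "tanimoto_path",
    "tanimoto_shortest_path",
    "tanimoto_substructure",
    "lingo",
    "equality",
)


@dataclass(frozen=True)
class Comparator:
    name: str
    mode: str  # "similarity" | "abs_difference"

    @staticmethod
    def from_name(name: str) -> "Comparator":
        if name in SIMILARITY_COMPARATORS:
            return Comparator(name, "similarity")
        if name in desc_mod.DESCRIPTORS:
            return Comparator(name, "abs_difference")
        raise KeyError(
            f"unknown comparator {name!r}; valid names: "
            + ", ".join(list_comparators())
        )


def list_comparators() -> list[str]:
    """All valid comparator names (similarities first, then descriptors)."""
    return list(SIMILARITY_COMPARATORS) + desc_mod.list_descriptors()


@dataclass(frozen=True)
class PairMetric:
    pair_index: int
    value: float
    defined: bool = True


@dataclass
class ComparisonResult:
    comparator: Comparator
    metrics: list[PairMetric]
    n_valid: int = field(init=False)
    n_failed: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_valid = sum(1 for m in self.metrics if m.defined)
        self.n_failed = len(self.metrics) - self.n_valid

    def defined_values(self) -> list[float]:
        return [m.value for m in self.metrics if m.defined]

    @property
    def stats(self) -> Optional[dict[str, float]]:
        vals = self.defined_values()
        if not vals:
            return None
        return {
            "mean": sum(vals) / len(vals),
            "min": min(vals),
            "max": max(vals),
        }


class _MoleculeFeatureCache:
    """Memoises per-molecule features keyed by canonical SMILES.

    Thread-safe in the benign sense: concurrent misses may compute the same
    feature twice, but the value stored is identical either way.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], object] = {}

    def get(self, g: MolGraph, feature: str, compute) -> object:
        key = (canonical_form(g), feature)
        hit = self._store.get(key)
        if hit is None:
            hit = compute(g)
            self._store[key] = hit
        return hit


def _pair_value(
    pair: MoleculePair, comp: Comparator, cache: _MoleculeFeatureCache
) -> PairMetric:
    if not pair.valid:
        return PairMetric(pair.index, math.nan, defined=False)
    ga, gb = pair.original.graph, pair.predicted.graph
    assert ga is not None and gb is not None

    if comp.mode == "similarity":
        if comp.name == "equality":
            return PairMetric(pair.index, desc_mod.equality(ga, gb))
        if comp.name == "lingo":
            pa = cache.get(ga, "lingo", fp_mod.lingo_profile)
            pb = cache.get(gb, "lingo", fp_mod.lingo_profile)
            return PairMetric(pair.index, fp_mod.lingo_similarity(pa, pb))
        fp_fn = {
            "tanimoto_path": fp_mod.path_fingerprint,
            "tanimoto_shortest_path": fp_mod.shortest_path_fingerprint,
            "tanimoto_substructure": fp_mod.substructure_fingerprint,
        }[comp.name]
        fa = cache.get(ga, comp.name, fp_fn)
        fb = cache.get(gb, comp.name, fp_fn)
        return PairMetric(pair.index, fp_mod.tanimoto(fa, fb))

    da: desc_mod.DescriptorValue = cache.get(
        ga, comp.name, lambda g: desc_mod.compute(g, comp.name)
    )
    db: desc_mod.DescriptorValue = cache.get(
        gb, comp.name, lambda g: desc_mod.compute(g, comp.name)
    )
    if not (da.defined and db.defined):
        return PairMetric(pair.index, math.nan, defined=False)
    return PairMetric(pair.index, abs(da.value - db.value))


def evaluate(
    pairs: PairedSet,
    comparators: list[Comparator | str],
    n_threads: int = 1,
) -> list[ComparisonResult]:
    """Evaluate each comparator on every pair.

    Results are returned in comparator order; each metric vector is in pair
    order and is identical for every ``n_threads``.
    """
    if not comparators:
        raise ValueError("at least one comparator is required")
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    comps = [
        c if isinstance(c, Comparator) else Comparator.from_name(c)
        for c in comparators
    ]
    cache = _MoleculeFeatureCache()
    results = []
    plist = pairs.pairs
    for comp in comps:
        if n_threads == 1 or len(plist) < 64:
            metrics = [_pair_value(p, comp, cache) for p in plist]
        else:
            chunk = max(64, -(-len(plist) // (n_threads * 4)))
            spans = [plist[i : i + chunk] for i in range(0, len(plist), chunk)]
            with ThreadPoolExecutor(max_workers=n_threads) as pool:
                parts = pool.map(
                    lambda span: [_pair_value(p, comp, cache) for p in span], spans
                )
                metrics = [m for part in parts for m in part]
        results.append(ComparisonResult(comp, metrics))
    return results


def summarize(result: ComparisonResult) -> str:
    """Plain-text summary: comparator, pair accounting and mean/min/max."""
    lines = [
        f"Comparator: {result.comparator.name} ({result.comparator.mode})",
        f"Pairs evaluated: {len(result.metrics)}",
        f"Valid (defined) pairs: {result.n_valid}",
        f"Failed/undefined pairs: {result.n_failed}",
    ]
    stats = result.stats
    if stats is None:
        lines.append("No defined values; statistics omitted.")
    else:
        lines.append(f"Mean: {stats['mean']:.6g}")
        lines.append(f"Minimum: {stats['min']:.6g}")
        lines.append(f"Maximum: {stats['max']:.6g}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# persistence


@dataclass(frozen=True)
class SavedPair:
    """Lightweight pair info kept in a results file for drill-down listings."""

    index: int
    original_raw: str
    predicted_raw: str
    valid: bool


@dataclass
class ResultsDocument:
    results: list[ComparisonResult]
    pairs: list[SavedPair]
    source_a: str = ""
    source_b: str = ""


class ResultsFormatError(ValueError):
    """Raised on loading a file that is not a compatible results document."""


def save_results(
    results: list[ComparisonResult],
    path: str | Path,
    pairs: Optional[PairedSet] = None,
) -> None:
    """Write a versioned JSON results document (lossless round-trip)."""
    doc = {
        "format": RESULTS_FORMAT,
        "version": RESULTS_VERSION,
        "source_a": pairs.source_a if pairs else "",
        "source_b": pairs.source_b if pairs else "",
        "pairs": [
            {
                "index": p.index,
                "original": p.original.raw,
                "predicted": p.predicted.raw,
                "valid": p.valid,
            }
            for p in (pairs.pairs if pairs else [])
        ],
        "results": [
            {
                "comparator": {"name": r.comparator.name, "mode": r.comparator.mode},
                "metrics": [
                    {"pair_index": m.pair_index, "value": None if not m.defined else m.value,
                     "defined": m.defined}
                    for m in r.metrics
                ],
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_results(path: str | Path) -> ResultsDocument:
    """Load a results document written by :func:`save_results`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ResultsFormatError(f"not a valid results file: {path} ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != RESULTS_FORMAT:
        raise ResultsFormatError(f"not a {RESULTS_FORMAT} document: {path}")
    if doc.get("version") != RESULTS_VERSION:
        raise ResultsFormatError(
            f"unsupported results version {doc.get('version')!r} (expected {RESULTS_VERSION})"
        )
    results = []
    for r in doc["results"]:
        comp = Comparator(r["comparator"]["name"], r["comparator"]["mode"])
        metrics = [
            PairMetric(
                m["pair_index"],
                math.nan if not m["defined"] else float(m["value"]),
                m["defined"],
            )
            for m in r["metrics"]
        ]
        results.append(ComparisonResult(comp, metrics))
    pairs = [
        SavedPair(p["index"], p["original"], p["predicted"], p["valid"])
        for p in doc.get("pairs", [])
    ]
    return ResultsDocument(results, pairs, doc.get("source_a", ""), doc.get("source_b", ""))
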