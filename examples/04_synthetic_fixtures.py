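"""The synthetic paired-set generator and what it guarantees.

Every perturbation operator yields a *different* valid molecule, and
unperturbed predictions are re-spelled (atom-order shuffled) copies, so the
expected fraction of exact matches is exactly 1 - perturbation_rate.  This
script generates runs at three rates and shows the recovered fractions.
"""

import tempfile
from pathlib import Path

from molsetcomp import compare, fixtures, molio

for rate in (0.0, 0.3, 1.0):
    with tempfile.TemporaryDirectory() as tmp:
        a, b = Path(tmp) / "a.smi", Path(tmp) / "b.smi"
        fixtures.generate_paired_sets(
            fixtures.FixtureSpec(n_pairs=1000, perturbation_rate=rate, seed=7),
            a, b,
        )
        pairs = molio.pair_sets(molio.read_set(a), molio.read_set(b))
        (res,) = compare.evaluate(pairs, ["equality"])
        frac = sum(m.value for m in res.metrics) / len(res.metrics)
        print(f"perturbation rate {rate:.1f}: equality fraction {frac:.3f} "
              f"(expected {1 - rate:.1f})")

print("\nThe recovered fraction tracks 1 - rate within binomial noise; at the")
print("extremes (0 and 1) it is exact because the operators are guaranteed to")
print("change, or a re-spelling to preserve, the canonical structure.")
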