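"""Compare two positionally paired molecule sets.

Builds two tiny SMILES files in a temp directory — originals and the
molecules a hypothetical recognition model returned for them — evaluates a
fingerprint similarity and two descriptor differences per pair, and prints
the textual summaries.
"""

import tempfile
from pathlib import Path

from molsetcomp import compare, molio

ORIGINALS = ["CC(=O)Oc1ccccc1C(=O)O", "c1ccncc1", "CCO", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"]
# line i is the prediction for line i above; the 2nd and 3rd are wrong
PREDICTED = ["OC(=O)c1ccccc1OC(C)=O", "c1ccccc1", "CCN", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"]

with tempfile.TemporaryDirectory() as tmp:
    a, b = Path(tmp) / "orig.smi", Path(tmp) / "pred.smi"
    a.write_text("\n".join(ORIGINALS) + "\n")
    b.write_text("\n".join(PREDICTED) + "\n")

    pairs = molio.pair_sets(molio.read_set(a), molio.read_set(b))
    results = compare.evaluate(pairs, ["tanimoto_path", "equality", "atoms_all"])

for res in results:
    print(compare.summarize(res))
    print()

print("Similarity comparators score each original/predicted pair in [0, 1]")
print("(1 = identical bit sets / same molecule); descriptor comparators give")
print("the absolute difference, so 0 means the prediction matched exactly.")
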