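"""Single-molecule descriptors and fingerprint similarities.

Computes a spread of topological descriptors for aspirin and paracetamol
and the four similarity measures between them.
"""

from molsetcomp import descriptors, fingerprints
from molsetcomp.molgraph import parse_smiles

aspirin = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
paracetamol = parse_smiles("CC(=O)Nc1ccc(O)cc1")

names = [
    "atoms_all", "bonds_rotatable", "rings_aromatic", "hba", "hbd",
    "mannhold_logp", "molecular_weight", "wiener_path", "zagreb",
    "eccentric_connectivity", "kappa1", "petitjean", "largest_pi_system",
]
print(f"{'descriptor':26} {'aspirin':>10} {'paracetamol':>12}")
for name in names:
    a = descriptors.compute(aspirin, name)
    p = descriptors.compute(paracetamol, name)
    print(f"{name:26} {a.value:10.3f} {p.value:12.3f}")

print("\nsimilarities between the two molecules:")
print("  path Tanimoto         ",
      fingerprints.tanimoto(fingerprints.path_fingerprint(aspirin),
                            fingerprints.path_fingerprint(paracetamol)))
print("  shortest-path Tanimoto",
      fingerprints.tanimoto(fingerprints.shortest_path_fingerprint(aspirin),
                            fingerprints.shortest_path_fingerprint(paracetamol)))
print("  substructure Tanimoto ",
      fingerprints.tanimoto(fingerprints.substructure_fingerprint(aspirin),
                            fingerprints.substructure_fingerprint(paracetamol)))
print("  LINGO (q=4)           ",
      fingerprints.lingo_similarity(fingerprints.lingo_profile(aspirin),
                                    fingerprints.lingo_profile(paracetamol)))
print("\nEach similarity is |A∩B|/|A∪B| over the respective feature sets;")
print("shared aromatic-ring and carbonyl features keep the values well above 0.")
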