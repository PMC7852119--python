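# Methods

## Problem model

The unit of analysis is the *positional molecule pair*: record *i* of the
original set and record *i* of the predicted set. Pairing is strictly by
file position — there is no identifier matching, no sorting, no
deduplication — because the upstream producers of such files (recognition
and generation models evaluated in batch) emit predictions line-aligned
with their inputs. Everything else follows from protecting that
alignment:

* blank lines become `empty` placeholder records instead of being skipped;
* records that fail to parse become `parse_failed` records;
* a pair is *valid* only if both members parsed, and invalid pairs occupy
  their slot in every metric vector with `defined = false`.

Per-pair scores are either similarities (fingerprint Tanimoto, LINGO,
canonical-form equality; range [0, 1]) or absolute descriptor differences
(range [0, ∞)). Both are symmetric functions of the pair, which gives the
package's set-swap invariance: interchanging the two input files changes
no result.

## Molecular graph conventions

All metrics are functions of a hydrogen-suppressed graph with implicit-H
counts, built on RDKit for lexical parsing, aromaticity perception (RDKit's
default model, applied uniformly at parse time), SSSR ring perception and
canonical SMILES. Choices that matter downstream:

* **"All atoms" means heavy atoms.** An opt-in flag extends the count by
  implicit hydrogens, but no registered comparator uses it.
* **Aromatic bonds** carry an `aromatic` flag and are counted only by the
  aromatic selector, never under single/double.
* **SSSR** uses the non-symmetrized smallest set of smallest rings, so the
  ring count always equals the circuit rank *m − n + c* (the symmetrized
  variant returns an extra ring on symmetric cages such as norbornane,
  which would break ring-count descriptors).
* **Multi-fragment inputs** (dot-disconnected SMILES) are accepted;
  distance-based indices are evaluated on the largest connected fragment,
  and cross-fragment distances are an explicit unreachable sentinel.
* **Molecular weight** uses standard atomic weights summed with `math.fsum`
  over sorted terms. This is not cosmetic: per-molecule values are memoised
  by canonical form, and a left-to-right float sum depends on atom input
  order, which would make results depend on which spelling of a molecule
  was encountered first (and would break set-swap invariance at the
  10⁻¹³ level). Isotope labels are not distinguished.

## Pinned descriptor definitions

The descriptor names in the registry denote families with several
conventions in the literature; one definition per name is frozen here.

| descriptor | definition |
|---|---|
| CnSPm carbon counts | carbons of RDKit hybridisation SPm bonded to exactly n other carbons |
| spiro atoms | atoms shared by two SSSR rings whose intersection is exactly that atom |
| rotatable bonds | non-ring single bonds, both atoms of heavy-degree ≥ 2, amide C–N excluded |
| acidic / basic / HBA / HBD | total unique matches of the bundled SMARTS lists in `data/*.smarts` (carboxylic/sulfonic/sulfinic/phosphonic acids, phenol, aci-nitro, thioacid; aliphatic amines excluding acylated N, amidine, guanidine, pyridine-type N; Lipinski N/O acceptors and N–H/O–H donors) |
| rings_small | SSSR rings of size ≤ 9; `rings_size_k` counts exactly size k |
| Mannhold logP | 1.46 + 0.11·nC − 0.11·nHet (heavy non-carbon atoms) |
| Wiener path number | Σ_{i<j} d(i,j) over the largest fragment |
| Wiener polarity number | number of atom pairs at topological distance 3 |
| Zagreb index | Σ degree² over heavy atoms |
| eccentric connectivity | Σ degree(i)·eccentricity(i) |
| Petitjean number | (diameter − radius)/radius; undefined at radius 0 |
| kappa 1–3 | Kier's shape indices on the hydrogen-suppressed graph: κ₁ = A(A−1)²/P₁², κ₂ = (A−1)(A−2)²/P₂², κ₃ = (A−1)(A−3)²/P₃² for odd A and (A−3)(A−2)²/P₃² for even A, with Pᵢ the count of simple paths of i bonds; undefined when Pᵢ = 0 |
| vertex adjacency | 1 + log₂(m) for m heavy-heavy bonds, 0 when m = 0 |
| SP3 fraction | sp3 carbons / all carbons; undefined with no carbon |
| largest chain | atom count of the longest simple path among non-ring atoms |
| longest aliphatic chain | same, among non-aromatic sp3 carbons |
| largest pi system | same, among atoms with pi electrons (aromatic, or incident to a double/triple bond) |
| equality | 1 if canonical SMILES match, else 0; treated as a similarity |

P₂ and P₃ are computed in closed form (Σ C(d,2); edge-product sum corrected
for triangles) and cross-checked in the tests against brute-force simple-path
enumeration. The longest-simple-path descriptors use exhaustive DFS, which
is exponential in the worst case; induced subsets larger than 60 atoms
yield `defined = false` instead of an unbounded search. Undefined cases in
general are flags, never exceptions, and are excluded from statistics and
histograms but reported as counts.

## Fingerprints

* **Path ("basic") fingerprint**: all linear atom-bond paths of 0–7 bonds
  as canonical strings (element symbols joined by `-`, `=`, `#`, `$`, `:`;
  direction chosen as the lexicographically smaller reading), hashed with
  32-bit FNV-1a modulo 1024 bits. FNV-1a is pinned for cross-platform
  bit-exact reproducibility; there is no folding cascade and there are no
  count bits. This family is behaviour-compatible with classic hashed-path
  fingerprints but intentionally not bit-compatible with any particular
  toolkit.
* **Shortest-path fingerprint**: one string per atom pair — the
  lexicographically smallest canonical string among that pair's shortest
  paths — plus one string per atom; hashed the same way. Cross-fragment
  pairs contribute nothing.
* **Substructure fingerprint**: one bit per SMARTS pattern of the bundled
  functional-group key (`data/substructure.smarts`, 45 patterns), no
  hashing.
* **LINGO**: multiset of 4-grams of the canonical SMILES after replacing
  ring-closure digits outside brackets with `0`; similarity is the multiset
  Tanimoto Σ min / Σ max.

Degenerate conventions: two all-zero fingerprints (or two empty q-gram
profiles) score 1.0 — they are identical objects — while empty vs
non-empty scores 0.0. Zero-length fingerprints (empty pattern list) are a
configuration error at comparison time.

## Histograms

Bins are half-open `[b_i, b_{i+1})` with the last bin closed, so the
maximum is always counted. Defaults: 10 equal-width bins spanning
[min, max] of the defined values; bin labels show the upper border.
Values outside user-set borders are tallied as `n_out_of_range`, never
clamped into edge bins, preserving the conservation identity
Σ counts + n_out_of_range = number of defined values under every border
configuration. An all-equal value vector (routine for equality runs) or a
range too narrow for the float resolution at that magnitude expands to
value ± 0.5 rather than erroring. Percentages are printed to one decimal
in text/CSV output; JSON keeps full precision.

## Synthetic paired sets

The generator emulates a recognition model's output over a 75-molecule
drug-like seed list (bundled). Originals are seed molecules re-spelled by
atom-order shuffling; each prediction is, independently with probability
`perturbation_rate` (default 0.3 — a mid-range error rate that leaves both
histogram tails populated), one random valence-preserving edit: C↔N element
swap, single↔double bond-order change, methyl addition, or terminal-atom
deletion. Every operator changes the molecular formula or bond multiset, so
a perturbed pair is never canonically equal, and unperturbed pairs always
are; hence the exact-match fraction has expectation 1 − rate, which the
recovery tests assert to within three binomial standard errors. Edits that
fail sanitisation are resampled (up to 50 attempts). An `invalid_rate`
option injects malformed SMILES to exercise the failure policies.
Identical specs give byte-identical files.

What the generator does **not** emulate: the error *structure* of any real
recognition system (errors here are local edits, not systematic confusions),
stereochemistry, tautomerism, charge states beyond the seed list, or very
large molecules. Passing tests therefore demonstrate the pipeline's
correctness and invariances, not performance claims about any real model.

## Determinism and parallelism

Per-molecule features are memoised by canonical SMILES; every cached value
is a pure, atom-order-independent function of the molecule, so cache-hit
order cannot affect results. Parallel evaluation chunks the pair list
deterministically and reassembles in order; a thread count changes only
wall-clock time, and saved results are byte-identical for any `--threads`
value. All generator randomness flows from a single integer seed.

## Problem sizes

The test suite exercises runs of up to 10,000 pairs for byte-level
thread-invariance and one 100,000-pair path-fingerprint run as a
throughput/scaling check; oracle comparisons use 200 random molecules of
≤ 12 heavy atoms (exhaustive path enumeration stays trivially cheap there).
The acceptance script uses 2,000-pair runs, enough to pin the recovered
match fraction within ±3 % at three standard errors.

## Known limitations

* No stereochemistry: descriptors and fingerprints see the constitution
  only; enantiomer pairs compare as equal.
* Aromaticity and implicit-H conventions follow RDKit's defaults;
  aromatic-atom/bond counts under other perception models will differ.
* Descriptor values are this package's pinned definitions; they are
  deliberately reproducible rather than numerically interchangeable with
  any other toolkit's same-named descriptors.
* SDF reading accepts V2000/V3000 records with `$$$$` delimiters; SD data
  fields are ignored except the title line (used as the record name).
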