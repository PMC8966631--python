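# Methods

## Problem and approach

Given a black-box predictor f̂ over molecules and a base molecule x with
prediction f̂(x), a *counterfactual explanation* is a molecule x′ that is as
similar as possible to x while receiving a different prediction:

* classification: minimize d(x, x′) subject to f̂(x′) ≠ f̂(x);
* regression: minimize d(x, x′) subject to |f̂(x′) − f̂(x)| ≥ Δ, where Δ is
  the problem-specific minimum change of interest (increases and decreases
  both qualify and are annotated with their sign).

Molecular graphs are discrete, so the optimization cannot follow gradients.
molcf instead *enumerates* a local chemical space around x, evaluates f̂ on
the whole enumeration in a single batch call, applies the counterfactual
condition, and selects a small diverse set of the most similar qualifying
molecules. The predictor is consulted only through its outputs: no
gradients, no weights, no architecture assumptions, which is what makes the
method model-agnostic (a lookup table and an equivalent function produce
identical explanations, and the test suite asserts this bit-for-bit).

## Distance

All similarity in the pipeline is Tanimoto similarity s of ECFP4 fingerprints
(Morgan circular environments of radius 2 = diameter 4), folded to 2048 bits
by default (configurable; 2048 is the conventional folding width and
similarity values are stable well below it). Distance is d = 1 − s. Two
empty fingerprints — structurally possible only for degenerate inputs — are
defined to have similarity 1.0, since they are indistinguishable objects.
Fingerprints are computed with RDKit's Morgan generator; Tanimoto is exact
set arithmetic on the on-bit sets and is property-tested against an
independent oracle.

## SELFIES codec

Chemical-space enumeration relies on SELFIES, a string representation whose
defining property is surjectivity: *every* token string decodes to a valid
molecule, because the decoder derives the graph under per-element valence
caps (a bond that would exceed the remaining valence of either endpoint is
reduced or dropped; branches and rings that cannot form are skipped; a chain
continuing past a saturated atom terminates derivation). Token-level edits
therefore always yield molecules.

The package ships its own codec (`molcf.selfies`), one fixed dialect
(`molcf-selfies-1`) of the SELFIES v2-style grammar:

* atom tokens `[C]`, `[=O]`, `[#N]`, `[O-1]`, `[NH2+1]` (bond prefix,
  element, optional explicit-H count, optional charge);
* branch tokens `[Branch1]`/`[=Branch2]`/…, whose following N tokens are
  read as a base-16 index giving the branch length;
* ring tokens `[Ring1]`/`[=Ring2]`/…, whose index addresses the atom derived
  Q+1 positions earlier.

The valence table covers H, B, C, N, O, F, P, S, Cl, Br, I plus common
charged states; every entry is acceptable to RDKit's sanitizer, so every
derivation is constructible. The encoder walks the kekulized molecular graph
depth-first from atom 0 in neighbor-index order; re-numbering atoms yields a
different, non-canonical spelling of the same molecule, which is how the
sampler gets starting-point diversity. Encoding is self-verifying: the token
string is decoded back and compared by canonical SMILES, first with implicit
hydrogens, then with explicit hydrogen counts on every atom; if neither
round-trips, an `EncodingError` is raised rather than ever emitting a lossy
encoding. Multi-fragment species (salts) and isotope labels are outside the
dialect and rejected at encode time.

One dialect choice matters for alphabet hygiene: the sixteen index tokens
(base-16 digits read after branch/ring tokens) are all drawn from the
restricted element set — digit 15 is `[=O]`, not `[P]`. A token edit can
expose an index digit as an atom token, and that re-interpretation must not
smuggle in an element the mutation alphabet excludes.

## Sampler

The sampler (`molcf.sampler`) perturbs the base molecule's SELFIES:

1. draw a fresh randomized (non-canonical) spelling of the base;
2. apply k token edits, k drawn uniformly from `mutation_counts`
   (default {1, 2}); each edit deletes, replaces, or inserts one token,
   operation, position and token all uniform; deletions never produce the
   empty string;
3. decode, canonicalize, deduplicate by canonical SMILES; the base itself is
   excluded.

Defaults: 3000 samples, edits drawn from {1, 2}, the basic alphabet, an
attempt budget of 10 × `num_samples` raw draws. One or two edits keep the
space local; the similarity mass shifts down as k grows (measured: on a
10-heavy-atom base at 500 samples, median Tanimoto similarity to base falls
from ≈0.17 at k=1 to ≈0.08 at k=5), which is why larger edit counts mostly
waste predictor calls. Small molecules exhaust their 1–2-edit neighborhood;
when the attempt budget runs out the sampler returns what exists with a
warning and diagnostics (draws, rejects, duplicates) rather than failing.
The sampler owns a seeded `random.Random`; no global RNG state is touched.

A note on canonicalization: for a few unusual ring systems RDKit's
aromaticity perception differs between a freshly built molecule and one
re-parsed from its own SMILES output, so the canonical writer is iterated to
a write/parse fixed point before a string is used as a deduplication key.

## Alphabet

The mutation vocabulary is restricted by default to the "basic" alphabet:
neutral atom tokens over B, C, N, O, S, F, Cl, Br, I, the O-minus token, and
the branch/ring structure tokens. Permissive vocabularies mostly propose
counterfactuals by ionizing atoms or inserting exotic elements — valid
molecules, poor explanations. Elements already present in the base persist
through mutations of its spelling; the restriction applies to what mutation
can *introduce*. Custom alphabets load from token-per-line text files; a
`#!dialect` pin in the file is checked against the codec's dialect at load
time and a mismatch is a hard error, because token semantics are not stable
across grammar versions.

## Counterfactual selection

After one batched predictor call over base + candidates:

* candidates are annotated with similarity, output, and the counterfactual
  flag (non-finite regression outputs are discarded with a diagnostic; a
  non-finite *base* prediction is a contract error);
* the counterfactual subset — only that subset, so non-qualifying regions
  cannot dominate the geometry — is clustered with DBSCAN on the Tanimoto
  distance matrix, ε = 0.15 and minimum 5 samples per cluster;
* from each cluster the member most similar to the base is taken
  (ties break on lexicographically smallest canonical SMILES, for
  reproducibility); if there are more representatives than requested, the
  most similar ones are kept (plain truncation, no re-clustering); if fewer,
  DBSCAN noise points top up the list in similarity order — this preserves
  the one-per-cluster diversity intent while never returning fewer
  counterfactuals than the space contains;
* the final list is sorted by similarity, descending.

An empty counterfactual set (e.g. under a constant predictor) is a
legitimate result: the engine returns an empty list plus an advisory
diagnostic suggesting a larger sample or more mutations, and the CLI maps it
to exit status 2, distinct from errors.

## Chemical-space projection

The 2-D map of candidate space is classical multidimensional scaling
(principal coordinates) of the Tanimoto distance matrix: eigen-decomposition
of the double-centered squared-distance matrix, keeping the two leading
axes. Negative eigenvalues (Tanimoto distances are not exactly Euclidean)
are clipped to zero. Axis signs are fixed by making each axis's
largest-magnitude loading positive, so plots are reproducible run to run.
All-identical inputs project to the origin.

## PubChem expansion

As an alternative space source, candidates can come from PubChem's
`fastsimilarity_2d` PUG-REST search (default threshold 90%, 200 records —
artifact defaults, configurable). Hits are re-parsed locally, the query
molecule is excluded, malformed records are skipped with a diagnostic, and
similarity to the base is recomputed locally with ECFP4/Tanimoto so both
space sources share one metric. The HTTP transport is injected
(`url -> text`); the default uses stdlib urllib with exponential-backoff
retries, and the test suite uses canned fixture transports exclusively — a
sentinel transport proves no live call is ever attempted. Responses are
cached on disk keyed by (query, threshold, max_records). Database-derived
counterfactuals are typically less similar to the base than mutation-derived
ones, the price of restricting the space to molecules that exist.

## Fixture predictors

The test predictors are pure structure rules, not trained models: a SMARTS
substructure classifier (default pattern: carboxylic acid), an exact
heavy-atom-count regressor, a Crippen-logP regressor, constant predictors,
and an opaque lookup table keyed by canonical SMILES. Their counterfactual
structure is analytically known — every counterfactual of the acid
classifier must lack the acid group; every counterfactual of the atom-count
regressor must differ in count by at least Δ — so the engine's guarantees
are checked exactly, on every run, without downloads or training. What these
fixtures do *not* emulate: prediction noise, miscalibration near decision
boundaries, and out-of-distribution behavior of real models on mutant
molecules; a passing suite shows the search and selection machinery is
correct, not that any particular trained model's explanations are
chemically meaningful.

## Problem sizes in the checks

The package's standing checks run at desk scale by design: ≥10,000 mutation
draws across 10 diverse bases for the validity and alphabet invariants,
500 samples per edit count for the similarity-trend measurement, 200 random
≤15-point instances for the clustering oracle, and a few hundred samples per
end-to-end explanation. These sizes are far past the point where the binary
properties (validity, condition enforcement, determinism) stabilize.

## Known limitations

* Stereochemistry is dropped at canonicalization; the codec has no stereo
  tokens. Enantiomers collapse to one record.
* Multi-fragment inputs (salts, mixtures) are rejected rather than
  normalized; desalt upstream.
* The valence model is a fixed table; exotic oxidation states outside it
  cannot be encoded (they are still *decoded* safely — the cap just limits
  what mutation can build).
* Validity is valence-validity: the sampler can propose synthetically
  implausible molecules; the PubChem source is the remedy when experimental
  realizability matters.
* MCS-based difference highlighting in reports is an approximation: for
  heavily rearranged counterfactuals the highlighted atom set can overstate
  the change.
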