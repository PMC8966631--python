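# molcf

Model-agnostic counterfactual explanations for molecular property
predictors.

A counterfactual explanation answers the question a feature-attribution
score cannot: *what is the smallest structural change that would flip this
prediction?* Given any black-box model f̂ over molecules — a function from
SMILES strings to labels or real values, with no access to gradients or
internals — molcf finds, for a base molecule x, molecules x′ solving

    minimize d(x, x′)   subject to   f̂(x′) ≠ f̂(x)            (classification)
    minimize d(x, x′)   subject to   |f̂(x′) − f̂(x)| ≥ Δ      (regression)

with d = 1 − Tanimoto similarity of ECFP4 fingerprints. Because molecular
space is discrete, the optimization is solved by enumeration: the local
chemical space around x is expanded by SELFIES token mutation (delete /
replace / insert on randomized spellings, 3000 samples with 1–2 edits by
default) — SELFIES strings always decode to valid molecules, so every mutant
is usable — or, alternatively, by a PubChem 2-D similarity search when only
experimentally known molecules should be proposed. The predictor is called
once with the whole batch; candidates that satisfy the counterfactual
condition are clustered with DBSCAN on the Tanimoto distance matrix
(ε = 0.15, min 5 per cluster) and the most similar member of each cluster is
returned, so the handful of counterfactuals you see is both close to the
base and structurally diverse.

The package ships its own SELFIES codec (valence-capped decoder with the
surjectivity guarantee, self-verifying graph-walk encoder), the mutation
sampler with a restricted "basic" token alphabet (B, C, N, O, S, F, Cl, Br,
I; no charged tokens except O⁻), the counterfactual engine, an offline-
testable PubChem expander, rule-based fixture predictors, and a CLI.
It is aimed at anyone who ships molecular property models — QSAR,
ADMET, activity screening — and needs per-prediction explanations that a
chemist can read as structures rather than weights.

## Worked example

Explain a substructure-rule classifier (label 1 iff the molecule contains a
carboxylic acid) on hydrocinnamic acid:

```python
import molcf
from molcf.fixtures import substructure_classifier

result = molcf.explain(
    "OC(=O)CCc1ccccc1",                      # hydrocinnamic acid
    substructure_classifier(),               # label 1 iff carboxylic acid present
    molcf.SamplerConfig(num_samples=3000, seed=42),
)
print("base:", result.base.record.canonical_smiles, "f =", result.base.output)
for i, c in enumerate(result.counterfactuals, 1):
    print(f"counterfactual {i}: {c.record.canonical_smiles:24s} "
          f"f = {c.output}  similarity = {c.similarity:.3f}")
```

prints

```
base: O=C(O)CCc1ccccc1 f = 1
counterfactual 1: BC(=O)CCc1ccccc1         f = 0  similarity = 0.667
counterfactual 2: CC(=O)CCc1ccccc1         f = 0  similarity = 0.667
counterfactual 3: NC(=O)CCc1ccccc1         f = 0  similarity = 0.667
```

Every counterfactual replaces the acid's hydroxyl — turning it into a
ketone, amide, or acylborane — and flips the label, which reads directly as
"the carboxylic acid is why this molecule is predicted active". Similarity
is Tanimoto on ECFP4; the three are distinct single-token modifications of
the same site, surfaced from different DBSCAN clusters or noise, sorted
best-first. `result.all_candidates` holds the full annotated space (here
3000 candidates, 2056 of them label-flipping) for tables and plots.

The same thing from a shell, plus figures:

```sh
molcf --smiles "OC(=O)CCc1ccccc1" --predictor builtin:carboxylic-acid \
      --seed 42 --out explanation/ --plot
```

writes `candidates.csv`, `counterfactuals.csv`, `run-metadata.json` (enough
to repeat the run bit-identically), a structure grid with the changed atoms
highlighted, and the 2-D chemical-space projection. Any model can be
plugged in as `import:<module>:<attr>` (a `PredictorContract`) or
`exec:<command>` (SMILES on stdin, one output per line). Exit status 2
means "no counterfactual found", distinct from errors. For regression add
`--mode regression --delta 1`. `--source pubchem` swaps the mutation
sampler for the database search.

See `docs/methods.md` for the model, the codec grammar, parameter defaults
and their rationale, and known limitations.

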