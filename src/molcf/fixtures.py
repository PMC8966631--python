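"""Deterministic rule-based predictors and molecule sets for testing.

Real demonstration models (random forests, RNNs, GNNs) need external data
and trained weights; none of that is required to exercise a model-agnostic
explainer.  These predictors are pure functions of molecular structure with
analytically known counterfactual structure — a substructure classifier's
counterfactuals must lack the substructure, a heavy-atom regressor's must
differ in atom count — so every engine guarantee can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

from rdkit import Chem

from .engine import PredictorContract
from .molecules import canonical_smiles

__all__ = [
    "RulePredictor",
    "substructure_classifier",
    "heavy_atom_regressor",
    "logp_regressor",
    "constant_predictor",
    "lookup_predictor",
    "fixture_molecules",
    "pubchem_fixture_response",
    "CARBOXYLIC_ACID",
]

#: SMARTS for a carboxylic acid group (protonated or deprotonated).
CARBOXYLIC_ACID = "[CX3](=O)[OX2H1,OX1-]"


@dataclass(frozen=True)
class RulePredictor(PredictorContract):
    """A named deterministic structure rule satisfying the batch contract."""

    name: str = "rule"


def _batched(fn: Callable[[Chem.Mol], object]) -> Callable[[Sequence[str]], list]:
    def predict(batch: Sequence[str]) -> list:
        out = []
        for smi in batch:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"fixture predictor got invalid SMILES {smi!r}")
            out.append(fn(mol))
        return out
    return predict


def substructure_classifier(smarts_pattern: str = CARBOXYLIC_ACID) -> RulePredictor:
    """Label 1 iff the molecule contains the given substructure."""
    query = Chem.MolFromSmarts(smarts_pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS: {smarts_pattern!r}")
    return RulePredictor(
        predict=_batched(lambda mol: int(mol.HasSubstructMatch(query))),
        mode="classification",
        name=f"substructure[{smarts_pattern}]",
    )


def heavy_atom_regressor() -> RulePredictor:
    """Exact heavy-atom count as a real-valued prediction."""
    return RulePredictor(
        predict=_batched(lambda mol: float(mol.GetNumHeavyAtoms())),
        mode="regression",
        name="heavy_atoms",
    )


def logp_regressor() -> RulePredictor:
    """Crippen logP — a smooth structure-dependent regression target."""
    from rdkit.Chem import Crippen

    return RulePredictor(
        predict=_batched(Crippen.MolLogP),
        mode="regression",
        name="crippen_logp",
    )


def constant_predictor(value, mode: str = "classification") -> RulePredictor:
    """Always the same output; its counterfactual set is provably empty."""
    return RulePredictor(
        predict=lambda batch: [value] * len(batch),
        mode=mode,
        name=f"constant[{value}]",
    )


def lookup_predictor(table: dict[str, object], mode: str = "classification",
                     default=0) -> RulePredictor:
    """An opaque table keyed by canonical SMILES; the black-box probe.

    Inputs are canonicalized before lookup, so any spelling of a tabulated
    molecule hits its entry; unknown molecules get ``default``.
    """
    canon_table = {canonical_smiles(k): v for k, v in table.items()}
    return RulePredictor(
        predict=lambda batch: [canon_table.get(canonical_smiles(s), default)
                               for s in batch],
        mode=mode,
        name="lookup",
    )


def fixture_molecules() -> list[str]:
    """Curated small molecules (acids, esters, amines, aromatics, halides)."""
    text = resources.files("molcf.data").joinpath("fixture_molecules.smi").read_text()
    out = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.append(line.split()[0])
    return out


def pubchem_fixture_response(name: str = "similar_to_benzoic_acid") -> dict:
    """A canned PubChem-style similarity response (synthetic, stored in-repo)."""
    text = resources.files("molcf.data").joinpath("pubchem_fixture.json").read_text()
    return json.loads(text)[name]
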