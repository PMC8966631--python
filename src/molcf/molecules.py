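"""Molecule representations, ECFP4 fingerprints and Tanimoto similarity.

Everything downstream — sampling, the counterfactual condition, clustering —
measures chemical distance the same way: Tanimoto similarity of ECFP4
(Morgan radius-2) fingerprints, and distance ``d = 1 - s``.  This module owns
that metric plus the canonical forms that make deduplication stable: one
canonical-SMILES writer (RDKit's, non-isomeric) is used for the whole run so
two spellings of one molecule always collapse to the same key.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from . import selfies as sf

__all__ = [
    "InvalidSmilesError",
    "Fingerprint",
    "MoleculeRecord",
    "parse_molecule",
    "canonical_smiles",
    "ecfp4_fingerprint",
    "tanimoto",
    "distance",
    "randomized_selfies",
    "CANONICALIZER",
]

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors surface as exceptions

#: Canonical-SMILES writer identity, recorded in run metadata so output files
#: can be reproduced against the same dialect.
CANONICALIZER = f"rdkit-{Chem.rdBase.rdkitVersion}-nonisomeric"

_DEFAULT_NBITS = 2048


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


@dataclass(frozen=True)
class Fingerprint:
    """A folded binary fingerprint, stored as the set of on bits."""

    bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit index out of range")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule in all the representations the pipeline needs."""

    input_smiles: str
    canonical_smiles: str
    selfies: str
    fingerprint: Fingerprint

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def _stable_canonical(mol: Chem.Mol) -> tuple[str, Chem.Mol]:
    """Canonical SMILES iterated to a write/parse fixed point.

    For a few unusual ring systems RDKit's aromaticity perception differs
    between a freshly built molecule and one re-parsed from its own output;
    one or two extra round trips converge, and a stable string is what makes
    deduplication keys trustworthy.
    """
    smiles = Chem.MolToSmiles(mol, isomericSmiles=False)
    for _ in range(4):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - writer output should re-parse
            raise InvalidSmilesError(f"canonical SMILES failed to re-parse: {smiles!r}")
        again = Chem.MolToSmiles(mol, isomericSmiles=False)
        if again == smiles:
            return smiles, mol
        smiles = again
    return smiles, mol  # pragma: no cover - convergence beyond 4 unheard of


def canonical_smiles(smiles: str) -> str:
    """Canonical (non-isomeric) SMILES under the run's single writer."""
    return _stable_canonical(_mol_from_smiles(smiles))[0]


def ecfp4_fingerprint(mol: Chem.Mol | MoleculeRecord, n_bits: int = _DEFAULT_NBITS) -> Fingerprint:
    """ECFP4 fingerprint: circular atom environments of radius 2 (diameter 4),
    folded to ``n_bits``.

    Deterministic: the same canonical structure always yields the same bits.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be at least 64")
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol
    gen = _fp_generator(n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


_GENERATORS: dict[int, object] = {}


def _fp_generator(n_bits: int):
    gen = _GENERATORS.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        _GENERATORS[n_bits] = gen
    return gen


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a ∩ b| / |a ∪ b| on fingerprint bits.

    Two empty fingerprints are identical objects and score 1.0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto distance ``d = 1 - s``; the clustering metric."""
    return 1.0 - tanimoto(a, b)


def parse_molecule(smiles: str, n_bits: int = _DEFAULT_NBITS) -> MoleculeRecord:
    """Parse a SMILES string into a fully populated :class:`MoleculeRecord`.

    Raises
    ------
    InvalidSmilesError
        if the SMILES does not parse.
    selfies.EncodingError
        if the molecule parses but cannot be written in the SELFIES dialect
        (multi-fragment inputs, exotic valences).
    """
    # SELFIES and fingerprint are computed on the canonical, stereo-stripped
    # structure so all representations describe the same object
    canonical, mol = _stable_canonical(_mol_from_smiles(smiles))
    selfies_str = sf.encode(mol)
    return MoleculeRecord(
        input_smiles=smiles,
        canonical_smiles=canonical,
        selfies=selfies_str,
        fingerprint=ecfp4_fingerprint(mol, n_bits),
    )


def record_from_mol(mol: Chem.Mol, input_smiles: str | None = None,
                    n_bits: int = _DEFAULT_NBITS) -> MoleculeRecord:
    """Build a record from an already-parsed molecule (internal fast path)."""
    canonical, cmol = _stable_canonical(mol)
    return MoleculeRecord(
        input_smiles=input_smiles if input_smiles is not None else canonical,
        canonical_smiles=canonical,
        selfies=sf.encode(cmol),
        fingerprint=ecfp4_fingerprint(cmol, n_bits),
    )


def randomized_selfies(record: MoleculeRecord, n: int,
                       rng: random.Random | int | None = None) -> list[str]:
    """``n`` non-canonical SELFIES spellings of one molecule.

    Each spelling encodes the molecule under a random atom renumbering, so the
    token sequence starts from a different atom and walks the graph in a
    different order; every spelling decodes back to ``canonical_smiles``.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(n):
        perm = list(range(n_atoms))
        rng.shuffle(perm)
        out.append(sf.encode(Chem.RenumberAtoms(mol, perm)))
    return out
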