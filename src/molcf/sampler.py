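"""Local chemical-space enumeration by SELFIES token mutation.

The sampler perturbs a base molecule's SELFIES string — token deletion,
replacement, or insertion, each position and token drawn uniformly — and
relies on the codec's surjectivity so that every mutant decodes to a valid
molecule.  Starting diversity comes from mutating a fresh non-canonical
SELFIES spelling of the base for every draw: the same edit applied to
different spellings reaches different neighborhoods.

With one or two token edits most mutants stay close to the base (Tanimoto
similarity well above 0.5); the similarity mass shifts downward as the edit
count grows, which is why ``mutation_counts={1, 2}`` is the default.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

from rdkit import Chem

from . import selfies as sf
from .alphabet import Alphabet, basic_alphabet
from .molecules import MoleculeRecord, record_from_mol

__all__ = ["SamplerConfig", "SampleDiagnostics", "mutate_once", "mutate_k", "expand_space"]

_OPS = ("delete", "replace", "insert")


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of the chemical-space expansion.

    num_samples
        Target number of unique candidate molecules (default 3000 — large
        enough to populate clusters, small enough that one batched model
        call stays cheap).
    mutation_counts
        Edit counts to draw from, uniformly per candidate; {1, 2} keeps the
        space local.
    alphabet
        Token vocabulary for replacement/insertion; the restricted basic
        alphabet by default.
    seed
        Seed of the sampler-owned RNG; no global state is touched.
    max_attempts_factor
        Budget of raw draws per requested sample before giving up on filling
        ``num_samples`` (small molecules exhaust their 1–2 edit neighborhood).
    """

    num_samples: int = 3000
    mutation_counts: frozenset[int] = frozenset({1, 2})
    alphabet: Alphabet = field(default_factory=basic_alphabet)
    seed: int = 0
    max_attempts_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")
        counts = frozenset(int(k) for k in self.mutation_counts)
        if not counts or min(counts) < 1:
            raise ValueError("mutation counts must be positive")
        object.__setattr__(self, "mutation_counts", counts)
        if self.max_attempts_factor <= 0:
            raise ValueError("max_attempts_factor must be positive")


@dataclass
class SampleDiagnostics:
    """Bookkeeping of one expansion run, exposed for logging."""

    draws: int = 0
    rejected: int = 0      # mutants that decoded to nothing usable
    duplicates: int = 0    # mutants collapsing onto an already-seen molecule
    exhausted: bool = False  # attempt budget hit before num_samples reached


def mutate_once(tokens: list[str], alphabet: Alphabet,
                rng: random.Random) -> list[str]:
    """Apply one uniformly chosen token edit (delete / replace / insert).

    The empty string is never produced: a deletion scheduled on a single-token
    sequence resamples the operation.  Validity of the result is the decoder's
    concern, not the mutator's.
    """
    if not tokens:
        raise ValueError("cannot mutate an empty token sequence")
    vocab = alphabet.ordered()
    while True:
        op = rng.choice(_OPS)
        if op == "delete":
            if len(tokens) == 1:
                continue  # never emit an empty string
            pos = rng.randrange(len(tokens))
            return tokens[:pos] + tokens[pos + 1:]
        if op == "replace":
            pos = rng.randrange(len(tokens))
            return tokens[:pos] + [rng.choice(vocab)] + tokens[pos + 1:]
        pos = rng.randrange(len(tokens) + 1)
        return tokens[:pos] + [rng.choice(vocab)] + tokens[pos:]


def mutate_k(tokens: list[str], alphabet: Alphabet, k: int,
             rng: random.Random) -> list[str]:
    """``k`` successive single-token edits (``k >= 1``)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for _ in range(k):
        tokens = mutate_once(tokens, alphabet, rng)
    return tokens


def expand_space(base: MoleculeRecord, config: SamplerConfig | None = None,
                 ) -> tuple[list[MoleculeRecord], SampleDiagnostics]:
    """Enumerate up to ``num_samples`` unique molecules around ``base``.

    Each draw encodes the base under a fresh random atom ordering, applies
    ``k`` token edits with ``k`` drawn from ``mutation_counts``, decodes, and
    canonicalizes.  Results are deduplicated by canonical SMILES and the base
    itself is excluded.  Deterministic under a fixed seed.
    """
    if config is None:
        config = SamplerConfig()
    rng = random.Random(config.seed)
    counts = sorted(config.mutation_counts)
    diag = SampleDiagnostics()
    seen: set[str] = {base.canonical_smiles}
    out: list[MoleculeRecord] = []
    n_bits = base.fingerprint.n_bits
    base_mol = Chem.MolFromSmiles(base.canonical_smiles)
    n_atoms = base_mol.GetNumAtoms()
    max_attempts = int(config.max_attempts_factor * config.num_samples)

    while len(out) < config.num_samples and diag.draws < max_attempts:
        diag.draws += 1
        perm = list(range(n_atoms))
        rng.shuffle(perm)
        try:
            spelling = sf.encode(Chem.RenumberAtoms(base_mol, perm))
        except sf.EncodingError:  # pragma: no cover - base already encoded once
            diag.rejected += 1
            continue
        k = counts[0] if len(counts) == 1 else rng.choice(counts)
        mutant = mutate_k(sf.tokenize(spelling), config.alphabet, k, rng)
        mol = _decode_mutant(mutant)
        if mol is None:
            diag.rejected += 1
            continue
        canonical = Chem.MolToSmiles(mol, isomericSmiles=False)
        if canonical in seen:
            diag.duplicates += 1
            continue
        try:
            record = record_from_mol(mol, n_bits=n_bits)
        except sf.EncodingError:
            # guards against decode->re-encode edge cases; counted, never raised
            diag.rejected += 1
            continue
        seen.add(canonical)
        if record.canonical_smiles != canonical:
            # canonicalization needed extra write/parse rounds to converge;
            # dedup on the converged key as well
            if record.canonical_smiles in seen:
                diag.duplicates += 1
                continue
            seen.add(record.canonical_smiles)
        out.append(record)

    if len(out) < config.num_samples:
        diag.exhausted = True
        warnings.warn(
            f"chemical space exhausted: {len(out)} unique molecules after "
            f"{diag.draws} draws (requested {config.num_samples})",
            stacklevel=2,
        )
    return out, diag


def _decode_mutant(tokens: list[str]) -> Chem.Mol | None:
    """Decode a mutant token list, treating empty derivations as rejects."""
    try:
        mol = sf.decode("".join(tokens))
    except sf.TokenError:  # pragma: no cover - mutations preserve token syntax
        return None
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return mol
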