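"""SELFIES codec: a robust string representation of molecular graphs.

SELFIES (SELF-referencIng Embedded Strings) encode a molecule as a sequence
of bracketed tokens.  Their defining property is *surjectivity*: every token
sequence over the grammar decodes to a chemically valid molecule, because the
decoder derives the graph under per-element valence caps — a bond that would
exceed an atom's remaining valence is reduced or dropped rather than emitted.
Token-level edits (delete / replace / insert) therefore always yield valid
molecules, which is what makes string mutation a usable chemical-space
enumeration move.

Grammar implemented here (one dialect, recorded as :data:`DIALECT`):

* atom tokens ``[C]``, ``[=O]``, ``[#N]``, ``[O-1]``, ``[NH2+1]`` — an
  optional bond prefix (``=`` double, ``#`` triple), an element symbol, an
  optional explicit hydrogen count, an optional formal charge;
* branch tokens ``[Branch1]``, ``[=Branch2]`` ... — the next *N* tokens
  (N = 1, 2 or 3) are read as a base-16 index giving *Q*; the following
  ``Q + 1`` tokens form a branch attached to the current atom, connected with
  the bond order of the branch prefix;
* ring tokens ``[Ring1]``, ``[=Ring2]`` ... — *N* index tokens give *Q*; a
  ring bond is formed between the current atom and the atom derived ``Q + 1``
  positions earlier.

Decoding never raises on grammatically well-formed tokens: impossible
branches and rings are skipped, over-valent bonds are capped, and a trailing
chain on a saturated atom terminates derivation.  A token string deriving no
atoms at all decodes to ``None`` (the empty molecule).

Encoding walks the kekulized molecular graph depth-first and emits the token
sequence; it verifies its own output by decoding it back and comparing
canonical SMILES, so an encoding that the dialect cannot represent raises
:class:`EncodingError` instead of silently corrupting the molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem

__all__ = [
    "DIALECT",
    "DecodedAtom",
    "EncodingError",
    "TokenError",
    "tokenize",
    "parse_token",
    "decode",
    "decode_to_smiles",
    "encode",
    "encode_smiles",
    "semantic_alphabet",
]

#: Name of the token dialect; alphabet files record it so that a vocabulary
#: built against a different grammar is rejected at load time.
DIALECT = "molcf-selfies-1"

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(
    r"^(?P<bond>[=#]?)"
    r"(?P<elem>[A-Z][a-z]?)"
    r"(?:H(?P<hcount>\d+))?"
    r"(?:(?P<sign>[+-])(?P<charge>\d+))?$"
)
_BRANCH_RE = re.compile(r"^(?P<bond>[=#]?)Branch(?P<n>[123])$")
_RING_RE = re.compile(r"^(?P<bond>[=#]?)Ring(?P<n>[123])$")

_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Maximum total valence (bonds + hydrogens) the decoder grants an atom.
# Neutral entries follow the common organic-subset caps; charged entries are
# the usual isoelectronic adjustments.  Values must be acceptable to RDKit's
# sanitizer so that every derivation is a constructible molecule.
_VALENCE: dict[tuple[str, int], int] = {
    ("H", 0): 1,
    ("B", 0): 3,
    ("C", 0): 4,
    ("N", 0): 3,
    ("O", 0): 2,
    ("F", 0): 1,
    ("P", 0): 5,
    ("S", 0): 6,
    ("Cl", 0): 1,
    ("Br", 0): 1,
    ("I", 0): 1,
    ("B", -1): 4,
    ("C", 1): 3,
    ("C", -1): 3,
    ("N", 1): 4,
    ("N", -1): 2,
    ("O", 1): 3,
    ("O", -1): 1,
    ("S", 1): 3,
    ("S", -1): 1,
    ("P", 1): 4,
}

# Index interpretation of tokens when they follow a Branch/Ring token; any
# token absent from this table counts as 0.  Sixteen symbols give base-16
# digits, most significant first.  All sixteen are drawn from the restricted
# element set on purpose: token edits can expose an index digit as an atom
# token, and that re-interpretation must never smuggle in an element the
# mutation alphabet excludes.
_INDEX_OF_TOKEN = {
    "[C]": 0,
    "[Ring1]": 1,
    "[Ring2]": 2,
    "[Branch1]": 3,
    "[=Branch1]": 4,
    "[#Branch1]": 5,
    "[Branch2]": 6,
    "[=Branch2]": 7,
    "[#Branch2]": 8,
    "[O]": 9,
    "[N]": 10,
    "[=N]": 11,
    "[=C]": 12,
    "[#C]": 13,
    "[S]": 14,
    "[=O]": 15,
}
_TOKEN_OF_INDEX = {v: k for k, v in _INDEX_OF_TOKEN.items()}

_PERIODIC = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "W", "Pt", "Au", "Hg", "Tl", "Pb",
    "Bi",
}


class TokenError(ValueError):
    """A string is not a well-formed token of this dialect."""


class EncodingError(ValueError):
    """A molecule cannot be represented in this dialect."""


@dataclass(frozen=True)
class _Atom:
    element: str
    hcount: int | None  # None -> hydrogens implicit
    charge: int
    bond: int  # order of the bond attaching this atom to its predecessor


@dataclass(frozen=True)
class _Branch:
    bond: int
    n_index: int


@dataclass(frozen=True)
class _Ring:
    bond: int
    n_index: int


#: Public alias used by callers inspecting parsed tokens.
DecodedAtom = _Atom


def tokenize(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracketed tokens.

    Raises :class:`TokenError` if any character falls outside a token.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise TokenError(f"not a well-formed SELFIES string: {selfies!r}")
    return tokens


def parse_token(token: str):
    """Parse one token into an atom / branch / ring descriptor."""
    if not (token.startswith("[") and token.endswith("]")):
        raise TokenError(f"not a bracketed token: {token!r}")
    body = token[1:-1]
    m = _BRANCH_RE.match(body)
    if m:
        return _Branch(_BOND_ORDER[m.group("bond")], int(m.group("n")))
    m = _RING_RE.match(body)
    if m:
        return _Ring(_BOND_ORDER[m.group("bond")], int(m.group("n")))
    m = _ATOM_RE.match(body)
    if m and m.group("elem") in _PERIODIC:
        charge = 0
        if m.group("sign"):
            charge = int(m.group("charge"))
            if m.group("sign") == "-":
                charge = -charge
        hcount = m.group("hcount")
        return _Atom(
            element=m.group("elem"),
            hcount=int(hcount) if hcount is not None else None,
            charge=charge,
            bond=_BOND_ORDER[m.group("bond")],
        )
    raise TokenError(f"unrecognized token: {token!r}")


def _max_valence(element: str, charge: int) -> int:
    try:
        return _VALENCE[(element, charge)]
    except KeyError:
        base = _VALENCE.get((element, 0), 8)
        return max(1, base - abs(charge))


class _Derivation:
    """State machine building a molecular graph from a token stream."""

    def __init__(self) -> None:
        self.atoms: list[_Atom] = []
        self.caps: list[int] = []
        self.bonds: dict[tuple[int, int], int] = {}

    def _add_bond(self, i: int, j: int, order: int) -> None:
        self.bonds[(min(i, j), max(i, j))] = order
        self.caps[i] -= order
        self.caps[j] -= order

    def _read_index(self, tokens: list[str], pos: int, n: int) -> tuple[int, int]:
        q = 0
        for _ in range(n):
            digit = 0
            if pos < len(tokens):
                digit = _INDEX_OF_TOKEN.get(tokens[pos], 0)
                pos += 1
            q = q * 16 + digit
        return q, pos

    def derive(self, tokens: list[str], lo: int, hi: int,
               prev: int | None, init_bond: int | None) -> None:
        """Derive tokens[lo:hi] as a chain attached to atom ``prev``.

        ``init_bond`` overrides the first atom's bond prefix (branch entry).
        """
        pos = lo
        first = True
        while pos < hi:
            tok = tokens[pos]
            pos += 1
            desc = parse_token(tok)
            if isinstance(desc, _Atom):
                cap = _max_valence(desc.element, desc.charge)
                hcount = desc.hcount
                if hcount is not None:
                    hcount = min(hcount, cap)
                    cap -= hcount
                    desc = _Atom(desc.element, hcount, desc.charge, desc.bond)
                if prev is None:
                    self.atoms.append(desc)
                    self.caps.append(cap)
                    prev = len(self.atoms) - 1
                else:
                    if self.caps[prev] <= 0:
                        return  # saturated: chain terminates, rest ignored
                    want = init_bond if (first and init_bond is not None) else desc.bond
                    order = min(want, self.caps[prev], cap)
                    if order <= 0:
                        return  # new atom cannot bond (e.g. fully H-capped)
                    self.atoms.append(desc)
                    self.caps.append(cap)
                    idx = len(self.atoms) - 1
                    self._add_bond(prev, idx, order)
                    prev = idx
                first = False
            elif isinstance(desc, _Branch):
                q, pos = self._read_index(tokens, pos, desc.n_index)
                blo, bhi = pos, min(pos + q + 1, hi)
                pos = pos + q + 1
                # a branch needs >=2 free valences: one for itself, one so
                # the main chain can continue (mirrors the reference grammar,
                # where branches in states X0/X1 are ignored)
                if prev is not None and self.caps[prev] >= 2 and blo < bhi:
                    self.derive(tokens, blo, bhi, prev, desc.bond)
                first = False
            elif isinstance(desc, _Ring):
                q, pos = self._read_index(tokens, pos, desc.n_index)
                if prev is not None:
                    target = max(0, prev - (q + 1))
                    key = (min(prev, target), max(prev, target))
                    if target != prev and key not in self.bonds:
                        order = min(desc.bond, self.caps[prev], self.caps[target])
                        if order > 0:
                            self._add_bond(prev, target, order)
                first = False

    def to_mol(self) -> Chem.Mol | None:
        if not self.atoms:
            return None
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.charge)
            if atom.hcount is not None:
                a.SetNumExplicitHs(atom.hcount)
                a.SetNoImplicit(True)
            rw.AddAtom(a)
        for (i, j), order in self.bonds.items():
            rw.AddBond(i, j, _RDKIT_BOND[order])
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - valence caps should prevent this
            return None
        return mol


def decode(selfies: str) -> Chem.Mol | None:
    """Decode a SELFIES string into an RDKit molecule.

    Returns ``None`` only for the empty derivation (no atom token ever
    executes); every other well-formed token string yields a valid molecule.
    """
    tokens = tokenize(selfies)
    d = _Derivation()
    d.derive(tokens, 0, len(tokens), None, None)
    return d.to_mol()


def decode_to_smiles(selfies: str) -> str | None:
    """Decode to a canonical SMILES string (``None`` for empty derivation)."""
    mol = decode(selfies)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _index_tokens(q: int) -> list[str]:
    digits = []
    while True:
        digits.append(q % 16)
        q //= 16
        if q == 0:
            break
    if len(digits) > 3:
        raise EncodingError("branch/ring index exceeds 3 base-16 digits")
    return [_TOKEN_OF_INDEX[d] for d in reversed(digits)]


def _atom_token(atom: Chem.Atom, bond_order: int, explicit_h: bool) -> str:
    if atom.GetIsotope():
        raise EncodingError("isotope labels are not representable")
    elem = atom.GetSymbol()
    body = _BOND_PREFIX[bond_order] + elem
    if explicit_h or atom.GetNoImplicit() or atom.GetFormalCharge() != 0:
        body += f"H{atom.GetTotalNumHs()}"
    q = atom.GetFormalCharge()
    if q != 0:
        body += f"{'+' if q > 0 else '-'}{abs(q)}"
    return f"[{body}]"


class _Encoder:
    def __init__(self, mol: Chem.Mol, explicit_h: bool) -> None:
        self.mol = mol
        self.explicit_h = explicit_h
        self.pos: dict[int, int] = {}
        self.counter = 0
        self.closed: set[tuple[int, int]] = set()

    def _bond_order(self, a: int, b: int) -> int:
        bond = self.mol.GetBondBetweenAtoms(a, b)
        order = int(bond.GetBondTypeAsDouble())
        if order not in (1, 2, 3):
            raise EncodingError(f"unsupported bond order {bond.GetBondType()}")
        return order

    def walk(self, idx: int, parent: int | None, bond_order: int) -> list[str]:
        atom = self.mol.GetAtomWithIdx(idx)
        tokens = [_atom_token(atom, bond_order, self.explicit_h)]
        self.pos[idx] = self.counter
        self.counter += 1
        nbrs = sorted(n.GetIdx() for n in atom.GetNeighbors())
        # ring closures: back edges to already-placed atoms
        for n in nbrs:
            if n == parent or n not in self.pos:
                continue
            key = (min(idx, n), max(idx, n))
            if key in self.closed:
                continue
            self.closed.add(key)
            q = self.pos[idx] - self.pos[n] - 1
            ring_idx = _index_tokens(q)
            tokens.append(f"[{_BOND_PREFIX[self._bond_order(idx, n)]}Ring{len(ring_idx)}]")
            tokens.extend(ring_idx)
        # children are re-checked every iteration: a branch recursion may have
        # reached a sibling through a ring, turning it into a closed back edge
        while True:
            children = [n for n in nbrs if n not in self.pos]
            if not children:
                return tokens
            child = children[0]
            order = self._bond_order(idx, child)
            if len(children) > 1:
                payload = self.walk(child, idx, 1)
                branch_idx = _index_tokens(len(payload) - 1)
                tokens.append(f"[{_BOND_PREFIX[order]}Branch{len(branch_idx)}]")
                tokens.extend(branch_idx)
                tokens.extend(payload)
            else:
                tokens.extend(self.walk(child, idx, order))
                return tokens


def _kekulized(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def encode(mol: Chem.Mol) -> str:
    """Encode an RDKit molecule as a SELFIES string.

    The atom walk starts at atom index 0 and follows ascending neighbor
    indices, so the token sequence follows the molecule's atom numbering:
    renumbering the atoms yields a different (non-canonical) spelling of the
    same molecule.  The output is decoded back and compared by canonical
    SMILES; a mismatch raises :class:`EncodingError`.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise EncodingError("cannot encode an empty molecule")
    kek = _kekulized(mol)
    if len(Chem.GetMolFrags(kek)) > 1:
        raise EncodingError("multi-fragment molecules are not representable")
    reference = Chem.MolToSmiles(mol)
    for explicit_h in (False, True):
        enc = _Encoder(kek, explicit_h)
        selfies = "".join(enc.walk(0, None, 1))
        if decode_to_smiles(selfies) == reference:
            return selfies
    raise EncodingError(f"molecule {reference!r} is outside the dialect's valence model")


def encode_smiles(smiles: str) -> str:
    """Encode a SMILES string (convenience wrapper around :func:`encode`)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparseable SMILES: {smiles!r}")
    return encode(mol)


def semantic_alphabet() -> set[str]:
    """All atom, branch and ring tokens of the neutral organic-subset grammar.

    This is the unrestricted vocabulary; :mod:`molcf.alphabet` filters it to
    the recommended "basic" set.
    """
    tokens: set[str] = set()
    for (elem, charge), valence in _VALENCE.items():
        if elem == "H":
            continue
        suffix = "" if charge == 0 else f"{'+' if charge > 0 else '-'}{abs(charge)}"
        for order in range(1, min(3, valence) + 1):
            tokens.add(f"[{_BOND_PREFIX[order]}{elem}{suffix}]")
    for n in (1, 2):
        for prefix in ("", "=", "#"):
            tokens.add(f"[{prefix}Branch{n}]")
            tokens.add(f"[{prefix}Ring{n}]")
    return tokens
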