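"""Mutation alphabets: the token vocabularies available to the sampler.

The recommended "basic" alphabet restricts insertion/replacement tokens to
the elements B, C, N, O, S, F, Cl, Br and I and removes every charged atom
token except O-minus.  A permissive vocabulary mostly proposes counterfactuals
by ionizing atoms or swapping in exotic elements — changes that are valid
molecules but poor explanations — so a small, chemically plain token set is
the default.

Custom alphabets are plain text files, one token per line, ``#`` comments
allowed.  The first comment may carry a dialect pin
(``#!dialect molcf-selfies-1``); a file built against a different grammar
version is rejected at load time rather than silently re-interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import selfies as sf

__all__ = ["Alphabet", "basic_alphabet", "load_alphabet"]

BASIC_ELEMENTS = frozenset({"B", "C", "N", "O", "S", "F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class Alphabet:
    """A named, validated set of SELFIES tokens usable in mutations."""

    name: str
    tokens: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("alphabet must contain at least one token")
        for tok in self.tokens:
            sf.parse_token(tok)  # raises TokenError on junk

    def ordered(self) -> list[str]:
        """Tokens in sorted order, for reproducible uniform draws."""
        return sorted(self.tokens)


def _is_basic(token: str) -> bool:
    desc = sf.parse_token(token)
    if not isinstance(desc, sf.DecodedAtom):
        return True  # branch/ring structure tokens carry no chemistry
    if desc.element not in BASIC_ELEMENTS:
        return False
    if desc.charge == 0:
        return True
    return desc.element == "O" and desc.charge == -1


def basic_alphabet() -> Alphabet:
    """The recommended restricted alphabet (neutral B/C/N/O/S/F/Cl/Br/I + O-)."""
    tokens = {t for t in sf.semantic_alphabet() if _is_basic(t)}
    tokens.add("[O-1]")
    return Alphabet(name="basic", tokens=frozenset(tokens))


def load_alphabet(path: str | Path, name: str | None = None) -> Alphabet:
    """Load a custom alphabet from a token-per-line text file."""
    path = Path(path)
    tokens: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#!dialect"):
            pinned = line.split(None, 1)[1].strip()
            if pinned != sf.DIALECT:
                raise ValueError(
                    f"{path}: alphabet built for dialect {pinned!r}, "
                    f"this codec is {sf.DIALECT!r}"
                )
            continue
        if not line or line.startswith("#"):
            continue
        try:
            sf.parse_token(line)
        except sf.TokenError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        tokens.add(line)
    if not tokens:
        raise ValueError(f"{path}: no tokens found")
    return Alphabet(name=name or f"custom:{path.name}", tokens=frozenset(tokens))
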