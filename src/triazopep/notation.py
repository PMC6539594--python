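"""Parser and printer for the branched triazolopeptide sequence notation.

Sequences read N→C, residues separated by hyphens, except that no hyphen
follows a triazole unit (``Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg``).  A
parenthesised segment is a single-residue branch acylating the preceding
residue's side-chain amine; ``D-`` marks D-configuration and ``Fmoc-``
an Fmoc-capped backbone amine.  ASCII spellings ``Psi[Trl]`` and a bare
``[Trl]`` suffix are accepted on ``Gly``; printed tables occasionally
double the closing bracket, so runs of ``]`` collapse to one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .blocks import REGISTRY, TRIAZOLE_UNIT, get_block

__all__ = ["Token", "CompoundSequence", "ParseError", "StructureError",
           "parse_sequence", "canonical_string"]


class ParseError(ValueError):
    """Raised when a sequence string cannot be tokenized."""


class StructureError(ValueError):
    """Raised when a sequence tokenizes but violates the chemistry rules."""


@dataclass(frozen=True)
class Token:
    """One building block of a sequence.

    ``stereo`` is "D" when a ``D-`` prefix is present, "L" for an
    unprefixed alpha amino acid and "n/a" for blocks without a
    stereocenter.  Stereo flags and caps never change the elemental
    composition.
    """

    name: str
    stereo: str = "L"
    cap: Optional[str] = None
    branch: Optional["Token"] = None

    def __post_init__(self) -> None:
        block = get_block(self.name)
        default = "L" if block.kind == "alpha_amino_acid" else "n/a"
        if block.kind != "alpha_amino_acid" and self.stereo == "L":
            object.__setattr__(self, "stereo", default)

    @property
    def kind(self) -> str:
        return get_block(self.name).kind


@dataclass(frozen=True)
class CompoundSequence:
    tokens: Tuple[Token, ...]
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.tokens:
            raise StructureError("empty sequence")
        if self.tokens[0].kind == "triazole_unit":
            raise StructureError(
                "a triazole unit cannot open the chain: its backbone amide "
                "nitrogen must be acylated by a preceding residue")
        for tok in self.tokens:
            if tok.branch is not None:
                if get_block(tok.name).side_attach is None:
                    raise StructureError(
                        f"{tok.name} has no side-chain amine to carry the "
                        f"branch {tok.branch.name}")
                if tok.branch.branch is not None:
                    raise StructureError(
                        "nested branches are not part of the grammar")

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return canonical_string(self)


_STEREO_RE = re.compile(r"D-")
_CAP_RE = re.compile(r"Fmoc-")
# longest codes first so e.g. "Gly" does not shadow nothing and "Har" is safe
_CODES = sorted((name for name in REGISTRY if REGISTRY[name].kind != "cap"
                 and name != TRIAZOLE_UNIT), key=len, reverse=True)
_CODE_RE = re.compile("|".join(re.escape(c) for c in _CODES))
_TRL_SUFFIX_RE = re.compile(r"(?:Ψ\[Trl|Psi\[Trl|\[Trl)\]+")


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def eof(self) -> bool:
        return self.pos >= len(self.text)

    def peek(self, s: str) -> bool:
        return self.text.startswith(s, self.pos)

    def take(self, pattern: re.Pattern) -> Optional[str]:
        m = pattern.match(self.text, self.pos)
        if m is None:
            return None
        self.pos = m.end()
        return m.group(0)

    def expect(self, s: str) -> None:
        if not self.peek(s):
            raise ParseError(
                f"expected {s!r} at position {self.pos} in {self.text!r}")
        self.pos += len(s)

    def fail(self, why: str) -> None:
        raise ParseError(f"{why} at position {self.pos} in {self.text!r}")


def _scan_token(sc: _Scanner, allow_branch: bool) -> Token:
    cap = None
    stereo = "L"
    # cap and stereo prefixes in either order
    for _ in range(2):
        if sc.take(_CAP_RE):
            cap = "Fmoc"
        elif sc.take(_STEREO_RE):
            stereo = "D"
    code = sc.take(_CODE_RE)
    if code is None:
        tail = sc.text[sc.pos:sc.pos + 12]
        raise ParseError(
            f"unknown residue code starting at {tail!r} "
            f"(position {sc.pos} in {sc.text!r})")
    name = code
    if code == "Gly" and sc.take(_TRL_SUFFIX_RE):
        name = TRIAZOLE_UNIT
    branch = None
    if sc.peek("("):
        if not allow_branch:
            sc.fail("nested branch is not part of the grammar")
        sc.expect("(")
        branch = _scan_token(sc, allow_branch=False)
        if sc.peek("("):
            sc.fail("nested branch is not part of the grammar")
        sc.expect(")")
    return Token(name=name, stereo=stereo, cap=cap, branch=branch)


def parse_sequence(text: str) -> CompoundSequence:
    """Parse a notation string into a :class:`CompoundSequence`.

    Raises :class:`ParseError` for unreadable text and
    :class:`StructureError` for grammatical but chemically invalid input
    (leading triazole unit, branch on a residue without a side-chain
    amine, nested branches).
    """
    if not text or not text.strip():
        raise ParseError("empty sequence string")
    sc = _Scanner(text.strip())
    tokens = []
    while True:
        tok = _scan_token(sc, allow_branch=True)
        tokens.append(tok)
        if sc.eof():
            break
        if sc.peek("-"):
            sc.expect("-")
        elif tok.name != TRIAZOLE_UNIT:
            # a missing separator is only legal right after a triazole unit
            sc.fail("expected '-' between residues")
    return CompoundSequence(tokens=tuple(tokens), source_text=text)


def _token_str(tok: Token) -> str:
    parts = []
    if tok.cap:
        parts.append(f"{tok.cap}-")
    if tok.stereo == "D":
        parts.append("D-")
    parts.append(tok.name)
    if tok.branch is not None:
        parts.append(f"({_token_str(tok.branch)})")
    return "".join(parts)


def canonical_string(seq: CompoundSequence) -> str:
    """Deterministic notation string; hyphens everywhere except after a
    triazole unit, matching the style of the source tables."""
    out = []
    for i, tok in enumerate(seq.tokens):
        if i > 0 and seq.tokens[i - 1].name != TRIAZOLE_UNIT:
            out.append("-")
        out.append(_token_str(tok))
    return "".join(out)
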