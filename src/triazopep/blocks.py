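"""Building-block registry for the branched triazolopeptide notation.

Each block is stored in the dehydrated "residue" convention familiar from
peptide chemistry: the elemental formula of a mid-chain residue, i.e. the
free molecule minus one water.  A whole molecule is the sum of its residue
formulas plus one H2O; an Fmoc carbamate cap contributes a net C15H10O2
(the C15H11O2 fragment replaces one hydrogen on the capped amine).

The glycyl-triazole unit (``GlyΨ[Trl]``) is special: it is a glycine whose
C-terminal amide bond is replaced by a 1,4-disubstituted 1,2,3-triazole
ring.  Its heavy-atom fragment carries four nitrogens (amide N, ring N1,
N2, N3) but its residue formula only three, because ring N1 *is* the
backbone nitrogen of the following residue — the azide that closes the
ring is made from that residue's amine.  At assembly the following block's
backbone N is therefore merged into ring N1 (see :mod:`triazopep.structure`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

__all__ = [
    "FragmentAtom",
    "BlockDefinition",
    "REGISTRY",
    "TRIAZOLE_UNIT",
    "FMOC_CAP_FORMULA",
    "get_block",
]


@dataclass(frozen=True)
class FragmentAtom:
    """One heavy atom of a block fragment in its mid-chain state.

    ``hydrogens`` is the hydrogen count the atom carries when the block sits
    in the middle of a chain; terminal/cap adjustments are applied at
    assembly time.  ``role`` labels chemically meaningful atoms ("Calpha",
    "guanidine C", "ring C5", ...) so descriptor code never has to guess.
    """

    name: str
    element: str  # C, N or O
    hydrogens: int
    role: str = ""


@dataclass(frozen=True)
class BlockDefinition:
    name: str
    kind: str  # alpha_amino_acid | omega_amino_acid | triazole_unit | cap
    residue_formula: Mapping[str, int]
    atoms: Tuple[FragmentAtom, ...]
    bonds: Tuple[Tuple[str, str], ...]
    n_attach: Optional[str] = None
    c_attach: Optional[str] = None
    side_attach: Optional[str] = None
    guanidine_anchor: Optional[str] = None

    def __post_init__(self) -> None:
        names = {a.name for a in self.atoms}
        if len(names) != len(self.atoms):
            raise ValueError(f"{self.name}: duplicate atom names")
        for attach in (self.n_attach, self.c_attach, self.side_attach,
                       self.guanidine_anchor):
            if attach is not None and attach not in names:
                raise ValueError(f"{self.name}: attach point {attach!r} "
                                 "names no atom of the fragment")
        for a, b in self.bonds:
            if a not in names or b not in names:
                raise ValueError(f"{self.name}: bond {a}-{b} names unknown atom")

    def atom(self, name: str) -> FragmentAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)


def _backbone(alpha_h: int = 1) -> Tuple[Tuple[FragmentAtom, ...],
                                         Tuple[Tuple[str, str], ...]]:
    atoms = (
        FragmentAtom("N", "N", 1, "backbone N"),
        FragmentAtom("CA", "C", alpha_h, "Calpha"),
        FragmentAtom("C", "C", 0, "carbonyl C"),
        FragmentAtom("O", "O", 0, "carbonyl O"),
    )
    bonds = (("N", "CA"), ("CA", "C"), ("C", "O"))
    return atoms, bonds


def _chain(prefix: str, n: int, start: str) -> Tuple[Tuple[FragmentAtom, ...],
                                                     Tuple[Tuple[str, str], ...]]:
    """A -(CH2)n- chain bonded onto ``start``."""
    atoms = tuple(FragmentAtom(f"{prefix}{i + 1}", "C", 2) for i in range(n))
    bonds = tuple(
        (start if i == 0 else f"{prefix}{i}", f"{prefix}{i + 1}")
        for i in range(n)
    )
    return atoms, bonds


def _guanidine(tail: str) -> Tuple[Tuple[FragmentAtom, ...],
                                   Tuple[Tuple[str, str], ...]]:
    """NE-C(=NH)(NH2) guanidine head bonded onto ``tail``."""
    atoms = (
        FragmentAtom("NE", "N", 1),
        FragmentAtom("CZ", "C", 0, "guanidine C"),
        FragmentAtom("NH1", "N", 1),
        FragmentAtom("NH2", "N", 2),
    )
    bonds = (
        (tail, "NE"), ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
    )
    return atoms, bonds


def _alpha(name: str, formula: Mapping[str, int],
           side_atoms: Sequence[FragmentAtom] = (),
           side_bonds: Sequence[Tuple[str, str]] = (),
           *, alpha_h: int = 1, side_attach: Optional[str] = None,
           guanidine_anchor: Optional[str] = None) -> BlockDefinition:
    atoms, bonds = _backbone(alpha_h)
    return BlockDefinition(
        name=name, kind="alpha_amino_acid", residue_formula=dict(formula),
        atoms=atoms + tuple(side_atoms), bonds=bonds + tuple(side_bonds),
        n_attach="N", c_attach="C", side_attach=side_attach,
        guanidine_anchor=guanidine_anchor,
    )


def _gly() -> BlockDefinition:
    return _alpha("Gly", {"C": 2, "H": 3, "N": 1, "O": 1}, alpha_h=2)


def _ala() -> BlockDefinition:
    return _alpha("Ala", {"C": 3, "H": 5, "N": 1, "O": 1},
                  (FragmentAtom("CB", "C", 3),), (("CA", "CB"),))


def _pro() -> BlockDefinition:
    # pyrrolidine ring: the backbone N is secondary, 0 H mid-chain
    atoms = (
        FragmentAtom("N", "N", 0, "backbone N"),
        FragmentAtom("CA", "C", 1, "Calpha"),
        FragmentAtom("CB", "C", 2),
        FragmentAtom("CG", "C", 2),
        FragmentAtom("CD", "C", 2),
        FragmentAtom("C", "C", 0, "carbonyl C"),
        FragmentAtom("O", "O", 0, "carbonyl O"),
    )
    bonds = (("N", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
             ("CD", "N"), ("CA", "C"), ("C", "O"))
    return BlockDefinition(
        name="Pro", kind="alpha_amino_acid",
        residue_formula={"C": 5, "H": 7, "N": 1, "O": 1},
        atoms=atoms, bonds=bonds, n_attach="N", c_attach="C",
    )


def _phe() -> BlockDefinition:
    ring = (
        FragmentAtom("CB", "C", 2),
        FragmentAtom("CG", "C", 0),
        FragmentAtom("CD1", "C", 1), FragmentAtom("CD2", "C", 1),
        FragmentAtom("CE1", "C", 1), FragmentAtom("CE2", "C", 1),
        FragmentAtom("CZ", "C", 1),
    )
    bonds = (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
             ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"))
    return _alpha("Phe", {"C": 9, "H": 9, "N": 1, "O": 1}, ring, bonds)


def _lys() -> BlockDefinition:
    side = (
        FragmentAtom("CB", "C", 2), FragmentAtom("CG", "C", 2),
        FragmentAtom("CD", "C", 2), FragmentAtom("CE", "C", 2),
        FragmentAtom("NZ", "N", 2, "side-chain amine N"),
    )
    bonds = (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
             ("CE", "NZ"))
    return _alpha("Lys", {"C": 6, "H": 12, "N": 2, "O": 1}, side, bonds,
                  side_attach="NZ")


def _dab() -> BlockDefinition:
    side = (FragmentAtom("CB", "C", 2), FragmentAtom("CG", "C", 2),
            FragmentAtom("ND", "N", 2, "side-chain amine N"))
    bonds = (("CA", "CB"), ("CB", "CG"), ("CG", "ND"))
    return _alpha("Dab", {"C": 4, "H": 8, "N": 2, "O": 1}, side, bonds,
                  side_attach="ND")


def _dap() -> BlockDefinition:
    side = (FragmentAtom("CB", "C", 2),
            FragmentAtom("NG", "N", 2, "side-chain amine N"))
    bonds = (("CA", "CB"), ("CB", "NG"))
    return _alpha("Dap", {"C": 3, "H": 6, "N": 2, "O": 1}, side, bonds,
                  side_attach="NG")


def _arg() -> BlockDefinition:
    tail = (FragmentAtom("CB", "C", 2), FragmentAtom("CG", "C", 2),
            FragmentAtom("CD", "C", 2))
    tbonds = (("CA", "CB"), ("CB", "CG"), ("CG", "CD"))
    g_atoms, g_bonds = _guanidine("CD")
    return _alpha("Arg", {"C": 6, "H": 12, "N": 4, "O": 1},
                  tail + g_atoms, tbonds + g_bonds,
                  guanidine_anchor="CZ")


def _har() -> BlockDefinition:
    # homoarginine: lysine side chain closed with a guanidine
    tail = (FragmentAtom("CB", "C", 2), FragmentAtom("CG", "C", 2),
            FragmentAtom("CD", "C", 2), FragmentAtom("CE", "C", 2))
    tbonds = (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"))
    g_atoms, g_bonds = _guanidine("CE")
    return _alpha("Har", {"C": 7, "H": 14, "N": 4, "O": 1},
                  tail + g_atoms, tbonds + g_bonds,
                  guanidine_anchor="CZ")


def _omega(name: str, n_ch2: int, formula: Mapping[str, int]) -> BlockDefinition:
    atoms = (FragmentAtom("N", "N", 1, "backbone N"),)
    ch2, ch2_bonds = _chain("C", n_ch2, "N")
    tail = (FragmentAtom("C", "C", 0, "carbonyl C"),
            FragmentAtom("O", "O", 0, "carbonyl O"))
    bonds = ch2_bonds + ((f"C{n_ch2}", "C"), ("C", "O"))
    return BlockDefinition(
        name=name, kind="omega_amino_acid", residue_formula=dict(formula),
        atoms=atoms + ch2 + tail, bonds=bonds, n_attach="N", c_attach="C",
    )


def _triazole_unit() -> BlockDefinition:
    """Glycyl-1,2,3-triazole unit.

    Chain direction N→C runs N_am → CH2 → C4 → (ring) → N1.  The 1,4-ring
    is closed by the click reaction: the alkyne supplies C4/C5 plus the
    CH2–NH2 arm, the azide (made from the next residue's backbone amine)
    supplies N1–N2–N3.  N1 therefore doubles as the next block's backbone
    nitrogen, which is why the residue formula has three N, not four.
    """
    atoms = (
        FragmentAtom("N_am", "N", 1, "backbone N"),
        FragmentAtom("CH2", "C", 2),
        FragmentAtom("C4", "C", 0, "ring C4"),
        FragmentAtom("C5", "C", 1, "ring C5"),
        FragmentAtom("N1", "N", 0, "ring N1"),
        FragmentAtom("N2", "N", 0, "ring N2"),
        FragmentAtom("N3", "N", 0, "ring N3"),
    )
    bonds = (
        ("N_am", "CH2"), ("CH2", "C4"),
        ("C4", "C5"), ("C5", "N1"), ("N1", "N2"), ("N2", "N3"), ("N3", "C4"),
    )
    return BlockDefinition(
        name=TRIAZOLE_UNIT, kind="triazole_unit",
        residue_formula={"C": 3, "H": 3, "N": 3, "O": 0},
        atoms=atoms, bonds=bonds, n_attach="N_am", c_attach="N1",
    )


def _fmoc() -> BlockDefinition:
    """Fluorenylmethyloxycarbonyl cap fragment (C15H11O2 before the
    replaced amine hydrogen is deducted; net contribution C15H10O2)."""
    atoms = [
        FragmentAtom("Ccarb", "C", 0, "carbamate C"),
        FragmentAtom("Ocarb", "O", 0),
        FragmentAtom("Oe", "O", 0),
        FragmentAtom("CM", "C", 2),
        FragmentAtom("C9", "C", 1),
        FragmentAtom("C9a", "C", 0), FragmentAtom("C4a", "C", 0),
        FragmentAtom("C4b", "C", 0), FragmentAtom("C8a", "C", 0),
    ]
    for i in (1, 2, 3, 4, 5, 6, 7, 8):
        atoms.append(FragmentAtom(f"C{i}", "C", 1))
    bonds = (
        ("Ccarb", "Ocarb"), ("Ccarb", "Oe"), ("Oe", "CM"), ("CM", "C9"),
        # five-membered ring
        ("C9", "C9a"), ("C9a", "C4a"), ("C4a", "C4b"), ("C4b", "C8a"),
        ("C8a", "C9"),
        # benzo ring A
        ("C9a", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"),
        ("C4", "C4a"),
        # benzo ring B
        ("C4b", "C5"), ("C5", "C6"), ("C6", "C7"), ("C7", "C8"),
        ("C8", "C8a"),
    )
    return BlockDefinition(
        name="Fmoc", kind="cap",
        residue_formula={"C": 15, "H": 10, "N": 0, "O": 2},
        atoms=tuple(atoms), bonds=bonds, n_attach="Ccarb",
    )


TRIAZOLE_UNIT = "GlyΨ[Trl]"

#: Net elemental contribution of one Fmoc cap to a molecule.
FMOC_CAP_FORMULA = {"C": 15, "H": 10, "N": 0, "O": 2}

REGISTRY: Mapping[str, BlockDefinition] = {
    b.name: b
    for b in (
        _gly(), _ala(), _pro(), _phe(), _lys(), _arg(), _har(),
        _dab(), _dap(),
        _omega("6Ahx", 5, {"C": 6, "H": 11, "N": 1, "O": 1}),
        _omega("5Ava", 4, {"C": 5, "H": 9, "N": 1, "O": 1}),
        _triazole_unit(), _fmoc(),
    )
}


def get_block(name: str) -> BlockDefinition:
    """Look up a registered block; unknown codes raise ``KeyError``."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown block code: {name!r}") from None
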