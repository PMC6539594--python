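"""Assembly of parsed sequences into molecular graphs, formulas and m/z.

Two independent routes to the elemental formula are kept deliberately
separate: :func:`additive_formula` does residue-formula bookkeeping (sum of
dehydrated residues + one H2O + C15H10O2 per Fmoc cap), while
:func:`formula_from_graph` counts atoms of the assembled heavy-atom graph.
Their agreement on every buildable sequence is the central structural
cross-check of the package.

Junction chemistry, in the direction N→C:

* standard amide: acyl carbon of block *k* bonds the backbone N of block
  *k+1*, which keeps one hydrogen (zero for proline);
* into a triazole unit: the acyl carbon bonds the unit's amide nitrogen;
* out of a triazole unit: ring N1 *is* the next block's backbone nitrogen
  (the azide that closed the ring was made from that amine), so the next
  block's own N atom is merged into N1, which carries no hydrogen;
* branch: the branch residue's acyl carbon bonds the side-chain amine of
  the carrier (Lys/Dab/Dap), leaving one hydrogen on it;
* termini: every free backbone amine gains one hydrogen over the mid-chain
  state; the C-terminal carbonyl gains a hydroxyl oxygen;
* Fmoc: the carbamate carbon bonds the capped nitrogen, which loses one
  hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .blocks import FMOC_CAP_FORMULA, TRIAZOLE_UNIT, get_block
from .notation import CompoundSequence, StructureError, Token

__all__ = [
    "ElementalFormula", "MzValue", "MolecularGraph",
    "additive_formula", "assemble_graph", "formula_from_graph",
    "monoisotopic_mass", "monoisotopic_mz",
    "PROTON_MASS", "ISOTOPE_MASS",
]

#: Lightest-isotope atomic masses (Da), CODATA/AME values.
ISOTOPE_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

PROTON_MASS = 1.007276

_HILL_ORDER = ("C", "H", "N", "O")


@dataclass(frozen=True)
class ElementalFormula:
    """Element→count map printable in CxHyNzOw order."""

    counts: Tuple[Tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: Dict[str, int]) -> "ElementalFormula":
        unknown = set(d) - set(_HILL_ORDER)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        if any(v < 0 for v in d.values()):
            raise ValueError("negative element count")
        return cls(tuple((el, d.get(el, 0)) for el in _HILL_ORDER))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        # table style: counts of 1 are left implicit (C2H5NO2)
        return "".join(el + (str(n) if n > 1 else "")
                       for el, n in self.counts if n > 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        a, b = self.as_dict(), other.as_dict()
        return ElementalFormula.from_dict(
            {el: a.get(el, 0) + b.get(el, 0) for el in _HILL_ORDER})


@dataclass(frozen=True)
class MzValue:
    mass: float  # neutral monoisotopic mass, Da
    charge: int
    mz: float  # (mass + z*m_proton)/z

    @property
    def mz_reported(self) -> float:
        """m/z rounded half-up to 4 decimals, the table convention."""
        return _round_half_up(self.mz, 4)


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class MolecularGraph:
    """Heavy-atom graph of an assembled compound.

    Nodes are integer atom ids with attributes ``element``, ``hydrogens``,
    ``block_index`` (position in the assembly walk), ``block`` (block name)
    and ``role``.  The underlying :class:`networkx.Graph` is exposed as
    ``.g`` for path queries.
    """

    def __init__(self, g: nx.Graph, provenance: CompoundSequence):
        self.g = g
        self.provenance = provenance

    @property
    def n_atoms(self) -> int:
        return self.g.number_of_nodes()

    def atoms_with_role(self, role: str) -> List[int]:
        return [n for n, d in self.g.nodes(data=True) if d["role"] == role]

    def element_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {"C": 0, "H": 0, "N": 0, "O": 0}
        for _, d in self.g.nodes(data=True):
            out[d["element"]] += 1
            out["H"] += d["hydrogens"]
        return out


def _check_buildable(seq: CompoundSequence) -> None:
    if seq.tokens[-1].name == TRIAZOLE_UNIT:
        raise StructureError(
            "a triazole unit cannot close the chain: its ring N1 must be "
            "donated to a following residue, and the molecule would lack "
            "a carboxyl terminus")
    for tok in seq.tokens:
        if tok.branch is not None and tok.branch.name == TRIAZOLE_UNIT:
            raise StructureError("a triazole unit cannot stand as a branch")
    for tok, nxt in zip(seq.tokens, seq.tokens[1:]):
        if tok.name != TRIAZOLE_UNIT:
            continue
        nblock = get_block(nxt.name)
        if nblock.atom(nblock.n_attach).hydrogens == 0:
            # ring N1 is made by diazotransfer from the next residue's
            # amine, which must be primary; proline's secondary amine
            # cannot close the ring
            raise StructureError(
                f"a triazole unit cannot precede {nxt.name}: its backbone "
                "amine is secondary and cannot be converted to the ring "
                "azide")


def additive_formula(seq: CompoundSequence) -> ElementalFormula:
    """Sum of residue formulas + one H2O, + net C15H10O2 per Fmoc cap."""
    _check_buildable(seq)
    total = {"C": 0, "H": 2, "N": 0, "O": 1}  # the one condensation water
    for tok in seq.tokens:
        for t in (tok, tok.branch):
            if t is None:
                continue
            for el, n in get_block(t.name).residue_formula.items():
                total[el] = total.get(el, 0) + n
            if t.cap == "Fmoc":
                for el, n in FMOC_CAP_FORMULA.items():
                    total[el] = total.get(el, 0) + n
    return ElementalFormula.from_dict(total)


class _Builder:
    def __init__(self) -> None:
        self.g = nx.Graph()
        self.next_id = 0
        self.block_index = 0

    def add_fragment(self, tok: Token) -> Dict[str, int]:
        block = get_block(tok.name)
        ids: Dict[str, int] = {}
        for atom in block.atoms:
            ids[atom.name] = self.next_id
            self.g.add_node(
                self.next_id, element=atom.element, hydrogens=atom.hydrogens,
                block=block.name, block_index=self.block_index,
                role=atom.role, atom_name=atom.name)
            self.next_id += 1
        for a, b in block.bonds:
            self.g.add_edge(ids[a], ids[b])
        self.block_index += 1
        return ids

    def add_h(self, node: int, delta: int) -> None:
        h = self.g.nodes[node]["hydrogens"] + delta
        if h < 0:
            raise StructureError("hydrogen bookkeeping went negative")
        self.g.nodes[node]["hydrogens"] = h

    def merge(self, keep: int, drop: int) -> None:
        """Identify ``drop`` with ``keep`` (triazole N1 absorbing the next
        block's backbone N); ``keep``'s hydrogen count wins."""
        for nb in list(self.g.neighbors(drop)):
            if nb != keep:
                self.g.add_edge(keep, nb)
        self.g.remove_node(drop)

    def cap_with_fmoc(self, nitrogen: int) -> None:
        cap = get_block("Fmoc")
        ids: Dict[str, int] = {}
        for atom in cap.atoms:
            ids[atom.name] = self.next_id
            self.g.add_node(
                self.next_id, element=atom.element, hydrogens=atom.hydrogens,
                block="Fmoc", block_index=self.block_index,
                role=atom.role, atom_name=atom.name)
            self.next_id += 1
        for a, b in cap.bonds:
            self.g.add_edge(ids[a], ids[b])
        self.block_index += 1
        self.add_h(nitrogen, -1)
        self.g.add_edge(nitrogen, ids[cap.n_attach])


def assemble_graph(seq: CompoundSequence) -> MolecularGraph:
    """Build the heavy-atom graph for a parsed sequence.

    Raises :class:`StructureError` for sequences with a dangling triazole
    attachment (terminal or branch-position unit).
    """
    _check_buildable(seq)
    b = _Builder()
    main_ids: List[Dict[str, int]] = []
    for tok in seq.tokens:
        main_ids.append(b.add_fragment(tok))

    # main-chain junctions
    for i in range(len(seq.tokens) - 1):
        tok, nxt = seq.tokens[i], seq.tokens[i + 1]
        block, nblock = get_block(tok.name), get_block(nxt.name)
        if tok.name == TRIAZOLE_UNIT:
            # ring N1 is the next block's backbone nitrogen
            n1 = main_ids[i]["N1"]
            b.merge(n1, main_ids[i + 1][nblock.n_attach])
            main_ids[i + 1][nblock.n_attach] = n1
        else:
            b.g.add_edge(main_ids[i][block.c_attach],
                         main_ids[i + 1][nblock.n_attach])

    # branches: branch acyl carbon onto the carrier's side-chain amine
    for i, tok in enumerate(seq.tokens):
        if tok.branch is None:
            continue
        carrier = get_block(tok.name)
        side_n = main_ids[i][carrier.side_attach]
        br_ids = b.add_fragment(tok.branch)
        br_block = get_block(tok.branch.name)
        if br_block.c_attach is None or br_block.kind == "triazole_unit":
            raise StructureError(
                f"{tok.branch.name} cannot acylate a side-chain amine")
        b.g.add_edge(br_ids[br_block.c_attach], side_n)
        b.add_h(side_n, -1)  # amine → amide
        # branch N-terminus: free amine unless capped
        br_n = br_ids[br_block.n_attach]
        b.add_h(br_n, +1)
        if tok.branch.cap == "Fmoc":
            b.cap_with_fmoc(br_n)

    # main-chain N-terminus
    first = seq.tokens[0]
    n_term = main_ids[0][get_block(first.name).n_attach]
    b.add_h(n_term, +1)
    if first.cap == "Fmoc":
        b.cap_with_fmoc(n_term)

    # C-terminus: carboxyl OH on the last acyl carbon
    last = seq.tokens[-1]
    c_term = main_ids[-1][get_block(last.name).c_attach]
    oh = b.next_id
    b.g.add_node(oh, element="O", hydrogens=1, block=last.name,
                 block_index=b.g.nodes[c_term]["block_index"],
                 role="carboxyl OH", atom_name="OXT")
    b.g.add_edge(c_term, oh)
    b.g.nodes[c_term]["role"] = "carboxyl C"

    if not nx.is_connected(b.g):
        raise StructureError("assembled graph is not connected")
    return MolecularGraph(b.g, seq)


def formula_from_graph(graph: MolecularGraph) -> ElementalFormula:
    """Element counts read off the assembled graph (cross-check path)."""
    return ElementalFormula.from_dict(graph.element_counts())


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da (lightest-isotope sum)."""
    return sum(n * ISOTOPE_MASS[el] for el, n in formula.counts)


def monoisotopic_mz(formula: ElementalFormula, charge: int = 1) -> MzValue:
    """m/z of the [M+zH]^z+ pseudomolecular ion, z ∈ {1, 2}."""
    if charge not in (1, 2):
        raise ValueError(f"charge must be 1 or 2, got {charge}")
    mass = monoisotopic_mass(formula)
    return MzValue(mass=mass, charge=charge,
                   mz=(mass + charge * PROTON_MASS) / charge)
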