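"""Structural descriptors: guanidine–guanidine topological distance, its
min–max normalization, and the two binary indicators of the three-variable
activity model.

Distance conventions
--------------------
``dis_N-C`` is the number of heavy atoms strictly between the two guanidine
carbons along a bond path.  A 1,2,3-triazole ring can be traversed on two
sides — through C5 (two bonds) or through N3–N2 (three bonds) — and the
choice is *not* a panel-wide constant: it scales with the number of rings
on the path, so it survives min–max normalization.  The default
(``ring_side="nitrogen"``) walks the all-nitrogen edge of the ring, the
convention under which the published one- and three-variable models are
reproduced at printed precision; ``ring_side="shortest"`` is the plain
BFS shortest path.  The *counting* convention (atoms between vs bonds) is
an affine shift and is irrelevant after normalization.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .blocks import TRIAZOLE_UNIT, get_block
from .notation import CompoundSequence, StructureError, Token
from .structure import MolecularGraph, assemble_graph

__all__ = [
    "guanidine_anchors", "topological_distance", "guanidine_distance",
    "indicator_trl2_cn", "indicator_am2n", "build_descriptor_matrix",
    "DescriptorError",
]


class DescriptorError(ValueError):
    """A descriptor is undefined for the given compound."""


def guanidine_anchors(graph: MolecularGraph) -> Tuple[int, int]:
    """Return (N-terminal-side, C-terminal-side) guanidine carbon atom ids.

    The descriptor is defined only for compounds carrying exactly two
    guanidine groups, one toward each terminus (as holds panel-wide:
    a homoarginine arm and the C-terminal arginine).
    """
    anchors = graph.atoms_with_role("guanidine C")
    if len(anchors) != 2:
        raise DescriptorError(
            f"guanidine distance needs exactly 2 guanidine groups, "
            f"found {len(anchors)}")
    # the C-terminal anchor sits in the block assembled last along the
    # main chain; branches are assembled after it, so order by proximity
    # to the carboxyl terminus instead of by block index
    carboxyl = graph.atoms_with_role("carboxyl C")
    if len(carboxyl) != 1:
        raise DescriptorError("expected exactly one carboxyl terminus")
    d = dict(nx.single_source_shortest_path_length(graph.g, carboxyl[0]))
    a, b = sorted(anchors, key=lambda n: d[n], reverse=True)
    return a, b


def topological_distance(graph: MolecularGraph, a: int, b: int,
                         ring_side: str = "nitrogen",
                         count: str = "atoms_between") -> int:
    """Topological distance between heavy atoms ``a`` and ``b``.

    ``ring_side="nitrogen"`` forces paths through triazole rings onto the
    N1–N2–N3 edge (by excluding ring C5 spur atoms from the search);
    ``"shortest"`` is an unconstrained BFS.  ``count`` selects the value
    convention: ``"atoms_between"`` (strictly-between atom count, the
    default) or ``"bonds"`` (bond count, one more).
    """
    if ring_side not in ("nitrogen", "shortest"):
        raise ValueError(f"unknown ring_side {ring_side!r}")
    if count not in ("atoms_between", "bonds"):
        raise ValueError(f"unknown count convention {count!r}")
    g = graph.g
    if ring_side == "nitrogen":
        drop = [n for n in graph.atoms_with_role("ring C5")
                if n not in (a, b)]
        if drop:
            g = g.copy()
            g.remove_nodes_from(drop)
    try:
        bonds = nx.shortest_path_length(g, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise DescriptorError(f"atoms {a} and {b} are not connected") from exc
    return bonds if count == "bonds" else max(bonds - 1, 0)


def guanidine_distance(graph: MolecularGraph,
                       ring_side: str = "nitrogen",
                       count: str = "atoms_between") -> int:
    """``dis_N-C``: topological distance between the two guanidine carbons."""
    a, b = guanidine_anchors(graph)
    return topological_distance(graph, a, b, ring_side=ring_side, count=count)


def _main_chain_walk(seq: CompoundSequence) -> List[Token]:
    """The N→C walk along which linkages are counted: if the first
    main-chain residue carries a branch, the walk starts at the branch
    residue (the molecule's N-terminal arm)."""
    walk = list(seq.tokens)
    if walk[0].branch is not None:
        walk = [walk[0].branch] + walk
    return walk


def _linkages(seq: CompoundSequence) -> List[Tuple[Token, Token, str]]:
    """Backbone linkages as (N-side block, C-side block, type) in N→C
    order.  A junction *out of* a triazole unit is the isosteric "triazole"
    linkage; every other junction (including into a unit's amide N) is an
    amide."""
    walk = _main_chain_walk(seq)
    out = []
    for left, right in zip(walk, walk[1:]):
        kind = "triazole" if left.name == TRIAZOLE_UNIT else "amide"
        out.append((left, right, kind))
    return out


def indicator_trl2_cn(seq: CompoundSequence) -> int:
    """1 iff the second backbone linkage counted from the C terminus is a
    triazole junction (``2Trl_C-N``)."""
    links = _linkages(seq)
    if len(links) < 2:
        raise DescriptorError(
            "2Trl_C-N needs at least two backbone linkages")
    return int(links[-2][2] == "triazole")


def _has_free_alpha_amine(tok: Token, seq: CompoundSequence) -> bool:
    """A free, uncapped alpha-amine on a backbone-terminal residue.

    Only chain N-termini qualify: the first main-chain residue (whose
    backbone N stays free even when its side chain carries the arm) and
    branch residues (N-terminus of the arm).  Omega amino acids have a
    backbone amine but no alpha-amine; side-chain amines never count.
    """
    if get_block(tok.name).kind != "alpha_amino_acid":
        return False
    if tok.cap is not None:
        return False
    terminal = tok is seq.tokens[0] or any(
        tok is t.branch for t in seq.tokens)
    return terminal


def indicator_am2n(seq: CompoundSequence) -> int:
    """1 iff a residue flanking the second backbone linkage counted from
    the N-terminal end bears a free alpha-amine (``am_2N``).

    The count starts at the arm residue when the first main-chain residue
    is branched, so for ``Lys(Har)-…`` linkage 1 is the side-chain amide
    Har→Lys and linkage 2 the Lys→linker bond, flanked by the lysine with
    its free alpha-amine.
    """
    links = _linkages(seq)
    if len(links) < 2:
        raise DescriptorError("am_2N needs at least two backbone linkages")
    left, right, _ = links[1]
    return int(_has_free_alpha_amine(left, seq)
               or _has_free_alpha_amine(right, seq))


def build_descriptor_matrix(
    compounds: Mapping[str, CompoundSequence] | Sequence[Tuple[str, CompoundSequence]],
    columns: Sequence[str] = ("dis_N-C", "dis_N-C,norm", "2Trl_C-N", "am_2N"),
    ring_side: str = "nitrogen",
    count: str = "atoms_between",
    am2n_override: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Compute named descriptor columns for a panel of compounds.

    Normalization metadata (panel min/max of the raw distance) is attached
    as ``DataFrame.attrs["dis_min"]/["dis_max"]``.  A degenerate panel
    (max == min) normalizes to 0 and sets ``attrs["degenerate_norm"]``.
    Descriptor failures raise :class:`DescriptorError` naming the compound
    rather than silently dropping the row.  ``am2n_override`` substitutes
    explicit 0/1 assignments for listed compound ids.
    """
    items = list(compounds.items()) if isinstance(compounds, Mapping) \
        else list(compounds)
    known = {"dis_N-C", "dis_N-C,norm", "2Trl_C-N", "am_2N"}
    unknown = set(columns) - known
    if unknown:
        raise ValueError(f"unknown descriptor columns: {sorted(unknown)}")

    need_dis = bool({"dis_N-C", "dis_N-C,norm"} & set(columns))
    rows: Dict[str, Dict[str, float]] = {}
    raw_dis: Dict[str, int] = {}
    for cid, seq in items:
        if cid in rows:
            raise ValueError(f"duplicate compound id {cid!r}")
        row: Dict[str, float] = {}
        try:
            if need_dis:
                raw_dis[cid] = guanidine_distance(
                    assemble_graph(seq), ring_side=ring_side, count=count)
            if "2Trl_C-N" in columns:
                row["2Trl_C-N"] = indicator_trl2_cn(seq)
            if "am_2N" in columns:
                if am2n_override and cid in am2n_override:
                    v = int(am2n_override[cid])
                    if v not in (0, 1):
                        raise DescriptorError(
                            f"am_2N override for {cid!r} must be 0/1")
                    row["am_2N"] = v
                else:
                    row["am_2N"] = indicator_am2n(seq)
        except (DescriptorError, StructureError) as exc:
            raise DescriptorError(f"compound {cid!r}: {exc}") from exc
        rows[cid] = row

    df = pd.DataFrame.from_dict(rows, orient="index")
    if need_dis:
        df["dis_N-C"] = pd.Series(raw_dis)
        lo, hi = df["dis_N-C"].min(), df["dis_N-C"].max()
        df.attrs["dis_min"], df.attrs["dis_max"] = int(lo), int(hi)
        if "dis_N-C,norm" in columns:
            if hi == lo:
                df["dis_N-C,norm"] = 0.0
                df.attrs["degenerate_norm"] = True
            else:
                df["dis_N-C,norm"] = (df["dis_N-C"] - lo) / (hi - lo)
    df = df[[c for c in columns]]
    df.index.name = "id"
    return df
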