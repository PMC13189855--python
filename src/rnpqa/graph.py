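"""Residue interaction graph construction and interface enumeration.

Residues are nodes. An undirected edge joins residues whose anchor atoms lie
within 14 A or with any heavy-atom pair within 6 A; undirected edges are
stored as two directed arcs with shared features, the convention of
message-passing layers. A residue is an interface residue when any of its
heavy atoms is within 6 A of a chain of the opposite polymer type, and an
interface is a (protein chain, RNA chain) pair with at least one such
contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    ComplexStructure,
    MissingAnchorError,
    PolymerType,
    Residue,
    anchor_atom,
)

__all__ = [
    "ComplexGraph",
    "build_graph",
    "interface_residues",
    "enumerate_interfaces",
    "DEFAULT_ANCHOR_CUTOFF",
    "DEFAULT_ATOM_CUTOFF",
]

DEFAULT_ANCHOR_CUTOFF = 14.0  # A, anchor-anchor edge rule
DEFAULT_ATOM_CUTOFF = 6.0  # A, any-atom edge and interface rule


@dataclass
class ComplexGraph:
    """Topology (+ optional features) of a residue interaction graph.

    ``arcs`` is a (2E, 2) int array of directed arcs; arc k and its reverse
    carry identical features. ``edges`` lists each undirected pair once with
    i < j in node order.
    """

    residues: list[Residue]
    arcs: np.ndarray  # (2E, 2) int
    edges: np.ndarray  # (E, 2) int, i < j
    interface_mask: np.ndarray  # (N,) bool
    interfaces: list[tuple[str, str]]  # (protein_chain_id, rna_chain_id)
    node_to_interface: dict[int, list[int]]  # node index -> interface indices
    polymer_flags: np.ndarray  # (N,) 1.0 protein / 0.0 RNA
    node_feat: np.ndarray | None = None  # (N, 66)
    edge_feat: np.ndarray | None = None  # (2E, 12), aligned with arcs

    @property
    def n_nodes(self) -> int:
        return len(self.residues)

    def interface_node_mask(self, interface_index: int) -> np.ndarray:
        """Boolean mask of nodes belonging to either chain of an interface."""
        pc, rc = self.interfaces[interface_index]
        return np.array([r.chain_id in (pc, rc) for r in self.residues])


def _residue_heavy_coords(residues: list[Residue]):
    coords = []
    owner = []
    for i, r in enumerate(residues):
        hc = r.heavy_coords()
        coords.append(hc)
        owner.extend([i] * len(hc))
    return np.vstack(coords), np.array(owner, int)


def _atom_contact_pairs(residues: list[Residue], cutoff: float) -> set[tuple[int, int]]:
    """All residue index pairs (i<j) with min heavy-atom distance <= cutoff."""
    coords, owner = _residue_heavy_coords(residues)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    for a, b in pairs:
        i, j = owner[a], owner[b]
        if i != j:
            out.add((min(i, j), max(i, j)))
    return out


def interface_residues(
    structure: ComplexStructure, atom_cutoff: float = DEFAULT_ATOM_CUTOFF
) -> np.ndarray:
    """Per-residue boolean: any heavy atom within cutoff of an
    opposite-polymer chain."""
    residues = list(structure.residues())
    flags = np.zeros(len(residues), dtype=bool)
    contacts = _atom_contact_pairs(residues, atom_cutoff)
    for i, j in contacts:
        ri, rj = residues[i], residues[j]
        if ri.polymer_type is not rj.polymer_type:
            flags[i] = True
            flags[j] = True
    return flags


def enumerate_interfaces(
    structure: ComplexStructure, atom_cutoff: float = DEFAULT_ATOM_CUTOFF
) -> list[tuple[str, str]]:
    """Ordered (protein_chain_id, rna_chain_id) pairs with >=1 contact."""
    residues = list(structure.residues())
    found: set[tuple[str, str]] = set()
    for i, j in _atom_contact_pairs(residues, atom_cutoff):
        ri, rj = residues[i], residues[j]
        if ri.polymer_type is rj.polymer_type:
            continue
        if ri.polymer_type is PolymerType.PROTEIN:
            found.add((ri.chain_id, rj.chain_id))
        else:
            found.add((rj.chain_id, ri.chain_id))
    return sorted(found)


def build_graph(
    structure: ComplexStructure,
    features=None,
    anchor_cutoff: float = DEFAULT_ANCHOR_CUTOFF,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
) -> ComplexGraph:
    """Build the residue interaction graph.

    ``features`` may be a (node_feat, edge_feat_fn) pair left to the
    featurization layer; topology alone is built here. Residues lacking an
    anchor atom are dropped with a warning.
    """
    import warnings

    residues = []
    for r in structure.residues():
        try:
            anchor_atom(r)
        except MissingAnchorError:
            warnings.warn(
                f"residue {r.chain_id}/{r.seq_index} has no anchor atom; excluded"
            )
            continue
        residues.append(r)
    n = len(residues)
    if n < 2:
        raise ValueError("graph needs >=2 residues with anchors")

    anchors = np.array([anchor_atom(r).coord for r in residues])
    tree = cKDTree(anchors)
    anchor_pairs = tree.query_pairs(r=anchor_cutoff, output_type="ndarray")
    pair_set = {(min(i, j), max(i, j)) for i, j in anchor_pairs}
    pair_set |= _atom_contact_pairs(residues, atom_cutoff)
    edges = np.array(sorted(pair_set), dtype=int).reshape(-1, 2)
    arcs = (
        np.vstack([edges, edges[:, ::-1]])
        if len(edges)
        else np.zeros((0, 2), dtype=int)
    )

    # interfaces on the same residue subset
    sub = ComplexStructureView(residues)
    iface_flags = interface_residues(sub, atom_cutoff)
    interfaces = enumerate_interfaces(sub, atom_cutoff)
    if_index = {pair: k for k, pair in enumerate(interfaces)}
    node_to_interface: dict[int, list[int]] = {}
    contacts = _atom_contact_pairs(residues, atom_cutoff)
    for i, j in contacts:
        ri, rj = residues[i], residues[j]
        if ri.polymer_type is rj.polymer_type:
            continue
        if ri.polymer_type is PolymerType.PROTEIN:
            pair = (ri.chain_id, rj.chain_id)
        else:
            pair = (rj.chain_id, ri.chain_id)
        k = if_index[pair]
        for node in (i, j):
            node_to_interface.setdefault(node, [])
            if k not in node_to_interface[node]:
                node_to_interface[node].append(k)

    polymer_flags = np.array(
        [1.0 if r.polymer_type is PolymerType.PROTEIN else 0.0 for r in residues]
    )
    return ComplexGraph(
        residues=residues,
        arcs=arcs,
        edges=edges,
        interface_mask=iface_flags,
        interfaces=interfaces,
        node_to_interface=node_to_interface,
        polymer_flags=polymer_flags,
    )


class ComplexStructureView:
    """Duck-typed structure over an explicit residue list (keeps interface
    logic shared between full structures and graph node subsets)."""

    def __init__(self, residues: list[Residue]):
        self._residues = residues

    def residues(self):
        return iter(self._residues)
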