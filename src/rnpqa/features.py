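"""Node (66-channel) and edge (12-channel) feature computation.

Features split into *annotated* channels — computed here from the model
coordinates by internal annotators (backbone torsions, a DSSP-style
hydrogen-bond secondary-structure assignment, Shrake-Rupley relative
solvent accessibility, geometric base-pair detection, nested
secondary-structure element decomposition, center-of-mass geometry) — and
*predicted* channels supplied by optional provider plug-ins (sequence-based
secondary structure/RSA/torsions for proteins, predicted intra-protein pair
distances/angles, predicted RNA base-pairing probabilities). Channels
without a provider are zero-filled.

Continuous channels are scaled: distances d -> min(d, D)/D, plane/bond
angles a -> a/180, torsions as (sin, cos) pairs with undefined values
encoded (0, 0) plus a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import angle_between, dihedral
from .graph import ComplexGraph, build_graph, interface_residues
from .structure import (
    STANDARD_AMINO_ACIDS,
    STANDARD_RIBONUCLEOTIDES,
    ComplexStructure,
    PolymerType,
    Residue,
    anchor_atom,
    center_of_mass,
)

__all__ = [
    "FeatureLayout",
    "DEFAULT_NODE_BLOCKS",
    "DEFAULT_EDGE_BLOCKS",
    "ProviderSet",
    "Annotations",
    "annotate",
    "backbone_torsions",
    "rna_pseudotorsions",
    "assign_secondary_structure",
    "shrake_rupley_sasa",
    "relative_solvent_accessibility",
    "annotate_rna_pairs",
    "rna_elements",
    "geometry_features",
    "node_features",
    "edge_features",
    "featurize",
]

NODE_DIST_SCALE = 50.0  # A, center-of-mass distance normalization
EDGE_DIST_SCALE = 20.0  # A, inter-residue distance normalization

SS8_STATES = "HGIEBTS-"
_AA_INDEX = {name: i for i, name in enumerate(STANDARD_AMINO_ACIDS)}
_NT_INDEX = {name: i for i, name in enumerate(STANDARD_RIBONUCLEOTIDES)}

DEFAULT_NODE_BLOCKS = [
    ("aa_onehot", 20),
    ("nt_onehot", 4),
    ("unknown_residue", 1),
    ("polymer_flag", 1),
    ("interface_flag", 1),
    ("com_geometry", 4),  # d/angle to complex COM, d/angle to chain COM
    ("ss8_onehot", 8),
    ("rsa", 1),
    ("protein_torsions", 4),  # phi/psi as sin/cos
    ("pred_ss3", 3),
    ("pred_rsa", 1),
    ("pred_torsions", 4),
    ("rna_pseudotorsions", 4),  # eta/theta as sin/cos
    ("rna_pair_flags", 3),  # canonical, non-canonical, any-paired
    ("rna_element", 5),  # stem, hairpin, interior, multiloop, exterior
    ("torsion_valid", 2),  # protein torsions defined, RNA pseudotorsions defined
]

DEFAULT_EDGE_BLOCKS = [
    ("min_atom_dist", 1),
    ("anchor_dist", 1),
    ("orientation_angles", 2),  # orientation vector vs anchor-anchor axis, each endpoint
    ("pred_protein_pair", 3),  # predicted distance + two angles
    ("rna_pair_annotated", 1),
    ("rna_pair_prob", 2),  # one channel per pairing predictor
    ("inter_chain", 1),
    ("protein_rna", 1),
]


@dataclass(frozen=True)
class FeatureLayout:
    """Named, contiguous channel blocks for node and edge vectors."""

    node_blocks: tuple = tuple(DEFAULT_NODE_BLOCKS)
    edge_blocks: tuple = tuple(DEFAULT_EDGE_BLOCKS)
    version: str = "default-1"

    def __post_init__(self):
        if self.node_width != 66:
            raise ValueError(f"node blocks sum to {self.node_width}, expected 66")
        if self.edge_width != 12:
            raise ValueError(f"edge blocks sum to {self.edge_width}, expected 12")

    @property
    def node_width(self) -> int:
        return sum(w for _, w in self.node_blocks)

    @property
    def edge_width(self) -> int:
        return sum(w for _, w in self.edge_blocks)

    def node_slice(self, name: str) -> slice:
        return self._slice(self.node_blocks, name)

    def edge_slice(self, name: str) -> slice:
        return self._slice(self.edge_blocks, name)

    @staticmethod
    def _slice(blocks, name: str) -> slice:
        off = 0
        for blk, width in blocks:
            if blk == name:
                return slice(off, off + width)
            off += width
        raise KeyError(name)

    def node_channel_names(self) -> list[str]:
        return [f"{blk}[{i}]" for blk, w in self.node_blocks for i in range(w)]

    def edge_channel_names(self) -> list[str]:
        return [f"{blk}[{i}]" for blk, w in self.edge_blocks for i in range(w)]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "version": self.version,
                "node_blocks": [list(b) for b in self.node_blocks],
                "edge_blocks": [list(b) for b in self.edge_blocks],
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "FeatureLayout":
        import json

        doc = json.loads(text)
        return FeatureLayout(
            node_blocks=tuple((n, int(w)) for n, w in doc["node_blocks"]),
            edge_blocks=tuple((n, int(w)) for n, w in doc["edge_blocks"]),
            version=doc["version"],
        )


DEFAULT_LAYOUT = FeatureLayout()


# ---------------------------------------------------------------------------
# torsions


def backbone_torsions(residues: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; None where undefined (termini or
    missing backbone atoms)."""
    out = []
    for i, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if None not in (n, ca, c):
            if i > 0:
                c_prev = residues[i - 1].atom("C")
                if c_prev is not None:
                    phi = dihedral(c_prev.coord, n.coord, ca.coord, c.coord)
            if i < len(residues) - 1:
                n_next = residues[i + 1].atom("N")
                if n_next is not None:
                    psi = dihedral(n.coord, ca.coord, c.coord, n_next.coord)
        out.append((phi, psi))
    return out


def rna_pseudotorsions(residues: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Per-residue pseudo-torsions (eta, theta) over P and C4' atoms.

    eta_i  = dihedral(C4'[i-1], P[i], C4'[i], P[i+1])
    theta_i = dihedral(P[i], C4'[i], P[i+1], C4'[i+1])
    """
    p = [r.atom("P") for r in residues]
    c4 = [r.atom("C4'") for r in residues]
    out = []
    for i in range(len(residues)):
        eta = theta = None
        if 0 < i < len(residues) - 1:
            if None not in (c4[i - 1], p[i], c4[i], p[i + 1]):
                eta = dihedral(c4[i - 1].coord, p[i].coord, c4[i].coord, p[i + 1].coord)
            if None not in (p[i], c4[i], p[i + 1], c4[i + 1]):
                theta = dihedral(p[i].coord, c4[i].coord, p[i + 1].coord, c4[i + 1].coord)
        out.append((eta, theta))
    return out


# ---------------------------------------------------------------------------
# secondary structure (DSSP-style hydrogen-bond assignment)

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_FACTOR = 0.084 * 332.0


def _amide_hydrogens(residues: list[Residue]) -> list[np.ndarray | None]:
    """Place the backbone amide H of each residue along the bisector of the
    previous peptide C=O direction, 1.0 A from N (first residue: none)."""
    out: list[np.ndarray | None] = [None]
    for i in range(1, len(residues)):
        n = residues[i].atom("N")
        c_prev = residues[i - 1].atom("C")
        o_prev = residues[i - 1].atom("O")
        if None in (n, c_prev, o_prev):
            out.append(None)
            continue
        d1 = n.coord - c_prev.coord
        d2 = n.coord - o_prev.coord
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = d1 + d2
        norm = np.linalg.norm(bis)
        out.append(n.coord + bis / norm if norm > 1e-9 else None)
    return out


def _hbond_matrix(residues: list[Residue]) -> np.ndarray:
    """hb[a, d] True when the N-H of residue d donates to the C=O of
    residue a with electrostatic energy < -0.5 kcal/mol."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    hpos = _amide_hydrogens(residues)
    for a in range(n):
        c, o = residues[a].atom("C"), residues[a].atom("O")
        if c is None or o is None:
            continue
        for d in range(n):
            if abs(a - d) < 2:
                continue
            nd, hd = residues[d].atom("N"), hpos[d]
            if nd is None or hd is None:
                continue
            r_on = np.linalg.norm(o.coord - nd.coord)
            r_ch = np.linalg.norm(c.coord - hd)
            r_oh = np.linalg.norm(o.coord - hd)
            r_cn = np.linalg.norm(c.coord - nd.coord)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a hydrogen bond
            e = _HB_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[a, d] = e < _HB_ENERGY_CUTOFF
    return hb


def assign_secondary_structure(residues: list[Residue]) -> str:
    """8-state secondary structure from backbone hydrogen bonding.

    States: H/G/I (4/3/5-turn helices), E/B (extended bridges), T (turn),
    S (bend), '-' (coil). Chains shorter than 4 residues are all '-'.
    """
    n = len(residues)
    if n < 4:
        return "-" * n
    hb = _hbond_matrix(residues)

    def turn(i: int, k: int) -> bool:
        return i + k < n and hb[i, i + k]

    labels = ["-"] * n

    # bends (lowest priority first; later assignments overwrite)
    for i in range(2, n - 2):
        ca = [residues[j].atom("CA") for j in (i - 2, i, i + 2)]
        if None in ca:
            continue
        if angle_between(ca[1].coord - ca[0].coord, ca[2].coord - ca[1].coord) > 70.0:
            labels[i] = "S"

    # hydrogen-bonded turns
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                for j in range(i + 1, min(i + k, n)):
                    labels[j] = "T"

    # bridges -> E (extended) / B (isolated)
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    has_bridge = bridge.any(axis=1)
    for i in range(n):
        if has_bridge[i]:
            ext = (i > 0 and has_bridge[i - 1]) or (i + 1 < n and has_bridge[i + 1])
            labels[i] = "E" if ext else "B"

    # helices (highest priority)
    for k, sym in ((5, "I"), (3, "G"), (4, "H")):
        for i in range(1, n):
            if turn(i - 1, k) and turn(i, k):
                for j in range(i, min(i + k, n)):
                    labels[j] = sym
    return "".join(labels)


# ---------------------------------------------------------------------------
# solvent accessibility

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "SE": 1.90}
_PROBE = 1.4

#: Theoretical maximum ASA per amino acid (Tien et al. scale), A^2.
MAX_ASA_PROTEIN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_MAX_ASA_RNA_CACHE: dict[str, float] = {}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    structure: ComplexStructure, n_points: int = 100
) -> dict[tuple[str, int], float]:
    """Per-residue solvent-accessible surface area (A^2), heavy atoms only."""
    atoms = []
    owners = []
    for res in structure.residues():
        for a in res.heavy_atoms():
            atoms.append(a)
            owners.append((res.chain_id, res.seq_index))
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_VDW_RADII.get(a.element.upper(), 1.70) + _PROBE for a in atoms])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    out: dict[tuple[str, int], float] = {}
    max_r = radii.max()
    for i, atom in enumerate(atoms):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neighbors:
            d = cdist(pts, coords[neighbors])
            buried = (d < radii[neighbors]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = frac * 4.0 * np.pi * radii[i] ** 2
        out[owners[i]] = out.get(owners[i], 0.0) + area
    return out


def _max_asa_rna(base: str, n_points: int = 200) -> float:
    """Max ASA of a nucleotide: the central residue of an extended
    synthetic trinucleotide, computed once and cached."""
    if base not in _MAX_ASA_RNA_CACHE:
        from .decoygen import _build_rna_strand  # deliberate: idealized fixture
        from .structure import ComplexStructure as _CS

        chain = _build_rna_strand(base * 3, "X")
        st = _CS(chains=[chain], source_path="<maxasa>")
        sasa = shrake_rupley_sasa(st, n_points=n_points)
        _MAX_ASA_RNA_CACHE[base] = sasa[("X", 2)]
    return _MAX_ASA_RNA_CACHE[base]


def relative_solvent_accessibility(
    structure: ComplexStructure, n_points: int = 100
) -> dict[tuple[str, int], float]:
    """Per-residue RSA in [0, 1]: SASA over residue-type maximum ASA."""
    sasa = shrake_rupley_sasa(structure, n_points=n_points)
    out = {}
    for res in structure.residues():
        key = (res.chain_id, res.seq_index)
        if res.polymer_type is PolymerType.PROTEIN:
            ref = MAX_ASA_PROTEIN.get(res.name, 200.0)
        else:
            ref = _max_asa_rna(res.name) if res.name in "ACGU" else 350.0
        out[key] = min(sasa.get(key, 0.0) / ref, 1.0)
    return out


# ---------------------------------------------------------------------------
# RNA base pairing and secondary-structure elements

_RNA_BACKBONE_SUGAR = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}
_COMPLEMENTARY = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WC_EDGE = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}


def _base_atoms(res: Residue) -> list:
    return [a for a in res.heavy_atoms() if a.name not in _RNA_BACKBONE_SUGAR]


def _base_plane_normal(res: Residue) -> np.ndarray | None:
    atoms = _base_atoms(res)
    if len(atoms) < 3:
        return None
    xyz = np.array([a.coord for a in atoms])
    xyz = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz)
    return vt[2]


def annotate_rna_pairs(
    structure: ComplexStructure,
    hbond_cutoff: float = 3.5,
    plane_angle_cutoff: float = 30.0,
):
    """Geometric base-pair detection.

    Canonical: complementary bases (A-U, G-C, G-U) whose Watson-Crick edge
    nitrogens (purine N1 / pyrimidine N3) are within ``hbond_cutoff`` with
    base planes within ``plane_angle_cutoff``. Non-canonical: any other
    base-base heavy-atom contact within the cutoff. Returns
    [((chain_i, seq_i), (chain_j, seq_j), canonical_flag), ...].
    """
    rna = [r for r in structure.residues() if r.polymer_type is PolymerType.RNA]
    out = []
    for i, ri in enumerate(rna):
        bi = _base_atoms(ri)
        if not bi:
            continue
        ci = np.array([a.coord for a in bi])
        for rj in rna[i + 1 :]:
            if rj.chain_id == ri.chain_id and abs(rj.seq_index - ri.seq_index) == 1:
                continue  # sequence neighbors stack, they do not pair
            bj = _base_atoms(rj)
            if not bj:
                continue
            cj = np.array([a.coord for a in bj])
            if cdist(ci, cj).min() > hbond_cutoff:
                continue
            canonical = False
            if (ri.name, rj.name) in _COMPLEMENTARY:
                ei = ri.atom(_WC_EDGE.get(ri.name, ""))
                ej = rj.atom(_WC_EDGE.get(rj.name, ""))
                ni, nj = _base_plane_normal(ri), _base_plane_normal(rj)
                if ei is not None and ej is not None and ni is not None and nj is not None:
                    if np.linalg.norm(ei.coord - ej.coord) <= hbond_cutoff:
                        ang = angle_between(ni, nj)
                        if min(ang, 180.0 - ang) <= plane_angle_cutoff:
                            canonical = True
            out.append(
                (
                    (ri.chain_id, ri.seq_index),
                    (rj.chain_id, rj.seq_index),
                    canonical,
                )
            )
    return out


RNA_ELEMENTS = ("stem", "hairpin", "interior", "multiloop", "exterior")


def _max_noncrossing(pairs: list[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    """Maximum non-crossing subset of candidate pairs (interval DP)."""
    pairset = {(min(i, j), max(i, j)) for i, j in pairs}
    memo: dict[tuple[int, int], tuple[int, frozenset]] = {}

    def solve(lo: int, hi: int):
        if lo >= hi:
            return 0, frozenset()
        if (lo, hi) in memo:
            return memo[(lo, hi)]
        best = solve(lo + 1, hi)
        for j in range(lo + 1, hi + 1):
            if (lo, j) in pairset:
                in_n, in_s = solve(lo + 1, j - 1)
                out_n, out_s = solve(j + 1, hi)
                cand = (1 + in_n + out_n, in_s | out_s | {(lo, j)})
                if cand[0] > best[0]:
                    best = cand
        memo[(lo, hi)] = best
        return best

    _, chosen = solve(0, n - 1)
    return sorted(chosen)


def rna_elements(pairs, chain_residues: list[Residue]) -> list[str]:
    """Per-residue secondary-structure element labels for one RNA chain.

    ``pairs`` is the annotate_rna_pairs output; only intra-chain pairs of
    this chain are used, reduced to their maximum non-crossing subset.
    Labels: stem (paired), hairpin / interior / multiloop (unpaired inside
    a loop closed by a pair with 0 / 1 / >=2 inner branches), exterior.
    """
    chain_id = chain_residues[0].chain_id
    index = {r.seq_index: k for k, r in enumerate(chain_residues)}
    n = len(chain_residues)
    cand = [
        (index[a[1]], index[b[1]])
        for a, b, _ in pairs
        if a[0] == chain_id and b[0] == chain_id and a[1] in index and b[1] in index
    ]
    nested = _max_noncrossing(cand, n)
    partner = {}
    for i, j in nested:
        partner[i] = j
        partner[j] = i

    labels = ["exterior"] * n
    for i in partner:
        labels[i] = "stem"

    # enclosing pair for each unpaired position: smallest (i,j) spanning it
    for k in range(n):
        if k in partner:
            continue
        enclosing = None
        for i, j in nested:
            if i < k < j and (enclosing is None or j - i < enclosing[1] - enclosing[0]):
                enclosing = (i, j)
        if enclosing is None:
            continue  # exterior
        i, j = enclosing
        # branches directly inside (i, j): pairs (a,b) with i<a, b<j not nested deeper
        children = []
        pos = i + 1
        while pos < j:
            if pos in partner and partner[pos] > pos:
                children.append((pos, partner[pos]))
                pos = partner[pos] + 1
            else:
                pos += 1
        if len(children) == 0:
            labels[k] = "hairpin"
        elif len(children) == 1:
            labels[k] = "interior"
        else:
            labels[k] = "multiloop"
    return labels


# ---------------------------------------------------------------------------
# center-of-mass geometry


def _orientation_vector(res: Residue) -> np.ndarray | None:
    if res.polymer_type is PolymerType.PROTEIN:
        ca = res.atom("CA")
        tip = res.atom("CB") or res.atom("C")
        if ca is None or tip is None:
            return None
        return tip.coord - ca.coord
    c3, c1 = res.atom("C3'"), res.atom("C1'")
    if c3 is None or c1 is None:
        return None
    return c1.coord - c3.coord


def geometry_features(structure: ComplexStructure, res: Residue):
    """(d_complex, a_complex, d_chain, a_chain): anchor distance and
    orientation-vector angle to the complex and own-chain centers of mass."""
    anchor = anchor_atom(res).coord
    all_atoms = [a for r in structure.residues() for a in r.atoms]
    chain_atoms = [a for r in structure.chain(res.chain_id).residues for a in r.atoms]
    com_all = center_of_mass(all_atoms)
    com_chain = center_of_mass(chain_atoms)
    orient = _orientation_vector(res)
    out = []
    for com in (com_all, com_chain):
        d = float(np.linalg.norm(anchor - com))
        if orient is None or d == 0.0:
            a = 0.0
        else:
            a = angle_between(orient, com - anchor)
        out.extend([d, a])
    return tuple(out)


# ---------------------------------------------------------------------------
# providers

ResidueProvider = Callable[[str, int], np.ndarray | None]
PairProvider = Callable[[str, int, str, int], np.ndarray | None]
PairProbProvider = Callable[[str, int, str, int], float | None]


@dataclass
class ProviderSet:
    """Plug-in contract for externally predicted features.

    protein_residue(chain_id, seq_index) -> 8-vector
        (ss3 probabilities[3], rsa, phi_sin, phi_cos, psi_sin, psi_cos)
    protein_pair(ci, i, cj, j) -> 3-vector (distance A, angle deg, angle deg)
    rna_pair_prob(ci, i, cj, j) -> base-pairing probability in [0, 1]

    Any provider may be None or return None; missing entries zero-fill.
    """

    protein_residue: ResidueProvider | None = None
    protein_pair: PairProvider | None = None
    rna_pair_prob: PairProbProvider | None = None
    rna_pair_prob_alt: PairProbProvider | None = None

    def pair_probabilities(self, ci: str, i: int, cj: str, j: int) -> tuple[float, float]:
        out = []
        for p in (self.rna_pair_prob, self.rna_pair_prob_alt):
            v = p(ci, i, cj, j) if p is not None else None
            out.append(0.0 if v is None else float(v))
        return out[0], out[1]


def load_residue_provider_tsv(path) -> ResidueProvider:
    """TSV with columns chain_id, seq_index, then feature values."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    table = {
        (str(row.iloc[0]), int(row.iloc[1])): row.iloc[2:].to_numpy(float)
        for _, row in df.iterrows()
    }
    return lambda c, i: table.get((c, i))


def load_pair_provider_tsv(path):
    """TSV with columns chain_i, i, chain_j, j, then values (symmetric)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    table = {}
    for _, row in df.iterrows():
        key = (str(row.iloc[0]), int(row.iloc[1]), str(row.iloc[2]), int(row.iloc[3]))
        val = row.iloc[4:].to_numpy(float)
        table[key] = val
        table[(key[2], key[3], key[0], key[1])] = val
    return lambda ci, i, cj, j: table.get((ci, i, cj, j))


# ---------------------------------------------------------------------------
# assembly


@dataclass
class Annotations:
    """All internally computed annotations keyed by (chain_id, seq_index)."""

    torsions: dict = field(default_factory=dict)  # protein (phi, psi)
    pseudotorsions: dict = field(default_factory=dict)  # RNA (eta, theta)
    secondary_structure: dict = field(default_factory=dict)  # 8-state char
    rsa: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)
    pair_flags: dict = field(default_factory=dict)  # (canonical, noncanonical)
    elements: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    interface: dict = field(default_factory=dict)


def annotate(structure: ComplexStructure, sasa_points: int = 100) -> Annotations:
    """Run every internal annotator once over a structure."""
    ann = Annotations()
    ann.rsa = relative_solvent_accessibility(structure, n_points=sasa_points)
    ann.pairs = annotate_rna_pairs(structure)
    for a, b, canonical in ann.pairs:
        for key in (a, b):
            flags = ann.pair_flags.get(key, [False, False])
            flags[0] = flags[0] or canonical
            flags[1] = flags[1] or not canonical
            ann.pair_flags[key] = flags
    iface = interface_residues(structure)
    for flag, res in zip(iface, structure.residues()):
        ann.interface[(res.chain_id, res.seq_index)] = bool(flag)
    for chain in structure.chains:
        keys = [(r.chain_id, r.seq_index) for r in chain.residues]
        if chain.polymer_type is PolymerType.PROTEIN:
            for key, tor in zip(keys, backbone_torsions(chain.residues)):
                ann.torsions[key] = tor
            ss = assign_secondary_structure(chain.residues)
            for key, s in zip(keys, ss):
                ann.secondary_structure[key] = s
        else:
            for key, tor in zip(keys, rna_pseudotorsions(chain.residues)):
                ann.pseudotorsions[key] = tor
            for key, lab in zip(keys, rna_elements(ann.pairs, chain.residues)):
                ann.elements[key] = lab
    for res in structure.residues():
        ann.geometry[(res.chain_id, res.seq_index)] = geometry_features(structure, res)
    return ann


def _sincos(angle_deg: float | None) -> tuple[float, float]:
    if angle_deg is None:
        return 0.0, 0.0
    rad = np.radians(angle_deg)
    return float(np.sin(rad)), float(np.cos(rad))


def node_features(
    structure: ComplexStructure,
    annotations: Annotations | None = None,
    providers: ProviderSet | None = None,
    layout: FeatureLayout = DEFAULT_LAYOUT,
    residues: list[Residue] | None = None,
) -> np.ndarray:
    """N x 66 node feature matrix following the layout."""
    if annotations is None:
        annotations = annotate(structure)
    if providers is None:
        providers = ProviderSet()
    if residues is None:
        residues = list(structure.residues())
    mat = np.zeros((len(residues), layout.node_width))
    for k, res in enumerate(residues):
        key = (res.chain_id, res.seq_index)
        row = mat[k]
        if res.polymer_type is PolymerType.PROTEIN:
            idx = _AA_INDEX.get(res.name)
            if idx is not None:
                row[layout.node_slice("aa_onehot")][idx] = 1.0
            else:
                row[layout.node_slice("unknown_residue")] = 1.0
            row[layout.node_slice("polymer_flag")] = 1.0
        else:
            idx = _NT_INDEX.get(res.name)
            if idx is not None:
                row[layout.node_slice("nt_onehot")][idx] = 1.0
            else:
                row[layout.node_slice("unknown_residue")] = 1.0
        row[layout.node_slice("interface_flag")] = float(annotations.interface.get(key, False))
        d1, a1, d2, a2 = annotations.geometry.get(key, (0.0, 0.0, 0.0, 0.0))
        row[layout.node_slice("com_geometry")] = [
            min(d1, NODE_DIST_SCALE) / NODE_DIST_SCALE,
            a1 / 180.0,
            min(d2, NODE_DIST_SCALE) / NODE_DIST_SCALE,
            a2 / 180.0,
        ]
        row[layout.node_slice("rsa")] = annotations.rsa.get(key, 0.0)
        valid = row[layout.node_slice("torsion_valid")]
        if res.polymer_type is PolymerType.PROTEIN:
            ss = annotations.secondary_structure.get(key, "-")
            row[layout.node_slice("ss8_onehot")][SS8_STATES.index(ss)] = 1.0
            phi, psi = annotations.torsions.get(key, (None, None))
            row[layout.node_slice("protein_torsions")] = [*_sincos(phi), *_sincos(psi)]
            valid[0] = float(phi is not None and psi is not None)
            if providers.protein_residue is not None:
                vec = providers.protein_residue(*key)
                if vec is not None:
                    vec = np.asarray(vec, float)
                    row[layout.node_slice("pred_ss3")] = vec[:3]
                    row[layout.node_slice("pred_rsa")] = vec[3]
                    row[layout.node_slice("pred_torsions")] = vec[4:8]
        else:
            eta, theta = annotations.pseudotorsions.get(key, (None, None))
            row[layout.node_slice("rna_pseudotorsions")] = [*_sincos(eta), *_sincos(theta)]
            valid[1] = float(eta is not None and theta is not None)
            canonical, noncanon = annotations.pair_flags.get(key, (False, False))
            row[layout.node_slice("rna_pair_flags")] = [
                float(canonical),
                float(noncanon),
                float(canonical or noncanon),
            ]
            elem = annotations.elements.get(key)
            if elem is not None:
                row[layout.node_slice("rna_element")][RNA_ELEMENTS.index(elem)] = 1.0
    if not np.all(np.isfinite(mat)):
        raise ValueError("node features contain non-finite values")
    return mat


def edge_features(
    structure: ComplexStructure,
    arcs: np.ndarray,
    residues: list[Residue],
    annotations: Annotations | None = None,
    providers: ProviderSet | None = None,
    layout: FeatureLayout = DEFAULT_LAYOUT,
) -> np.ndarray:
    """(n_arcs) x 12 edge feature matrix aligned with ``arcs``."""
    if annotations is None:
        annotations = annotate(structure)
    if providers is None:
        providers = ProviderSet()
    paired = {
        frozenset((a, b)) for a, b, _ in annotations.pairs
    }
    mat = np.zeros((len(arcs), layout.edge_width))
    anchors = [anchor_atom(r).coord for r in residues]
    orients = [_orientation_vector(r) for r in residues]
    heavy = [r.heavy_coords() for r in residues]
    for k, (i, j) in enumerate(arcs):
        ri, rj = residues[i], residues[j]
        row = mat[k]
        dmin = cdist(heavy[i], heavy[j]).min()
        danc = np.linalg.norm(anchors[i] - anchors[j])
        # canonical endpoint order keeps arc (i,j) and (j,i) features equal
        lo, hi = (i, j) if i < j else (j, i)
        axis = anchors[hi] - anchors[lo]
        a_i = angle_between(orients[lo], axis) if orients[lo] is not None else 0.0
        a_j = angle_between(orients[hi], -axis) if orients[hi] is not None else 0.0
        row[layout.edge_slice("min_atom_dist")] = min(dmin, EDGE_DIST_SCALE) / EDGE_DIST_SCALE
        row[layout.edge_slice("anchor_dist")] = min(danc, EDGE_DIST_SCALE) / EDGE_DIST_SCALE
        row[layout.edge_slice("orientation_angles")] = [a_i / 180.0, a_j / 180.0]
        key_i = (ri.chain_id, ri.seq_index)
        key_j = (rj.chain_id, rj.seq_index)
        both_protein = (
            ri.polymer_type is PolymerType.PROTEIN and rj.polymer_type is PolymerType.PROTEIN
        )
        both_rna = ri.polymer_type is PolymerType.RNA and rj.polymer_type is PolymerType.RNA
        if both_protein and providers.protein_pair is not None:
            vec = providers.protein_pair(*key_i, *key_j)
            if vec is not None:
                vec = np.asarray(vec, float)
                row[layout.edge_slice("pred_protein_pair")] = [
                    min(vec[0], EDGE_DIST_SCALE) / EDGE_DIST_SCALE,
                    vec[1] / 180.0,
                    vec[2] / 180.0,
                ]
        if both_rna:
            row[layout.edge_slice("rna_pair_annotated")] = float(
                frozenset((key_i, key_j)) in paired
            )
            row[layout.edge_slice("rna_pair_prob")] = providers.pair_probabilities(
                *key_i, *key_j
            )
        row[layout.edge_slice("inter_chain")] = float(ri.chain_id != rj.chain_id)
        row[layout.edge_slice("protein_rna")] = float(ri.polymer_type is not rj.polymer_type)
    if not np.all(np.isfinite(mat)):
        raise ValueError("edge features contain non-finite values")
    return mat


def featurize(
    structure: ComplexStructure,
    providers: ProviderSet | None = None,
    layout: FeatureLayout = DEFAULT_LAYOUT,
    anchor_cutoff: float | None = None,
    atom_cutoff: float | None = None,
) -> ComplexGraph:
    """Build the residue graph and fill node/edge feature matrices."""
    kwargs = {}
    if anchor_cutoff is not None:
        kwargs["anchor_cutoff"] = anchor_cutoff
    if atom_cutoff is not None:
        kwargs["atom_cutoff"] = atom_cutoff
    graph = build_graph(structure, **kwargs)
    ann = annotate(structure)
    graph.node_feat = node_features(structure, ann, providers, layout, graph.residues)
    graph.edge_feat = edge_features(structure, graph.arcs, graph.residues, ann, providers, layout)
    return graph
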