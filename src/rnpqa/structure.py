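"""Parsing and in-memory representation of protein-RNA complex structures.

A complex is held as an ordered list of chains, each typed as protein or RNA
by majority vote over its residue names. Coordinates are numpy float64 in
Angstroms. Waters, ions and other non-polymer residues are dropped at parse
time; alternate locations are resolved to the highest-occupancy conformer
(ties broken by file order). Hydrogens are kept in the atom lists but every
distance/mass computation in the package uses heavy atoms only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "PolymerType",
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "UnsupportedPolymerError",
    "MissingAnchorError",
    "read_structure",
    "write_pdb",
    "classify_chain",
    "anchor_atom",
    "center_of_mass",
    "STANDARD_AMINO_ACIDS",
    "STANDARD_RIBONUCLEOTIDES",
    "DEFAULT_ALIASES",
]


class StructureError(Exception):
    """Base class for structure parsing/validation problems."""


class FormatError(StructureError):
    """File could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """No polymer chains survived parsing."""


class UnsupportedPolymerError(StructureError):
    """Chain is neither protein nor RNA (e.g. DNA or unknown majority)."""


class MissingAnchorError(StructureError):
    """Residue lacks its anchor atom even after fallback."""


class PolymerType(Enum):
    PROTEIN = "protein"
    RNA = "rna"


STANDARD_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

STANDARD_RIBONUCLEOTIDES = ["A", "C", "G", "U"]

_DNA_NAMES = {"DA", "DC", "DG", "DT", "DI", "DU"}

#: Common modified-residue aliases mapped to their parent standard residue.
DEFAULT_ALIASES: dict[str, str] = {
    "MSE": "MET",
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "PSU": "U",
    "5MC": "C",
    "1MA": "A",
    "7MG": "G",
    "OMG": "G",
    "OMC": "C",
    "OMU": "U",
    "2MG": "G",
    "M2G": "G",
    "H2U": "U",
    "4SU": "U",
    "5MU": "U",
    "I": "A",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Standard atomic masses for heavy elements common in biomolecules.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "MG": 24.305, "MN": 54.938, "FE": 55.845,
    "ZN": 65.38, "NA": 22.990, "K": 39.098, "CA": 40.078,
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise StructureError("atom name must be nonempty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinate must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    name: str
    atoms: list[Atom]
    polymer_type: PolymerType | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.chain_id}/{self.seq_index} {self.name}: needs >=1 atom"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()], dtype=float)


@dataclass
class Chain:
    chain_id: str
    polymer_type: PolymerType
    residues: list[Residue] = field(default_factory=list)


@dataclass
class ComplexStructure:
    chains: list[Chain]
    source_path: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in {self.source_path!r}")

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type is PolymerType.PROTEIN]

    def rna_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type is PolymerType.RNA]

    def has_both_polymers(self) -> bool:
        return bool(self.protein_chains()) and bool(self.rna_chains())


def classify_chain(
    residues: Sequence[Residue] | Sequence[str],
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
) -> PolymerType:
    """Type a chain by majority vote over residue names.

    Accepts residues or bare residue-name strings. DNA chains and chains whose
    majority is neither standard amino acid nor A/C/G/U raise
    :class:`UnsupportedPolymerError`; so do exact protein/RNA ties.
    """
    if len(residues) == 0:
        raise StructureError("cannot classify an empty chain")
    names = [r if isinstance(r, str) else r.name for r in residues]
    names = [aliases.get(n, n) for n in names]
    n_aa = sum(n in STANDARD_AMINO_ACIDS for n in names)
    n_rna = sum(n in STANDARD_RIBONUCLEOTIDES for n in names)
    n_dna = sum(n in _DNA_NAMES for n in names)
    n = len(names)
    if n_dna * 2 > n:
        raise UnsupportedPolymerError("DNA chains are not supported")
    if n_aa * 2 > n and n_aa > n_rna:
        return PolymerType.PROTEIN
    if n_rna * 2 > n and n_rna > n_aa:
        return PolymerType.RNA
    raise UnsupportedPolymerError(
        f"chain majority is neither protein nor RNA (aa={n_aa}, rna={n_rna}, n={n})"
    )


def anchor_atom(residue: Residue) -> Atom:
    """Representative atom used in coarse distance rules.

    Protein: C-beta, falling back to C-alpha for glycine or when the side
    chain is absent. RNA: C3'.
    """
    if residue.polymer_type is PolymerType.RNA:
        a = residue.atom("C3'") or residue.atom("C3*")
        if a is None:
            raise MissingAnchorError(
                f"RNA residue {residue.chain_id}/{residue.seq_index} lacks C3'"
            )
        return a
    a = residue.atom("CB")
    if a is None or residue.name == "GLY":
        a = residue.atom("CA")
    if a is None:
        raise MissingAnchorError(
            f"residue {residue.chain_id}/{residue.seq_index} lacks CB and CA"
        )
    return a


def center_of_mass(atoms: Sequence[Atom]) -> np.ndarray:
    """Mass-weighted mean of heavy-atom coordinates (hydrogens ignored)."""
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        raise StructureError("center_of_mass: no heavy atoms")
    masses = np.array([ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in heavy])
    coords = np.array([a.coord for a in heavy])
    return masses @ coords / masses.sum()


def _resolve_altlocs(atom_records: list[tuple[str, str, str, np.ndarray, float]]):
    """Keep, per atom name, the highest-occupancy altloc (ties: file order)."""
    best: dict[str, tuple[float, int]] = {}
    out = {}
    for i, (name, altloc, element, coord, occ) in enumerate(atom_records):
        key = name
        if key not in best or occ > best[key][0]:
            best[key] = (occ, i)
            out[key] = Atom(name=name, element=element, coord=coord, occupancy=occ)
    return list(out.values())


def read_structure(
    path: str | Path,
    format: str = "auto",
    aliases: Mapping[str, str] = DEFAULT_ALIASES,
) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Waters and non-polymer residues are excluded; chains are typed by
    majority vote after alias mapping. DNA chains raise
    :class:`UnsupportedPolymerError`; a file with no polymer residues raises
    :class:`EmptyStructureError`.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip()
            if name in _WATER_NAMES:
                continue
            mapped = aliases.get(name, name)
            if (
                mapped not in STANDARD_AMINO_ACIDS
                and mapped not in STANDARD_RIBONUCLEOTIDES
                and mapped not in _DNA_NAMES
            ):
                continue  # ligand/ion/unknown heterogen
            records = [
                (
                    a.name.strip(),
                    a.altloc or "",
                    a.element.name if a.element else "",
                    np.array([a.pos.x, a.pos.y, a.pos.z]),
                    a.occ,
                )
                for a in gres
            ]
            atoms = _resolve_altlocs(records)
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_index=gres.seqid.num,  # keep author numbering for model/reference correspondence
                    name=mapped,
                    atoms=atoms,
                )
            )
        if not residues:
            continue
        ptype = classify_chain(residues, aliases)
        for r in residues:
            r.polymer_type = ptype
        chains.append(Chain(chain_id=gchain.name, polymer_type=ptype, residues=residues))

    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chains")
    return ComplexStructure(chains=chains, source_path=str(path))


_RNA_ONE_TO_PDB = {n: n for n in STANDARD_RIBONUCLEOTIDES}


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a structure as a minimal standard PDB file."""
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            resname = res.name if len(res.name) <= 3 else res.name[:3]
            for atom in res.atoms:
                name = atom.name
                # PDB column convention: 1-char elements start in column 14
                if len(name) < 4 and len(atom.element) <= 1:
                    name = " " + name
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain.chain_id[:1]}"
                    f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def rigid_transform(
    structure: ComplexStructure, rotation: np.ndarray, translation: np.ndarray
) -> ComplexStructure:
    """Return a copy with every coordinate mapped to R x + t."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    chains = []
    for chain in structure.chains:
        residues = []
        for res in chain.residues:
            atoms = [
                Atom(a.name, a.element, rotation @ a.coord + translation, a.occupancy)
                for a in res.atoms
            ]
            residues.append(
                Residue(res.chain_id, res.seq_index, res.name, atoms, res.polymer_type)
            )
        chains.append(Chain(chain.chain_id, chain.polymer_type, residues))
    return ComplexStructure(chains=chains, source_path=structure.source_path)
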