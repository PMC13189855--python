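"""Ground-truth quality scores of a model against a reference structure.

Global fold: backbone lDDT and single-superposition GDT-TS/GDT-HA
approximations. Global interface: interface lDDT (inter-chain atom pairs
only), interface contact score (F1 over inter-chain residue contacts) and
interface patch similarity (Jaccard over interface residue sets). Per
protein-RNA interface: ICS and IPS restricted to one chain pair. iRMSD is
the RMSD of reference-defined interface backbone atoms after optimal
superposition of those atoms; it is evaluation-only, never a training
target.

Undefined values (e.g. no inter-chain reference contacts) are returned as
NaN; downstream losses mask them. Residues correspond between model and
reference by (chain_id, seq_index), atoms by name — the CASP convention of
identical chain labeling is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .graph import enumerate_interfaces
from .structure import ComplexStructure, PolymerType, Residue, anchor_atom

__all__ = [
    "GroundTruthBundle",
    "kabsch_superpose",
    "lddt",
    "ilddt",
    "ics",
    "ips",
    "irmsd",
    "gdt_approx",
    "truth_bundle",
    "PROTEIN_BACKBONE",
    "RNA_BACKBONE",
]

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
RNA_BACKBONE = ("P", "C3'", "C4'", "O3'", "O5'")

DEFAULT_LDDT_RADIUS = 15.0
DEFAULT_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
DEFAULT_ICS_CUTOFF = 5.0
DEFAULT_IRMSD_CUTOFF = 10.0
GDT_TS_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class GroundTruthBundle:
    """All ground-truth scores for one model/reference pair.

    Similarity scores are in [0, 1] (NaN when undefined); irmsd is in
    Angstroms. ``per_interface`` is aligned with
    ``enumerate_interfaces(reference)``.
    """

    bb_lddt: float
    gdt_ts_approx: float
    gdt_ha_approx: float
    ilddt: float
    ics: float
    ips: float
    irmsd: float
    per_interface: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    gdt_is_approximate: bool = True

    def masks(self) -> dict[str, bool]:
        """True where the corresponding score is defined."""
        return {
            "bb_lddt": np.isfinite(self.bb_lddt),
            "gdt_ts": np.isfinite(self.gdt_ts_approx),
            "gdt_ha": np.isfinite(self.gdt_ha_approx),
            "ilddt": np.isfinite(self.ilddt),
            "ips": np.isfinite(self.ips),
            "ics": np.isfinite(self.ics),
        }


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) mapping ``moving`` onto ``fixed``: R @ x + t.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("paired (n,3) coordinate sets required")
    if len(moving) < 3:
        raise ValueError("superposition needs n >= 3 points")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_f - rot @ mu_m
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


def _residue_index(structure: ComplexStructure) -> dict[tuple[str, int], Residue]:
    return {(r.chain_id, r.seq_index): r for r in structure.residues()}


def _backbone_names(residue: Residue):
    return PROTEIN_BACKBONE if residue.polymer_type is PolymerType.PROTEIN else RNA_BACKBONE


def _paired_backbone_atoms(model: ComplexStructure, reference: ComplexStructure):
    """Backbone atoms present in both structures, with residue bookkeeping.

    Returns (model_coords, ref_coords, res_keys, chain_ids) aligned arrays.
    """
    m_idx = _residue_index(model)
    mc, rc, keys, chains = [], [], [], []
    for rres in reference.residues():
        key = (rres.chain_id, rres.seq_index)
        mres = m_idx.get(key)
        if mres is None:
            continue
        for name in _backbone_names(rres):
            ra, ma = rres.atom(name), mres.atom(name)
            if ra is None or ma is None:
                continue
            rc.append(ra.coord)
            mc.append(ma.coord)
            keys.append(key)
            chains.append(rres.chain_id)
    return (
        np.array(mc, float).reshape(-1, 3),
        np.array(rc, float).reshape(-1, 3),
        keys,
        chains,
    )


def _lddt_from_pairs(model_xyz, ref_xyz, pair_mask, thresholds) -> float:
    dr = cdist(ref_xyz, ref_xyz)
    dm = cdist(model_xyz, model_xyz)
    iu = np.triu_indices(len(ref_xyz), k=1)
    sel = pair_mask[iu]
    if not np.any(sel):
        return float("nan")
    delta = np.abs(dm[iu][sel] - dr[iu][sel])
    return float(np.mean([(delta < t).mean() for t in thresholds]))


def lddt(
    model: ComplexStructure,
    reference: ComplexStructure,
    inclusion_radius: float = DEFAULT_LDDT_RADIUS,
    thresholds=DEFAULT_LDDT_THRESHOLDS,
) -> float:
    """Superposition-free backbone lDDT of model against reference."""
    mc, rc, keys, _ = _paired_backbone_atoms(model, reference)
    if len(rc) == 0:
        return float("nan")
    dr = cdist(rc, rc)
    same_res = np.array(
        [[k1 == k2 for k2 in keys] for k1 in keys]
    )
    mask = (dr <= inclusion_radius) & ~same_res
    return _lddt_from_pairs(mc, rc, mask, thresholds)


def ilddt(
    model: ComplexStructure,
    reference: ComplexStructure,
    inclusion_radius: float = DEFAULT_LDDT_RADIUS,
    thresholds=DEFAULT_LDDT_THRESHOLDS,
) -> float:
    """Interface lDDT: as lddt but only atom pairs on different chains."""
    mc, rc, keys, chains = _paired_backbone_atoms(model, reference)
    if len(rc) == 0:
        return float("nan")
    dr = cdist(rc, rc)
    chains = np.array(chains)
    diff_chain = chains[:, None] != chains[None, :]
    mask = (dr <= inclusion_radius) & diff_chain
    return _lddt_from_pairs(mc, rc, mask, thresholds)


def _interchain_contacts(
    structure: ComplexStructure,
    cutoff: float,
    restrict: tuple[str, str] | None = None,
    keys_allowed: set | None = None,
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    residues = [
        r
        for r in structure.residues()
        if keys_allowed is None or (r.chain_id, r.seq_index) in keys_allowed
    ]
    out = set()
    for i, ri in enumerate(residues):
        ci = ri.heavy_coords()
        for rj in residues[i + 1 :]:
            if ri.chain_id == rj.chain_id:
                continue
            if restrict is not None and {ri.chain_id, rj.chain_id} != set(restrict):
                continue
            if cdist(ci, rj.heavy_coords()).min() <= cutoff:
                a, b = (ri.chain_id, ri.seq_index), (rj.chain_id, rj.seq_index)
                out.add((a, b) if a <= b else (b, a))
    return out


def ics(
    model: ComplexStructure,
    reference: ComplexStructure,
    contact_cutoff: float = DEFAULT_ICS_CUTOFF,
    restrict: tuple[str, str] | None = None,
) -> float:
    """Interface contact score: F1 between inter-chain residue contact sets."""
    common = set(_residue_index(model)) & set(_residue_index(reference))
    ref_contacts = _interchain_contacts(reference, contact_cutoff, restrict, common)
    if not ref_contacts:
        return float("nan")
    mod_contacts = _interchain_contacts(model, contact_cutoff, restrict, common)
    tp = len(ref_contacts & mod_contacts)
    fp = len(mod_contacts - ref_contacts)
    fn = len(ref_contacts - mod_contacts)
    if tp == 0:
        return 0.0
    return float(2 * tp / (2 * tp + fp + fn))


def _interface_residue_set(
    structure: ComplexStructure,
    cutoff: float,
    restrict: tuple[str, str] | None,
    keys_allowed: set | None,
) -> set[tuple[str, int]]:
    residues = [
        r
        for r in structure.residues()
        if keys_allowed is None or (r.chain_id, r.seq_index) in keys_allowed
    ]
    out: set[tuple[str, int]] = set()
    for i, ri in enumerate(residues):
        ci = ri.heavy_coords()
        for rj in residues[i + 1 :]:
            if ri.polymer_type is rj.polymer_type:
                continue
            if restrict is not None and {ri.chain_id, rj.chain_id} != set(restrict):
                continue
            if cdist(ci, rj.heavy_coords()).min() <= cutoff:
                out.add((ri.chain_id, ri.seq_index))
                out.add((rj.chain_id, rj.seq_index))
    return out


def ips(
    model: ComplexStructure,
    reference: ComplexStructure,
    interface_cutoff: float = 6.0,
    restrict: tuple[str, str] | None = None,
) -> float:
    """Interface patch similarity: Jaccard index of interface residue sets."""
    common = set(_residue_index(model)) & set(_residue_index(reference))
    ref_set = _interface_residue_set(reference, interface_cutoff, restrict, common)
    mod_set = _interface_residue_set(model, interface_cutoff, restrict, common)
    union = ref_set | mod_set
    if not union:
        return float("nan")
    return float(len(ref_set & mod_set) / len(union))


def irmsd(
    model: ComplexStructure,
    reference: ComplexStructure,
    interface_cutoff: float = DEFAULT_IRMSD_CUTOFF,
) -> float:
    """Interface RMSD over reference-defined interface backbone atoms.

    Interface residues come from the REFERENCE (any heavy atom within
    ``interface_cutoff`` of an opposite-polymer chain); their shared
    backbone atoms are optimally superposed and the RMSD reported.
    """
    iface_keys = _interface_residue_set(reference, interface_cutoff, None, None)
    m_idx = _residue_index(model)
    mc, rc = [], []
    for rres in reference.residues():
        key = (rres.chain_id, rres.seq_index)
        if key not in iface_keys:
            continue
        mres = m_idx.get(key)
        if mres is None:
            continue
        for name in _backbone_names(rres):
            ra, ma = rres.atom(name), mres.atom(name)
            if ra is not None and ma is not None:
                rc.append(ra.coord)
                mc.append(ma.coord)
    if len(mc) < 3:
        raise ValueError("fewer than 3 interface backbone atoms")
    _, _, rmsd = kabsch_superpose(np.array(mc), np.array(rc))
    return rmsd


def gdt_approx(
    model: ComplexStructure,
    reference: ComplexStructure,
    thresholds_ts=GDT_TS_THRESHOLDS,
    thresholds_ha=GDT_HA_THRESHOLDS,
) -> tuple[float, float]:
    """Single-superposition GDT-TS/GDT-HA approximation on anchor atoms.

    One global least-squares superposition of all corresponding anchors; the
    full iterative multi-seed GDT search is deliberately not performed, so
    these values are lower bounds of the exact GDT and are labeled
    approximate throughout the package.
    """
    m_idx = _residue_index(model)
    mc, rc = [], []
    for rres in reference.residues():
        mres = m_idx.get((rres.chain_id, rres.seq_index))
        if mres is None:
            continue
        try:
            ra, ma = anchor_atom(rres), anchor_atom(mres)
        except Exception:
            continue
        rc.append(ra.coord)
        mc.append(ma.coord)
    if len(mc) < 3:
        raise ValueError("fewer than 3 anchor correspondences")
    mc = np.array(mc)
    rc = np.array(rc)
    rot, trans, _ = kabsch_superpose(mc, rc)
    moved = mc @ rot.T + trans
    dist = np.linalg.norm(moved - rc, axis=1)
    ts = float(np.mean([(dist <= t).mean() for t in thresholds_ts]))
    ha = float(np.mean([(dist <= t).mean() for t in thresholds_ha]))
    return ts, ha


def truth_bundle(model: ComplexStructure, reference: ComplexStructure) -> GroundTruthBundle:
    """All global and per-interface ground-truth scores for one model."""
    ts, ha = gdt_approx(model, reference)
    per = []
    for iface in enumerate_interfaces(reference):
        per.append(
            (
                iface,
                ics(model, reference, restrict=iface),
                ips(model, reference, restrict=iface),
            )
        )
    return GroundTruthBundle(
        bb_lddt=lddt(model, reference),
        gdt_ts_approx=ts,
        gdt_ha_approx=ha,
        ilddt=ilddt(model, reference),
        ics=ics(model, reference),
        ips=ips(model, reference),
        irmsd=irmsd(model, reference),
        per_interface=per,
    )
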