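"""Brute-force reference implementations used as independent oracles.

Every function here deliberately avoids spatial indexing, vectorized
shortcuts and code sharing with the package: plain double loops over
residues/atoms, so agreement is meaningful.
"""

import numpy as np

from rnpqa.structure import PolymerType

PROTEIN_BB = ("N", "CA", "C", "O")
RNA_BB = ("P", "C3'", "C4'", "O3'", "O5'")


def _heavy(res):
    return [a for a in res.atoms if a.element.upper() not in ("H", "D")]


def _min_dist(res_a, res_b):
    best = np.inf
    for a in _heavy(res_a):
        for b in _heavy(res_b):
            d = np.linalg.norm(a.coord - b.coord)
            best = min(best, d)
    return best


def brute_edges(residues, anchor_coords, anchor_cutoff, atom_cutoff):
    edges = set()
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(anchor_coords[i] - anchor_coords[j]) <= anchor_cutoff:
                edges.add((i, j))
            elif _min_dist(residues[i], residues[j]) <= atom_cutoff:
                edges.add((i, j))
    return edges


def brute_interface_flags(residues, cutoff):
    n = len(residues)
    flags = [False] * n
    for i in range(n):
        for j in range(n):
            if i == j or residues[i].polymer_type is residues[j].polymer_type:
                continue
            if _min_dist(residues[i], residues[j]) <= cutoff:
                flags[i] = True
    return flags


def _bb_names(res):
    return PROTEIN_BB if res.polymer_type is PolymerType.PROTEIN else RNA_BB


def _paired_atoms(model, reference):
    m_idx = {(r.chain_id, r.seq_index): r for r in model.residues()}
    rows = []
    for rres in reference.residues():
        mres = m_idx.get((rres.chain_id, rres.seq_index))
        if mres is None:
            continue
        for name in _bb_names(rres):
            ra = next((a for a in rres.atoms if a.name == name), None)
            ma = next((a for a in mres.atoms if a.name == name), None)
            if ra is not None and ma is not None:
                rows.append(
                    ((rres.chain_id, rres.seq_index), rres.chain_id, ma.coord, ra.coord)
                )
    return rows


def brute_lddt(model, reference, radius=15.0, thresholds=(0.5, 1, 2, 4), interface_only=False):
    rows = brute_paired = _paired_atoms(model, reference)
    kept = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            key_i, chain_i, m_i, r_i = rows[i]
            key_j, chain_j, m_j, r_j = rows[j]
            if key_i == key_j:
                continue
            if interface_only and chain_i == chain_j:
                continue
            dr = np.linalg.norm(r_i - r_j)
            if dr > radius:
                continue
            dm = np.linalg.norm(m_i - m_j)
            kept.append(abs(dm - dr))
    if not kept:
        return float("nan")
    fracs = []
    for t in thresholds:
        fracs.append(sum(1 for d in kept if d < t) / len(kept))
    return sum(fracs) / len(fracs)


def brute_contacts(structure, cutoff, keys_allowed):
    out = set()
    residues = [
        r for r in structure.residues() if (r.chain_id, r.seq_index) in keys_allowed
    ]
    for i, ri in enumerate(residues):
        for rj in residues[i + 1 :]:
            if ri.chain_id == rj.chain_id:
                continue
            if _min_dist(ri, rj) <= cutoff:
                a = (ri.chain_id, ri.seq_index)
                b = (rj.chain_id, rj.seq_index)
                out.add((a, b) if a <= b else (b, a))
    return out


def brute_ics(model, reference, cutoff=5.0):
    common = {(r.chain_id, r.seq_index) for r in model.residues()} & {
        (r.chain_id, r.seq_index) for r in reference.residues()
    }
    ref_c = brute_contacts(reference, cutoff, common)
    if not ref_c:
        return float("nan")
    mod_c = brute_contacts(model, cutoff, common)
    tp = len(ref_c & mod_c)
    if tp == 0:
        return 0.0
    prec = tp / len(mod_c)
    rec = tp / len(ref_c)
    return 2 * prec * rec / (prec + rec)


def brute_iface_set(structure, cutoff, keys_allowed):
    out = set()
    residues = [
        r for r in structure.residues() if (r.chain_id, r.seq_index) in keys_allowed
    ]
    for ri in residues:
        for rj in residues:
            if ri is rj or ri.polymer_type is rj.polymer_type:
                continue
            if _min_dist(ri, rj) <= cutoff:
                out.add((ri.chain_id, ri.seq_index))
    return out


def brute_ips(model, reference, cutoff=6.0):
    common = {(r.chain_id, r.seq_index) for r in model.residues()} & {
        (r.chain_id, r.seq_index) for r in reference.residues()
    }
    ref_s = brute_iface_set(reference, cutoff, common)
    mod_s = brute_iface_set(model, cutoff, common)
    union = ref_s | mod_s
    if not union:
        return float("nan")
    return len(ref_s & mod_s) / len(union)


def brute_irmsd(model, reference, cutoff=10.0):
    """Oracle superposition via scipy Rotation.align_vectors (independent
    of the package's Kabsch implementation)."""
    from scipy.spatial.transform import Rotation

    common = {(r.chain_id, r.seq_index) for r in model.residues()} & {
        (r.chain_id, r.seq_index) for r in reference.residues()
    }
    iface = brute_iface_set(reference, cutoff, common)
    rows = [row for row in _paired_atoms(model, reference) if row[0] in iface]
    mc = np.array([r[2] for r in rows])
    rc = np.array([r[3] for r in rows])
    mc_c = mc - mc.mean(axis=0)
    rc_c = rc - rc.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc_c, mc_c)
    moved = rot.apply(mc_c)
    return float(np.sqrt(np.mean(np.sum((moved - rc_c) ** 2, axis=1))))


def brute_deal(labels, k, seed):
    """Independent re-implementation of stratified dealing."""
    import numpy as np

    rng = np.random.default_rng(seed)
    sizes = [0] * k
    assignment = {}
    clans, seqs = {}, {}
    for cid in sorted(labels):
        clan, seq = labels[cid]
        (clans.setdefault(clan, []) if clan is not None else seqs.setdefault(seq, [])).append(cid)
    strata = [clans[c] for c in sorted(clans)] + [seqs[s] for s in sorted(seqs)]
    for members in strata:
        members = list(members)
        rng.shuffle(members)
        for cid in members:
            fold = min(range(k), key=lambda f: (sizes[f], f))
            assignment[cid] = fold
            sizes[fold] += 1
    return assignment
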