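import numpy as np
import pytest

from rnpqa.decoygen import _build_protein_helix, _build_rna_strand, make_aform_duplex
from rnpqa.features import (
    DEFAULT_LAYOUT,
    FeatureLayout,
    ProviderSet,
    annotate,
    annotate_rna_pairs,
    assign_secondary_structure,
    backbone_torsions,
    edge_features,
    featurize,
    geometry_features,
    node_features,
    relative_solvent_accessibility,
    rna_elements,
    rna_pseudotorsions,
    shrake_rupley_sasa,
)
from rnpqa.geometry import rotation_matrix
from rnpqa.structure import (
    Atom,
    Chain,
    ComplexStructure,
    PolymerType,
    Residue,
    rigid_transform,
)


class TestLayout:
    def test_default_widths(self):
        assert DEFAULT_LAYOUT.node_width == 66
        assert DEFAULT_LAYOUT.edge_width == 12

    def test_blocks_contiguous_and_nonoverlapping(self):
        for blocks, getter, width in (
            (DEFAULT_LAYOUT.node_blocks, DEFAULT_LAYOUT.node_slice, 66),
            (DEFAULT_LAYOUT.edge_blocks, DEFAULT_LAYOUT.edge_slice, 12),
        ):
            covered = []
            for name, _ in blocks:
                s = getter(name)
                covered.extend(range(s.start, s.stop))
            assert covered == list(range(width))

    def test_bad_layout_rejected(self):
        with pytest.raises(ValueError):
            FeatureLayout(node_blocks=(("a", 10),))

    def test_json_round_trip(self):
        back = FeatureLayout.from_json(DEFAULT_LAYOUT.to_json())
        assert back == DEFAULT_LAYOUT


class TestTorsions:
    def test_helix_round_trip(self):
        # chain constructed from phi=-57 psi=-47; recovery is the oracle
        chain = _build_protein_helix(["ALA"] * 8)
        tors = backbone_torsions(chain.residues)
        for phi, psi in tors[1:-1]:
            assert phi == pytest.approx(-57.0, abs=1e-6)
            assert psi == pytest.approx(-47.0, abs=1e-6)
        assert tors[0][0] is None and tors[-1][1] is None

    def test_single_residue_chain_undefined(self):
        chain = _build_protein_helix(["ALA"])
        assert backbone_torsions(chain.residues) == [(None, None)]

    def test_missing_backbone_atom_flags_neighbors(self):
        chain = _build_protein_helix(["ALA"] * 5)
        chain.residues[2].atoms = [a for a in chain.residues[2].atoms if a.name != "N"]
        tors = backbone_torsions(chain.residues)
        assert tors[2] == (None, None)
        assert tors[1][1] is None  # psi of the previous residue needs N(i+1)

    def test_rna_pseudotorsions_constant_on_ideal_strand(self):
        chain = _build_rna_strand("AAAAAA")
        tors = rna_pseudotorsions(chain.residues)
        interior = tors[1:-1]
        etas = [t[0] for t in interior]
        thetas = [t[1] for t in interior]
        assert np.ptp(etas) < 1e-6 and np.ptp(thetas) < 1e-6
        assert tors[0] == (None, None) and tors[-1] == (None, None)

    def test_rna_pseudotorsions_rotation_invariant(self):
        chain = _build_rna_strand("ACGUA")
        st = ComplexStructure(chains=[chain], source_path="<s>")
        moved = rigid_transform(st, rotation_matrix([1, 1, 0], 63.0), np.array([5, -2, 1.0]))
        a = rna_pseudotorsions(chain.residues)
        b = rna_pseudotorsions(moved.chains[0].residues)
        for (e1, t1), (e2, t2) in zip(a[1:-1], b[1:-1]):
            assert e1 == pytest.approx(e2, abs=1e-6)
            assert t1 == pytest.approx(t2, abs=1e-6)

    def test_two_residue_strand_all_undefined(self):
        chain = _build_rna_strand("AU")
        assert rna_pseudotorsions(chain.residues) == [(None, None)] * 2


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self):
        chain = _build_protein_helix(["ALA"] * 12)
        ss = assign_secondary_structure(chain.residues)
        assert set(ss[2:-2]) == {"H"}

    def test_short_chain_is_coil(self):
        chain = _build_protein_helix(["ALA"] * 3)
        assert assign_secondary_structure(chain.residues) == "---"

    def test_extended_chain_has_no_helix_or_strand(self):
        # build a fully extended conformation: no hydrogen-bond partners
        from rnpqa.decoygen import _PHI, _PSI
        import rnpqa.decoygen as dg

        orig_phi, orig_psi = dg._PHI, dg._PSI
        dg._PHI, dg._PSI = -180.0, 180.0
        try:
            chain = _build_protein_helix(["ALA"] * 8)
        finally:
            dg._PHI, dg._PSI = orig_phi, orig_psi
        ss = assign_secondary_structure(chain.residues)
        assert set(ss) <= {"-", "S"}


class TestSolventAccessibility:
    def test_isolated_residue_fully_exposed(self):
        chain = _build_protein_helix(["ALA"])
        st = ComplexStructure(chains=[chain], source_path="<one>")
        rsa = relative_solvent_accessibility(st)
        assert rsa[("A", 1)] > 0.9

    def test_caged_residue_buried(self):
        # enclose a single atom residue in a tight synthetic cage of atoms
        from rnpqa.features import _fibonacci_sphere

        center = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))], PolymerType.PROTEIN)
        cage_atoms = [
            Atom("CA", "C", 3.0 * p) for p in _fibonacci_sphere(150)
        ]
        cage = Residue("A", 2, "GLY", cage_atoms, PolymerType.PROTEIN)
        st = ComplexStructure(
            chains=[Chain("A", PolymerType.PROTEIN, [center, cage])], source_path="<cage>"
        )
        sasa = shrake_rupley_sasa(st)
        assert sasa[("A", 1)] < 1.0

    def test_sphere_point_convergence(self, toy_complex):
        r100 = relative_solvent_accessibility(toy_complex, n_points=100)
        r200 = relative_solvent_accessibility(toy_complex, n_points=200)
        diffs = [abs(r100[k] - r200[k]) for k in r100]
        assert max(diffs) < 0.05


class TestRnaPairs:
    def test_duplex_watson_crick_recovery(self):
        c1, c2 = make_aform_duplex(6, seed=2)
        st = ComplexStructure(chains=[c1, c2], source_path="<dup>")
        pairs = annotate_rna_pairs(st)
        canonical = {
            frozenset((a, b)) for a, b, c in pairs if c
        }
        expected = {
            frozenset(((c1.chain_id, i + 1), (c2.chain_id, 6 - i))) for i in range(6)
        }
        assert expected <= canonical

    def test_single_strand_has_no_pairs(self):
        st = ComplexStructure(chains=[_build_rna_strand("ACGUACGU")], source_path="<ss>")
        assert annotate_rna_pairs(st) == []

    def test_atom_order_invariance(self):
        c1, c2 = make_aform_duplex(4, seed=3)
        st = ComplexStructure(chains=[c1, c2], source_path="<dup>")
        ref = annotate_rna_pairs(st)
        rng = np.random.default_rng(0)
        for chain in st.chains:
            for res in chain.residues:
                rng.shuffle(res.atoms)
        assert sorted(map(str, annotate_rna_pairs(st))) == sorted(map(str, ref))


class TestRnaElements:
    def _chain(self, n):
        return [
            Residue("Q", i + 1, "A", [Atom("C1'", "C", np.array([float(i), 0, 0]))],
                    PolymerType.RNA)
            for i in range(n)
        ]

    def test_hairpin_decomposition(self):
        res = self._chain(14)
        pairs = [(("Q", i), ("Q", 13 - i), True) for i in range(1, 5)]
        labels = rna_elements(pairs, res)
        assert labels[:4] == ["stem"] * 4
        assert labels[4:8] == ["hairpin"] * 4
        assert labels[8:12] == ["stem"] * 4
        assert labels[12:] == ["exterior"] * 2

    def test_unpaired_strand_is_exterior(self):
        assert rna_elements([], self._chain(5)) == ["exterior"] * 5

    def test_bulge_between_stems_is_interior(self):
        # pairs (1,12),(2,11) then bulge 3, then (4,10),(5,9)
        res = self._chain(12)
        pairs = [
            (("Q", 1), ("Q", 12), True),
            (("Q", 2), ("Q", 11), True),
            (("Q", 4), ("Q", 10), True),
            (("Q", 5), ("Q", 9), True),
        ]
        labels = rna_elements(pairs, res)
        assert labels[2] == "interior"
        assert labels[5:8] == ["hairpin"] * 3

    def test_crossing_pairs_reduced_to_max_nested_subset(self):
        res = self._chain(8)
        # (1,5) crosses (3,7); plus nested (2,4) under (1,5)
        pairs = [
            (("Q", 1), ("Q", 5), True),
            (("Q", 3), ("Q", 7), True),
            (("Q", 2), ("Q", 4), True),
        ]
        labels = rna_elements(pairs, res)
        assert labels.count("stem") == 4  # max non-crossing keeps two pairs


class TestGeometryFeatures:
    def test_rigid_invariance(self, toy_complex):
        res = toy_complex.chains[0].residues[3]
        before = geometry_features(toy_complex, res)
        moved = rigid_transform(
            toy_complex, rotation_matrix([3, 1, 2], 77.0), np.array([10.0, -5.0, 2.0])
        )
        after = geometry_features(moved, moved.chains[0].residues[3])
        np.testing.assert_allclose(before, after, atol=1e-6)

    def test_orthogonal_construction_gives_90_degrees(self):
        # anchor at origin, orientation along +x, COM along +y
        res = Residue(
            "A", 1, "ALA",
            [Atom("CA", "C", np.zeros(3)), Atom("CB", "C", np.array([1.0, 0, 0]))],
            PolymerType.PROTEIN,
        )
        heavy = Residue(
            "A", 2, "GLY", [Atom("CA", "C", np.array([1.0, 100.0, 0.0]))], PolymerType.PROTEIN
        )
        st = ComplexStructure(
            chains=[Chain("A", PolymerType.PROTEIN, [res, heavy])], source_path="<orth>"
        )
        d1, a1, d2, a2 = geometry_features(st, res)
        com_dir_angle = a1
        # CB direction (1,0,0) vs anchor->COM: COM is dominated by the heavy
        # residue at (1, 100, 0) => angle close to 90 degrees
        assert com_dir_angle == pytest.approx(90.0, abs=1.0)


class TestFeatureMatrices:
    def test_node_matrix_shape_and_onehots(self, toy_complex, toy_graph):
        nf = toy_graph.node_feat
        assert nf.shape[1] == 66
        aa = nf[:, DEFAULT_LAYOUT.node_slice("aa_onehot")]
        nt = nf[:, DEFAULT_LAYOUT.node_slice("nt_onehot")]
        assert ((aa.sum(axis=1) <= 1) & (nt.sum(axis=1) <= 1)).all()
        # every protein node has exactly one aa one-hot; rna nodes exactly one nt
        prot = toy_graph.polymer_flags == 1.0
        assert (aa[prot].sum(axis=1) == 1).all()
        assert (nt[~prot].sum(axis=1) == 1).all()
        assert np.isfinite(nf).all()

    def test_providerless_predicted_blocks_zero(self, toy_graph):
        nf = toy_graph.node_feat
        for blk in ("pred_ss3", "pred_rsa", "pred_torsions"):
            assert not nf[:, DEFAULT_LAYOUT.node_slice(blk)].any()
        ef = toy_graph.edge_feat
        assert not ef[:, DEFAULT_LAYOUT.edge_slice("pred_protein_pair")].any()

    def test_edge_indicator_channels(self, toy_complex, toy_graph):
        ef = toy_graph.edge_feat
        inter = ef[:, DEFAULT_LAYOUT.edge_slice("inter_chain")].ravel()
        prna = ef[:, DEFAULT_LAYOUT.edge_slice("protein_rna")].ravel()
        for k, (i, j) in enumerate(toy_graph.arcs):
            ri, rj = toy_graph.residues[i], toy_graph.residues[j]
            assert inter[k] == float(ri.chain_id != rj.chain_id)
            assert prna[k] == float(ri.polymer_type is not rj.polymer_type)

    def test_features_rigid_invariant(self, toy_complex):
        g1 = featurize(toy_complex)
        moved = rigid_transform(
            toy_complex, rotation_matrix([1, 4, 2], 33.0), np.array([7.0, 1.0, -9.0])
        )
        g2 = featurize(moved)
        rsa = DEFAULT_LAYOUT.node_slice("rsa")
        exact = np.ones(66, dtype=bool)
        exact[rsa] = False
        np.testing.assert_allclose(g1.node_feat[:, exact], g2.node_feat[:, exact], atol=1e-6)
        # Shrake-Rupley quadrature uses a fixed sphere orientation; its
        # discretization error bounds the RSA change under rotation
        np.testing.assert_allclose(g1.node_feat[:, rsa], g2.node_feat[:, rsa], atol=0.05)
        np.testing.assert_allclose(g1.edge_feat, g2.edge_feat, atol=1e-6)

    def test_single_residue_chains_no_nan(self):
        prot = _build_protein_helix(["GLY"])
        rna = _build_rna_strand("A", "R")
        # place them in contact
        shift = prot.residues[0].atoms[0].coord - rna.residues[0].atoms[0].coord + 3.0
        for a in rna.residues[0].atoms:
            a.coord = a.coord + shift
        st = ComplexStructure(chains=[prot, rna], source_path="<tiny>")
        g = featurize(st)
        assert np.isfinite(g.node_feat).all()
        assert np.isfinite(g.edge_feat).all()

    def test_provider_channels_filled_from_tsv(self, toy_complex, tmp_path):
        from rnpqa.features import load_residue_provider_tsv

        path = tmp_path / "prov.tsv"
        rows = ["chain\tseq\tss_h\tss_e\tss_c\trsa\tps\tpc\tqs\tqc"]
        for res in toy_complex.chains[0].residues:
            rows.append(f"A\t{res.seq_index}\t1\t0\t0\t0.5\t0.1\t0.2\t0.3\t0.4")
        path.write_text("\n".join(rows) + "\n")
        providers = ProviderSet(protein_residue=load_residue_provider_tsv(path))
        nf = node_features(toy_complex, providers=providers)
        prot_rows = nf[: len(toy_complex.chains[0].residues)]
        assert (prot_rows[:, DEFAULT_LAYOUT.node_slice("pred_ss3")][:, 0] == 1).all()
        assert (prot_rows[:, DEFAULT_LAYOUT.node_slice("pred_rsa")] == 0.5).all()
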