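"""Pose geometry: connectivity, hydroxyl detection, orientation counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ugtcap.errors import GeometryError
from ugtcap.geometry import (
    BindingSiteSpec,
    GlycosidicReference,
    classify_hydroxyl_orientation,
    classify_udpga_binding,
    count_orientations,
    default_orientation_cutoff,
    find_hydroxyl_oxygens,
    infer_connectivity,
    locate_glycosidic_midpoint,
    min_hydroxyl_distance,
)
from ugtcap.simulate import (
    SUBSTRATE_TEMPLATES,
    PoseFixtureSpec,
    generate_pose_fixture,
    make_receptor_stub,
    make_udpga_pose,
)
from ugtcap.structures import Atom, Pose, PoseSet, ReceptorStructure


def _pose(spec, bonds=None):
    """spec: list of (element, xyz)."""
    atoms = [
        Atom(serial=i + 1, name=f"{e}{i + 1}", element=e, residue_name="LIG",
             residue_number=1, chain="A", position=np.asarray(p, float))
        for i, (e, p) in enumerate(spec)
    ]
    return Pose(atoms=atoms, pose_index=1, bonds=bonds or [])


class TestConnectivity:
    def test_oh_bond_detected(self):
        pose = _pose([("O", (0, 0, 0)), ("H", (0, 0, 0.97))])
        assert infer_connectivity(pose) == [(0, 1)]

    def test_distant_carbons_unbonded(self):
        pose = _pose([("C", (0, 0, 0)), ("C", (3.0, 0, 0))])
        assert infer_connectivity(pose) == []

    def test_water_like_two_bonds(self):
        pose = _pose(
            [("O", (0, 0, 0)), ("H", (0.96, 0, 0)), ("H", (-0.24, 0.93, 0))]
        )
        assert infer_connectivity(pose) == [(0, 1), (0, 2)]

    def test_unknown_element_raises(self):
        pose = _pose([("Xx", (0, 0, 0)), ("C", (1.5, 0, 0))])
        with pytest.raises(GeometryError, match="Xx"):
            infer_connectivity(pose)

    def test_explicit_bonds_override_inference(self):
        pose = _pose(
            [("C", (0, 0, 0)), ("C", (1.5, 0, 0))], bonds=[(1, 0)]
        )
        assert infer_connectivity(pose) == [(0, 1)]

    def test_matches_rdkit_on_phenol(self):
        """Covalent-radius inference reproduces RDKit's bond graph."""
        Chem = pytest.importorskip("rdkit.Chem")
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1O"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        conf = mol.GetConformer()
        spec = [
            (atom.GetSymbol(), tuple(conf.GetAtomPosition(atom.GetIdx())))
            for atom in mol.GetAtoms()
        ]
        pose = _pose(spec)
        expected = sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mol.GetBonds()
        )
        assert infer_connectivity(pose) == expected


class TestHydroxylDetection:
    def test_acetaminophen_like_single_phenol(self):
        elements, coords, oxy = SUBSTRATE_TEMPLATES["aap-like"]()
        pose = _pose(list(zip(elements, coords)))
        # brute-force oracle: enumerate oxygen neighborhoods directly
        assert find_hydroxyl_oxygens(pose) == oxy

    def test_estradiol_like_two_hydroxyls(self):
        elements, coords, oxy = SUBSTRATE_TEMPLATES["e2-like"]()
        pose = _pose(list(zip(elements, coords)))
        assert find_hydroxyl_oxygens(pose) == sorted(oxy)

    def test_carboxylic_oh_counts_carbonyl_does_not(self):
        elements, coords, oxy = SUBSTRATE_TEMPLATES["carboxyl-like"]()
        pose = _pose(list(zip(elements, coords)))
        assert find_hydroxyl_oxygens(pose) == oxy  # only the O-H oxygen

    def test_ether_oxygens_excluded(self):
        pose = _pose(
            [("C", (0, 0, 0)), ("O", (1.4, 0, 0)), ("C", (2.8, 0, 0))]
        )
        assert find_hydroxyl_oxygens(pose) == []

    def test_hydrogen_free_terminal_oxygen_qualifies(self):
        pose = _pose([("C", (0, 0, 0)), ("O", (1.4, 0, 0))])
        assert find_hydroxyl_oxygens(pose) == [1]


class TestGlycosidicMidpoint:
    def test_toy_midpoint_is_arithmetic_mean(self):
        pose = _pose(
            [("C", (0, 0, 0)), ("O", (1, 0, 0)), ("P", (2, 0, 0)),
             ("O", (-0.7, 1.2, 0))],
            bonds=[(0, 1), (1, 2), (0, 3)],
        )
        ref = locate_glycosidic_midpoint(pose)
        np.testing.assert_allclose(ref.midpoint, [0.5, 0, 0])
        assert (ref.carbon_index, ref.oxygen_index) == (0, 1)

    def test_no_phosphorus_is_zero_candidates(self):
        pose = _pose(
            [("C", (0, 0, 0)), ("O", (1.4, 0, 0)), ("O", (-0.7, 1.2, 0))],
            bonds=[(0, 1), (0, 2)],
        )
        with pytest.raises(GeometryError, match="found 0"):
            locate_glycosidic_midpoint(pose)

    def test_two_bridges_is_two_candidates(self):
        pose = _pose(
            [("C", (0, 0, 0)), ("O", (1, 0, 0)), ("P", (2, 0, 0)),
             ("O", (-0.7, 1.2, 0)),
             ("C", (10, 0, 0)), ("O", (11, 0, 0)), ("P", (12, 0, 0)),
             ("O", (9.3, 1.2, 0))],
            bonds=[(0, 1), (1, 2), (0, 3), (4, 5), (5, 6), (4, 7)],
        )
        with pytest.raises(GeometryError, match="found 2"):
            locate_glycosidic_midpoint(pose)

    def test_synthetic_udpga_has_unique_bridge(self):
        pose, expected = make_udpga_pose()
        ref = locate_glycosidic_midpoint(pose)
        np.testing.assert_allclose(ref.midpoint, expected.midpoint)


class TestOrientation:
    reference = GlycosidicReference(
        carbon_index=0, oxygen_index=1, midpoint=np.zeros(3)
    )

    def _substrate_at(self, d):
        return _pose([("C", (d + 1.4, 0, 0)), ("O", (d, 0, 0)),
                      ("H", (d, 0, 0.97))])

    @pytest.mark.parametrize(
        "distance,expected",
        [(3.70, True), (3.90, False), (3.80, True)],  # inclusive boundary
    )
    def test_cutoff_boundary(self, distance, expected):
        pose = self._substrate_at(distance)
        assert classify_hydroxyl_orientation(pose, self.reference) is expected

    def test_no_hydroxyl_is_an_error(self):
        pose = _pose([("C", (0, 0, 0)), ("O", (1.4, 0, 0)),
                      ("C", (2.8, 0, 0))])
        with pytest.raises(GeometryError, match="no conjugatable hydroxyl"):
            classify_hydroxyl_orientation(pose, self.reference)

    def test_default_cutoff_arithmetic(self):
        assert default_orientation_cutoff() == pytest.approx(3.8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("template", ["aap-like", "e2-like"])
    def test_counts_match_brute_force_oracle(self, seed, template):
        """count_orientations equals an independent all-distances scan."""
        spec = PoseFixtureSpec(
            n_poses=40, frac_oriented=0.35, seed=seed,
            substrate_template=template,
        )
        _, labels, pose_set, reference = generate_pose_fixture(spec)
        s_dh, s_dt = count_orientations(pose_set, reference, spec.cutoff)
        # oracle: brute force over every hydroxyl oxygen of every pose
        brute = 0
        for pose in pose_set.poses:
            ds = [
                np.linalg.norm(a.position - reference.midpoint)
                for i, a in enumerate(pose.atoms)
                if i in find_hydroxyl_oxygens(pose)
            ]
            brute += min(ds) <= spec.cutoff
        assert (s_dh, s_dt) == (brute, 40)
        assert s_dh == int(labels["oriented"].sum())

    def test_sdh_monotone_in_cutoff(self):
        spec = PoseFixtureSpec(n_poses=50, frac_oriented=0.4, seed=4)
        _, _, pose_set, reference = generate_pose_fixture(spec)
        counts = [
            count_orientations(pose_set, reference, c)[0]
            for c in (2.0, 3.0, 3.8, 5.0, 12.0)
        ]
        assert counts == sorted(counts)
        assert 0 <= counts[0] and counts[-1] <= len(pose_set)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        """One rotation+translation of everything changes no classification."""
        rng = np.random.default_rng(seed)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-50, 50, size=3)
        spec = PoseFixtureSpec(n_poses=10, frac_oriented=0.5, seed=seed % 7)
        _, _, pose_set, reference = generate_pose_fixture(spec)
        moved_poses = []
        for pose in pose_set.poses:
            atoms = [
                Atom(serial=a.serial, name=a.name, element=a.element,
                     residue_name=a.residue_name,
                     residue_number=a.residue_number, chain=a.chain,
                     position=q @ a.position + t)
                for a in pose.atoms
            ]
            moved_poses.append(Pose(atoms=atoms, pose_index=pose.pose_index))
        moved_set = PoseSet(ligand_id=pose_set.ligand_id, poses=moved_poses)
        moved_ref = GlycosidicReference(
            carbon_index=reference.carbon_index,
            oxygen_index=reference.oxygen_index,
            midpoint=q @ reference.midpoint + t,
        )
        for before, after in zip(pose_set.poses, moved_set.poses):
            d0 = min_hydroxyl_distance(before, reference)
            d1 = min_hydroxyl_distance(after, moved_ref)
            assert d1 == pytest.approx(d0, abs=1e-6)


class TestUdpgaBinding:
    def test_ligand_in_site_contacts_all_seven(self):
        pose, reference = make_udpga_pose()
        receptor = make_receptor_stub(around=reference.midpoint,
                                      contact_distance=3.0)
        ok, contacted = classify_udpga_binding(pose, receptor)
        assert ok and len(contacted) == 7

    def test_far_ligand_contacts_nothing(self):
        pose, reference = make_udpga_pose()
        receptor = make_receptor_stub(around=reference.midpoint + 100.0)
        ok, contacted = classify_udpga_binding(pose, receptor)
        assert not ok and contacted == []

    def test_quorum_of_four_fails_min_contacts_five(self):
        pose, reference = make_udpga_pose()
        receptor = make_receptor_stub(around=reference.midpoint)
        # push three residues out of reach
        far = {355, 376, 377}
        for atom in receptor.atoms:
            if atom.residue_number in far:
                atom.position = atom.position + 100.0
        ok, contacted = classify_udpga_binding(
            pose, receptor, BindingSiteSpec(min_contacts=5)
        )
        assert not ok and len(contacted) == 4

    def test_missing_site_residue_is_error(self):
        pose, reference = make_udpga_pose()
        receptor = make_receptor_stub(around=reference.midpoint)
        kept = [a for a in receptor.atoms if a.residue_number != 173]
        with pytest.raises(GeometryError, match="173"):
            classify_udpga_binding(pose, ReceptorStructure(atoms=kept))

    def test_mutated_residue_name_warns_not_errors(self):
        pose, reference = make_udpga_pose()
        receptor = make_receptor_stub(around=reference.midpoint)
        for atom in receptor.atoms:
            if atom.residue_number == 376:
                atom.residue_name = "ARG"  # H376R-like site mutation
        with pytest.warns(UserWarning, match="376"):
            ok, contacted = classify_udpga_binding(pose, receptor)
        assert ok and (376, "ARG") in contacted
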