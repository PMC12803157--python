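import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from denngap import structure
from denngap.structure import (
    Atom,
    ComplexModel,
    InterfaceSet,
    StrandAnnotation,
    StructureError,
    compare_surfaces,
    detect_arginine_finger,
    in_interstrand_loop,
    interface_residues,
    kabsch,
    match_residues,
    read_strand_annotation,
    read_structure,
    superpose,
    transform_model,
    transplant_ligand,
    write_structure,
)
from denngap.synthetic import ToyComplexSpec, make_toy_complex


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, altloc=" ", record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
    )


class TestReadStructure:
    def test_single_atom(self):
        model = read_structure(_pdb_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0))
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz == pytest.approx((1.0, 2.0, 3.0))

    def test_altloc_b_dropped(self):
        text = "\n".join(
            [
                _pdb_line(1, "CA", "SER", "A", 1, 0, 0, 0, altloc="A"),
                _pdb_line(2, "CA", "SER", "A", 1, 5, 5, 5, altloc="B"),
            ]
        )
        model = read_structure(text)
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz == pytest.approx((0, 0, 0))

    def test_no_atoms_is_an_error(self):
        with pytest.raises(StructureError, match="no ATOM"):
            read_structure("REMARK nothing here\n")

    def test_toy_fixture_roundtrips(self):
        _, model_text = make_toy_complex()
        model = read_structure(model_text)
        again = read_structure(write_structure(model))
        assert [a.xyz for a in again.atoms] == [a.xyz for a in model.atoms]
        assert [a.res_name for a in again.atoms] == [a.res_name for a in model.atoms]


class TestMatchResidues:
    def test_identical_sequences_map_identically(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        assert match_residues(seq, seq) == [(i, i) for i in range(40)]

    def test_leading_deletion_offsets_pairs(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        pairs = match_residues(seq, seq[5:])
        assert pairs == [(i + 5, i) for i in range(35)]

    def test_global_alignment_aligns_end_to_end(self):
        # brute-force check: with gap open -10, aligning AAA/CCC without
        # gaps scores 3*(-4) = -12 > any gapped arrangement
        assert match_residues("AAA", "CCC") == [(0, 0), (1, 1), (2, 2)]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StructureError, match="at least 3"):
            match_residues("AA", "AA")


def _random_points(rng, n=10):
    return rng.normal(size=(n, 3)) * 5.0


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        P = _random_points(rng)
        R, t, rmsd = kabsch(P, P)
        assert rmsd <= 1e-10
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.allclose(t, 0, atol=1e-8)

    def test_recovers_known_transform(self, rng):
        P = _random_points(rng)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T + np.array([0.0, 0.0, 5.0])
        R, t, rmsd = kabsch(P, Q)
        assert rmsd <= 1e-10
        assert np.allclose(R, Rz, atol=1e-8)
        assert np.allclose(t, [0, 0, 5], atol=1e-8)

    def test_rotation_is_proper(self, rng):
        P = _random_points(rng)
        Q = -P  # tempts a reflection
        R, _, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_noisy_rmsd_matches_noise_scale(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(40, 3)) * 8.0
        Q = P + rng.normal(scale=0.1, size=P.shape)
        _, _, rmsd = kabsch(P, Q)
        assert 0.10 <= rmsd <= 0.20

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(StructureError, match="degenerate"):
            kabsch(P, P + 1.0)

    def test_agrees_with_scipy_align_vectors(self, rng):
        P = _random_points(rng, 15)
        Q = _random_points(rng, 15)
        R, t, rmsd = kabsch(P, Q)
        rot, ssd = Rotation.align_vectors(
            Q - Q.mean(0), P - P.mean(0)
        )
        assert np.allclose(R, rot.as_matrix(), atol=1e-6)

    def test_beats_random_rigid_transforms(self, rng):
        # optimality: no random rigid motion does better than Kabsch
        P = _random_points(rng)
        Q = _random_points(rng)
        _, _, best = kabsch(P, Q)
        for _ in range(1000):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-10, 10, 3)
            rmsd = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
            assert rmsd >= best - 1e-9


class TestSuperposeAndTransplant:
    def test_reference_onto_exact_rigid_copy(self, toy_complex):
        ref, _ = toy_complex
        rng = np.random.default_rng(4)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-15, 15, 3)
        moved = transform_model(ref, R, t)
        sup = superpose(ref, moved, None, "G", "G")
        assert sup.rmsd <= 1e-6
        assert np.allclose(sup.rotation, R, atol=1e-8)

    def test_transplanted_pg_follows_transform(self, toy_complex):
        ref, _ = toy_complex
        rng = np.random.default_rng(5)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-15, 15, 3)
        moved = transform_model(ref, R, t)
        sup = superpose(ref, moved, None, "G", "G")
        lig = transplant_ligand(ref, sup)
        pg_ref = next(a for a in ref.het_atoms("GTP") if a.atom_name == "PG")
        pg_placed = dict(lig.atoms)["PG"]
        assert np.allclose(pg_placed, R @ np.asarray(pg_ref.xyz) + t, atol=1e-8)

    def test_missing_gamma_phosphorus_rejected(self, toy_complex):
        ref, _ = toy_complex
        stripped = ComplexModel(
            atoms=[a for a in ref.atoms if a.atom_name != "PG"]
        )
        sup = superpose(ref, ref, None, "G", "G")
        with pytest.raises(StructureError, match="PG"):
            transplant_ligand(stripped, sup)

    def test_partial_gamma_set_tolerated(self, toy_complex):
        ref, _ = toy_complex
        no_o3g = ComplexModel(atoms=[a for a in ref.atoms if a.atom_name != "O3G"])
        sup = superpose(no_o3g, no_o3g, None, "G", "G")
        lig = transplant_ligand(no_o3g, sup)
        assert {a[0] for a in lig.gamma_atoms} == {"PG", "O1G", "O2G"}


def _finger_setup(toy_complex):
    ref, model = toy_complex
    sup = superpose(ref, model, None, "G", "G")
    return model, transplant_ligand(ref, sup)


class TestDetectArginineFinger:
    def test_planted_residue_is_top_call(self, toy_complex):
        model, lig = _finger_setup(toy_complex)
        calls = detect_arginine_finger(model, lig, "A")
        assert calls[0].res_number == 116
        assert calls[0].passes
        assert calls[0].min_distance == pytest.approx(3.0, abs=0.01)

    def test_chain_without_arginine_yields_no_calls(self, toy_complex):
        model, lig = _finger_setup(toy_complex)
        no_arg = ComplexModel(
            atoms=[a for a in model.atoms if a.res_name != "ARG"]
        )
        assert detect_arginine_finger(no_arg, lig, "A") == []

    def test_cutoff_controls_pass_flag(self, toy_complex):
        model, lig = _finger_setup(toy_complex)
        call = detect_arginine_finger(model, lig, "A", cutoff=2.5)[0]
        assert call.min_distance == pytest.approx(3.0, abs=0.01)
        assert not call.passes

    def test_min_distance_invariant_under_rigid_motion(self, toy_complex):
        ref, model = toy_complex
        base = _finger_distance(ref, model)
        rng = np.random.default_rng(42)
        for _ in range(10):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-30, 30, 3)
            moved = transform_model(model, R, t)
            assert abs(_finger_distance(ref, moved) - base) <= 1e-6


def _finger_distance(ref, model):
    sup = superpose(ref, model, None, "G", "G")
    lig = transplant_ligand(ref, sup)
    return detect_arginine_finger(model, lig, "A")[0].min_distance


def _two_chain_model(offsets):
    """Chain A residues at given distances (x) from a chain-B atom at origin."""
    atoms = [Atom("B", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0))]
    for i, d in enumerate(offsets, start=1):
        atoms.append(Atom("A", i, "ALA", "CA", "C", (float(d), 0.0, 0.0)))
    return ComplexModel(atoms=atoms)


class TestInterfaceAndSurfaces:
    def test_distant_chains_have_empty_interface(self):
        model = _two_chain_model([100.0, 120.0])
        assert interface_residues(model, "A", "B").residue_numbers == frozenset()

    def test_constructed_contacts_detected(self):
        model = _two_chain_model([3.8, 3.8, 10.0, 12.0])
        got = interface_residues(model, "A", "B", cutoff=4.0)
        assert got.residue_numbers == frozenset({1, 2})
        assert interface_residues(model, "A", "B", cutoff=3.5).residue_numbers == frozenset()

    def test_monotone_in_cutoff(self, rng):
        model = _two_chain_model(rng.uniform(2, 8, 20))
        sets = [
            interface_residues(model, "A", "B", cutoff=c).residue_numbers
            for c in (3.5, 4.0, 5.0)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_unknown_chain_rejected(self):
        model = _two_chain_model([3.0])
        with pytest.raises(StructureError, match="not present"):
            interface_residues(model, "A", "C")

    def test_identical_surfaces_are_shared(self):
        a = InterfaceSet("A", frozenset({1, 2, 3}), 4.0)
        res = compare_surfaces(a, a)
        assert res.jaccard == 1.0 and res.classification == "shared"

    def test_disjoint_surfaces_are_distinct(self):
        a = InterfaceSet("A", frozenset({1, 2}), 4.0)
        b = InterfaceSet("A", frozenset({5, 6}), 4.0)
        res = compare_surfaces(a, b)
        assert res.jaccard == 0.0 and res.classification == "distinct"

    def test_partial_overlap_counts(self):
        a = InterfaceSet("A", frozenset(range(1, 11)), 4.0)
        b = InterfaceSet("A", frozenset(range(6, 16)), 4.0)
        res = compare_surfaces(a, b)
        assert res.jaccard == pytest.approx(5 / 15)
        assert res.classification == "overlapping"
        assert compare_surfaces(b, a).jaccard == res.jaccard

    def test_chain_mismatch_rejected(self):
        a = InterfaceSet("A", frozenset({1}), 4.0)
        b = InterfaceSet("B", frozenset({1}), 4.0)
        with pytest.raises(StructureError, match="different chains"):
            compare_surfaces(a, b)


class TestStrandAnnotation:
    ann = StrandAnnotation(strands=(("β4", 100, 110), ("β5", 120, 130)))

    @pytest.mark.parametrize(
        "residue,expected", [(116, True), (110, False), (120, False), (131, False)]
    )
    def test_strictly_between_strands(self, residue, expected):
        assert in_interstrand_loop(self.ann, residue) is expected

    def test_missing_label_is_an_error(self):
        with pytest.raises(StructureError, match="β6"):
            in_interstrand_loop(self.ann, 116, downstream="β6")

    def test_tsv_roundtrip(self):
        ann = read_strand_annotation("β4\t100\t110\nβ5\t120\t130\n")
        assert ann == self.ann

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(StructureError, match="overlaps"):
            StrandAnnotation(strands=(("β4", 100, 110), ("β5", 105, 130)))
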