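import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rxngrow.block_library import PreservedFragment
from rxngrow.chem_core import parse_molecule
from rxngrow.pose_eval import (
    DegenerateGrowthError,
    InteractionTarget,
    Receptor,
    ScoreWeights,
    ScoringError,
    align_to_preserved,
    check_direction,
    generate_conformers,
    group_efficiency,
    refine_pose,
    score_pose,
)

from .oracles import brute_score


@pytest.fixture(scope="module")
def anilide():
    return parse_molecule("CC(=O)Nc1ccccc1")


def _fragment_from_pose(mol, coords, smiles):
    pattern = parse_molecule(smiles)
    tmp = PreservedFragment(
        pattern=pattern, reference_coords=np.zeros((pattern.GetNumAtoms(), 3))
    )
    emb = tmp.embeddings(mol)[0]
    ref = coords[[emb[p] for p in sorted(emb)]]
    return PreservedFragment(pattern=pattern, reference_coords=ref)


class TestConformers:
    def test_k_one(self, anilide):
        assert len(generate_conformers(anilide, k=1, seed=3)) == 1

    def test_deterministic(self, anilide):
        a = generate_conformers(anilide, k=6, seed=11)
        b = generate_conformers(anilide, k=6, seed=11)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.allclose(x, y)

    def test_benzene_planar(self):
        benzene = parse_molecule("c1ccccc1")
        for coords in generate_conformers(benzene, k=5, seed=1):
            centered = coords - coords.mean(axis=0)
            # smallest singular value ~ 0 for a planar ring
            s = np.linalg.svd(centered, compute_uv=False)
            assert s[-1] < 0.1

    def test_inherited_coords_anchor_pose(self, anilide):
        base = generate_conformers(anilide, k=1, seed=5)[0]
        inherited = {i: base[i] for i in range(6)}
        confs = generate_conformers(anilide, k=4, seed=5, inherited_coords=inherited)
        for coords in confs:
            rmsd = np.sqrt(((coords[:6] - base[:6]) ** 2).sum(axis=1).mean())
            assert rmsd < 2.0


class TestAlignment:
    def test_identity_when_posed(self, anilide):
        coords = generate_conformers(anilide, k=1, seed=2)[0]
        frag = _fragment_from_pose(anilide, coords, "c1ccccc1")
        aligned, overlap = align_to_preserved(anilide, coords, frag)
        assert overlap == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(aligned, coords, atol=1e-3)

    def test_restores_translated_pose(self, anilide):
        coords = generate_conformers(anilide, k=1, seed=2)[0]
        frag = _fragment_from_pose(anilide, coords, "c1ccccc1")
        moved = coords + np.array([50.0, -20.0, 7.0])
        aligned, overlap = align_to_preserved(anilide, moved, frag)
        assert overlap == pytest.approx(1.0, abs=1e-6)

    def test_restores_rotated_pose(self, anilide):
        coords = generate_conformers(anilide, k=1, seed=2)[0]
        frag = _fragment_from_pose(anilide, coords, "c1ccccc1")
        rot = Rotation.from_rotvec([0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + 10.0
        aligned, overlap = align_to_preserved(anilide, moved, frag)
        assert overlap == pytest.approx(1.0, abs=1e-5)

    def test_single_atom_fragment(self):
        mol = parse_molecule("CO")
        coords = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]])
        frag = PreservedFragment(
            pattern=parse_molecule("O"), reference_coords=np.array([[5.0, 5.0, 5.0]])
        )
        aligned, overlap = align_to_preserved(mol, coords, frag)
        assert overlap == pytest.approx(1.0, abs=1e-6)

    def test_internal_geometry_unchanged(self, anilide):
        coords = generate_conformers(anilide, k=1, seed=2)[0]
        frag = _fragment_from_pose(anilide, coords, "c1ccccc1")
        moved = coords + 30.0
        aligned, _ = align_to_preserved(anilide, moved, frag)
        d0 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d1 = np.linalg.norm(aligned[:, None] - aligned[None, :], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_missing_fragment_raises(self, anilide):
        coords = generate_conformers(anilide, k=1, seed=2)[0]
        frag = PreservedFragment(
            pattern=parse_molecule("c1ccncc1"), reference_coords=np.zeros((6, 3))
        )
        from rxngrow.chem_core import RxngrowError

        with pytest.raises(RxngrowError):
            align_to_preserved(anilide, coords, frag)


def _simple_receptor(**kw):
    defaults = dict(
        elements=["N"], coords=np.array([[0.0, 0.0, 0.0]]), donors=(0,)
    )
    defaults.update(kw)
    return Receptor(**defaults)


class TestScorer:
    def test_empty_neighborhood_scores_zero(self):
        lig = parse_molecule("CCO")
        coords = generate_conformers(lig, k=1, seed=1)[0]
        rec = _simple_receptor(coords=np.array([[100.0, 0.0, 0.0]]))
        assert score_pose(lig, coords, rec) == 0.0

    def test_single_ideal_hbond(self):
        lig = parse_molecule("CO")
        coords = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]])
        rec = _simple_receptor(coords=np.array([[4.4, 0.0, 0.0]]))
        assert score_pose(lig, coords, rec) == pytest.approx(-1.0)

    def test_missing_coords_raises(self):
        lig = parse_molecule("CCO")
        with pytest.raises(ScoringError):
            score_pose(lig, np.zeros((2, 3)), _simple_receptor())

    def test_matches_brute_force(self, rng, pocket):
        mols = [
            parse_molecule(s)
            for s in ("CCO", "CC(=O)Nc1ccccc1", "CS(=O)(=O)Cl", "Oc1cccc(N)c1Br")
        ]
        weights = ScoreWeights()
        for _ in range(20):
            mol = mols[int(rng.integers(len(mols)))]
            coords = generate_conformers(mol, k=1, seed=int(rng.integers(1000)))[0]
            coords = coords + rng.uniform(-8, 8, 3)
            fast = score_pose(mol, coords, pocket.receptor, weights)
            slow = brute_score(mol, coords, pocket.receptor, weights)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_rigid_motion_invariance(self, pocket):
        mol = parse_molecule("CC(=O)Nc1ccccc1")
        coords = generate_conformers(mol, k=1, seed=9)[0]
        e0 = score_pose(mol, coords, pocket.receptor)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        shift = np.array([3.0, -7.0, 11.0])
        rec2 = Receptor(
            elements=pocket.receptor.elements,
            coords=pocket.receptor.coords @ rot.T + shift,
            donors=pocket.receptor.donors,
            acceptors=pocket.receptor.acceptors,
            hydrophobic=pocket.receptor.hydrophobic,
        )
        e1 = score_pose(mol, coords @ rot.T + shift, rec2)
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_far_separation_scores_zero(self, pocket):
        mol = parse_molecule("CC(=O)Nc1ccccc1")
        coords = generate_conformers(mol, k=1, seed=9)[0]
        span = pocket.receptor.coords.mean(axis=0)
        far = coords - coords.mean(axis=0) + span + 500.0
        assert score_pose(mol, far, pocket.receptor) == 0.0


class TestDirection:
    def _target(self, kind="hydrophobic"):
        return InteractionTarget(
            id="t", anchor=np.array([5.0, 0.0, 0.0]), kind=kind, satisfied_radius=3.0
        )

    def test_strictly_closer_and_compatible(self):
        mol = parse_molecule("CC")
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert check_direction(mol, coords, {1}, self._target(), 4.0)

    def test_grown_away(self):
        mol = parse_molecule("CC")
        coords = np.array([[0.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        assert not check_direction(mol, coords, {1}, self._target(), 4.0)

    def test_equal_distance_fails(self):
        mol = parse_molecule("CC")
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert not check_direction(mol, coords, {1}, self._target(), 4.0)

    def test_type_compatibility(self):
        mol = parse_molecule("CO")
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert check_direction(mol, coords, {1}, self._target("hbond-donor"), 4.0)
        assert not check_direction(mol, coords, {1}, self._target("aromatic"), 4.0)


class TestGroupEfficiency:
    def test_arithmetic(self):
        assert group_efficiency(-7.5, -5.0, 25, 20) == pytest.approx(-0.5)

    def test_no_gain_is_zero(self):
        assert group_efficiency(-5.0, -5.0, 25, 20) == 0.0

    def test_exact_boundary_value(self):
        assert group_efficiency(-5.4, -5.0, 24, 20) == pytest.approx(-0.1)

    def test_degenerate_growth(self):
        with pytest.raises(DegenerateGrowthError):
            group_efficiency(-6.0, -5.0, 20, 20)

    def test_two_routes_agree(self, pocket):
        mol_small = parse_molecule("Oc1cccc(N)c1Br")
        mol_big = parse_molecule("CC(=O)Nc1cccc(O)c1Br")
        cs = generate_conformers(mol_small, k=1, seed=4)[0]
        cb = generate_conformers(mol_big, k=1, seed=4)[0]
        e1 = score_pose(mol_small, cs, pocket.receptor)
        e2 = score_pose(mol_big, cb, pocket.receptor)
        ge = group_efficiency(
            e2, e1, mol_big.GetNumHeavyAtoms(), mol_small.GetNumHeavyAtoms()
        )
        assert ge == pytest.approx((e2 - e1) / 3.0, abs=1e-9)


class TestRefine:
    def test_never_increases_energy(self, pocket):
        mol = parse_molecule("CC(=O)Nc1cccc(O)c1Br")
        for seed in (1, 2, 3):
            coords = generate_conformers(mol, k=1, seed=seed)[0]
            e0 = score_pose(mol, coords, pocket.receptor)
            _, e1 = refine_pose(mol, coords, pocket.receptor)
            assert e1 <= e0 + 1e-12

    def test_deterministic(self, pocket):
        mol = parse_molecule("CC(=O)Nc1cccc(O)c1Br")
        coords = generate_conformers(mol, k=1, seed=8)[0]
        c1, e1 = refine_pose(mol, coords, pocket.receptor)
        c2, e2 = refine_pose(mol, coords, pocket.receptor)
        assert e1 == e2 and np.allclose(c1, c2)

    def test_frozen_atoms_do_not_move(self, pocket):
        mol = parse_molecule("CC(=O)Nc1cccc(O)c1Br")
        coords = generate_conformers(mol, k=1, seed=8)[0]
        frozen = frozenset(range(4, 10))
        c1, _ = refine_pose(
            mol, coords, pocket.receptor, use_rigid=False, frozen=frozen
        )
        assert np.allclose(c1[sorted(frozen)], coords[sorted(frozen)])


class TestReceptorIO:
    def test_json_round_trip(self, pocket):
        back = Receptor.from_json(pocket.receptor.to_json())
        assert back.elements == pocket.receptor.elements
        assert np.allclose(back.coords, pocket.receptor.coords)
        assert back.donors == pocket.receptor.donors

    def test_pdb_reader(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  O   ALA A   1       2.100   1.200   0.000  1.00  0.00           O\n"
            "END\n"
        )
        rec = Receptor.from_pdb(pdb)
        assert rec.elements == ["N", "C", "O"]
        assert rec.donors == (0,) and rec.acceptors == (2,) and rec.hydrophobic == (1,)
        assert rec.residues == ["ALA1", "ALA1", "ALA1"]

    def test_bad_site_index_rejected(self):
        with pytest.raises(ValueError):
            Receptor(elements=["C"], coords=np.zeros((1, 3)), donors=(5,))
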