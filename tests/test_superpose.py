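import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import qtykit as q
from qtykit.structure import StructureError


def rotation_search_rmsd(P, Q, n_seeds=300, n_refine=80, rng_seed=0):
    """Brute-force minimum RMSD over rotations (quaternion search oracle).

    Independent of the SVD route: samples many random rotations, keeps
    the best, then refines it with shrinking random perturbations.  Each
    candidate rotation is scored after optimal translation (centroid
    matching), which is exact for a fixed rotation.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def score(R):
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    rng = np.random.default_rng(rng_seed)
    candidates = Rotation.random(n_seeds, rng).as_matrix()
    best = min(candidates, key=score)
    best_val = score(best)
    angle = 0.5
    for _ in range(n_refine):
        for _ in range(8):
            delta = Rotation.from_rotvec(
                angle * rng.standard_normal(3)
            ).as_matrix()
            cand = delta @ best
            val = score(cand)
            if val < best_val:
                best, best_val = cand, val
        angle *= 0.85
    return best_val


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        res = q.kabsch(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_motion(self):
        P = np.random.default_rng(1).normal(size=(8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T + np.array([5.0, 0.0, 0.0])
        res = q.kabsch(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, Rz, atol=1e-9)
        assert np.allclose(res.transform(P), Q, atol=1e-9)

    def test_mirror_image_stays_proper(self):
        # chiral 4-point set: reflection cannot be reproduced by rotation
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2.0]])
        Q = P * np.array([1, 1, -1.0])
        res = q.kabsch(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1
        assert res.rmsd == pytest.approx(
            rotation_search_rmsd(P, Q), abs=1e-3
        )

    def test_matches_rotation_search_oracle(self):
        """Closed-form result equals brute-force rotation search on 100
        random small point sets."""
        rng = np.random.default_rng(42)
        for i in range(100):
            n = int(rng.integers(3, 7))
            P = rng.normal(size=(n, 3)) * 3
            Q = rng.normal(size=(n, 3)) * 3
            ours = q.kabsch(P, Q).rmsd
            oracle = rotation_search_rmsd(P, Q, rng_seed=i)
            assert ours <= oracle + 1e-9
            assert ours == pytest.approx(oracle, abs=2e-3)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            P = rng.normal(size=(12, 3))
            Q = rng.normal(size=(12, 3))
            ours = q.kabsch(P, Q)
            rot, rssd = Rotation.align_vectors(
                Q - Q.mean(axis=0), P - P.mean(axis=0)
            )
            assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-8)

    def test_rigid_motion_invariance_and_symmetry(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(20, 3))
        Q = rng.normal(size=(20, 3))
        base = q.kabsch(P, Q).rmsd
        M = Rotation.random(1, rng).as_matrix()[0]
        t = rng.normal(size=3) * 10
        assert q.kabsch(P @ M.T + t, Q @ M.T + t).rmsd == pytest.approx(
            base, abs=1e-9
        )
        assert q.kabsch(Q, P).rmsd == pytest.approx(base, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            q.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_still_returns_minimizer(self):
        P = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0], [0, 0, 3.0]])
        Q = P + 1.0
        res = q.kabsch(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)


class TestSuperposeModels:
    def test_self_superposition_is_zero(self, bundle):
        pairing = q.pair_residues(bundle.model, bundle.model)
        res = q.superpose_models(bundle.model, bundle.model, pairing)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_rejected == 0

    def test_cycles_zero_equals_raw_kabsch(self, bundle):
        pert = q.perturb_structure(bundle.model, 0.3, seed=5)
        pairing = q.pair_residues(bundle.model, pert)
        res = q.superpose_models(bundle.model, pert, pairing, cycles=0)
        P = np.array([bundle.model.residue(a).ca.pos for a, _ in pairing.pairs])
        Q = np.array([pert.residue(b).ca.pos for _, b in pairing.pairs])
        assert res.rmsd == pytest.approx(q.kabsch(P, Q).rmsd, abs=1e-12)
        assert res.rmsd_all_pairs is None

    def test_displaced_residue_rejected(self, bundle):
        """One residue thrown 10 Å off is rejected at cutoff 2.0 and the
        refined RMSD returns to the pre-displacement value."""
        pert = q.perturb_structure(bundle.model, 0.2, seed=6)
        pairing = q.pair_residues(bundle.model, pert)
        baseline = q.superpose_models(bundle.model, pert, pairing).rmsd
        res_list = list(pert.residues)
        victim = res_list[40]
        atom = victim.atoms[0]
        moved = q.Residue(
            victim.chain, victim.number, victim.icode, victim.name,
            victim.is_polymer,
            (q.Atom(atom.name, atom.element,
                    tuple(np.asarray(atom.pos) + [10.0, 0, 0])),),
        )
        res_list[40] = moved
        displaced = q.StructureModel(id="disp", residues=tuple(res_list))
        refined = q.superpose_models(
            bundle.model, displaced, pairing, cycles=3, cutoff=2.0
        )
        assert refined.n_rejected == 1
        assert refined.rmsd == pytest.approx(baseline, abs=0.05)
        assert refined.rmsd <= refined.rmsd_all_pairs

    def test_rejection_below_three_pairs_errors(self):
        helix = q.ideal_helix(4)
        residues = tuple(
            q.Residue("A", i + 1, "", "GLY", True,
                      (q.Atom("CA", "C", tuple(xyz)),))
            for i, xyz in enumerate(helix)
        )
        a = q.StructureModel(id="a", residues=residues)
        scattered = q.perturb_structure(a, 30.0, seed=1)
        pairing = q.pair_residues(a, scattered)
        with pytest.raises(StructureError, match="fewer than 3"):
            q.superpose_models(a, scattered, pairing, cycles=5, cutoff=0.01)


class TestApplyTransform:
    def test_identity(self, bundle):
        res = q.SuperpositionResult(
            rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0,
            n_pairs_used=3,
        )
        out = q.apply_transform(bundle.model, res)
        assert np.allclose(out.all_coords(), bundle.model.all_coords())

    def test_translation_shifts_centroid(self, bundle):
        t = np.array([1.0, -2.0, 3.0])
        res = q.SuperpositionResult(
            rotation=np.eye(3), translation=t, rmsd=0.0, n_pairs_used=3
        )
        out = q.apply_transform(bundle.model, res)
        assert np.allclose(
            out.all_coords().mean(axis=0),
            bundle.model.all_coords().mean(axis=0) + t,
        )

    def test_transform_then_inverse_round_trips(self, bundle):
        pert = q.perturb_structure(bundle.model, 1.0, seed=8)
        pairing = q.pair_residues(bundle.model, pert)
        fwd = q.superpose_models(bundle.model, pert, pairing)
        moved = q.apply_transform(bundle.model, fwd)
        inv = q.SuperpositionResult(
            rotation=fwd.rotation.T,
            translation=-fwd.rotation.T @ fwd.translation,
            rmsd=fwd.rmsd,
            n_pairs_used=fwd.n_pairs_used,
        )
        back = q.apply_transform(moved, inv)
        assert np.allclose(
            back.all_coords(), bundle.model.all_coords(), atol=1e-9
        )

    def test_rmsd_reproduced_after_transform(self, bundle):
        pert = q.perturb_structure(bundle.model, 0.5, seed=9)
        pairing = q.pair_residues(bundle.model, pert)
        res = q.superpose_models(bundle.model, pert, pairing)
        moved = q.apply_transform(bundle.model, res)
        d = [
            np.linalg.norm(
                moved.residue(a).ca.xyz - pert.residue(b).ca.xyz
            )
            for a, b in pairing.pairs
        ]
        assert np.sqrt(np.mean(np.square(d))) == pytest.approx(
            res.rmsd, abs=1e-9
        )
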