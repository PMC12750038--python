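import itertools
import math

import numpy as np
import pytest

from conftest import brute_force_valid_permutations, random_ligand
from ligeval.errors import SuperpositionError, UndefinedScoreError
from ligeval.pose import (
    bisy_rmsd,
    find_binding_site,
    kabsch_superpose,
    lddt_core,
    lddt_pli,
    ligand_automorphisms,
    score_target,
    site_metrics,
)
from ligeval.structures import (
    Atom,
    Ligand,
    PredictedEntry,
    ProteinStructure,
    ReferenceComplex,
    Residue,
)
from ligeval.synthetic import get_template, make_complex, perturb_pose


def _rot(axis, deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = math.radians(deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def toy_complex(cb_dists, target_id="TOY"):
    """Two-carbon ligand at the origin; residue i's CB placed at exactly
    cb_dists[i] Angstrom from the nearest ligand atom."""
    lig = Ligand(
        [Atom("C", "C1", np.zeros(3)), Atom("C", "C2", np.array([1.5, 0.0, 0.0]))],
        [(0, 1, 1)],
        "0",
    )
    residues = []
    for i, d in enumerate(cb_dists):
        theta = 2 * math.pi * i / max(len(cb_dists), 3) + 0.3
        u = np.array([0.0, math.cos(theta), math.sin(theta)])
        cb = d * u
        ca = cb + 2.0 * u + np.array([0.1 * i, 0, 0])
        atoms = [
            Atom("N", "N", ca + np.array([-0.9, 1.0, 0.2])),
            Atom("C", "CA", ca),
            Atom("C", "C", ca + np.array([1.0, 0.9, -0.2])),
            Atom("O", "O", ca + np.array([1.4, 2.0, 0.1])),
            Atom("C", "CB", cb),
        ]
        residues.append(Residue("A", i + 1, "ALA", atoms))
    return ReferenceComplex(target_id, ProteinStructure(residues), [lig])


def exact_prediction(ref, group_id=1, model_num=1):
    return PredictedEntry(
        group_id=group_id,
        target_id=ref.target_id,
        model_num=model_num,
        protein=ref.protein,
        ligand_poses=[ref.ligand_instances[0].with_coords(ref.ligand_instances[0].coords(), "m1")],
    )


class TestFindBindingSite:
    def test_cutoff_boundary(self):
        ref = toy_complex([3.9, 4.1, 3.0, 3.5, 3.2])
        site = find_binding_site(ref, ref.ligand_instances[0], cutoff=4.0)
        seqs = {r.seq_num for r in site.residues}
        assert 1 in seqs and 2 not in seqs

    def test_matches_brute_force_scan(self, hybrid_complex):
        ref = hybrid_complex
        instance = ref.ligand_instances[0]
        site = find_binding_site(ref, instance, cutoff=4.0)
        lig_xyz = instance.heavy_coords()
        expected = set()
        for res in ref.protein.residues:
            dmin = min(
                np.linalg.norm(a.pos - q)
                for a in res.atoms if a.is_heavy
                for q in lig_xyz
            )
            if dmin <= 4.0:
                expected.add(res.match_key)
        assert {r.match_key for r in site.residues} == expected
        assert expected  # generator guarantees a non-empty site

    def test_remote_ligand_raises(self):
        ref = toy_complex([3.0, 3.1, 3.2, 3.3])
        far = ref.ligand_instances[0].transformed(np.eye(3), np.array([50.0, 0, 0]))
        with pytest.raises(SuperpositionError):
            find_binding_site(ref, far, cutoff=4.0)


class TestKabsch:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(12, 3))
        mov = ref @ _rot([0, 0, 1], 37.0).T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd, degenerate = kabsch_superpose(ref, mov)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert not degenerate
        assert np.abs(mov @ rot.T + trans - ref).max() < 1e-9

    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd, _ = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3))
        mov = ref * np.array([-1.0, 1.0, 1.0])  # reflection
        rot, _t, _r, _d = kabsch_superpose(ref, mov)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_collinear_flagged(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        _rot_, _t, _r, degenerate = kabsch_superpose(ref, ref + 1.0)
        assert degenerate

    def test_matches_direct_numerical_minimizer(self):
        """Gaussian-jittered points: SVD result equals a generic optimizer's."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        ref = rng.normal(size=(20, 3)) * 3.0
        mov = ref @ _rot([1, 2, 3], 25.0).T + 4.0 + rng.normal(scale=0.1, size=(20, 3))
        _rot_m, _t, rmsd, _d = kabsch_superpose(ref, mov)

        def objective(params):
            r = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = mov @ r.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            (
                minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
                for x0 in (np.zeros(6), np.array([0.1, -0.4, 0.45, -4, -4, -4]))
            ),
            key=lambda r: r.fun,
        )
        assert rmsd <= best.fun + 1e-6
        assert rmsd == pytest.approx(best.fun, abs=1e-4)
        # jitter sigma=0.1: optimal rmsd should be near sigma scale
        assert 0.05 < rmsd < 0.15


class TestAutomorphisms:
    def test_benzene_ring_has_12(self):
        ring = get_template("ring6")
        autos = ligand_automorphisms(ring)
        assert len(autos) == 12
        assert autos == brute_force_valid_permutations(ring)
        assert autos[0] == tuple(range(6))

    def test_asymmetric_tree_identity_only(self):
        bran = get_template("branched")
        autos = ligand_automorphisms(bran)
        assert autos == [tuple(range(5))]

    def test_para_disubstituted_ring_matches_brute_force(self):
        ring = get_template("ring6")
        coords = ring.coords()
        atoms = list(ring.atoms)
        bonds = list(ring.bonds)
        for anchor in (0, 3):  # para substituents
            atoms.append(Atom("O", f"O{anchor}", coords[anchor] * 1.8))
            bonds.append((anchor, len(atoms) - 1, 1))
        para = Ligand(atoms, bonds, "para")
        autos = ligand_automorphisms(para)
        assert autos == brute_force_valid_permutations(para)
        assert len(autos) == 4

    def test_random_ligands_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            lig = random_ligand(rng)
            assert ligand_automorphisms(lig) == brute_force_valid_permutations(lig)


class TestBisyRmsd:
    def test_exact_copy_scores_zero(self, ring_complex):
        pred = exact_prediction(ring_complex)
        res = bisy_rmsd(ring_complex, ring_complex.ligand_instances[0], pred,
                        pred.ligand_poses[0])
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_operation_scores_zero(self, ring_complex):
        pred = perturb_pose(ring_complex, "symmetry_flip", 0, seed=1)
        res = bisy_rmsd(ring_complex, ring_complex.ligand_instances[0], pred,
                        pred.ligand_poses[0])
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_shift_measured_exactly(self, branched_complex):
        pred = perturb_pose(branched_complex, "translate", 3.0, seed=2)
        res = bisy_rmsd(branched_complex, branched_complex.ligand_instances[0],
                        pred, pred.ligand_poses[0])
        assert res.rmsd == pytest.approx(3.0, abs=1e-9)

    def test_never_exceeds_identity_permutation_rmsd(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            lig = random_ligand(rng)
            ref = make_complex(int(rng.integers(2**31)), lig, 8)
            pose = ref.ligand_instances[0].with_coords(
                ref.ligand_instances[0].coords() + rng.normal(scale=0.5, size=(len(lig.atoms), 3))
            )
            pred = PredictedEntry(1, ref.target_id, 1, protein=ref.protein,
                                  ligand_poses=[pose])
            res = bisy_rmsd(ref, ref.ligand_instances[0], pred, pose)
            plain = np.sqrt(np.mean(np.sum(
                (pose.heavy_coords() - ref.ligand_instances[0].heavy_coords()) ** 2, axis=1)))
            assert res.rmsd <= plain + 1e-9


class TestLddtCore:
    def test_perfect_model(self):
        d = np.array([2.0, 3.0, 3.5])
        assert lddt_core(d, d) == 1.0

    def test_all_off_beyond_max_threshold(self):
        d = np.array([2.0, 3.0])
        assert lddt_core(d, d + 10.0) == 0.0

    def test_hand_enumerated_indicator_table(self):
        # deviations {0.3, 1.5, 5.0}, thresholds {0.5,1,2,4}, 1 penalty pair:
        # hits = 4 + 2 + 0 = 6; denominator = 4 * (3 + 1) = 16
        ref = np.array([1.0, 2.0, 3.0])
        model = ref + np.array([0.3, 1.5, 5.0])
        assert lddt_core(ref, model, (0.5, 1, 2, 4), penalty_pairs=1) == pytest.approx(6 / 16)

    def test_zero_reference_pairs_raises(self):
        with pytest.raises(UndefinedScoreError):
            lddt_core(np.array([]), np.array([]))

    def test_missing_counterpart_fails_all_thresholds(self):
        ref = np.array([1.0, 2.0])
        model = np.array([1.0, np.nan])
        assert lddt_core(ref, model) == pytest.approx(0.5)

    def test_penalty_monotonically_decreases_score(self):
        ref = np.linspace(1, 4, 8)
        model = ref + 0.2
        scores = [lddt_core(ref, model, penalty_pairs=k) for k in range(5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            lddt_core(np.array([1.0]), np.array([1.0]), thresholds=(4, 2, 1, 0.5))


class TestLddtPli:
    def test_exact_copy_scores_one(self, ring_complex):
        pred = exact_prediction(ring_complex)
        val = lddt_pli(ring_complex, ring_complex.ligand_instances[0], pred,
                       pred.ligand_poses[0])
        assert val == pytest.approx(1.0)

    def test_pose_in_solvent_scores_zero(self, ring_complex):
        pred = perturb_pose(ring_complex, "rebind_site", 0, seed=1)
        val = lddt_pli(ring_complex, ring_complex.ligand_instances[0], pred,
                       pred.ligand_poses[0])
        assert val == pytest.approx(0.0)

    def test_automorphism_flip_is_score_neutral(self, ring_complex):
        base = perturb_pose(ring_complex, "translate", 0.8, seed=4)
        pose = base.ligand_poses[0]
        autos = ligand_automorphisms(pose)
        flipped = pose.with_coords(pose.coords()[np.array(autos[5])])
        v1 = lddt_pli(ring_complex, ring_complex.ligand_instances[0], base, pose)
        v2 = lddt_pli(ring_complex, ring_complex.ligand_instances[0], base, flipped)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_no_reference_contacts_raises(self):
        ref = toy_complex([8.0, 8.5, 9.0, 9.5])  # all residues outside 4 A
        pred = exact_prediction(ref)
        with pytest.raises(UndefinedScoreError):
            lddt_pli(ref, ref.ligand_instances[0], pred, pred.ligand_poses[0])

    def test_matches_exhaustive_enumeration(self):
        """Independent pure-python recomputation over all pairs and perms."""
        rng = np.random.default_rng(11)
        for trial in range(8):
            lig = random_ligand(rng)
            ref = make_complex(int(rng.integers(2**31)), lig, 8)
            instance = ref.ligand_instances[0]
            pose = instance.with_coords(
                instance.coords() + rng.normal(scale=0.6, size=(len(instance.atoms), 3)))
            pred = PredictedEntry(1, ref.target_id, 1, protein=ref.protein,
                                  ligand_poses=[pose])
            got = lddt_pli(ref, instance, pred, pose)
            assert got == pytest.approx(
                _oracle_lddt_pli(ref, instance, pose), abs=1e-12)


def _oracle_lddt_pli(ref, instance, pose, radius=4.0, thresholds=(0.5, 1, 2, 4)):
    env = [
        (a.pos, (res.match_key, a.name))
        for res in ref.protein.residues for a in res.atoms if a.is_heavy
    ]
    inst_xyz = instance.heavy_coords()
    pose_xyz = pose.heavy_coords()
    best = 0.0
    for perm in brute_force_valid_permutations(instance):
        # pose atom p plays instance atom perm-inverse... map instance l -> pose atom
        inv = {v: k for k, v in enumerate(perm)}
        hits, n_ref, penalty = 0, 0, 0
        for l in range(len(inst_xyz)):
            for e_pos, _eid in env:
                d_ref = float(np.linalg.norm(inst_xyz[l] - e_pos))
                d_mod = float(np.linalg.norm(pose_xyz[inv[l]] - e_pos))
                if d_ref <= radius:
                    n_ref += 1
                    for t in thresholds:
                        if abs(d_mod - d_ref) <= t:
                            hits += 1
                elif d_mod <= radius:
                    penalty += 1
        score = hits / (len(thresholds) * (n_ref + penalty))
        best = max(best, score)
    return best


class TestSiteMetrics:
    def test_identity_prediction(self, hybrid_complex):
        pred = exact_prediction(hybrid_complex)
        bb, lp = site_metrics(hybrid_complex, hybrid_complex.ligand_instances[0], pred)
        assert bb == pytest.approx(0.0, abs=1e-9)
        assert lp == pytest.approx(1.0)

    def test_pure_translation_absorbed_by_superposition(self, hybrid_complex):
        shifted = hybrid_complex.protein.transformed(np.eye(3), np.array([1.0, 0, 0]))
        pred = PredictedEntry(1, hybrid_complex.target_id, 1, protein=shifted,
                              ligand_poses=[hybrid_complex.ligand_instances[0]])
        bb, lp = site_metrics(hybrid_complex, hybrid_complex.ligand_instances[0], pred)
        assert bb == pytest.approx(0.0, abs=1e-9)
        assert lp == pytest.approx(1.0)

    def test_lddt_lp_matches_exhaustive_enumeration(self, hybrid_complex):
        rng = np.random.default_rng(9)
        jittered = []
        for res in hybrid_complex.protein.residues:
            atoms = [Atom(a.element, a.name, a.pos + rng.normal(scale=0.4, size=3))
                     for a in res.atoms]
            jittered.append(Residue(res.chain_id, res.seq_num, res.name, atoms))
        pred = PredictedEntry(1, hybrid_complex.target_id, 1,
                              protein=ProteinStructure(jittered),
                              ligand_poses=[hybrid_complex.ligand_instances[0]])
        _bb, lp = site_metrics(hybrid_complex, hybrid_complex.ligand_instances[0], pred)

        site = find_binding_site(hybrid_complex, hybrid_complex.ligand_instances[0])
        pred_atoms = {(r.match_key, a.name): a.pos
                      for r in jittered for a in r.atoms if a.is_heavy}
        records = site.atom_records
        hits, total = 0, 0
        for i, j in itertools.combinations(range(len(records)), 2):
            (ki, ni, pi), (kj, nj, pj) = records[i], records[j]
            if ki == kj:
                continue
            d_ref = float(np.linalg.norm(pi - pj))
            d_mod = float(np.linalg.norm(pred_atoms[(ki, ni)] - pred_atoms[(kj, nj)]))
            total += 4
            hits += sum(1 for t in (0.5, 1, 2, 4) if abs(d_mod - d_ref) <= t)
        assert lp == pytest.approx(hits / total, abs=1e-12)


class TestScoreTarget:
    def test_identity_prediction_all_metrics(self, ring_complex):
        score = score_target(ring_complex, exact_prediction(ring_complex))
        assert score.rmsd == pytest.approx(0.0, abs=1e-9)
        assert score.lddt_pli == pytest.approx(1.0)
        assert score.bb_rmsd == pytest.approx(0.0, abs=1e-9)
        assert score.lddt_lp == pytest.approx(1.0)

    def test_prediction_matching_second_copy(self):
        ref = make_complex(21, "branched", 8, multi_copy=True)
        copy_b = ref.ligand_instances[1]
        pred = PredictedEntry(1, ref.target_id, 1, protein=ref.protein,
                              ligand_poses=[copy_b.with_coords(copy_b.coords(), "m1")])
        score = score_target(ref, pred)
        assert score.rmsd == pytest.approx(0.0, abs=1e-9)
        assert score.lddt_pli == pytest.approx(1.0)
        assert score.matched_reference == copy_b.instance_id

    def test_prediction_matching_alternate_conformation(self):
        ref = make_complex(22, "hybrid", 8, alt_conf=True)
        alt = ref.ligand_instances[1]
        pred = PredictedEntry(1, ref.target_id, 1, protein=ref.protein,
                              ligand_poses=[alt.with_coords(alt.coords(), "m1")])
        score = score_target(ref, pred)
        assert score.rmsd == pytest.approx(0.0, abs=1e-9)
        assert score.lddt_pli == pytest.approx(1.0)

    def test_pairing_grid_matches_exhaustive_pairing(self):
        ref = make_complex(23, "branched", 8, multi_copy=True)
        rng = np.random.default_rng(23)
        poses = []
        for k, inst in enumerate(ref.ligand_instances):
            noisy = inst.with_coords(
                inst.coords() + rng.normal(scale=0.4 + 0.3 * k, size=(len(inst.atoms), 3)),
                instance_id=f"p{k}",
            )
            poses.append(noisy)
        pred = PredictedEntry(1, ref.target_id, 1, protein=ref.protein, ligand_poses=poses)
        score = score_target(ref, pred)
        pli_grid, rmsd_grid = [], []
        for inst in ref.ligand_instances:
            for pose in poses:
                pli_grid.append(lddt_pli(ref, inst, pred, pose))
                rmsd_grid.append(bisy_rmsd(ref, inst, pred, pose).rmsd)
        assert score.lddt_pli == pytest.approx(max(pli_grid), abs=1e-12)
        assert score.rmsd == pytest.approx(min(rmsd_grid), abs=1e-12)

    def test_skipped_entry_raises(self, ring_complex):
        entry = PredictedEntry(1, ring_complex.target_id, 1, skipped=True)
        with pytest.raises(UndefinedScoreError):
            score_target(ring_complex, entry)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 4.0])
    def test_monotone_degradation_under_translation(self, hybrid_complex, d):
        pred = perturb_pose(hybrid_complex, "translate", d, seed=int(d * 10))
        score = score_target(hybrid_complex, pred)
        assert score.rmsd == pytest.approx(d, abs=1e-9)

    def test_lddt_pli_nonincreasing_in_translation(self, hybrid_complex):
        plis = []
        for d in (0.5, 1.0, 2.0, 4.0):
            pred = perturb_pose(hybrid_complex, "translate", d, seed=99)
            plis.append(score_target(hybrid_complex, pred).lddt_pli)
        assert all(a >= b for a, b in zip(plis, plis[1:]))

    def test_rigid_invariance_of_all_metrics(self, hybrid_complex):
        pred = perturb_pose(hybrid_complex, "translate", 1.2, seed=8)
        base = score_target(hybrid_complex, pred)
        rot = _rot([1, 1, 0], 53.0)
        shift = np.array([7.0, -2.0, 4.0])
        moved_pred = PredictedEntry(
            pred.group_id, pred.target_id, pred.model_num,
            protein=pred.protein.transformed(rot, shift),
            ligand_poses=[p.transformed(rot, shift) for p in pred.ligand_poses],
        )
        moved = score_target(hybrid_complex, moved_pred)
        assert moved.rmsd == pytest.approx(base.rmsd, abs=1e-9)
        assert moved.lddt_pli == pytest.approx(base.lddt_pli, abs=1e-12)
        assert moved.bb_rmsd == pytest.approx(base.bb_rmsd, abs=1e-9)
        assert moved.lddt_lp == pytest.approx(base.lddt_lp, abs=1e-12)
        # moving the reference instead must also leave the metrics unchanged
        moved_ref = ReferenceComplex(
            hybrid_complex.target_id,
            hybrid_complex.protein.transformed(rot, shift),
            [lig.transformed(rot, shift) for lig in hybrid_complex.ligand_instances],
        )
        ref_side = score_target(moved_ref, pred)
        assert ref_side.rmsd == pytest.approx(base.rmsd, abs=1e-9)
        assert ref_side.lddt_pli == pytest.approx(base.lddt_pli, abs=1e-12)

    def test_torsion_jitter_beats_large_translation(self, hybrid_complex):
        small_torsion = perturb_pose(hybrid_complex, "torsion", 15.0, seed=6)
        big_shift = perturb_pose(hybrid_complex, "translate", 5.0, seed=6)
        s_t = score_target(hybrid_complex, small_torsion)
        s_s = score_target(hybrid_complex, big_shift)
        assert s_t.lddt_pli > s_s.lddt_pli
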