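"""Superposition, fluctuation, helix geometry, and displacement metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import porekinetics as pk
from porekinetics.conformation import _kabsch
from porekinetics.io import TrajectoryEnsemble


def quaternion_grid_rmsd(mobile, reference, seed=0):
    """Hierarchically refined orientation-grid search for the minimum RMSD —
    an oracle independent of the Kabsch solver."""
    rng = np.random.default_rng(seed)
    cm, cr = mobile.mean(0), reference.mean(0)
    A, B = mobile - cm, reference - cr

    def rmsd_of(quats):
        Rm = Rotation.from_quat(quats).as_matrix()
        diff = np.einsum("nij,kj->nki", Rm, A) - B
        return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))

    q = rng.normal(size=(4000, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    vals = rmsd_of(q)
    best = q[np.argmin(vals)]
    best_val = vals.min()
    scale = 0.3
    for _ in range(8):
        q = best + rng.normal(size=(2000, 4)) * scale
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        vals = rmsd_of(q)
        if vals.min() < best_val:
            best_val = vals.min()
            best = q[np.argmin(vals)]
        scale *= 0.35
    return best_val


class TestSuperposition:
    def test_self_superposition_identity(self, straight_helix):
        model, _ = straight_helix
        res = pk.superpose_kabsch(model, model, "backbone")
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_known_rotation_recovered(self, straight_helix):
        model, _ = straight_helix
        R = Rotation.from_euler("xyz", [15, -75, 120], degrees=True).as_matrix()
        moved = model.with_coords(model.coords @ R.T + np.array([2.0, 1.0, -4.0]))
        res = pk.superpose_kabsch(moved, model, "backbone")
        assert res.rmsd < 1e-6
        assert np.allclose(res.rotation, R.T, atol=1e-6)

    def test_rmsd_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(0, 3.0, (10, 3))
        R = Rotation.from_euler("zxz", [40, 30, -60], degrees=True).as_matrix()
        mob = ref @ R.T + rng.normal(0, 0.4, (10, 3))
        _, _, rmsd = _kabsch(mob, ref)
        oracle = quaternion_grid_rmsd(mob, ref)
        assert abs(rmsd - oracle) < 1e-3

    def test_aligned_rmsd_never_exceeds_unaligned(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            ref = rng.normal(0, 3.0, (12, 3))
            mob = ref + rng.normal(0, 1.0, (12, 3))
            _, _, aligned = _kabsch(mob, ref)
            unaligned = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
            assert aligned <= unaligned + 1e-12

    def test_mismatched_selection_raises_pairing_error(self, straight_helix,
                                                       five_atom_model):
        model, _ = straight_helix
        with pytest.raises(ValueError, match="pairs unequally"):
            pk.superpose_kabsch(model, five_atom_model, "name CA")


class TestFluctuationProfiles:
    def _ensemble(self, model, frames, interval=1.0):
        return TrajectoryEnsemble(replicas=[np.asarray(frames)],
                                  frame_interval=interval,
                                  box=[np.zeros((len(frames), 3))],
                                  topology=model)

    def test_static_trajectory_zero_rmsf(self, straight_helix):
        model, _ = straight_helix
        frames = np.repeat(model.coords[None], 5, axis=0)
        out = pk.fluctuation_profiles(self._ensemble(model, frames),
                                      align_expr="backbone",
                                      measure_expr="ca")
        assert np.allclose(out["rmsf"], 0.0, atol=1e-9)

    def test_isotropic_jitter_rmsf_sigma_sqrt3(self):
        # many atoms so the rigid-body fit absorbs a negligible share
        model, _ = pk.generate_kinked_helix(80)
        sigma = 0.3
        rng = np.random.default_rng(5)
        frames = model.coords[None] + rng.normal(
            0, sigma, (2000, len(model), 3))
        out = pk.fluctuation_profiles(self._ensemble(model, frames),
                                      align_expr="backbone",
                                      measure_expr="backbone")
        mean_rmsf = out["rmsf"].mean()
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_rigid_wobble_removed_by_alignment(self, straight_helix):
        model, _ = straight_helix
        frames = []
        for k in range(10):
            R = Rotation.from_euler("z", 5 * np.sin(k), degrees=True).as_matrix()
            frames.append(model.coords @ R.T + np.array([0.1 * k, 0, 0]))
        out = pk.fluctuation_profiles(self._ensemble(model, np.array(frames)),
                                      align_expr="backbone",
                                      measure_expr="ca")
        assert np.max(out["rmsd_series"][0]) < 1e-6

    def test_single_frame_warns(self, straight_helix):
        model, _ = straight_helix
        frames = model.coords[None]
        with pytest.warns(UserWarning, match="single-frame"):
            out = pk.fluctuation_profiles(self._ensemble(model, frames),
                                          align_expr="backbone",
                                          measure_expr="ca")
        assert np.allclose(out["rmsf"], 0.0)


class TestHelixGeometry:
    def test_straight_split_is_near_zero(self, straight_helix):
        model, _ = straight_helix
        geom = pk.helix_axes_and_bend(model, (1, 15), (16, 30))
        assert geom.bend_angle < 1.0

    def test_generated_kink_recovered(self):
        model, truth = pk.generate_kinked_helix(30, kink_after=15, bend_deg=30.0)
        geom = pk.helix_axes_and_bend(model, (1, 15), (16, 30))
        assert geom.bend_angle == pytest.approx(30.0, abs=2.0)

    def test_segment_swap_symmetric(self):
        model, _ = pk.generate_kinked_helix(30, kink_after=15, bend_deg=30.0)
        a = pk.helix_axes_and_bend(model, (1, 15), (16, 30)).bend_angle
        b = pk.helix_axes_and_bend(model, (16, 30), (1, 15)).bend_angle
        assert a == pytest.approx(b)

    def test_invariant_under_rigid_transform_and_scaling(self):
        model, _ = pk.generate_kinked_helix(30, kink_after=15, bend_deg=25.0)
        base = pk.helix_axes_and_bend(model, (1, 15), (16, 30)).bend_angle
        R = Rotation.from_euler("xyz", [33, -44, 55], degrees=True).as_matrix()
        moved = model.with_coords(2.0 * (model.coords @ R.T) + 7.0)
        assert pk.helix_axes_and_bend(moved, (1, 15), (16, 30)).bend_angle == \
            pytest.approx(base, abs=1e-6)

    def test_short_segment_refused(self, straight_helix):
        model, _ = straight_helix
        with pytest.raises(ValueError, match="5"):
            pk.helix_axes_and_bend(model, (1, 4), (16, 30))


class TestHelicity:
    def test_ideal_helix_fully_helical(self):
        model, _ = pk.generate_kinked_helix(20)
        prof = pk.helicity_profile(model, (1, 20))
        assert prof["helical_mask"].all()

    @pytest.mark.parametrize("tail", [2, 5, 7])
    def test_tail_length_recovered_exactly(self, tail):
        model, truth = pk.generate_kinked_helix(30, unwound_tail=tail)
        prof = pk.helicity_profile(model, (1, 30))
        nonhel = [r for r, s in prof["status"].items() if s == "non-helical"]
        assert nonhel == truth["tail_resids"]

    def test_extended_strand_all_non_helical(self):
        model, _ = pk.generate_kinked_helix(15, unwound_tail=14)
        prof = pk.helicity_profile(model, (1, 15))
        assert not prof["helical_mask"].any()

    def test_missing_backbone_marked_indeterminate(self):
        model, _ = pk.generate_kinked_helix(10)
        # drop one residue's carbonyl C
        keep = [a for a in model.atoms if not (a.resid == 5 and a.name == "C")]
        from porekinetics.model import MolecularModel
        broken = MolecularModel(keep)
        prof = pk.helicity_profile(broken, (1, 10))
        assert prof["status"][5] == "indeterminate"


class TestChargeDisplacement:
    def test_identical_models_zero_displacement(self, straight_helix):
        model, _ = straight_helix
        out = pk.charge_displacement(model, model,
                                     [("R1", 10, "CA"), ("R2", 20, "CA")],
                                     align_expr="backbone")
        assert out["R1"]["magnitude"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_label_translation_measured(self, straight_helix):
        model, _ = straight_helix
        coords = model.coords.copy()
        idx = [i for i, a in enumerate(model.atoms)
               if a.resid in (25, 28) and a.name == "CA"]
        coords[idx] += np.array([0.0, 0.0, 5.0])
        moved = model.with_coords(coords)
        out = pk.charge_displacement(model, moved,
                                     [("R4", 25, "CA"), ("R5", 28, "CA")],
                                     align_expr="resid 1-20 and backbone")
        assert out["R4"]["magnitude"] == pytest.approx(5.0, abs=1e-6)
        assert out["R5"]["magnitude"] == pytest.approx(5.0, abs=1e-6)

    def test_missing_label_marked(self, straight_helix):
        model, _ = straight_helix
        out = pk.charge_displacement(model, model, [("X", 999, "CA")],
                                     align_expr="backbone")
        assert out["X"] is None
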