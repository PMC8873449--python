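"""Gating-geometry observables against planted rigid-motion truths."""

import math

import numpy as np
import pytest

import allopath as ap
from allopath.geometry import GeometryError, HelixDefinition
from allopath.trajectory_io import AtomRecord, ResidueSelection, TrajectoryEnsemble

from conftest import HELIX_HINGE_INDEX, HELIX_N_RES, HELIX_WINDOWS


def _helix_def(**kw) -> HelixDefinition:
    return HelixDefinition(chain_id="A", residue_range=(1, HELIX_N_RES), **kw)


class TestBendingAngle:
    def test_collinear_toy_exactly_180(self):
        atoms = [AtomRecord(i, "CA", "C", i + 1, "GLY", "A") for i in range(3)]
        coords = np.array([[[0, 0, 5.0], [0, 0, 0.0], [0, 0, -5.0]]])
        traj = TrajectoryEnsemble(atoms=atoms, coords=coords)
        hd = HelixDefinition(
            chain_id="A", residue_range=(1, 3),
            top_range=(1, 1), middle_range=(2, 2), bottom_range=(3, 3),
        )
        assert ap.bending_angle(traj, hd)[0] == pytest.approx(180.0, abs=1e-9)

    def test_straight_helix_near_180(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=HELIX_N_RES, n_frames=3))
        theta = ap.bending_angle(traj, _helix_def(**HELIX_WINDOWS))
        assert theta[0] == pytest.approx(180.0, abs=2.0)

    def test_hinge_bend_reduces_theta(self):
        traj = ap.make_helix_traj(
            ap.HelixMotionSpec(
                n_res=HELIX_N_RES, applied_hinge_bend=30.0,
                hinge_residue=HELIX_HINGE_INDEX, n_frames=5,
            )
        )
        theta = ap.bending_angle(traj, _helix_def(**HELIX_WINDOWS))
        assert theta[-1] == pytest.approx(150.0, abs=2.0)

    def test_missing_windows_rejected(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=2))
        with pytest.raises(GeometryError):
            ap.bending_angle(traj, HelixDefinition(chain_id="A", residue_range=(1, 21)))


class TestS4Rotation:
    def test_frame_zero_is_zero(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=4))
        hd = HelixDefinition(chain_id="A", residue_range=(1, 21), axis=(0, 0, 1.0))
        assert ap.s4_rotation(traj, hd, anchor_n=8)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_axial_rotation_recovered(self):
        traj = ap.make_helix_traj(
            ap.HelixMotionSpec(n_res=21, applied_axial_rotation=40.0, n_frames=9)
        )
        hd = HelixDefinition(chain_id="A", residue_range=(1, 21), axis=(0, 0, 1.0))
        alpha = ap.s4_rotation(traj, hd, anchor_n=8)
        assert alpha[-1] == pytest.approx(40.0, abs=1e-6)

    def test_translation_gives_zero_rotation(self):
        traj = ap.make_helix_traj(
            ap.HelixMotionSpec(n_res=21, applied_axial_shift=7.0, n_frames=6)
        )
        hd = HelixDefinition(chain_id="A", residue_range=(1, 21), axis=(0, 0, 1.0))
        alpha = ap.s4_rotation(traj, hd, anchor_n=8)
        assert np.abs(alpha).max() == pytest.approx(0.0, abs=1e-6)


class TestS4Displacement:
    def test_frame_zero_and_axial_shift(self):
        traj = ap.make_helix_traj(
            ap.HelixMotionSpec(n_res=21, applied_axial_shift=5.0, n_frames=11)
        )
        hd = HelixDefinition(chain_id="A", residue_range=(1, 21), axis=(0, 0, 1.0))
        d = ap.s4_displacement(traj, hd)
        assert d[0] == 0.0
        assert d[-1] == pytest.approx(5.0, abs=1e-12)

    def test_orthogonal_translation_projects_to_zero(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=4))
        coords = traj.coords.copy()
        coords[2:] += np.array([5.0, 0.0, 0.0])  # shift orthogonal to z
        traj2 = TrajectoryEnsemble(atoms=traj.atoms, coords=coords)
        hd = HelixDefinition(chain_id="A", residue_range=(1, 21), axis=(0, 0, 1.0))
        assert np.abs(ap.s4_displacement(traj2, hd)).max() < 1e-9


def _four_chain_fixture(ctd_rotation_deg: float = 0.0, n_frames: int = 2):
    """Four chains on a square; TMD residue 1 at z=0, CTD residue 2 at z=-20.

    The TMD square is axis-aligned; the CTD square is rotated 90° so that
    the (1,3) vectors start orthogonal; an extra CTD rotation about z is
    applied linearly over frames.
    """
    atoms, base = [], []
    for ci, chain in enumerate("ABCD"):
        ang = math.radians(90.0 * ci)
        atoms.append(AtomRecord(2 * ci, "CA", "C", 1, "ALA", chain))
        base.append([20 * math.cos(ang), 20 * math.sin(ang), 0.0])
        atoms.append(AtomRecord(2 * ci + 1, "CA", "C", 2, "ALA", chain))
        ang_c = ang + math.radians(90.0)
        base.append([20 * math.cos(ang_c), 20 * math.sin(ang_c), -20.0])
    base = np.array(base)
    frames = []
    for f in range(n_frames):
        frac = f / (n_frames - 1) if n_frames > 1 else 0.0
        rot = math.radians(ctd_rotation_deg * frac)
        c, s = math.cos(rot), math.sin(rot)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        pos = base.copy()
        ctd_rows = [1, 3, 5, 7]
        pos[ctd_rows] = pos[ctd_rows] @ rz.T
        frames.append(pos)
    traj = TrajectoryEnsemble(atoms=atoms, coords=np.stack(frames))
    tmd = [ResidueSelection(((ch, 1),), f"tmd{ch}") for ch in "ABCD"]
    ctd = [ResidueSelection(((ch, 2),), f"ctd{ch}") for ch in "ABCD"]
    return traj, tmd, ctd


class TestPdCtdRotation:
    def test_orthogonal_vectors_give_90(self):
        traj, tmd, ctd = _four_chain_fixture()
        phi13, phi24, mean = ap.pd_ctd_rotation(traj, tmd, ctd)
        assert phi13[0] == pytest.approx(90.0, abs=1e-9)
        assert phi24[0] == pytest.approx(90.0, abs=1e-9)
        assert mean[0] == pytest.approx(90.0, abs=1e-9)

    def test_rigid_ctd_rotation_changes_mean_by_applied_angle(self):
        traj, tmd, ctd = _four_chain_fixture(ctd_rotation_deg=15.0)
        _, _, mean = ap.pd_ctd_rotation(traj, tmd, ctd)
        assert abs(mean[-1] - mean[0]) == pytest.approx(15.0, abs=0.1)

    def test_global_translation_leaves_phi_unchanged(self):
        traj, tmd, ctd = _four_chain_fixture(ctd_rotation_deg=25.0, n_frames=3)
        shifted = TrajectoryEnsemble(
            atoms=traj.atoms, coords=traj.coords + np.array([3.0, -8.0, 12.0])
        )
        a = ap.pd_ctd_rotation(traj, tmd, ctd)[2]
        b = ap.pd_ctd_rotation(shifted, tmd, ctd)[2]
        assert np.allclose(a, b, atol=1e-9)

    def test_wrong_number_of_chains_rejected(self):
        traj, tmd, ctd = _four_chain_fixture()
        with pytest.raises(GeometryError):
            ap.pd_ctd_rotation(traj, tmd[:3], ctd)


class TestFitHelixAxis:
    def test_ideal_helix_axis_along_z(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=2))
        axis = ap.fit_helix_axis(traj, HelixDefinition(chain_id="A", residue_range=(1, 21)))
        assert np.abs(axis - np.array([0, 0, 1.0])).max() < 1e-3

    def test_reversed_residue_order_flips_sign(self):
        traj = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=2))
        # same coordinates, residue numbering running the other way
        flipped = TrajectoryEnsemble(
            atoms=[AtomRecord(i, "CA", "C", 21 - i, "ALA", "A") for i in range(21)],
            coords=traj.coords,
        )
        axis = ap.fit_helix_axis(flipped, HelixDefinition(chain_id="A", residue_range=(1, 21)))
        assert axis[2] == pytest.approx(-1.0, abs=1e-3)

    def test_straight_line_exact_direction(self):
        atoms = [AtomRecord(i, "CA", "C", i + 1, "GLY", "A") for i in range(6)]
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        coords = (np.arange(6)[:, None] * direction * 3.8)[None, :, :]
        traj = TrajectoryEnsemble(atoms=atoms, coords=coords)
        axis = ap.fit_helix_axis(traj, HelixDefinition(chain_id="A", residue_range=(1, 6)))
        assert np.abs(axis - direction).max() < 1e-9


class TestRigidBodyInvariance:
    def test_angles_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(9)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.normal(scale=30.0, size=3)

        spec = ap.HelixMotionSpec(
            n_res=HELIX_N_RES, applied_hinge_bend=20.0,
            hinge_residue=HELIX_HINGE_INDEX, n_frames=5,
        )
        traj = ap.make_helix_traj(spec)
        moved = TrajectoryEnsemble(atoms=traj.atoms, coords=traj.coords @ q.T + t)

        hd = _helix_def(**HELIX_WINDOWS)
        assert np.allclose(
            ap.bending_angle(traj, hd), ap.bending_angle(moved, hd), atol=1e-9
        )
        # rotation/displacement need consistently transformed axes
        hd_fixed = _helix_def(axis=(0, 0, 1.0))
        axis_moved = tuple(q @ np.array([0, 0, 1.0]))
        hd_moved = _helix_def(axis=axis_moved)
        assert np.allclose(
            ap.s4_rotation(traj, hd_fixed, anchor_n=8),
            ap.s4_rotation(moved, hd_moved, anchor_n=8),
            atol=1e-9,
        )
        assert np.allclose(
            ap.s4_displacement(traj, hd_fixed),
            ap.s4_displacement(moved, hd_moved),
            atol=1e-9,
        )


class TestGeometrySeries:
    def test_subunit_averages_equal_mean_of_series(self):
        traj, tmd, ctd = _four_chain_fixture(ctd_rotation_deg=10.0, n_frames=4)
        # build four single-chain helices by stacking helix fixtures per chain
        helix = ap.make_helix_traj(ap.HelixMotionSpec(n_res=21, n_frames=4))
        atoms, blocks = [], []
        for ci, chain in enumerate("ABCD"):
            for a in helix.atoms:
                atoms.append(AtomRecord(len(atoms), "CA", "C", a.residue_id, "ALA", chain))
            blocks.append(helix.coords + np.array([60.0 * ci, 0, 0]))
        four = TrajectoryEnsemble(atoms=atoms, coords=np.concatenate(blocks, axis=1))
        s6 = [
            HelixDefinition(chain_id=ch, residue_range=(1, 21),
                            top_range=(1, 5), middle_range=(9, 13), bottom_range=(17, 21))
            for ch in "ABCD"
        ]
        s4 = [
            HelixDefinition(chain_id=ch, residue_range=(1, 21), axis=(0, 0, 1.0))
            for ch in "ABCD"
        ]
        # merge the four-chain square fixture for the phi observables
        merged_atoms = atoms + [
            AtomRecord(len(atoms) + i, "CA", "C", 100 + a.residue_id, "ALA", a.chain_id)
            for i, a in enumerate(traj.atoms)
        ]
        merged = TrajectoryEnsemble(
            atoms=merged_atoms,
            coords=np.concatenate([four.coords, traj.coords + np.array([0, 0, -80.0])], axis=1),
        )
        tmd2 = [ResidueSelection(((ch, 101),), f"tmd{ch}") for ch in "ABCD"]
        ctd2 = [ResidueSelection(((ch, 102),), f"ctd{ch}") for ch in "ABCD"]
        series = ap.geometry_series(
            merged, s6_helices=s6, s4_helices=s4,
            s4_middle_anchors=[8] * 4, s4_bottom_anchors=[14] * 4,
            tmd_selections=tmd2, ctd_selections=ctd2,
        )
        for name in ("s6_bending", "s4_displacement", "s4_rotation_middle"):
            per = series.per_subunit[name]
            assert np.allclose(series.mean[name], np.nanmean(per, axis=1), atol=1e-12)
        assert np.allclose(
            series.mean["pd_ctd_rotation"],
            0.5 * (series.per_subunit["phi13"][:, 0] + series.per_subunit["phi24"][:, 0]),
            atol=1e-12,
        )
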