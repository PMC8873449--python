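"""Geometric gating descriptors for voltage-gated channels.

Per-frame observables:

* S6 bending angle θ — angle at the helix middle between vectors to the
  helix top and bottom Cα centroids (a straight helix gives θ ≈ 180°).
* S4 axial rotation α — angle between the axis-orthogonal components of
  v_rot(t) and v_rot(0), where v_rot points from the midpoint of Cα(n)
  and Cα(n+4) to Cα(n+2); unsigned, in [0°, 180°].
* S4 axial displacement d — signed projection of the helix Cα-COM
  displacement from frame 0 onto the helix axis versor ĥ (Å).
* PD–CTD rotation φ13/φ24 — angle between the vector joining the
  transmembrane-domain centers of mass of non-neighbouring chains (1,3)
  or (2,4) and the corresponding cytosolic-domain vector; the reported
  rotation is the mean of φ13 and φ24.

Helix sub-range centroids use Cα only (unweighted); domain centers of
mass use all selected heavy atoms with standard element masses.  The
helix axis ĥ is fitted on a reference frame (see
:func:`fit_helix_axis`), sign-fixed from first to last residue, and held
fixed over the trajectory; an explicit axis may be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory_io import ResidueSelection, TrajectoryEnsemble

__all__ = [
    "HelixDefinition",
    "GeometrySeries",
    "fit_helix_axis",
    "bending_angle",
    "s4_rotation",
    "s4_displacement",
    "pd_ctd_rotation",
    "geometry_series",
]

log = logging.getLogger(__name__)

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


class GeometryError(Exception):
    pass


@dataclass(frozen=True)
class HelixDefinition:
    """Residue windows of one helix in one chain.

    Ranges are inclusive ``(first_resid, last_resid)`` tuples.  ``axis``
    may be given explicitly; otherwise it is fitted from ``axis_source``
    (a reference frame index, default 0).
    """

    chain_id: str
    residue_range: tuple[int, int]
    top_range: tuple[int, int] | None = None
    middle_range: tuple[int, int] | None = None
    bottom_range: tuple[int, int] | None = None
    rotation_anchor_residues: tuple[int, ...] = ()
    axis: tuple[float, float, float] | None = None
    axis_source: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        for rng in (self.top_range, self.middle_range, self.bottom_range):
            if rng is not None and not (lo <= rng[0] <= rng[1] <= hi):
                raise GeometryError(f"sub-range {rng} outside helix range {self.residue_range}")
        if self.axis is not None:
            n = float(np.linalg.norm(self.axis))
            if not np.isclose(n, 1.0, atol=1e-6):
                raise GeometryError("axis must be a unit vector")


@dataclass
class GeometrySeries:
    """Per-frame observables, per subunit and four-subunit averages.

    ``per_subunit[name]`` is (n_frames, n_subunits); ``mean[name]`` the
    subunit average.  ``pd_ctd_rotation`` is mean(φ13, φ24).
    """

    per_subunit: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]

    def observable(self, name: str) -> np.ndarray:
        try:
            return self.mean[name]
        except KeyError:
            raise GeometryError(f"observable {name!r} missing from geometry series") from None


# ------------------------------------------------------------------ helpers


def _ca_for_range(traj: TrajectoryEnsemble, chain: str, rng: tuple[int, int]):
    hits = [
        (a.residue_id, i)
        for i, a in enumerate(traj.atoms)
        if a.chain_id == chain and rng[0] <= a.residue_id <= rng[1] and a.name == "CA"
    ]
    if not hits:
        raise GeometryError(f"no Cα atoms in chain {chain} residues {rng[0]}-{rng[1]}")
    return np.array([i for _, i in sorted(hits)], dtype=int)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between stacked vectors, degrees; NaN where either is ~zero."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu < 1e-9) | (nv < 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...a,...a->...", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    if np.any(bad):
        log.warning("degenerate (zero-length) vectors in %d frames; NaN", int(np.sum(bad)))
        ang = np.where(bad, np.nan, ang)
    return ang


def fit_helix_axis(
    traj: TrajectoryEnsemble, helix: HelixDefinition, reference_frame: int | None = None
) -> np.ndarray:
    """Unit axis versor ĥ of the helix Cα trace in the reference frame.

    For a helical trace the local curvature vectors (second differences of
    consecutive Cα) are perpendicular to the axis, so ĥ is taken as the
    least-variance direction of those vectors — exact for an ideal helix
    of any length, unlike the principal axis of the raw point cloud, which
    is biased by partial turns.  Collinear traces (zero curvature) fall
    back to the principal axis of the points themselves.  The sign points
    from the first toward the last residue of the range.
    """
    if helix.axis is not None:
        return np.asarray(helix.axis, dtype=float)
    frame = helix.axis_source if reference_frame is None else reference_frame
    idx = _ca_for_range(traj, helix.chain_id, helix.residue_range)
    if idx.size < 5:
        raise GeometryError("axis fit needs >= 5 Cα atoms")
    pts = traj.coords[frame, idx, :]
    curv = pts[2:] - 2 * pts[1:-1] + pts[:-2]
    if np.linalg.norm(curv, axis=1).max() > 1e-8:
        _, s, vt = np.linalg.svd(curv - curv.mean(axis=0), full_matrices=False)
        if s[1] - s[2] < 1e-9 * max(s[0], 1.0):
            raise GeometryError("degenerate curvature: helix axis undefined")
        axis = vt[2]
    else:
        centered = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] - s[1] < 1e-9 * max(s[0], 1.0):
            raise GeometryError("degenerate point cloud: helix axis undefined")
        axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


# --------------------------------------------------------------- observables


def bending_angle(traj: TrajectoryEnsemble, helix: HelixDefinition) -> np.ndarray:
    """Per-frame bending angle θ (degrees) of the helix."""
    if None in (helix.top_range, helix.middle_range, helix.bottom_range):
        raise GeometryError("bending angle needs top/middle/bottom ranges")
    tops = _ca_for_range(traj, helix.chain_id, helix.top_range)
    mids = _ca_for_range(traj, helix.chain_id, helix.middle_range)
    bots = _ca_for_range(traj, helix.chain_id, helix.bottom_range)
    v_ct = traj.coords[:, tops, :].mean(axis=1) - traj.coords[:, mids, :].mean(axis=1)
    v_cb = traj.coords[:, bots, :].mean(axis=1) - traj.coords[:, mids, :].mean(axis=1)
    return _angle_deg(v_ct, v_cb)


def _v_rot(traj: TrajectoryEnsemble, helix: HelixDefinition, anchor_n: int) -> np.ndarray:
    cas = {}
    for off in (0, 2, 4):
        idx = _ca_for_range(traj, helix.chain_id, (anchor_n + off, anchor_n + off))
        cas[off] = traj.coords[:, idx[0], :]
    return cas[2] - 0.5 * (cas[0] + cas[4])


def s4_rotation(
    traj: TrajectoryEnsemble, helix: HelixDefinition, anchor_n: int
) -> np.ndarray:
    """Per-frame axial rotation α (degrees, unsigned) at window n..n+4."""
    h = fit_helix_axis(traj, helix)
    v = _v_rot(traj, helix, anchor_n)
    v_perp = v - np.outer(v @ h, h)
    ref = v_perp[0]
    if np.linalg.norm(ref) < 1e-9:
        raise GeometryError("reference v_rot parallel to helix axis")
    return _angle_deg(v_perp, np.broadcast_to(ref, v_perp.shape))


def s4_displacement(traj: TrajectoryEnsemble, helix: HelixDefinition) -> np.ndarray:
    """Per-frame signed displacement d (Å) of the helix Cα-COM along ĥ."""
    h = fit_helix_axis(traj, helix)
    idx = _ca_for_range(traj, helix.chain_id, helix.residue_range)
    com = traj.coords[:, idx, :].mean(axis=1)
    return (com - com[0]) @ h


def _mass_com(traj: TrajectoryEnsemble, sel: ResidueSelection) -> np.ndarray:
    keys = set(sel.members)
    idx = [
        i
        for i, a in enumerate(traj.atoms)
        if a.residue_key in keys and not a.is_hydrogen
    ]
    if not idx:
        raise GeometryError(f"selection {sel.label!r} has no heavy atoms")
    masses = np.array([_MASSES.get(traj.atoms[i].element, 12.011) for i in idx])
    return np.einsum("fia,i->fa", traj.coords[:, idx, :], masses) / masses.sum()


def pd_ctd_rotation(
    traj: TrajectoryEnsemble,
    tmd_selections: list[ResidueSelection],
    ctd_selections: list[ResidueSelection],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (φ13, φ24, mean) in degrees.

    Selections are given in chain order 1..4; the non-neighbouring pairs
    are (1,3) and (2,4).
    """
    if len(tmd_selections) != 4 or len(ctd_selections) != 4:
        raise GeometryError("need exactly four TMD and four CTD selections")
    tmd = [_mass_com(traj, s) for s in tmd_selections]
    ctd = [_mass_com(traj, s) for s in ctd_selections]
    phi13 = _angle_deg(tmd[2] - tmd[0], ctd[2] - ctd[0])
    phi24 = _angle_deg(tmd[3] - tmd[1], ctd[3] - ctd[1])
    return phi13, phi24, 0.5 * (phi13 + phi24)


def geometry_series(
    traj: TrajectoryEnsemble,
    s6_helices: list[HelixDefinition],
    s4_helices: list[HelixDefinition],
    s4_middle_anchors: list[int],
    s4_bottom_anchors: list[int],
    tmd_selections: list[ResidueSelection],
    ctd_selections: list[ResidueSelection],
) -> GeometrySeries:
    """Assemble the full observable set with subunit averaging.

    θ, α (middle and bottom anchors separately) and d are averaged over
    the four subunits; the PD–CTD rotation is mean(φ13, φ24).
    """
    theta = np.column_stack([bending_angle(traj, h) for h in s6_helices])
    alpha_mid = np.column_stack(
        [s4_rotation(traj, h, n) for h, n in zip(s4_helices, s4_middle_anchors)]
    )
    alpha_bot = np.column_stack(
        [s4_rotation(traj, h, n) for h, n in zip(s4_helices, s4_bottom_anchors)]
    )
    disp = np.column_stack([s4_displacement(traj, h) for h in s4_helices])
    phi13, phi24, phi_mean = pd_ctd_rotation(traj, tmd_selections, ctd_selections)
    per = {
        "s6_bending": theta,
        "s4_rotation_middle": alpha_mid,
        "s4_rotation_bottom": alpha_bot,
        "s4_displacement": disp,
        "phi13": phi13[:, None],
        "phi24": phi24[:, None],
    }
    mean = {k: np.nanmean(v, axis=1) for k, v in per.items()}
    mean["pd_ctd_rotation"] = phi_mean
    # the headline S4 rotation is the middle-anchor subunit average
    mean["s4_rotation"] = mean["s4_rotation_middle"]
    return GeometrySeries(per_subunit=per, mean=mean)
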