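"""Synthetic trajectories with planted ground truth.

Three generators stand in for MD output at every downstream stage:

* :func:`make_planted_network_traj` — Gaussian fluctuations with a planted
  chain of correlated residues.  Residue ``k`` of the planted chain couples
  to two shared latent 3-vectors ``p(t), q(t)`` (i.i.d. standard normal per
  frame) through a chain phase ω::

      Δr_k(t) = λ [cos(kω) p(t) + sin(kω) q(t)] + ε_k(t),   ε ~ N(0, σ² I)

  which gives the closed-form pair correlation

      Corr(k, j) = cos((k−j)ω) · λ² / (λ² + σ²).

  With the default ω = 0 every planted residue shares one latent factor and
  consecutive-pair correlation is exactly λ²/(λ²+σ²).  A non-zero ω makes
  correlation decay with chain separation, so only consecutive residues
  clear a communication-graph cutoff and the chain itself becomes the
  unique shortest route — the planted truth used by the path-recovery
  tests.  Non-planted residues get independent noise only.

* :func:`make_helix_traj` — an ideal α-helix (rise 1.5 Å, twist 100°)
  subjected to known rigid axial shifts, axial rotations and hinge bends,
  interpolated linearly over frames.

* :func:`make_contact_traj` — residue pairs whose single side-chain heavy
  atoms follow scripted distance-vs-frame profiles, so contact formation
  and breaking frames are known arithmetic.

Identical seeds give bitwise-identical trajectories.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .trajectory_io import AtomRecord, TrajectoryEnsemble

__all__ = [
    "PlantedNetworkSpec",
    "HelixMotionSpec",
    "ContactScriptSpec",
    "make_planted_network_traj",
    "make_helix_traj",
    "make_contact_traj",
    "planted_pair_correlation",
]


class SyntheticSpecError(ValueError):
    """Raised for invalid generator specifications."""


# --------------------------------------------------------------------------
# planted correlation network
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the latent-factor fluctuation model.

    ``loading`` is the latent coupling λ (dimensionless, in (0, 1] by
    convention), ``noise_sd`` the per-axis Gaussian noise σ in Å and
    ``chain_phase_deg`` the chain phase ω in degrees (0 = single shared
    factor).  ``planted_path`` lists residue indices (0-based) in chain
    order.
    """

    n_residues: int = 20
    planted_path: tuple[int, ...] = (0, 1, 2, 3, 4)
    loading: float = 1.0
    noise_sd: float = 0.5
    chain_phase_deg: float = 0.0
    n_frames: int = 1000
    seed: int = 0
    grid_spacing: float = 12.0

    def __post_init__(self) -> None:
        if not set(self.planted_path) <= set(range(self.n_residues)):
            raise SyntheticSpecError("planted_path residues outside 0..n_residues-1")
        if self.loading < 0 or self.noise_sd <= 0:
            raise SyntheticSpecError("need loading >= 0 and noise_sd > 0")
        if self.n_frames < 10:
            raise SyntheticSpecError("n_frames < 10: too few frames to be useful")
        if self.grid_spacing < 10.0:
            raise SyntheticSpecError("grid_spacing must be >= 10 Å")


def planted_pair_correlation(spec: PlantedNetworkSpec, sep: int = 1) -> float:
    """Closed-form |Corr| between planted residues ``sep`` chain steps apart."""
    lam2 = spec.loading**2
    if lam2 == 0:
        return 0.0
    omega = math.radians(spec.chain_phase_deg)
    return abs(math.cos(sep * omega)) * lam2 / (lam2 + spec.noise_sd**2)


def _grid_positions(n: int, spacing: float) -> np.ndarray:
    """Mean Cα positions on a cubic grid with the given spacing."""
    side = max(2, math.ceil(n ** (1 / 3)))
    pts = []
    for i in range(n):
        iz, rem = divmod(i, side * side)
        iy, ix = divmod(rem, side)
        pts.append((ix * spacing, iy * spacing, iz * spacing))
    return np.asarray(pts, dtype=float)


def _residue_atoms(key_base: int, residue_id: int, chain: str) -> list[AtomRecord]:
    """Alanine-like residue: backbone N/CA/C/O plus one side-chain heavy CB."""
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
    return [
        AtomRecord(
            atom_id=key_base + i,
            name=nm,
            element=el,
            residue_id=residue_id,
            residue_name="ALA",
            chain_id=chain,
        )
        for i, (nm, el) in enumerate(names)
    ]


# fixed intra-residue offsets (Å) from the Cα, roughly alanine-shaped
_ATOM_OFFSETS = np.array(
    [
        [-1.45, 0.0, 0.0],  # N
        [0.0, 0.0, 0.0],  # CA
        [1.52, 0.0, 0.0],  # C
        [2.15, 1.05, 0.0],  # O
        [-0.52, 1.42, 0.0],  # CB
    ]
)


def make_planted_network_traj(spec: PlantedNetworkSpec) -> TrajectoryEnsemble:
    """Generate the latent-factor trajectory described by ``spec``.

    Each residue moves rigidly (all five atoms share the Cα fluctuation),
    so Cα correlations are exactly the model's.
    """
    rng = np.random.default_rng(spec.seed)
    means = _grid_positions(spec.n_residues, spec.grid_spacing)
    omega = math.radians(spec.chain_phase_deg)

    # latent factors: two i.i.d. standard-normal 3-vectors per frame
    p = rng.standard_normal((spec.n_frames, 3))
    q = rng.standard_normal((spec.n_frames, 3))
    noise = rng.standard_normal((spec.n_frames, spec.n_residues, 3)) * spec.noise_sd

    disp = noise
    for step, res in enumerate(spec.planted_path):
        disp[:, res, :] += spec.loading * (
            math.cos(step * omega) * p + math.sin(step * omega) * q
        )

    atoms: list[AtomRecord] = []
    for r in range(spec.n_residues):
        atoms.extend(_residue_atoms(5 * r, r + 1, "A"))

    ca = means[None, :, :] + disp  # (frames, residues, 3)
    coords = ca[:, :, None, :] + _ATOM_OFFSETS[None, None, :, :]
    coords = coords.reshape(spec.n_frames, spec.n_residues * 5, 3)
    return TrajectoryEnsemble(atoms=atoms, coords=coords)


def planted_residue_keys(spec: PlantedNetworkSpec) -> list[tuple[str, int]]:
    """Residue keys of the planted chain, in chain order."""
    return [("A", r + 1) for r in spec.planted_path]


# --------------------------------------------------------------------------
# helix motions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HelixMotionSpec:
    """An ideal α-helix along +z with rigid motions applied linearly in time.

    Final-frame values: ``applied_axial_shift`` (Å along +z),
    ``applied_axial_rotation`` (degrees about z), ``applied_hinge_bend``
    (degrees; residues after ``hinge_residue`` rotate about an x-axis
    through that residue's Cα).
    """

    n_res: int = 21
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    applied_axial_shift: float = 0.0
    applied_axial_rotation: float = 0.0
    applied_hinge_bend: float = 0.0
    hinge_residue: int | None = None
    n_frames: int = 11

    def __post_init__(self) -> None:
        if self.n_res < 9:
            raise SyntheticSpecError("n_res must be >= 9 (rotation windows need n..n+4)")
        if self.n_frames < 2:
            raise SyntheticSpecError("need at least 2 frames")
        if self.applied_hinge_bend and self.hinge_residue is None:
            raise SyntheticSpecError("hinge bend requires hinge_residue")
        if self.hinge_residue is not None and not (
            0 <= self.hinge_residue < self.n_res
        ):
            raise SyntheticSpecError("hinge_residue outside helix")


def _ideal_helix(spec: HelixMotionSpec) -> np.ndarray:
    k = np.arange(spec.n_res)
    t = np.radians(spec.twist_per_residue) * k
    return np.column_stack(
        [spec.radius * np.cos(t), spec.radius * np.sin(t), spec.rise_per_residue * k]
    )


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def make_helix_traj(spec: HelixMotionSpec) -> TrajectoryEnsemble:
    """Cα-only trajectory of the helix under the spec's rigid motions."""
    ref = _ideal_helix(spec)
    frames = []
    for f in range(spec.n_frames):
        frac = f / (spec.n_frames - 1)
        pos = ref @ _rot_z(frac * spec.applied_axial_rotation).T
        if spec.applied_hinge_bend:
            pivot = pos[spec.hinge_residue]
            after = np.arange(spec.n_res) > spec.hinge_residue
            pos = pos.copy()
            pos[after] = (pos[after] - pivot) @ _rot_x(
                frac * spec.applied_hinge_bend
            ).T + pivot
        pos = pos + np.array([0.0, 0.0, frac * spec.applied_axial_shift])
        frames.append(pos)
    atoms = [
        AtomRecord(
            atom_id=i,
            name="CA",
            element="C",
            residue_id=i + 1,
            residue_name="ALA",
            chain_id="A",
        )
        for i in range(spec.n_res)
    ]
    return TrajectoryEnsemble(atoms=atoms, coords=np.stack(frames))


# --------------------------------------------------------------------------
# scripted contacts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactScriptSpec:
    """Residue pairs following piecewise-linear distance profiles.

    ``pair_schedule`` maps a pair label to a list of ``(frame, distance_Å)``
    knots; distances between knots interpolate linearly.  Every profile is
    realised by a dedicated residue pair whose CB–CB distance tracks the
    profile to machine precision.
    """

    pair_schedule: tuple[tuple[str, tuple[tuple[int, float], ...]], ...]
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for label, knots in self.pair_schedule:
            if len(knots) < 2:
                raise SyntheticSpecError(f"profile {label!r} needs >= 2 knots")
            for _, d in knots:
                if not (np.isfinite(d) and d > 0):
                    raise SyntheticSpecError(f"profile {label!r}: distances must be > 0")


def profile_distances(
    knots: tuple[tuple[int, float], ...], n_frames: int
) -> np.ndarray:
    """Evaluate a piecewise-linear knot profile at every frame."""
    fr = np.array([k[0] for k in knots], dtype=float)
    di = np.array([k[1] for k in knots], dtype=float)
    return np.interp(np.arange(n_frames, dtype=float), fr, di)


def make_contact_traj(spec: ContactScriptSpec) -> TrajectoryEnsemble:
    """Trajectory realising the scripted pair distances.

    Pair ``k`` occupies residues ``10k+1`` and ``10k+5`` of chain A, separated
    along x around a base point; bases are 60 Å apart so pairs never
    interact.  Only the CB atoms matter for contacts; backbone atoms are
    placed 20 Å away on −y so they stay out of every side-chain distance.
    """
    n_pairs = len(spec.pair_schedule)
    frames = np.zeros((spec.n_frames, n_pairs * 2 * 5, 3))
    atoms: list[AtomRecord] = []
    for k, (label, knots) in enumerate(spec.pair_schedule):
        d = profile_distances(knots, spec.n_frames)
        base = np.array([0.0, 0.0, 60.0 * k])
        # residue ids 10k+1 / 10k+5: more than 2 apart, so the contact
        # module's sequence-neighbour exclusion never hides a scripted pair
        for side, rid in ((-0.5, 10 * k + 1), (+0.5, 10 * k + 5)):
            a0 = len(atoms)
            atoms.extend(_residue_atoms(a0, rid, "A"))
            cb = base[None, :] + np.column_stack(
                [side * d, np.zeros_like(d), np.zeros_like(d)]
            )
            # backbone parked far on -y, rigid with the base
            bb = base + np.array([side * 25.0, -20.0, 0.0])
            for j, nm in enumerate(["N", "CA", "C", "O", "CB"]):
                if nm == "CB":
                    frames[:, a0 + j, :] = cb
                else:
                    frames[:, a0 + j, :] = bb + _ATOM_OFFSETS[j]
    return TrajectoryEnsemble(atoms=atoms, coords=frames)


def spec_sidecar(spec) -> str:
    """JSON description of a generator spec, for fixture sidecar files."""
    return json.dumps({"type": type(spec).__name__, "spec": asdict(spec)}, indent=2)
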