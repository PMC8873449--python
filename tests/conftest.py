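"""Shared fixtures: all test inputs are generated programmatically."""

import math

import numpy as np
import pytest

from allopath import (
    ContactScriptSpec,
    HelixMotionSpec,
    PlantedNetworkSpec,
    TrajectoryEnsemble,
)
from allopath.trajectory_io import AtomRecord

# chain phase with cos(omega) = 0.9: consecutive planted |Corr| = 0.72 clears
# the e^{-0.40} = 0.6703 edge rule, two-step |Corr| <= 0.50 stays far below it
RECOVERABLE_PHASE_DEG = math.degrees(math.acos(0.9))


def recoverable_spec(seed: int, n_frames: int = 1000) -> PlantedNetworkSpec:
    return PlantedNetworkSpec(
        n_residues=20,
        planted_path=(0, 1, 2, 3, 4),
        loading=1.0,
        noise_sd=0.5,
        chain_phase_deg=RECOVERABLE_PHASE_DEG,
        n_frames=n_frames,
        seed=seed,
    )


def null_spec(seed: int, n_frames: int = 1000) -> PlantedNetworkSpec:
    return PlantedNetworkSpec(
        n_residues=20,
        planted_path=(0, 1, 2, 3, 4),
        loading=0.0,
        noise_sd=0.5,
        n_frames=n_frames,
        seed=seed,
    )


# helix geometry whose top/middle/bottom windows sit whole turns apart
# (100 deg x 18 residues = 5 turns), so window centroids share the helical
# phase and a straight helix measures exactly 180 deg
HELIX_N_RES = 77
HELIX_WINDOWS = dict(top_range=(1, 5), middle_range=(37, 41), bottom_range=(73, 77))
HELIX_HINGE_INDEX = 38  # 0-based; centre of the middle window


@pytest.fixture
def straight_helix():
    return HelixMotionSpec(n_res=HELIX_N_RES, n_frames=5)


def single_residue_traj(positions: dict[tuple[str, int], np.ndarray], n_frames: int = 1):
    """Static trajectory with one CA + one CB per residue at the given CA positions."""
    atoms, rows = [], []
    for i, (key, pos) in enumerate(sorted(positions.items())):
        chain, rid = key
        atoms.append(AtomRecord(2 * i, "CA", "C", rid, "ALA", chain))
        atoms.append(AtomRecord(2 * i + 1, "CB", "C", rid, "ALA", chain))
        rows.append(np.asarray(pos, dtype=float))
        rows.append(np.asarray(pos, dtype=float) + np.array([0.0, 0.9, 1.1]))
    coords = np.tile(np.stack(rows)[None, :, :], (n_frames, 1, 1))
    return TrajectoryEnsemble(atoms=atoms, coords=coords)


def brute_force_minimal_path(graph, s, t):
    """Independent shortest-path oracle: exhaustive DFS over simple paths,
    breaking length ties toward the lexicographically smallest node list."""
    best = None
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, length = stack.pop()
        if best is not None and length > best[1] + 1e-12:
            continue
        if node == t:
            if (
                best is None
                or length < best[1] - 1e-12
                or (abs(length - best[1]) <= 1e-12 and path < best[0])
            ):
                best = (path, length)
            continue
        for nb in graph.neighbors(node):
            if nb not in path:
                stack.append((nb, path + [nb], length + graph[node][nb]["weight"]))
    return best


def approach_contact_spec(n_frames: int = 100) -> ContactScriptSpec:
    """Distance 8 -> 2 Å linearly; crosses 5.0 Å between frames 49 and 50."""
    return ContactScriptSpec(
        pair_schedule=(("approach", ((0, 8.0), (n_frames - 1, 2.0))),),
        n_frames=n_frames,
    )
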