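"""Trajectory containers and readers.

The whole package operates on :class:`TrajectoryEnsemble`, a plain
frames × atoms × 3 coordinate array (Å) plus per-atom metadata.  File
reading (PDB topology, multi-model PDB / DCD / XTC frames) is delegated
to MDAnalysis; multi-model PDB is the first-class text format so every
fixture in the test suite can live as plain text.

Residues are identified by ``(chain_id, residue_id)``; insertion codes
are rejected.  Coordinates are always Å internally (MDAnalysis already
converts nm formats such as XTC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "TrajectoryEnsemble",
    "ResidueSelection",
    "load_trajectory",
    "write_multimodel_pdb",
    "ca_positions",
]

# backbone atom names for standard amino-acid residues (OXT = C-terminal
# carboxyl oxygen, still backbone)
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class TrajectoryError(Exception):
    """Base error for trajectory loading / consistency problems."""


class SelectionError(TrajectoryError):
    """Raised when an atom or residue selection is empty or invalid."""


class StructureError(TrajectoryError):
    """Raised when the molecular structure violates an analysis precondition."""


def _guess_element(name: str, element: str | None) -> str:
    if element:
        return element.strip().capitalize()
    # PDB convention: leading digits then element letter(s); "1HB" is H
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D"):
        return "H"
    # two-letter elements in proteins are rare; first letter suffices
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """Metadata for one atom; classification flags are derived, not stored twice."""

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_backbone(self) -> bool:
        return (not self.is_hydrogen) and self.name in _BACKBONE_NAMES

    @property
    def is_sidechain_heavy(self) -> bool:
        return (not self.is_hydrogen) and self.name not in _BACKBONE_NAMES

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_id)


@dataclass(frozen=True)
class ResidueSelection:
    """An ordered, duplicate-free set of ``(chain_id, residue_id)`` keys."""

    members: tuple[tuple[str, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise SelectionError(f"duplicate residues in selection {self.label!r}")

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms coordinates (Å) with per-atom metadata.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``frame_times`` is an
    optional per-frame time axis in ns.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_times: np.ndarray | None = None
    _residue_keys: list[tuple[str, int]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atoms):
            raise TrajectoryError(
                f"frame has {self.coords.shape[1]} coordinates for "
                f"{len(self.atoms)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise TrajectoryError("non-finite coordinates in trajectory")
        if self._residue_keys is None:
            seen: dict[tuple[str, int], None] = {}
            for a in self.atoms:
                seen.setdefault(a.residue_key, None)
            self._residue_keys = list(seen)

    # ------------------------------------------------------------------ basic
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int]]:
        """Residue keys in order of first appearance."""
        return list(self._residue_keys)

    def residues_sorted(self) -> list[tuple[str, int]]:
        """Residue keys sorted by ``(chain_id, residue_id)``."""
        return sorted(self._residue_keys)

    def atom_indices(self, predicate) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)

    # ------------------------------------------------------------- restriction
    def select_atoms(self, predicate, label: str = "") -> "TrajectoryEnsemble":
        idx = self.atom_indices(predicate)
        if idx.size == 0:
            raise SelectionError(f"selection {label!r} matches no atoms")
        return TrajectoryEnsemble(
            atoms=[self.atoms[i] for i in idx],
            coords=self.coords[:, idx, :],
            frame_times=self.frame_times,
        )

    def select_residues(self, selection: ResidueSelection) -> "TrajectoryEnsemble":
        keys = set(selection.members)
        missing = keys - set(self._residue_keys)
        if missing:
            raise SelectionError(f"residues not in trajectory: {sorted(missing)}")
        return self.select_atoms(lambda a: a.residue_key in keys, selection.label)

    def slice_frames(self, sl: slice) -> "TrajectoryEnsemble":
        times = self.frame_times[sl] if self.frame_times is not None else None
        return TrajectoryEnsemble(
            atoms=list(self.atoms), coords=self.coords[sl], frame_times=times
        )


_SELECTION_EXPRS = {
    "all": lambda a: True,
    "ca": lambda a: a.name == "CA",
    "backbone": lambda a: a.is_backbone,
    "sidechain-heavy": lambda a: a.is_sidechain_heavy,
    "heavy": lambda a: not a.is_hydrogen,
}


def _parse_selection(expr: str | None):
    if expr is None:
        return lambda a: True
    try:
        return _SELECTION_EXPRS[expr.strip().lower()]
    except KeyError:
        raise SelectionError(
            f"unknown selection {expr!r}; choose from {sorted(_SELECTION_EXPRS)}"
        ) from None


def load_trajectory(
    topology_path,
    frames_path=None,
    selection_expr: str | None = None,
    stride: int = 1,
) -> TrajectoryEnsemble:
    """Read a trajectory into a :class:`TrajectoryEnsemble`.

    ``topology_path`` is a PDB (or any MDAnalysis-readable topology);
    ``frames_path`` may be a multi-model PDB, DCD or XTC.  ``stride``
    subsamples frames (the analysis frame rate is caller-chosen).
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if frames_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(frames_path))
    except (OSError, ValueError) as exc:
        raise TrajectoryError(f"cannot read trajectory: {exc}") from exc

    atoms = []
    for i, a in enumerate(u.atoms):
        icode = getattr(a, "icode", "")
        if icode and icode.strip():
            raise StructureError(
                f"insertion code {icode!r} on residue {a.resid}: unsupported"
            )
        try:
            element = a.element
        except mda.exceptions.NoDataError:
            element = None
        chain = getattr(a, "chainID", "") or getattr(a, "segid", "") or "A"
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=a.name,
                element=_guess_element(a.name, element),
                residue_id=int(a.resid),
                residue_name=a.resname,
                chain_id=str(chain).strip() or "A",
            )
        )

    frames = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory[::stride]:
            frames.append(u.atoms.positions.astype(float).copy())
            times.append(float(ts.time))
    traj = TrajectoryEnsemble(
        atoms=atoms,
        coords=np.stack(frames),
        frame_times=np.asarray(times) / 1000.0,  # MDAnalysis ps -> ns
    )
    if selection_expr is not None:
        traj = traj.select_atoms(_parse_selection(selection_expr), selection_expr)
    return traj


def write_multimodel_pdb(traj: TrajectoryEnsemble, path) -> None:
    """Write all frames as a multi-model PDB (text fixture format)."""
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, a in enumerate(traj.atoms):
                x, y, z = traj.coords[m, i]
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {i + 1:5d} {name:<4s}{a.residue_name:>4s} "
                    f"{a.chain_id[:1]:1s}{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def ca_positions(traj: TrajectoryEnsemble) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Per-frame Cα coordinate matrices, rows ordered by ``(chain_id, residue_id)``.

    Returns ``(array of shape (n_frames, n_residues, 3), residue_keys)``.
    Raises :class:`StructureError` naming any residue without exactly one Cα.
    """
    keys = traj.residues_sorted()
    index: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
    for i, a in enumerate(traj.atoms):
        if a.name == "CA" and not a.is_hydrogen:
            index[a.residue_key].append(i)
    rows = []
    for k in keys:
        hits = index[k]
        if len(hits) != 1:
            raise StructureError(
                f"residue {k[0]}:{k[1]} has {len(hits)} CA atoms (expected 1)"
            )
        rows.append(hits[0])
    return traj.coords[:, rows, :], keys
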