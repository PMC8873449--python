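"""Residue contact maps and contact kinetics.

Two residues are in contact in a frame when any pair of their side-chain
heavy atoms is closer than the cutoff (default 5.0 Å, strict ``<``).
Along a trajectory each pair is classified as conserved, formed (with a
formation frame ``t_f``), broken (``t_b``), transient or absent; over a
whole trajectory an occupancy-based probability map flags pairs in
contact for at least a threshold fraction of frames (default 75%).

Event frames for formed/broken contacts are defined through terminal
persistent runs: ``t_f`` is the earliest present frame from which the
pair stays present in at least the persistence fraction of the remaining
frames (and symmetrically for ``t_b``).  This anti-flicker rule is this
package's own determinisation of per-pair event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import TrajectoryEnsemble

__all__ = [
    "ContactClass",
    "ContactTimeline",
    "ContactProbabilityMap",
    "contact_map_frame",
    "contact_maps",
    "classify_contacts",
    "contact_probability",
    "diff_contact_maps",
]

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int]
Pair = tuple[ResidueKey, ResidueKey]


class ContactAnalysisError(Exception):
    pass


class ContactClass(str, Enum):
    CONSERVED = "conserved"
    FORMED = "formed"
    BROKEN = "broken"
    TRANSIENT = "transient"
    ABSENT = "absent"


@dataclass(frozen=True)
class ContactTimeline:
    pair: Pair
    present: np.ndarray  # boolean per frame
    contact_class: ContactClass
    t_f: int | None = None
    t_b: int | None = None


@dataclass(frozen=True)
class ContactProbabilityMap:
    occupancy: dict[Pair, Fraction]
    occupancy_threshold: float = 0.75

    def in_contact(self, pair: Pair) -> bool:
        return self.occupancy.get(_norm_pair(*pair), Fraction(0)) >= Fraction(
            self.occupancy_threshold
        ).limit_denominator(10**6)

    def flagged_pairs(self) -> set[Pair]:
        thr = Fraction(self.occupancy_threshold).limit_denominator(10**6)
        return {p for p, occ in self.occupancy.items() if occ >= thr}


def _norm_pair(a: ResidueKey, b: ResidueKey) -> Pair:
    return (a, b) if a <= b else (b, a)


def _sidechain_heavy_groups(traj: TrajectoryEnsemble, neighbour_exclusion: int):
    """Atom indices of side-chain heavy atoms grouped per residue.

    Glycine-like residues (no side-chain heavy atom) are excluded and
    logged once each.
    """
    groups: dict[ResidueKey, list[int]] = {}
    for i, a in enumerate(traj.atoms):
        if a.is_sidechain_heavy:
            groups.setdefault(a.residue_key, []).append(i)
    skipped = [k for k in traj.residues_sorted() if k not in groups]
    for k in skipped:
        log.info("residue %s:%d has no side-chain heavy atoms; excluded", *k)
    if not groups:
        raise ContactAnalysisError("no side-chain heavy atoms in trajectory")
    return groups


def _excluded(a: ResidueKey, b: ResidueKey, neighbour_exclusion: int) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= neighbour_exclusion


def contact_map_frame(
    traj: TrajectoryEnsemble,
    frame: int,
    cutoff: float = 5.0,
    neighbour_exclusion: int = 2,
) -> set[Pair]:
    """Unordered residue pairs in side-chain contact in one frame.

    A pair is included iff the minimum over side-chain heavy-atom pairs of
    the Euclidean distance is strictly below ``cutoff``.  Pairs in the same
    chain with ``|Δresidue_id| <= neighbour_exclusion`` are skipped.
    """
    if not (0 <= frame < traj.n_frames):
        raise ContactAnalysisError(f"frame {frame} outside [0, {traj.n_frames})")
    groups = _sidechain_heavy_groups(traj, neighbour_exclusion)
    keys = sorted(groups)
    atom_idx = np.concatenate([groups[k] for k in keys])
    owner = np.concatenate(
        [np.full(len(groups[k]), j) for j, k in enumerate(keys)]
    )
    pos = traj.coords[frame, atom_idx, :]
    tree = cKDTree(pos)
    pairs = set()
    for ia, ib in tree.query_pairs(r=cutoff):
        ra, rb = keys[owner[ia]], keys[owner[ib]]
        if ra == rb or _excluded(ra, rb, neighbour_exclusion):
            continue
        # query_pairs uses <=; the rule is strict "closer than"
        if np.linalg.norm(pos[ia] - pos[ib]) < cutoff:
            pairs.add(_norm_pair(ra, rb))
    return pairs


def contact_maps(
    traj: TrajectoryEnsemble, cutoff: float = 5.0, neighbour_exclusion: int = 2
) -> list[set[Pair]]:
    """Per-frame contact maps for the whole trajectory."""
    return [
        contact_map_frame(traj, f, cutoff, neighbour_exclusion)
        for f in range(traj.n_frames)
    ]


def _terminal_run_start(flags: np.ndarray, persistence: float) -> int | None:
    """Earliest index t with flags[t] and mean(flags[t:]) >= persistence."""
    n = len(flags)
    tail_true = np.cumsum(flags[::-1])[::-1]  # true count in flags[t:]
    for t in range(n):
        if flags[t] and tail_true[t] >= persistence * (n - t):
            return t
    return None


def classify_contacts(
    maps: Sequence[set[Pair]],
    ref_window: float = 0.05,
    end_window: float = 0.05,
    persistence: float = 0.75,
) -> list[ContactTimeline]:
    """Classify every pair ever seen (or seen in the reference window).

    A pair present in at least ``persistence`` of both the reference window
    (first ``ref_window`` fraction of frames) and the end window is
    conserved; initial-only pairs are broken with ``t_b`` the start of the
    terminal persistent-absence run; final-only pairs are formed with
    ``t_f`` the start of the terminal persistent-presence run; everything
    else seen at least once is transient.
    """
    n = len(maps)
    if n < 20:
        raise ContactAnalysisError("need >= 20 frames to classify contact kinetics")
    if ref_window + end_window > 1:
        raise ContactAnalysisError("ref_window + end_window exceed the trajectory")
    n_ref = max(1, int(round(ref_window * n)))
    n_end = max(1, int(round(end_window * n)))

    all_pairs = sorted(set().union(*maps)) if maps else []
    out = []
    for pair in all_pairs:
        present = np.array([pair in m for m in maps], dtype=bool)
        init = present[:n_ref].mean() >= persistence
        final = present[n - n_end :].mean() >= persistence
        t_f = t_b = None
        if init and final:
            cls = ContactClass.CONSERVED
        elif init and not final:
            cls = ContactClass.BROKEN
            t_b = _terminal_run_start(~present, persistence)
        elif final and not init:
            cls = ContactClass.FORMED
            t_f = _terminal_run_start(present, persistence)
        else:
            cls = ContactClass.TRANSIENT if present.any() else ContactClass.ABSENT
        out.append(
            ContactTimeline(pair=pair, present=present, contact_class=cls, t_f=t_f, t_b=t_b)
        )
    return out


def contact_probability(
    maps: Sequence[set[Pair]], threshold: float = 0.75
) -> ContactProbabilityMap:
    """Occupancy fraction per pair; flagged in-contact iff occupancy >= threshold."""
    if len(maps) < 1:
        raise ContactAnalysisError("need at least one frame")
    counts: dict[Pair, int] = {}
    for m in maps:
        for p in m:
            counts[p] = counts.get(p, 0) + 1
    occ = {p: Fraction(c, len(maps)) for p, c in counts.items()}
    return ContactProbabilityMap(occupancy=occ, occupancy_threshold=threshold)


def diff_contact_maps(
    map_a: ContactProbabilityMap, map_b: ContactProbabilityMap
) -> tuple[set[Pair], set[Pair]]:
    """(gained, lost) flagged pairs going from ``map_a`` to ``map_b``."""
    a, b = map_a.flagged_pairs(), map_b.flagged_pairs()
    return b - a, a - b


def timelines_to_records(timelines: Iterable[ContactTimeline]) -> list[dict]:
    """Flat dict records (for a DataFrame / CSV) of a classification run."""
    return [
        {
            "chain_i": t.pair[0][0],
            "res_i": t.pair[0][1],
            "chain_j": t.pair[1][0],
            "res_j": t.pair[1][1],
            "class": t.contact_class.value,
            "t_f": t.t_f,
            "t_b": t.t_b,
            "occupancy": float(t.present.mean()),
        }
        for t in timelines
    ]
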