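"""Residue-correlation communication networks.

The pipeline is: Cα fluctuation correlation matrix (vector correlation of
3D displacement, optionally after least-squares superposition of every
frame onto the mean structure) → information distances d_ij = −ln|Corr_ij|
→ communication graph keeping edges with d_ij below a cutoff G_cut
(default 0.40, i.e. |Corr| > e^{−0.40} ≈ 0.6703) → Dijkstra minimal paths
between source and sink regions, with the average minimal path length
⟨d_min⟩, a per-residue centrality index (fraction of minimal paths through
the residue) and Brandes betweenness.

Source/sink regions are residue sets whose Cα stays within a radius
(default 7 Å) of any center residue's Cα in at least an occupancy fraction
of frames (default 70%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .trajectory_io import TrajectoryEnsemble, ca_positions

__all__ = [
    "CorrelationMatrix",
    "InformationDistanceMatrix",
    "Region",
    "PathReport",
    "correlation_matrix",
    "information_distance",
    "build_graph",
    "define_region",
    "shortest_paths",
    "gcut_scan",
    "superpose_frames",
]

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int]


class NetworkAnalysisError(Exception):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    values: np.ndarray  # residue x residue, in [-1, 1]
    residues: tuple[ResidueKey, ...]
    n_frames_used: int
    alignment_applied: bool

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise NetworkAnalysisError("correlation matrix not symmetric")


@dataclass(frozen=True)
class InformationDistanceMatrix:
    """d_ij = −ln|Corr_ij|; np.inf where Corr = 0."""

    values: np.ndarray
    residues: tuple[ResidueKey, ...]
    log_base: float = math.e


@dataclass(frozen=True)
class Region:
    label: str
    center_residues: tuple[ResidueKey, ...]
    members: tuple[ResidueKey, ...]
    radius: float = 7.0
    occupancy: float = 0.70


@dataclass(frozen=True)
class PathReport:
    """Minimal source→sink paths and derived per-residue statistics."""

    paths: dict[tuple[ResidueKey, ResidueKey], tuple[list[ResidueKey], float]]
    d_min_mean: float | None
    ci: dict[ResidueKey, float]
    betweenness: dict[ResidueKey, float]
    n_unreachable: int
    ci_threshold: float = 0.15

    @property
    def no_path(self) -> bool:
        return len(self.paths) == 0

    def central_residues(self) -> list[ResidueKey]:
        return sorted(k for k, v in self.ci.items() if v > self.ci_threshold)

    def path_node_union(self) -> set[ResidueKey]:
        return set().union(*(set(p) for p, _ in self.paths.values())) if self.paths else set()


# --------------------------------------------------------------------- fit


def superpose_frames(ca: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Least-squares (Kabsch) superposition of every frame onto the mean
    Cα structure, iterated so the mean is self-consistent."""
    out = ca - ca.mean(axis=1, keepdims=True)
    for _ in range(n_iter):
        ref = out.mean(axis=0)
        ref = ref - ref.mean(axis=0)
        for f in range(out.shape[0]):
            x = out[f] - out[f].mean(axis=0)
            u, _, vt = np.linalg.svd(x.T @ ref)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, d]) @ vt
            out[f] = x @ rot
    return out


def correlation_matrix(
    traj_or_ca: TrajectoryEnsemble | np.ndarray,
    residues: tuple[ResidueKey, ...] | None = None,
    align: bool = True,
) -> CorrelationMatrix:
    """Vector correlation of Cα fluctuations.

    Corr_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr the per-frame
    deviation from the time-mean position.  With ``align`` every frame is
    first superposed onto the mean structure so rigid-body drift does not
    masquerade as internal correlation.  Zero-fluctuation residues get
    Corr = 0 against everything (flagged with a warning log).
    """
    if isinstance(traj_or_ca, TrajectoryEnsemble):
        ca, keys = ca_positions(traj_or_ca)
    else:
        ca = np.asarray(traj_or_ca, dtype=float)
        if residues is None:
            keys = [("A", i + 1) for i in range(ca.shape[1])]
        else:
            keys = list(residues)
    if ca.shape[0] < 2:
        raise NetworkAnalysisError("need >= 2 frames for a correlation matrix")
    if align:
        if ca.shape[1] < 3:
            raise NetworkAnalysisError("alignment needs >= 3 residues")
        ca = superpose_frames(ca)

    fluct = ca - ca.mean(axis=0, keepdims=True)  # (frames, residues, 3)
    # covariance of 3D fluctuation vectors: frame-average of dot products
    cov = np.einsum("fia,fja->ij", fluct, fluct) / ca.shape[0]
    var = np.diag(cov).copy()
    frozen = var <= 0
    if frozen.any():
        log.warning("%d zero-fluctuation residues; their Corr set to 0", frozen.sum())
        var[frozen] = 1.0
    corr = cov / np.sqrt(np.outer(var, var))
    corr[frozen, :] = 0.0
    corr[:, frozen] = 0.0
    np.fill_diagonal(corr, np.where(frozen, 1.0, np.diag(corr)))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        values=corr,
        residues=tuple(keys),
        n_frames_used=ca.shape[0],
        alignment_applied=align,
    )


def information_distance(
    corr: CorrelationMatrix, log_base: float = math.e
) -> InformationDistanceMatrix:
    """d_ij = −log|Corr_ij| (natural log by default); |Corr| = 0 → ∞."""
    a = np.abs(corr.values)
    with np.errstate(divide="ignore"):
        d = -np.log(a) / math.log(log_base)
    d[a == 0.0] = np.inf
    np.fill_diagonal(d, 0.0)
    return InformationDistanceMatrix(
        values=d, residues=corr.residues, log_base=log_base
    )


def build_graph(
    dist: InformationDistanceMatrix,
    g_cut: float = 0.40,
    neighbour_exclusion: int = 0,
) -> nx.Graph:
    """Communication graph: edge (i, j) iff d_ij < g_cut.

    ``neighbour_exclusion`` > 0 additionally drops same-chain pairs with
    |Δresidue_id| at or below it (off by default: sequence neighbours stay).
    """
    if g_cut <= 0:
        raise NetworkAnalysisError("g_cut must be > 0")
    g = nx.Graph()
    keys = dist.residues
    g.add_nodes_from(keys)
    d = dist.values
    for i, j in zip(*np.nonzero(np.triu(d < g_cut, k=1))):
        a, b = keys[i], keys[j]
        if neighbour_exclusion and a[0] == b[0] and abs(a[1] - b[1]) <= neighbour_exclusion:
            continue
        g.add_edge(a, b, weight=float(d[i, j]))
    if g.number_of_edges() == 0:
        log.warning("communication graph has no edges at g_cut=%.3f", g_cut)
    return g


def define_region(
    traj: TrajectoryEnsemble,
    centers: list[ResidueKey],
    radius: float = 7.0,
    occupancy: float = 0.70,
    label: str = "region",
) -> Region:
    """Residues whose Cα is within ``radius`` of any center Cα in at least
    ``occupancy`` of frames.  Centers are always members."""
    ca, keys = ca_positions(traj)
    index = {k: i for i, k in enumerate(keys)}
    for c in centers:
        if c not in index:
            raise NetworkAnalysisError(f"unknown center residue {c}")
    cpos = ca[:, [index[c] for c in centers], :]  # (frames, centers, 3)
    dmin = np.linalg.norm(ca[:, :, None, :] - cpos[:, None, :, :], axis=-1).min(axis=2)
    frac = (dmin < radius).mean(axis=0)
    members = [k for i, k in enumerate(keys) if frac[i] >= occupancy]
    members = sorted(set(members) | set(centers))
    return Region(
        label=label,
        center_residues=tuple(centers),
        members=tuple(members),
        radius=radius,
        occupancy=occupancy,
    )


def _lexicographic_shortest_path(
    g: nx.Graph, source: ResidueKey, target: ResidueKey
) -> tuple[list[ResidueKey], float] | None:
    """Deterministic minimal path: among co-minimal paths, the node sequence
    that is lexicographically smallest, built by walking the shortest-path
    DAG greedily."""
    try:
        dist_s = nx.single_source_dijkstra_path_length(g, source, weight="weight")
        dist_t = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    except nx.NodeNotFound:
        return None
    if target not in dist_s:
        return None
    total = dist_s[target]
    path = [source]
    cur = source
    visited = {source}
    while cur != target:
        candidates = [
            v
            for v in g.neighbors(cur)
            if v not in visited
            and v in dist_t
            and math.isclose(
                dist_s[cur] + g[cur][v]["weight"] + dist_t[v], total, abs_tol=1e-9
            )
            and math.isclose(dist_s[v], dist_s[cur] + g[cur][v]["weight"], abs_tol=1e-9)
        ]
        if not candidates:
            # zero-weight cycles can trap the greedy walk; fall back to a
            # plain Dijkstra path (still a minimal path, ties unordered)
            return nx.dijkstra_path(g, source, target, weight="weight"), total
        cur = min(candidates)
        visited.add(cur)
        path.append(cur)
    return path, total


def shortest_paths(
    graph: nx.Graph,
    source: Region,
    sink: Region,
    ci_threshold: float = 0.15,
    ci_over_cominimal: bool = False,
) -> PathReport:
    """Minimal paths for every reachable (source-residue, sink-residue) pair.

    ⟨d_min⟩ averages minimal lengths over reachable pairs only; unreachable
    pairs are counted in ``n_unreachable``.  CI(r) is the fraction of
    reported minimal paths containing r (with ``ci_over_cominimal``, the
    fraction of pairs where r lies on *any* co-minimal path).  Betweenness
    is Brandes' algorithm over the whole weighted graph.
    """
    s_nodes = [r for r in source.members if r in graph]
    t_nodes = [r for r in sink.members if r in graph]
    if not source.members or not sink.members:
        raise NetworkAnalysisError("source/sink region is empty")
    if set(source.members) & set(sink.members):
        raise NetworkAnalysisError("source and sink regions overlap")

    paths: dict[tuple[ResidueKey, ResidueKey], tuple[list[ResidueKey], float]] = {}
    on_any: dict[tuple[ResidueKey, ResidueKey], set[ResidueKey]] = {}
    n_unreachable = 0
    for s in s_nodes:
        for t in t_nodes:
            hit = _lexicographic_shortest_path(graph, s, t)
            if hit is None:
                n_unreachable += 1
                continue
            paths[(s, t)] = hit
            if ci_over_cominimal:
                nodes: set[ResidueKey] = set()
                for p in nx.all_shortest_paths(graph, s, t, weight="weight"):
                    nodes |= set(p)
                on_any[(s, t)] = nodes
            else:
                on_any[(s, t)] = set(hit[0])
    n_unreachable += (len(source.members) * len(sink.members)) - (
        len(s_nodes) * len(t_nodes)
    )

    if paths:
        d_min_mean = float(np.mean([l for _, l in paths.values()]))
    else:
        d_min_mean = None
        log.warning("no communication path between %s and %s", source.label, sink.label)

    ci: dict[ResidueKey, float] = {}
    if paths:
        for nodes in on_any.values():
            for r in nodes:
                ci[r] = ci.get(r, 0) + 1
        ci = {r: c / len(paths) for r, c in ci.items()}

    betweenness = nx.betweenness_centrality(graph, weight="weight", normalized=True)
    return PathReport(
        paths=paths,
        d_min_mean=d_min_mean,
        ci=ci,
        betweenness=dict(betweenness),
        n_unreachable=n_unreachable,
        ci_threshold=ci_threshold,
    )


def gcut_scan(
    dist: InformationDistanceMatrix,
    source: Region,
    sink: Region,
    g_values: list[float],
    neighbour_exclusion: int = 0,
) -> list[dict]:
    """One row per g_cut: edge count, connectivity, ⟨d_min⟩, path node union."""
    if sorted(g_values) != list(g_values):
        raise NetworkAnalysisError("g_values must be sorted ascending")
    rows = []
    for g_cut in g_values:
        graph = build_graph(dist, g_cut=g_cut, neighbour_exclusion=neighbour_exclusion)
        report = shortest_paths(graph, source, sink)
        rows.append(
            {
                "g_cut": g_cut,
                "n_edges": graph.number_of_edges(),
                "n_components": nx.number_connected_components(graph),
                "connected_pairs": len(report.paths),
                "d_min_mean": report.d_min_mean,
                "path_nodes": sorted(report.path_node_union()),
            }
        )
    return rows
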