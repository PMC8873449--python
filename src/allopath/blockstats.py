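"""Block-variance reproducibility statistics for information distances.

A trajectory is split into N_B contiguous, equal-length, non-overlapping
blocks (default 4; 1000 frames → 4 × 250).  Each block yields its own
information-distance matrix Ḡ_B (independent superposition and
correlation).  Treating blocks as uncorrelated measurements, the
variance of the mean of each matrix element is

    σ²((Ḡ_ij)_B) = 1 / (N_B (N_B − 1)) · Σ_B ((Ḡ_ij)_B − ⟨(Ḡ_ij)_B⟩)²

i.e. the unbiased sample variance across blocks divided by N_B.
Summaries (min/max/mean) are reported over all pairs and over the most
correlated pairs (⟨Ḡ_ij⟩ < G_cut); pairs with any infinite block value
(zero correlation) are excluded from summaries and counted.  A per-edge
table along a stated pathway supports the comparison of path-edge
variance against the whole-network average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import InformationDistanceMatrix, correlation_matrix, information_distance
from .trajectory_io import TrajectoryEnsemble, ca_positions

__all__ = [
    "BlockVarianceReport",
    "block_information_distances",
    "variance_of_mean",
    "pathway_variance",
]

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int]


class BlockStatsError(Exception):
    pass


@dataclass(frozen=True)
class BlockVarianceReport:
    residues: tuple[ResidueKey, ...]
    n_blocks: int
    mean: np.ndarray  # ⟨(Ḡ_ij)_B⟩
    var_of_mean: np.ndarray  # σ²((Ḡ_ij)_B)
    summary_all: dict[str, float]
    summary_correlated: dict[str, float]
    n_excluded_infinite: int
    g_cut: float = 0.40


def block_information_distances(
    traj: TrajectoryEnsemble, n_blocks: int = 4, align: bool = True
) -> list[InformationDistanceMatrix]:
    """Per-block information-distance matrices from contiguous time slices."""
    if n_blocks < 2:
        raise BlockStatsError("need at least 2 blocks")
    ca, keys = ca_positions(traj)
    n = ca.shape[0]
    size = n // n_blocks
    if size < 2:
        raise BlockStatsError("blocks would have fewer than 2 frames")
    if n % n_blocks:
        log.warning("dropping %d trailing frames (not divisible by %d blocks)", n % n_blocks, n_blocks)
    out = []
    for b in range(n_blocks):
        block = ca[b * size : (b + 1) * size]
        corr = correlation_matrix(block, residues=tuple(keys), align=align)
        out.append(information_distance(corr))
    return out


def variance_of_mean(
    block_matrices: list[InformationDistanceMatrix], g_cut: float = 0.40
) -> BlockVarianceReport:
    """Per-pair block mean and variance of the mean, with summaries."""
    if len(block_matrices) < 2:
        raise BlockStatsError("need at least 2 blocks")
    residues = block_matrices[0].residues
    stack = np.stack([m.values for m in block_matrices])  # (blocks, n, n)
    nb = stack.shape[0]
    mean = stack.mean(axis=0)
    # Eq-style variance of the mean: unbiased across-block variance / N_B
    with np.errstate(invalid="ignore"):
        var = stack.var(axis=0, ddof=1) / nb

    n = mean.shape[0]
    iu = np.triu_indices(n, k=1)
    finite = np.isfinite(stack).all(axis=0)[iu]
    n_excluded = int((~finite).sum())
    v_all = var[iu][finite]
    m_all = mean[iu][finite]
    correlated = m_all < g_cut

    def _summary(v: np.ndarray) -> dict[str, float]:
        if v.size == 0:
            return {"min": np.nan, "max": np.nan, "mean": np.nan, "n_pairs": 0}
        return {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "n_pairs": int(v.size),
        }

    return BlockVarianceReport(
        residues=residues,
        n_blocks=nb,
        mean=mean,
        var_of_mean=var,
        summary_all=_summary(v_all),
        summary_correlated=_summary(v_all[correlated]),
        n_excluded_infinite=n_excluded,
        g_cut=g_cut,
    )


def pathway_variance(
    path: list[ResidueKey],
    block_matrices: list[InformationDistanceMatrix],
    g_cut: float = 0.40,
) -> dict:
    """Edge table ⟨Ḡ⟩ / σ² along Res1→Res2→…→ResN plus the ratio of the
    path-edge mean σ² to the whole-network mean σ²."""
    if len(path) < 2:
        raise BlockStatsError("path needs at least 2 residues")
    report = variance_of_mean(block_matrices, g_cut=g_cut)
    index = {k: i for i, k in enumerate(report.residues)}
    for r in path:
        if r not in index:
            raise BlockStatsError(f"path residue {r} absent from matrices")
    edges = []
    for a, b in zip(path[:-1], path[1:]):
        i, j = index[a], index[b]
        edges.append(
            {
                "from": a,
                "to": b,
                "mean_G": float(report.mean[i, j]),
                "var_of_mean": float(report.var_of_mean[i, j]),
            }
        )
    finite_vars = [e["var_of_mean"] for e in edges if np.isfinite(e["var_of_mean"])]
    network_mean = report.summary_all["mean"]
    if finite_vars and network_mean and np.isfinite(network_mean) and network_mean > 0:
        ratio = float(np.mean(finite_vars) / network_mean)
    else:
        ratio = None  # constant matrices or no finite edges: ratio undefined
    return {
        "edges": edges,
        "path_mean_var": float(np.mean(finite_vars)) if finite_vars else None,
        "network_mean_var": network_mean,
        "ratio_path_to_network": ratio,
    }
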