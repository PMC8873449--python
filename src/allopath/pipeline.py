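"""Configuration-driven orchestration of the full analysis workflow.

``run_pipeline`` drives contacts → network → (optional) geometry → PMF →
block statistics over one trajectory and writes every stage's artifacts
plus a manifest into a run directory.  ``compare_systems`` contrasts the
path reports of several systems (wild type vs mutants vs split
constructs): Δ⟨d_min⟩ against the first system, Jaccard overlap of the
union-of-path node sets, and per-system no-path flags.

All fixed parameters default to the study-standard values: 5.0 Å contact
cutoff with 75% occupancy, G_cut = 0.40 with 7 Å / 70% source–sink
regions and CI threshold 0.15, T = 300.0 K, 4 blocks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blockstats, contacts, network
from .network import PathReport
from .trajectory_io import TrajectoryEnsemble, load_trajectory

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "compare_systems"]

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int]


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; defaults are the study's."""

    topology: str | None = None
    frames: str | None = None
    out_dir: str = "run"
    seed: int = 0
    # contacts
    contact_cutoff: float = 5.0
    contact_occupancy: float = 0.75
    neighbour_exclusion: int = 2
    # network
    g_cut: float = 0.40
    log_base: float = float(np.e)
    source_centers: list = field(default_factory=list)  # ["A:536", ...]
    sink_centers: list = field(default_factory=list)
    region_radius: float = 7.0
    region_occupancy: float = 0.70
    ci_threshold: float = 0.15
    align: bool = True
    # blocks
    n_blocks: int = 4
    # pmf
    temperature: float = 300.0
    # geometry: optional; see `_geometry_stage` for the schema
    geometry: dict | None = None

    def validate(self) -> None:
        if self.g_cut <= 0:
            raise ConfigError("g_cut must be > 0")
        if not (0 < self.contact_occupancy <= 1):
            raise ConfigError("contact_occupancy must be in (0, 1]")
        if not (0 < self.region_occupancy <= 1):
            raise ConfigError("region_occupancy must be in (0, 1]")
        if self.n_blocks < 2:
            raise ConfigError("n_blocks must be >= 2")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def parse_residue(label: str) -> ResidueKey:
    """'A:536' → ('A', 536)."""
    chain, _, rid = str(label).partition(":")
    if not rid:
        raise ConfigError(f"residue label {label!r} must be 'CHAIN:RESID'")
    return (chain, int(rid))


def _matrix_csv(values: np.ndarray, residues, path: Path) -> None:
    labels = [f"{c}:{r}" for c, r in residues]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)


def _path_report_json(report: PathReport) -> dict:
    return {
        "no_path": report.no_path,
        "d_min_mean": report.d_min_mean,
        "n_paths": len(report.paths),
        "n_unreachable": report.n_unreachable,
        "paths": [
            {
                "source": f"{s[0]}:{s[1]}",
                "sink": f"{t[0]}:{t[1]}",
                "length": length,
                "nodes": [f"{c}:{r}" for c, r in nodes],
            }
            for (s, t), (nodes, length) in sorted(report.paths.items())
        ],
        "ci": {f"{c}:{r}": v for (c, r), v in sorted(report.ci.items())},
        "ci_over_threshold": [f"{c}:{r}" for c, r in report.central_residues()],
        "betweenness": {f"{c}:{r}": v for (c, r), v in sorted(report.betweenness.items())},
    }


def _geometry_stage(traj: TrajectoryEnsemble, geo: dict) -> dict[str, list[float]]:
    """Compute the configured geometric observables.

    Schema (all sections optional, lists average over entries)::

        s6:  [{chain: A, range: [635, 667], top: [635, 639],
               middle: [646, 650], bottom: [663, 667]}, ...]
        s4:  [{chain: A, range: [1, 21], middle_anchor: 8,
               bottom_anchor: 14, axis: [0, 0, 1]}, ...]
        tmd: [["A", 100, 200], ...four chains...]   # with `ctd` → φ13/φ24
        ctd: [["A", 300, 400], ...]
    """
    from . import geometry as geom_mod

    out: dict[str, list[float]] = {}

    def _helix(entry: dict, **extra) -> geom_mod.HelixDefinition:
        axis = entry.get("axis")
        return geom_mod.HelixDefinition(
            chain_id=entry["chain"],
            residue_range=tuple(entry["range"]),
            axis=tuple(axis) if axis else None,
            **extra,
        )

    if geo.get("s6"):
        thetas = [
            geom_mod.bending_angle(
                traj,
                _helix(
                    e,
                    top_range=tuple(e["top"]),
                    middle_range=tuple(e["middle"]),
                    bottom_range=tuple(e["bottom"]),
                ),
            )
            for e in geo["s6"]
        ]
        out["s6_bending"] = list(np.nanmean(np.column_stack(thetas), axis=1))
    if geo.get("s4"):
        helices = [_helix(e) for e in geo["s4"]]
        disp = [geom_mod.s4_displacement(traj, h) for h in helices]
        out["s4_displacement"] = list(np.mean(np.column_stack(disp), axis=1))
        rot = [
            geom_mod.s4_rotation(traj, h, e["middle_anchor"])
            for h, e in zip(helices, geo["s4"])
        ]
        out["s4_rotation"] = list(np.nanmean(np.column_stack(rot), axis=1))
        if all("bottom_anchor" in e for e in geo["s4"]):
            rot_b = [
                geom_mod.s4_rotation(traj, h, e["bottom_anchor"])
                for h, e in zip(helices, geo["s4"])
            ]
            out["s4_rotation_bottom"] = list(np.nanmean(np.column_stack(rot_b), axis=1))
    if geo.get("tmd") and geo.get("ctd"):
        from .trajectory_io import ResidueSelection

        def _sel(entries, label):
            sels = []
            for chain, lo, hi in entries:
                keys = [
                    k
                    for k in set(a.residue_key for a in traj.atoms)
                    if k[0] == chain and lo <= k[1] <= hi
                ]
                sels.append(ResidueSelection(members=tuple(sorted(keys)), label=label))
            return sels

        _, _, phi_mean = geom_mod.pd_ctd_rotation(
            traj, _sel(geo["tmd"], "tmd"), _sel(geo["ctd"], "ctd")
        )
        out["pd_ctd_rotation"] = list(phi_mean)
    if not out:
        raise ConfigError("geometry config present but no observables configured")
    return out


def _pmf_csv(surf, path: Path) -> None:
    """Long-format grid: one row per bin with centers, H and PMF."""
    xc = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
    yc = 0.5 * (surf.y_edges[:-1] + surf.y_edges[1:])
    rows = [
        {
            surf.x_label: xc[i],
            surf.y_label: yc[j],
            "H": surf.hist[i, j],
            "pmf_kcal_mol": surf.pmf[i, j],
        }
        for i in range(len(xc))
        for j in range(len(yc))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(
    config: RunConfig, traj: TrajectoryEnsemble | None = None
) -> tuple[Path, PathReport]:
    """Run all stages; returns the run directory and the path report.

    A pre-loaded trajectory may be passed directly (synthetic fixtures);
    otherwise it is read from ``config.topology`` / ``config.frames``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": [], "parameters": dataclasses.asdict(config)}

    if traj is None:
        if config.topology is None:
            raise ConfigError("no trajectory: set topology/frames or pass traj")
        traj = load_trajectory(config.topology, config.frames)
    manifest["n_frames"] = traj.n_frames
    manifest["n_atoms"] = traj.n_atoms
    manifest["coords_sha1"] = hashlib.sha1(
        np.ascontiguousarray(traj.coords).tobytes()
    ).hexdigest()

    def stage(name):
        t0 = time.perf_counter()

        def done(**artifacts):
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3), **artifacts}
            )

        return done

    # ---- contacts
    done = stage("contacts")
    timelines: list = []
    try:
        maps = contacts.contact_maps(
            traj, cutoff=config.contact_cutoff, neighbour_exclusion=config.neighbour_exclusion
        )
        timelines = contacts.classify_contacts(maps)
        prob = contacts.contact_probability(maps, threshold=config.contact_occupancy)
        pd.DataFrame(contacts.timelines_to_records(timelines)).to_csv(
            out / "contact_classes.csv", index=False
        )
        pd.DataFrame(
            [
                {"chain_i": p[0][0], "res_i": p[0][1], "chain_j": p[1][0], "res_j": p[1][1],
                 "occupancy": float(occ), "in_contact": occ >= prob.occupancy_threshold}
                for p, occ in sorted(prob.occupancy.items())
            ]
        ).to_csv(out / "contact_probability.csv", index=False)
        done(n_pairs_classified=len(timelines))
    except contacts.ContactAnalysisError as exc:
        # e.g. a Cα-only trajectory: no side-chain heavy atoms to pair
        log.warning("contacts stage skipped: %s", exc)
        done(skipped=str(exc))

    # ---- network
    done = stage("network")
    corr = network.correlation_matrix(traj, align=config.align)
    dist = network.information_distance(corr, log_base=config.log_base)
    _matrix_csv(corr.values, corr.residues, out / "correlation_matrix.csv")
    _matrix_csv(dist.values, dist.residues, out / "information_distance.csv")
    graph = network.build_graph(dist, g_cut=config.g_cut)
    try:
        import networkx as nx

        nx.write_graphml(
            nx.relabel_nodes(graph, {n: f"{n[0]}:{n[1]}" for n in graph.nodes}),
            out / "communication_graph.graphml",
        )
    except Exception as exc:  # graph export is best-effort
        log.warning("GraphML export failed: %s", exc)
    report = None
    if config.source_centers and config.sink_centers:
        src = network.define_region(
            traj, [parse_residue(r) for r in config.source_centers],
            radius=config.region_radius, occupancy=config.region_occupancy, label="source",
        )
        snk = network.define_region(
            traj, [parse_residue(r) for r in config.sink_centers],
            radius=config.region_radius, occupancy=config.region_occupancy, label="sink",
        )
        report = network.shortest_paths(graph, src, snk, ci_threshold=config.ci_threshold)
        (out / "path_report.json").write_text(json.dumps(_path_report_json(report), indent=2))
    done(n_edges=graph.number_of_edges(), has_paths=report is not None and not report.no_path)

    # ---- geometry + PMF (only when a geometry config is present)
    if config.geometry:
        done = stage("geometry")
        observables = _geometry_stage(traj, config.geometry)
        pd.DataFrame(observables).to_csv(out / "geometry_series.csv", index_label="frame")
        done(observables=sorted(observables))

        done = stage("pmf")
        from . import pmf as pmf_mod

        n_surfaces = 0
        names = sorted(observables)
        for i, yn in enumerate(names):
            for xn in names[i + 1 :]:
                surf = pmf_mod.pmf_2d(
                    np.asarray(observables[xn]),
                    np.asarray(observables[yn]),
                    pmf_mod.PANEL_BIN_WIDTHS.get(xn, 1.0),
                    pmf_mod.PANEL_BIN_WIDTHS.get(yn, 1.0),
                    temperature=config.temperature,
                    x_label=xn,
                    y_label=yn,
                )
                _pmf_csv(surf, out / f"pmf_{yn}_vs_{xn}.csv")
                n_surfaces += 1
        done(n_surfaces=n_surfaces)

    # ---- block statistics
    done = stage("block_stats")
    blocks = blockstats.block_information_distances(traj, n_blocks=config.n_blocks, align=config.align)
    bv = blockstats.variance_of_mean(blocks, g_cut=config.g_cut)
    (out / "block_variance.json").write_text(
        json.dumps(
            {
                "n_blocks": bv.n_blocks,
                "summary_all": bv.summary_all,
                "summary_correlated": bv.summary_correlated,
                "n_excluded_infinite": bv.n_excluded_infinite,
            },
            indent=2,
        )
    )
    done(n_blocks=config.n_blocks)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_report_md(out, report, timelines)
    return out, report


def _write_report_md(out: Path, report: PathReport | None, timelines) -> None:
    lines = ["# Pipeline report", ""]
    by_class: dict[str, int] = {}
    for t in timelines:
        by_class[t.contact_class.value] = by_class.get(t.contact_class.value, 0) + 1
    lines.append(f"Contact classes: {json.dumps(by_class)}")
    if report is not None:
        if report.no_path:
            lines.append("Network: **no communication path** between source and sink.")
        else:
            lines.append(f"Network: <d_min> = {report.d_min_mean:.4f} over {len(report.paths)} pairs;")
            lines.append(
                "CI > threshold residues: "
                + ", ".join(f"{c}:{r}" for c, r in report.central_residues())
            )
    (out / "report.md").write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ComparisonReport:
    labels: tuple[str, ...]
    d_min_means: tuple[float | None, ...]
    delta_d_min: tuple[float | None, ...]  # vs first label
    jaccard_vs_first: tuple[float | None, ...]
    no_path: tuple[bool, ...]


def compare_systems(reports: list[PathReport], labels: list[str]) -> ComparisonReport:
    """Contrast several systems' path reports against the first one."""
    if len(reports) < 2:
        raise ConfigError("need at least 2 reports to compare")
    if len(reports) != len(labels):
        raise ConfigError("labels and reports differ in length")
    ref_nodes = reports[0].path_node_union()
    d0 = reports[0].d_min_mean
    deltas, jaccards = [], []
    for r in reports:
        if r.d_min_mean is None or d0 is None:
            deltas.append(None)
        else:
            deltas.append(r.d_min_mean - d0)
        nodes = r.path_node_union()
        union = ref_nodes | nodes
        jaccards.append(len(ref_nodes & nodes) / len(union) if union else None)
    return ComparisonReport(
        labels=tuple(labels),
        d_min_means=tuple(r.d_min_mean for r in reports),
        delta_d_min=tuple(deltas),
        jaccard_vs_first=tuple(jaccards),
        no_path=tuple(r.no_path for r in reports),
    )
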