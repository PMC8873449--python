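#!/usr/bin/env python
"""Communication-network analysis on planted-correlation trajectories.

Builds the information-distance graph (d_ij = −ln|Corr_ij|, G_cut = 0.40)
from Cα fluctuations of a latent-factor trajectory with a planted chain of
correlated residues, extracts source→sink minimal paths with ⟨d_min⟩,
centrality index and betweenness, and scans the cutoff G_cut.  The planted
chain is the known answer: the run reports how often it is re-identified
over 20 seeds, and that the null (uncoupled) model yields no path.
"""

import json
import math
from pathlib import Path

import pandas as pd

import allopath as ap

OUT = Path(__file__).resolve().parent.parent / "results"
PHASE_DEG = math.degrees(math.acos(0.9))


def _report(loading, seed):
    spec = ap.PlantedNetworkSpec(
        n_residues=20, planted_path=(0, 1, 2, 3, 4), loading=loading,
        noise_sd=0.5, chain_phase_deg=PHASE_DEG, n_frames=1000, seed=seed,
    )
    traj = ap.make_planted_network_traj(spec)
    corr = ap.correlation_matrix(traj, align=False)
    dist = ap.information_distance(corr)
    graph = ap.build_graph(dist, g_cut=0.40)
    planted = [("A", r + 1) for r in spec.planted_path]
    src = ap.Region("source", (planted[0],), (planted[0],))
    snk = ap.Region("sink", (planted[-1],), (planted[-1],))
    return ap.shortest_paths(graph, src, snk), planted, dist


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # one detailed run
    report, planted, dist = _report(1.0, seed=1)
    path, length = report.paths[(planted[0], planted[-1])]
    print("seed 1 minimal path:", " -> ".join(f"{c}:{r}" for c, r in path))
    print(f"  <d_min> = {report.d_min_mean:.4f}  "
          f"(4 edges x -ln 0.72 = {4 * -math.log(0.72):.4f} expected)")
    print("  CI = 1 on:", sorted(k for k, v in report.ci.items() if v == 1.0))

    # recovery statistics over 20 seeds
    hits = no_path_null = 0
    for seed in range(20):
        rep, pl, _ = _report(1.0, seed)
        if not rep.no_path:
            nodes, _ = rep.paths[(pl[0], pl[-1])]
            if set(nodes) >= set(pl):
                hits += 1
        rep0, _, _ = _report(0.0, seed)
        no_path_null += rep0.no_path
    print(f"\nplanted chain recovered in {hits}/20 seeds; "
          f"null model shows no path in {no_path_null}/20 seeds")

    # G_cut scan on the seed-1 system
    src = ap.Region("source", (planted[0],), (planted[0],))
    snk = ap.Region("sink", (planted[-1],), (planted[-1],))
    rows = ap.gcut_scan(dist, src, snk, [0.1, 0.2, 0.3, 0.4, 0.6, 1.0])
    scan = pd.DataFrame(
        [{k: (len(v) if k == "path_nodes" else v) for k, v in r.items()}
         for r in rows]
    ).rename(columns={"path_nodes": "n_path_nodes"})
    scan.to_csv(OUT / "gcut_scan.csv", index=False)
    print("\nG_cut scan (edge counts grow, path lengths shrink):")
    print(scan.to_string(index=False))

    summary = {
        "planted_recovery_seeds": f"{hits}/20",
        "null_no_path_seeds": f"{no_path_null}/20",
        "d_min_seed1": report.d_min_mean,
    }
    (OUT / "network_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
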