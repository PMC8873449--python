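#!/usr/bin/env python
"""Comparison runs: intact vs weakened vs decoupled communication.

The analogue of comparing a wild-type channel against mutants and split
constructs: the same planted-chain system is re-analysed with the latent
coupling intact (λ = 1.0), weakened (λ = 0.9, longer paths) and removed
(λ = 0, the split-construct analogue where no communication path should
be detected).  Reports Δ⟨d_min⟩ against the intact system, the Jaccard
overlap of path node sets, and no-path flags.
"""

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
    graph = ap.build_graph(ap.information_distance(corr), g_cut=0.40)
    src = ap.Region("source", (("A", 1),), (("A", 1),))
    snk = ap.Region("sink", (("A", 5),), (("A", 5),))
    return ap.shortest_paths(graph, src, snk)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in range(10):
        reports = [_report(lam, seed) for lam in (1.0, 0.9, 0.0)]
        cmp = ap.compare_systems(reports, ["intact", "weakened", "decoupled"])
        for i, label in enumerate(cmp.labels):
            rows.append({
                "seed": seed, "system": label,
                "d_min_mean": cmp.d_min_means[i],
                "delta_vs_intact": cmp.delta_d_min[i],
                "jaccard_vs_intact": cmp.jaccard_vs_first[i],
                "no_path": cmp.no_path[i],
            })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "system_comparison.csv", index=False)

    agg = df.groupby("system", sort=False).agg(
        d_min=("d_min_mean", "mean"),
        no_path_fraction=("no_path", "mean"),
    )
    print(df.head(9).to_string(index=False))
    print("\naverages over 10 seeds:")
    print(agg.to_string())
    print("\nweakened coupling (per-step |Corr| 0.72 -> 0.69, barely above "
          "the 0.67 edge rule) lengthens the path, and in seeds where an "
          "edge slips below the cutoff severs it; removing the coupling "
          "leaves no path at all, the split-construct signature.")


if __name__ == "__main__":
    main()
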