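#!/usr/bin/env python
"""Generate the synthetic ground-truth trajectories used by all later steps.

Three fixture families are written under results/fixtures/ as multi-model
PDB plus a JSON sidecar recording the generating spec:

* a planted-correlation trajectory (latent-factor chain, the communication
  network's ground truth),
* an ideal helix under known rigid motions (geometry ground truth),
* a scripted contact approach (contact-kinetics ground truth).

Only short versions are written to disk (the analysis steps regenerate
full-length trajectories in memory from the same specs).
"""

import math
from pathlib import Path

import allopath as ap
from allopath.synthetic import spec_sidecar

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
PHASE_DEG = math.degrees(math.acos(0.9))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    planted = ap.PlantedNetworkSpec(
        n_residues=20, planted_path=(0, 1, 2, 3, 4), loading=1.0, noise_sd=0.5,
        chain_phase_deg=PHASE_DEG, n_frames=50, seed=1,
    )
    traj = ap.make_planted_network_traj(planted)
    ap.write_multimodel_pdb(traj, OUT / "planted_network.pdb")
    (OUT / "planted_network.pdb.json").write_text(spec_sidecar(planted))
    print(f"planted network: {traj.n_frames} frames x {traj.n_atoms} atoms, "
          f"chain residues A:1..A:5, expected neighbour |Corr| = "
          f"{ap.planted_pair_correlation(planted):.3f}")

    helix = ap.HelixMotionSpec(
        n_res=21, applied_axial_shift=5.0, applied_axial_rotation=40.0, n_frames=11
    )
    traj = ap.make_helix_traj(helix)
    ap.write_multimodel_pdb(traj, OUT / "helix_motion.pdb")
    (OUT / "helix_motion.pdb.json").write_text(spec_sidecar(helix))
    print(f"helix motion: {traj.n_frames} frames, final shift 5.0 A + rotation 40 deg")

    contact = ap.ContactScriptSpec(
        pair_schedule=(("approach", ((0, 8.0), (99, 2.0))),), n_frames=100
    )
    traj = ap.make_contact_traj(contact)
    ap.write_multimodel_pdb(traj, OUT / "contact_script.pdb")
    (OUT / "contact_script.pdb.json").write_text(spec_sidecar(contact))
    print("contact script: pair A:1-A:5 approaching 8 -> 2 A over 100 frames "
          "(crosses 5.0 A between frames 49 and 50)")


if __name__ == "__main__":
    main()
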