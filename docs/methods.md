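# Methods

## Scope and model

The package analyses multi-frame coordinate trajectories of a multi-chain
protein. Five computations are implemented: residue-correlation
communication networks, contact-map kinetics, geometric gating
descriptors, pseudo-potentials of mean force, and block-variance
reproducibility statistics. All stages consume a common
`TrajectoryEnsemble` (frames × atoms × 3 coordinates in Å with per-atom
residue/chain metadata); file I/O goes through MDAnalysis, with
multi-model PDB as the first-class text format so fixtures stay plain
text.

## Communication networks

The correlation coefficient of Cα motion is the normalized covariance of
3D fluctuation vectors,

    Corr_ij = ⟨Δr_i · Δr_j⟩ / √(⟨Δr_i²⟩ ⟨Δr_j²⟩),  Δr = r − ⟨r⟩,

a scalar in [−1, 1] that contracts the full 3×3 covariance to the trace.
The information distance is d_ij = −ln|Corr_ij|. **Logarithm base**: the
natural log is the only base under which the stated cutoff pair
(G_cut = 0.40, |Corr| > 0.67) is self-consistent — e^(−0.40) = 0.6703,
whereas a base-10 reading would put the correlation threshold at 0.398.
The base is nevertheless a config parameter.

**Superposition.** By default every frame is least-squares (Kabsch)
superposed onto the iterated mean Cα structure before computing
correlations, so rigid-body drift does not masquerade as internal
correlation. For the synthetic latent-factor trajectories the analyses
run with `align=False`: those fixtures have no rigid-body motion by
construction, and superposition would partially absorb the planted
collective mode into the removed rigid-body fit, biasing the closed-form
correlations the fixtures are designed to exhibit. On real MD data the
default (aligned) setting is the appropriate one.

**Graph and paths.** Edges connect pairs with d_ij < G_cut (default
0.40); sequence-neighbour edges are retained by default with a config
switch. Dijkstra shortest paths and Brandes betweenness run through
networkx. Among co-minimal paths the reported one is the
lexicographically smallest node sequence, found by walking the
shortest-path DAG greedily; zero-weight cycles (|Corr| = 1 pairs, which
occur in deterministic fixtures) make the walk fall back to a plain
Dijkstra path. The centrality index CI(r) is the fraction of reported
minimal paths containing r; a flag recomputes it over all co-minimal
paths. ⟨d_min⟩ averages over reachable source–sink pairs only, with the
unreachable count always reported — a system with no reachable pair
reports an explicit no-path status rather than an infinite mean.
Source/sink regions collect residues whose Cα stays within 7 Å of any
center residue in ≥ 70% of frames; centers are always members. Residues
with zero fluctuation are flagged and contribute no edges.

## Contact kinetics

Two residues are in contact in a frame when any pair of side-chain heavy
atoms is strictly closer than 5.0 Å ("closer than" is read as a strict
inequality, so a pair at exactly 5.0 Å is not in contact). Glycine-like
residues without side-chain heavy atoms are excluded and logged.
Same-chain pairs within two sequence positions are excluded by default
(config knob) to suppress trivially persistent covalent-neighbour
contacts. Classification over a trajectory compares a reference window
(first 5% of frames) with an end window (last 5%) at a 75% persistence
level: present in both → conserved; present only initially → broken;
present only finally → formed. Event frames use terminal persistent
runs: t_f is the earliest present frame from which the pair remains
present in ≥ 75% of the remaining frames (symmetrically t_b for
absence). This anti-flicker rule is the package's own determinisation —
it is exact on monotone approach/retreat profiles and robust to
oscillation around the cutoff. Occupancy probabilities are exact
rationals (count/frames) and the in-contact flag is inclusive at the
threshold (750/1000 ≥ 75% is flagged; 749/1000 is not).

## Gating geometry

* **Bending θ**: angle at the helix middle window between Cα-centroid
  vectors to the top and bottom windows; a straight helix reads ≈ 180°
  and a hinge bend of β reads ≈ 180° − β.
* **Axial rotation α**: v_rot points from the midpoint of Cα(n) and
  Cα(n+4) to Cα(n+2); α is the angle between the components of v_rot(t)
  and v_rot(0) orthogonal to the helix axis, unsigned in [0°, 180°] (a
  signed variant using the triple product with the axis is available as
  a clearly marked extra column).
* **Axial displacement d**: signed projection of the helix Cα-COM
  displacement from frame 0 onto the axis versor ĥ.
* **Domain rotation φ13/φ24**: angle between the vector joining the
  transmembrane-domain mass centers of non-neighbouring chains (1,3) or
  (2,4) and the corresponding cytosolic-domain vector; the reported
  rotation is their mean. Domain COMs are mass-weighted over heavy
  atoms, whereas helix sub-range centroids are unweighted Cα centroids —
  domain centers of mass read naturally as physical COMs, helix windows
  as Cα constructions.

**Helix axis.** ĥ is fitted on a reference frame and held fixed, since
displacement compares each frame against frame 0 along one versor. The
fit uses the local curvature vectors (second differences of consecutive
Cα), which are exactly perpendicular to the axis of an ideal helix: the
least-variance direction of the curvature set recovers the axis to
machine precision for any helix length, where the principal axis of the
raw point cloud is biased by partial helical turns (≈ 1.4° for a
21-residue helix). Collinear traces fall back to the principal axis of
the points. The sign convention runs from the first toward the last
residue of the range. An explicit axis can be supplied instead, and the
anchor residues n for the rotation windows are configuration values.

Per-observable subunit averaging follows the convention that θ, α
(middle and bottom anchors separately) and d average over the four
subunits, and the domain rotation is mean(φ13, φ24).

## Pseudo-PMF

PMF(x, y) = −k_B T ln H(x, y) with H a normalized 2D histogram,
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹ and T defaulting to 300.0 K; a count
ratio of e between two bins therefore separates them by
k_B·300 = 0.5962 kcal/mol. Bin edges anchor at integer multiples of the
bin width (so shifting a series by whole widths relabels bins without
changing values); surfaces are min-shifted to zero for display with the
raw values retained; empty bins are masked NaN, never given a finite
penalty, because H = 0 has no defined free energy. The canonical
six-surface panel pairs S4 displacement (1.0 Å bins), S4 rotation (2°),
S6 bending (1°) and PD–CTD rotation (1°). When samples come from driven,
out-of-equilibrium trajectories the surface is a qualitative
("pseudo") landscape; the computation is identical and no reweighting is
attempted.

## Block statistics

Trajectories are split into N_B contiguous, equal, non-overlapping
blocks (default 4; trailing frames dropped with a warning). Contiguity
matters: interleaved blocks would defeat the premise that blocks are
approximately uncorrelated measurements. Each block gets an independent
superposition and correlation matrix. The variance of the mean is the
unbiased across-block sample variance divided by N_B. Pairs with any
infinite block distance (zero correlation) are excluded from summaries
and counted. Pathway tables report per-edge means and variances along a
stated residue chain plus the ratio of the path-edge mean variance to
the whole-network mean variance.

## Synthetic ground truth

The generators define the validation conditions; their defaults are not
tuned per run.

* **Planted correlation chains.** Planted residue k moves as
  Δr_k = λ[cos(kω) p(t) + sin(kω) q(t)] + ε, with p, q i.i.d. standard
  normal 3-vectors per frame and ε isotropic noise of sd σ per axis,
  giving the closed form Corr(k, j) = cos((k−j)ω)·λ²/(λ²+σ²).
  Defaults λ = 1, σ = 0.5 Å, 1000 frames. With ω = 0 (the default) all
  planted residues share one factor and neighbour correlation is exactly
  λ²/(λ²+σ²) = 0.8; the chain-recovery fixtures use cos ω = 0.9, so
  consecutive pairs sit at |Corr| = 0.72 (above the 0.6703 edge rule by
  ≈ 3 sampling standard deviations at 1000 frames) while two-step pairs
  sit at 0.50 and beyond (far below it) — which is precisely what makes
  the planted chain the unique shortest route rather than a shortcut
  through a long-range edge. Non-planted residues receive independent
  noise only; mean positions sit on a grid ≥ 10 Å apart so regions stay
  single-residue. Residues are alanine-like (backbone + one side-chain
  heavy pseudo-atom) so the contact rule applies unchanged. The latent
  factor is a full 3-vector, exercising the vector dot-product form of
  the correlation rather than a 1D special case.
* **Helix motions.** An ideal α-helix (rise 1.5 Å, twist 100°, radius
  2.3 Å) undergoes axial shifts, axial rotations about its exact axis
  and hinge bends (rotation of all residues past a hinge Cα), applied
  linearly in frame index. The bending-angle validation helix uses 77
  residues with 5-residue windows spaced 18 residues apart — five full
  turns — so the three window centroids share a helical phase and a
  straight helix measures exactly 180°; with the hinge at the middle
  window the residual window-straddling bias is ≈ 1° for a 30° bend,
  inside the 2° recovery tolerance.
* **Scripted contacts.** Each pair's single side-chain heavy atoms track
  a piecewise-linear distance profile to machine precision, making
  formation/breaking frames exact arithmetic.

What the fixtures do **not** emulate: an actual channel's spectrum of
motions, anharmonicity, membrane and solvent coupling, or realistic
contact geometry. Passing recovery tests therefore demonstrates the
correctness of the estimators and of the planted-truth bookkeeping, not
the biological conclusions one would draw from real trajectories.

## Numerical choices and problem sizes

Ties among co-minimal paths break lexicographically; correlations are
clipped to [−1, 1] and symmetrised; frozen residues yield Corr = 0 with
a warning; degenerate geometry (zero-length vectors) yields NaN for the
affected frame with a warning rather than an exception. Statistical
validations use 20 independent seeds at 1000 frames and 20 planted-model
residues; the oracle comparison uses 200 random graphs of at most 9
nodes against exhaustive simple-path enumeration. These sizes keep the
full suite around a few seconds while leaving the statistical margins
(≈ 3 sd on the edge rule) intact.

## Known limitations

Insertion codes are rejected; selections are name-based (no full
selection grammar); no mutual-information generalisation of the
correlation, no community detection, no suboptimal-path ensembles beyond
co-minimal ties, and no reweighting of biased trajectories to true free
energies. The contact module does not type interactions (salt bridge vs
hydrophobic); specific salt-bridge distance checks reduce to the same
primitives. Block lengths are caller-supplied; no autocorrelation-time
estimate justifies them.
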