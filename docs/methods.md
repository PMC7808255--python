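# Methods

## Scope and model

`tyrcav` re-implements the measurement-and-statistics layer of a
wild-type-vs-mutant structure comparison workflow for human tyrosinase:
given PDB snapshots at two timepoints of a simulation and a table of
per-mutation ΔΔG values, it produces surface/volume/cavity metrics, their
paired differences, stability classifications, and correlation reports.
It deliberately does **not** produce the inputs: homology modelling,
molecular dynamics, and ΔΔG estimation (e.g. FoldX) are upstream tools
whose outputs this package consumes.

## Two-state unfolding propensity

A mutation's ΔΔG (kcal/mol, positive = destabilising) is converted to the
fraction of protein in the unfolded state under a two-state Boltzmann
model:

    u(ΔΔG) = 1 / (1 + exp(−ΔΔG / (R·T))),  R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹

with T = 298 K by default (configurable). The form has u(0) = 0.5
exactly, is strictly increasing, and antisymmetric (u(−x) = 1 − u(x)).
Before adoption it was validated against the 19 published (ΔΔG,
unfolding) pairs for the OCA1B and OCA1A mutant panels: every pair agrees
within ±0.01 after rounding to two decimals, and 14 agree exactly; the
five discrepant rows (K142M, S323R, T325A, H367Y, H363Y) all sit within
0.005 of a two-decimal rounding boundary, where the published rounding
cannot be reproduced bit-for-bit. The test suite re-runs this check.

Severity bins the propensity **after** rounding to two decimals
(decimal half-up), which closes the gaps in the printed bin edges:
≤ 0.19 weak, 0.20–0.80 moderate, ≥ 0.81 severe. The *predicted effect*
additionally labels every ΔΔG < 0 mutant Severe: an over-stabilised
protein is assumed to fold to a non-native state. Per-residue
*foldability* is Σ w(class(uᵢ))·uᵢ over the substitutions at a residue;
the weights {weak: 0, moderate: 0.5, severe: 1} are an explicit,
configurable choice (no published weights exist) picked so weak
substitutions contribute nothing, consistent with published foldability
zeros at weak-only residues.

The identity control converts self-to-self ΔΔG values (ideally 0) and
reports mean, sample SD, t-based 95% CI, and a two-sided one-sample
t-test against 0.5.

## Surface area and accessible volume

SASA uses the Shrake–Rupley method: n quasi-uniform points (default 960)
on each atom's solvent-expanded sphere (r_vdw + probe, probe 1.4 Å); a
point is exposed if outside every other expanded sphere; per-atom area is
the exposed fraction times the sphere area. Points come from a
golden-spiral lattice — a deterministic construction, so areas are
bit-reproducible. At 960 points the discretisation error against a
4000-point run is under 2% on the test fixtures; agreement with an
independent Shrake–Rupley implementation (biotite) is ~0.03% at matched
radii.

Accessible volume is the region enclosed by the solvent-accessible
surface, estimated on a regular grid (default 0.5 Å): voxels within
r_vdw + probe of any atom centre, plus interior voxels a 6-connected
flood fill from the grid boundary cannot reach. Rigid-motion invariance
is better than 3% on fixtures and halving/doubling the spacing moves
results by under 10%.

Both computations use the heavy-atom convention — hydrogens and waters
excluded, metals kept — with a pinned van-der-Waals radius table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, Cu 1.40, P 1.80, default
1.70 Å), so results do not depend on whether an MD engine exported
hydrogens or on an external radius source. Absolute SASA/volume values
are estimator-specific; every downstream statistic uses *differences*
between paired structures measured with identical settings, which is
what the correlation analysis consumes.

## Cavity detection

The detector honours three scalar parameters on a voxel grid (default
spacing 0.6 Å): probe radius 3.00 Å (bulk solvent size), interior
threshold 1.25 Å (minimum clearance of a cavity voxel), minimum depth
5.00 Å (burial filter). Voxel clearance is distance to the nearest atom
surface. The exterior is flood-filled (6-connectivity, chosen to prevent
diagonal leakage through one-voxel walls) from the box boundary over
voxels with clearance ≥ probe, then expanded over connected voxels with
clearance ≥ interior threshold — so a pocket whose mouth admits the
probe is exterior, not a cavity. Remaining interior-clearance voxels
form cavities by connected components; a component's depth is the
largest distance from its voxels to the nearest exterior voxel, and
shallow components are discarded. Lining residues are those with an atom
within r_vdw + threshold + spacing of a cavity voxel.

The reference channel-analysis tool this emulates works on Voronoi
diagrams, and its published description gives only the three scalars, so
absolute volumes differ between implementations; the pipeline's claims
are about differences and rank order, which converge: hollow-shell
fixtures recover the analytic interior volume within 10% at 0.6 Å
spacing and change by under 10% on spacing halving. The total cavity
volume sums the three largest cavities (top-n configurable). The
interface cavity is the largest cavity whose lining intersects both of
two disjoint residue domains; for tyrosinase the EGF-like domain default
window is residues 19–118 and the canonical interface lining residues
(F98, F105, F176, W210, F429, Y433, F438) ship as a named constant.

## Metal sites

The copper-pair distance is the Euclidean separation of exactly two
atoms of the requested element (an error reports any other count).
Coordination counts ligand atoms — His ND1/NE2 by default — within a
cutoff of a metal centre. The 3.0 Å default allows Cu–N bonds
(1.9–2.2 Å) plus thermal slack; no published cutoff exists, so it is
configurable. The loss-of-coordination flag fires when a metal retains
≤ 1 ligand atom: a copper held by at most one contact is no longer fixed
in the site. Trajectory tracking evaluates the pair distance per frame
against explicit time labels.

## Superposition

Residues are paired by global Needleman–Wunsch alignment under BLOSUM-62
with affine gaps (open −11, extend −1 — the common defaults, as none are
published for this workflow; X scores 0 against everything). Paired CA
atoms are superimposed by the Kabsch least-squares fit (SVD with
determinant sign correction, so reflections are never returned), then
pruned iteratively: every pair farther than the cutoff (2.0 Å) is
dropped and the fit repeated until no pair exceeds the cutoff, or fewer
than 3 pairs would remain (the last valid fit is kept and flagged).
Batch pruning matches the "until no pair exceeds" stopping rule;
one-at-a-time pruning is available as an option. The result reports the
RMSD over retained pairs and over all initial pairs under the final
transform; the former never exceeds the latter.

## Differences and statistics

For each metric m ∈ {SA, V, V_cav}: Δm = m(t1) − m(t0) per structure and
ΔΔm = Δm_mut − Δm_wt per mutant. Timepoints are explicit labels, and the
table builder validates that every structure carries the same two.
Correlation uses the product-moment formula (one published rendering of
it carries a sign typo in the denominator; the correct minus sign is
implemented — the only reading consistent with the published adjusted-R²
values), adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with k = 1
regressor throughout, and the closed-form OLS line; all three are
cross-checked against scipy in the tests.

## Synthetic data

The generators define the study conditions for testing:

* **Hollow shells** (default radius 12 Å, carbon atoms golden-spiral
  placed at 1.5 Å spacing) enclose an analytic cavity of
  (4/3)π(R − r_vdw − 1.25)³; an aperture parameter opens a cone-shaped
  mouth, and a conservative seal bound (spacing < √3·(r_vdw +
  threshold)) rejects shells that could leak.
* **Two-domain structures** are a "cup" (bottom plate plus four walls,
  chain B) and a "piston" plate sliding inside it (chain A), sealed by a
  1 Å rim gap; the pocket between bottom and piston is the interface
  cavity, growing linearly with the per-frame drift (default 1.5 Å/frame
  along z from an 8 Å initial gap). The analytic pocket estimate is the
  inter-plane cuboid minus one contact margin (r_vdw + threshold) per
  face; grid detection converges to within 10% of it at ≤ 0.4 Å spacing.
  An optional embedded two-copper site (2.75 Å separation, three
  His-like nitrogens per copper at 2.1 Å) exercises the metal-site
  module.
* **ΔΔG tables** draw ΔΔG uniformly (default −2..6 kcal/mol, the span of
  the OCA1B panel) and set the cavity response to slope·ΔΔG + intercept
  (defaults 749.1 and 423.0, the published regression) plus Gaussian
  noise on the response only — ΔΔG comes from an energy function and is
  treated as exact, while the cavity volume is the noisy structural
  measurement. At the default range, response noise of ~1300 Å³
  reproduces the r ≈ 0.8 regime of real mutant panels; 600 Å³ gives
  r ≈ 0.94.

What the synthetic fixtures do *not* emulate: real protein packing,
side-chain chemistry, force-field energetics, or MD conformational
noise. Passing tests therefore demonstrate that the estimators are
correct and convergent on geometry with known ground truth and that the
statistical layer recovers planted relations — not that any specific
published MD observable (absolute cavity sizes, RMSDs, copper distances)
is reproduced, which would require the original trajectory endpoints.

## Numerical choices and limitations

* All geometry is deterministic (no RNG); table noise is seeded.
* Grid results carry O(spacing) discretisation error; defaults (0.5 Å
  volume, 0.6 Å cavities) balance accuracy against the cubic cost of
  finer grids, and a voxel-budget guard rejects grids that would exhaust
  memory, with the error message pointing to a larger spacing.
* Alt-loc resolution keeps the highest-occupancy conformer (ties to file
  order); malformed coordinate fields fail parsing with the line number
  rather than being silently zeroed.
* Severity bin edges are resolved by two-decimal half-up rounding;
  propensities within ~0.005 of an edge can legitimately land on either
  side of an independently rounded reference.
* The end-to-end `run` command measures 18 synthetic structures at
  0.6 Å/960-point settings (~40 s on one core); these sizes are the
  package defaults for the demo, chosen so the full analysis stays
  interactive.
* Sequence-based pairing assumes single-chain CA traces; insertion codes
  are tolerated in parsing but not used for pairing.
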