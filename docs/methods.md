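# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `solvsite`, and what the synthetic-data generators do and
do not emulate.

## Hydration-site clustering

Water-oxygen observations from all frames of a trajectory are pooled inside
an analysis region (sphere or box) and clustered greedily:

1. count, for each observation, its neighbours within `site_radius`
   (default 1.0 Å);
2. the observation with the most neighbours seeds a site (ties broken by
   lower `(frame, water_id)`, which makes the procedure fully
   deterministic); the site centre is the centroid of the seed's in-radius
   neighbourhood;
3. the site claims every unassigned observation within `site_radius` of the
   centre, keeping at most one per frame (the nearest);
4. no future seed may lie within `min_center_separation` (default 2.0 Å) of
   an accepted centre;
5. iterate until the best remaining candidate's occupancy falls below
   `min_occupancy_fraction` (default 0.5).

The first seed coincides by construction with an exhaustive
maximum-neighbour-count search, which the tests verify directly.

**Choosing the claiming radius.** A site whose positional spread is σ keeps
a fraction P(|N(0, σ²I)| ≤ `site_radius`) of its waters; with the default
1.0 Å radius and σ = 0.2 Å that fraction is ≈ 1 − 10⁻⁵, so over hundreds of
frames an occasional tail member is lost and recovered occupancy is biased
low by the truncated mass. When faithful occupancy estimates matter, set
`site_radius` ≳ 7σ of the tightest expected site (the recovery tests use
1.5 Å for σ = 0.2 Å sites). The defaults favour site resolution over
occupancy fidelity.

## Per-site thermodynamics

All energies are kcal/mol; k_B = 0.0019872 kcal/(mol·K); the default
temperature is 300 K. The bulk baseline (per-water mean energy `E_bulk` and
number density `rho_bulk`) must be supplied — either as constants or derived
from a bulk trajectory (mean sidecar energy, mean count / box volume). There
is deliberately no built-in default for `E_bulk`: it depends on the water
model and energy definition that produced the trajectory, and a silent
default would make ΔH meaningless.

**Enthalpy.** ΔH = mean member interaction energy − `E_bulk`. Member
energies come from the sidecar CSV (authoritative) or, when absent, from the
fallback nonbonded model below.

**Translational entropy.** The first-order (one-body) term of the
inhomogeneous-solvation entropy expansion is

    −TΔS_tr = k_B T ∫ ρ(r) ln( ρ(r) / ρ_bulk ) dr / N
            = k_B T ⟨ ln( m·p(r) / ρ_bulk ) ⟩,

where p is the member-position density, m = (members)/(frames) is the mean
number of occupying waters per frame, and ρ(r) = m·p(r) is the one-body
density. The m factor is what makes the null exact: members distributed
uniformly at bulk density give exactly zero. The differential entropy of p
is estimated with the first-nearest-neighbour (Kozachenko–Leonenko)
estimator with the Euler–Mascheroni bias correction — parameter-free and
directly checkable against quadrature of the defining integral.

**Orientational entropy.** The analogous one-body term relative to the
uniform distribution over orientation space (total measure 8π²):

    −TΔS_or = k_B T ( ln 8π² − H[p(ω)] ).

Orientations are unit quaternions with the antipodal identification q ≡ −q;
the metric is the geodesic rotation angle θ = 2·arccos|q₁·q₂|. The
nearest-neighbour estimator uses the exact measure of a geodesic ball in
SO(3), μ(B_r) = 8π(r − sin r), rather than the flat r³ approximation — at
the ball radii reached by weakly concentrated samples the curvature
correction is what keeps the uniform null at zero.

**Estimator reliability.** Below 10 members the estimates are returned
flagged `unreliable` rather than refused; coincident points saturate the
estimator (clamped nearest-neighbour distance, flagged) instead of raising.
Expected accuracy at n = 2000 samples, verified against quadrature oracles:
within 5% relative on Gaussian sites (σ 0.15–0.35 Å) and concentrated
orientations (κ 5–20), and uniform nulls within 0.1 kcal/mol of zero. The
estimators carry O(n^(-1/2)) statistical noise, so values within ≈ 0.05
kcal/mol of zero should be read as zero.

**Free energies and signs.** ΔG_site = ΔH + (−TΔS_tr) + (−TΔS_or) is the
site-minus-bulk free energy; ΔG_transfer = −ΔG_site is the free energy of
moving the site water into bulk. Hydration-map sign conventions are a
notorious source of confusion, so both are computed, serialized under
explicit names, and the identities ΔG_site = ΔH + Σ(−TΔS) and
ΔG_transfer = −ΔG_site hold exactly (same floating-point operations, no
re-derivation). Classification likewise avoids leaning on a sign:
`ENTHALPY_UNFAVOURABLE` flags ΔH > 0 and `HIGH_MAGNITUDE_DG` flags
|ΔG_site| ≥ 3.0 kcal/mol (threshold configurable).

Thermodynamics are reported per mean occupying water; occupancy is reported
separately rather than folded into the totals, so no quantity double-counts
partially occupied sites.

**Fallback nonbonded energy.** When no sidecar energies exist, a
Lennard-Jones + Coulomb pair sum is available: per-element LJ with
Lorentz–Berthelot combining, point charges, electrostatic constant
332.06 kcal·Å/(mol·e²), plain cutoff truncation at 9.0 Å, no switching
function and no periodic images. It is a deliberately simple model meant
for synthetic fixtures and sanity checks, not for production force-field
energetics.

## Displaced-solvent scoring

    ΔG_bind = Σ_sites w(d_min) · ΔG_transfer

with d_min the minimum distance from the site centre to a used ligand atom
and `Rco` = 2.24 Å by default. Two weight functionals are provided: `step`
(w = 1 if d_min < Rco else 0; the default) and `ramp`
(w = max(0, 1 − d_min/Rco)), selected by config — the step form treats
displacement as all-or-none, the ramp credits partial overlap. A site
displaced by several atoms contributes once (the sum runs over sites, not
atom–site pairs). Only heavy atoms are used by default because hydration
sites are oxygen-position clusters and hydrogen coordinates in typical
input structures are modelled, not observed; `atoms_used: all` overrides.

## Contact profiling

Bonds are inferred from distances (heavy–heavy < 1.9 Å, X–H < 1.2 Å).
Default criteria (all configurable; distances strict `<`, angles `≥`):

| contact            | criterion                                       |
|--------------------|-------------------------------------------------|
| H-bond             | D···A < 3.35 Å, D–H···A ≥ 120° (N/O donors/acceptors) |
| bifurcated H-bond  | one donor (or acceptor) in ≥ 2 simultaneous H-bonds |
| CH–O H-bond        | C···O < 3.7 Å, C–H···O ≥ 110°                   |
| salt bridge        | charged-group atoms < 4.0 Å                      |
| metal coordination | M···N/O < 2.6 Å; octahedral if 6 ligators, cis angles 90 ± 20° |
| π-π                | ring centroids < 5.5 Å; parallel ≤ 30° tilt, T-shaped ≥ 60°, else inclined |
| hydrophobic        | apolar C···C < 3.9 Å                             |

Design choices worth knowing:

* **Hydrogens** are used when present. When neither partner of a candidate
  N/O hydrogen bond carries a hydrogen (typical crystal structures), the
  angle test is skipped and distance-only detection applies, flagged
  `no-H`. CH–O bonds always require the hydrogen — the C–H direction is
  part of the definition, and without it the contact is indistinguishable
  from a generic close approach.
* **Ring perception** takes planar (≤ 0.3 Å out-of-plane) 5/6-cycles of C/N
  with at most 3 total bonds per atom. The degree cap is what rejects
  saturated rings: a realistic cyclohexane chair puckers only ±0.23 Å and
  would pass a pure planarity test.
* **Charged-group typing**: Lys/Arg/His side-chain nitrogens and Asp/Glu
  carboxylate oxygens on the protein side; phosphonate/phosphate oxygens
  (O bonded to P) and protonated amines (N with ≥ 3 H) on the ligand side.
  Metal ions are excluded from salt bridges and handled as coordination
  centres. Protonation is an input property, never inferred.
* Oxygens coordinating the same metal are never reported as hydrogen-bonded
  to each other (they are cluster ligands, not donor–acceptor pairs), and
  ring atoms of a detected π-π stack are not double-reported as hydrophobic
  contacts.

## PIE statistics

Variance and covariance use the **population** normalization (denominator
n): the ligand panel is the whole set under study and the statistics are
descriptive. Sample normalization would scale everything by n/(n−1) and
change no ranking. Fragment labels follow the FMO convention — fragment i
contains the backbone carbonyl of residue i−1 — and the documentation keeps
that shift explicit so interactions are not misattributed.

The PIEDA validator checks total = ES + EX + CT+mix + DI per cell with a
rounding-aware tolerance: when the table was read from a file, the printed
decimal places of each component are recorded and the tolerance is the
accumulated half-unit-in-the-last-place of the four components plus the
total's. This is what lets a table printed at mixed precision (e.g. an EX
term printed as an integer) validate without admitting real inconsistencies.

pIC50 values are inputs; the packaged example table carries none, and the
covariance tests use synthetic panels with planted slopes.

## Synthetic-data generators

The generators produce ground-truthed stand-ins for the expensive inputs:

* **Pocket trajectories**: each planted site is an independent
  Bernoulli(occupancy) × Gaussian(centre, σ²I) emitter with von
  Mises–Fisher orientations on S³ (κ = 0 is exactly uniform — one parameter
  family with an analytic uniform limit, ideal for estimator nulls) and
  Gaussian energies. Written as multi-MODEL PDB (rigid 3-site waters posed
  by the quaternion) or XYZ, with a full-precision CSV sidecar; energies
  live in the sidecar so thermodynamic ground truth is exact by
  construction, not a by-product of a force field.
* **Bulk trajectories**: ideal-gas-like — waters re-drawn independently and
  uniformly each frame at the stated density (default 0.0334 Å⁻³, liquid
  water at ambient conditions), uniform orientations. This makes the bulk
  translational excess entropy exactly zero, a clean estimator null.
* **Toy complexes**: each requested contact is built as an isolated motif
  on a 25 Å grid, realizing the requested distances/angles exactly (well
  below 0.01 Å / 0.5°), with a manifest of every contact a detector should
  report. Unsatisfiable geometry or steric clashes (< 1.5 Å between
  non-bonded heavy atoms) are rejected with the offending pair named.
* **PIE tables**: signal fragments follow slope·pIC50 + noise, others a
  constant + noise; slopes, baselines and the noise level are echoed.

What these generators do **not** emulate — and therefore what passing tests
do not show about real data: water–water correlation (sites are
independent, so no second-order entropy structure exists to miss),
force-field energetics (energies are planted labels), conformational
dynamics, crystallographic noise, protonation ambiguity, and realistic
chemical context around contacts. The tests establish that the estimators
and detectors are correct on data matching their model assumptions; on real
trajectories the first-order entropy truncation and the clustering model
are themselves approximations.

## Problem sizes and numerical conventions

Estimator-accuracy checks run at n = 2000 samples (where the
nearest-neighbour estimators' noise is comfortably below the 5% oracle
band), clustering recovery at 500 frames × 3 sites, and pipeline runs at
100–500 frames — sizes at which every oracle (grid/1-D quadrature,
brute-force neighbour search, closed-form covariance) is exact or cheap.
Coordinates are Cartesian Å exactly as read, never recentred; PDB residue
numbers are preserved verbatim (1-based), internal indices are 0-based;
energies are kcal/mol with no unit autodetection. Serialized site maps and
reports carry a `schema_version` and reject mismatches. JSON is written
with sorted keys and atomic rename, so identical seed + config reruns are
byte-identical; sidecar CSVs store floats at %.17g, which round-trips
float64 exactly (readers use round-trip float parsing).
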