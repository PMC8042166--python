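# Methods

## The measurement model

The package treats a protofilament trajectory as a sequence of coordinate
frames over a fixed atom list, annotated by a `FilamentModel` that maps
atoms to subunits (ordered bottom → top) and each subunit's residues to
its N- or C-terminal domain. The domain split is always supplied
configuration — it is experimental knowledge about the protein, and no
attempt is made to infer it from coordinates.

### Inter-subunit rotation decomposition

A right-handed filament frame is anchored on the middle subunit of the
reference (straight) filament: **z** runs from the lower to the upper
neighbour centroid, **x** is the middle subunit's C-domain centroid offset
projected perpendicular to z (the preferred bending direction), and
**y = z × x**. Per frame, the trajectory is superposed on the reference
via the middle subunit (Kabsch, proper rotations only); the rotation
carrying the moving subunit's reference pose onto its observed pose is
expressed in the filament-frame basis, `R_f = Bᵀ R_lab B`, and decomposed
as intrinsic rotations z → x → y into (θ1, θ2, θ3) in degrees.

θ1 is decomposed first because twist dominates the filament's
conformational range; the order is a config option (`order="ZXY"`) and is
recorded in every output, with θ1 ∈ (−180, 180], θ2 ∈ [−90, 90].
Decomposition and composition round-trip to < 1e-8 away from gimbal lock;
|θ2| > 89.9° sets a degeneracy flag. The same middle-subunit alignment is
used for the bottom subunit. The generator applies each cluster's rotation
about the moving subunit's own centroid (in the filament-frame basis):
using the frame origin as the pivot would also orbit the subunit away from
its interface, conflating rotation with interface opening, which the
generator controls separately and explicitly.

### Buried interface area

SASA is Shrake–Rupley quadrature: each atom carries a deterministic
Fibonacci-lattice point set on its probe-inflated sphere (probe 1.4 Å,
960 points), and a point is occluded when it lies strictly inside a
neighbour's inflated sphere. The buried area of an interface is
(M₁ + M₂ − M₁₊₂)/2. Internally the three surface evaluations are fused:
per atom the accessible fraction is computed once with own-subunit
occluders and once with all occluders; the result is identical (to 1e-13)
to the literal three-call evaluation, which the tests keep as the oracle.
Because the point lattice is fixed in the lab frame, SASA is invariant
under rigid motion only to quadrature error (≈1% at 960 points; doubling
the point count moves totals by < 1%).

All supplied atoms are used (no heavy-atom filter). For real structures a
small element → van-der-Waals radius table applies; synthetic bead
structures use a uniform radius, and analyses pass the template's bead
radius through.

### State classification

Subunits: relative to a tense-state reference distance, a reduction
strictly greater than 2.5 Å ⇒ R, at most 1.0 Å ⇒ T, otherwise
indeterminate. The observed distributions are bimodal with a clear gap,
so mid-gap frames are deliberately not force-labelled; the T band and the
indeterminate band are config-exposed. The reference defaults to the mean
over the first 5% of frames, which presumes a trajectory that starts
tense; for synthetic ensembles, whose clusters are sampled independently
per frame, the analyses pass the template's domain separation (30 Å)
explicitly.

Interfaces: buried area strictly above 1100 Å² ⇒ closed, strictly below
1000 Å² ⇒ open, otherwise intermediate.

Dimer species letters are ordered upper-subunit-first ("T-R" = tense
upper over relaxed lower); every output states this, because top-bottom
orderings are a chronic source of ambiguity. The census excludes, per
dimer position, frames with an indeterminate member and reports the count
excluded, so counts + exclusions always equal the frame total.

Category names pair the nucleotide tag with interface openness:
closed ⇒ IF1, open ⇒ IF2 within each tag. Modal twist angles per category
use a 1°-bin histogram with parabolic refinement of the peak bin;
categories under 10 samples are reported as undersampled rather than
given a meaningless mode.

### Free-energy landscapes

Features are the flattened upper triangles of per-frame Cα–Cα distance
matrices (rigid-motion invariant by construction), column-centered, with
independent runs concatenated before the thin SVD. Projections are left
singular vectors scaled by singular values; each component's sign is
fixed so its largest-magnitude loading is positive. The landscape is
F = −ln(P/P_max) in k_BT over a 40×40 histogram of (PC1, PC2) smoothed
with a 1-bin Gaussian; the best-sampled bin is exactly 0 and unsampled
bins carry +∞.

Funnels are detected by flooding occupied bins in order of increasing
energy (8-connected). A basin dying at a saddle has persistence
saddle − minimum; a funnel must have persistence ≥ 1 k_BT **and** a basin
holding ≥ 2% of all frames. The occupancy requirement exists because
persistence alone certifies isolated outlier frames (a 1-count corner bin
disconnected from the bulk is arbitrarily persistent); an energy funnel
is by definition a populated region. Both thresholds are config-exposed.
With the defaults, the GTP- and GDP-mode generator settings yield exactly
two and three funnels across seeds, and planted Gaussian mixtures with
1–4 components at ≥ 6 sd separation are recovered exactly.

### Adjusted regression

Slope, intercept and r come from ordinary least squares on all points.
Consecutive MD frames are not independent states, so the F-test p-value
uses the effective sample size n_eff = ⌊total time / decorrelation⌋ with
a 1 ns default decorrelation time: F = r²(n_eff − 2)/(1 − r²) on
(1, n_eff − 2) degrees of freedom. n_eff < 4 yields an undefined p with a
flag. With decorrelation equal to the frame spacing the test reduces
exactly to the classical F-test, and at n_eff = 100 with independent
Gaussian inputs the empirical type-I rate is 5% (calibrated over 2000
replicates in the test suite).

### Elastic-network correlations

Standard anisotropic network model: nodes within 15 Å are coupled by
identical springs; the off-diagonal 3×3 Hessian block of a contacting
pair is −γ(r⊗r)/|r|², diagonal blocks close the row sums. Zero modes are
identified by relative threshold (|λ| < 1e-8·λ_max) rather than "first
six", so disconnected networks are flagged instead of silently wrong.
Correlations use the 45 lowest non-zero modes by default (rigid-body
modes are excluded before counting):
cov_ij = Σ_k λ_k⁻¹ tr(v_k v_kᵀ)_ij, C_ij = cov_ij/√(cov_ii cov_jj). γ
cancels in C_ij exactly; truncated-mode maps converge to the
pseudo-inverse map as modes are added. For bead structures all beads are
nodes; for real structures, Cα only.

## The synthetic generator

Each subunit is two rigid bead clouds on jittered spherical shells
(30 + 24 beads, shell radius 11 Å, deterministic radial jitter 0.6 Å)
whose centroids sit exactly 30 Å apart along an axis tilted 20° off the
filament axis — the tilt gives the C-domain the transverse offset that
defines the preferred bending direction. Subunits stack at a 40 Å rise
(≈4 nm), chains A/B/C bottom → top. Beads are coarse (radius 6 Å, one
bead ≈ 3 residues): with only 54 beads per subunit, the bead radius is
what sets the absolute interface area scale, and 6 Å places the reference
closed interface near 1250 Å² buried while the 4 Å opening translation
drops it near 960 Å² — straddling the 1100/1000 Å² classifier bands the
way a real subunit interface does.

Frames are drawn independently from conformer clusters. Each cluster
specifies a rotation triple applied to both end subunits, a set of
subunits whose C-domain is translated 3 Å toward the N-domain along the
current inter-centroid axis (the tense → relaxed emulation; 3 Å clears
the 2.5 Å classifier threshold, and the translation provably induces no
spurious Kabsch rotation because the cross-covariance perturbation it
adds is symmetric), and a set of interfaces opened by rigidly translating
everything above them 4 Å along +z. Gaussian angle noise (default sd 2°)
and per-atom jitter (default sd 0.3 Å) are added last. All draws come
from a counter-based Philox generator keyed by (seed, frame, stage), so
any frame is reproducible in isolation and outputs are bitwise pure
functions of the spec.

GTP mode has two clusters — all-closed T-T-T at twist −6.1° and open-top
T-T-R at −35.7° — and GDP mode three: R-R-R at −9.4°, R-R-T at −33.1°
with both interfaces open, and R-T-R at −24.7° with the top interface
open; equal weights. The twist means are the modal values of the
closed- and open-interface populations observed in nucleotide-bound
filament simulations, and the cluster counts match the two- and
three-funnel structure of those ensembles.

What the generator does **not** emulate: atomic packing and sequence
chemistry (beads are uniform), force-field dynamics or kinetics (frames
are i.i.d. cluster draws — no dwell times, so "first switch frame"
statistics are not kinetic), realistic SASA magnitudes at atomic
resolution, and the decreasing end-to-end coupling with oligomer length
seen in real subunit topologies — the isotropic bead shells do not
reproduce that trend, so the network-model coupling profile on synthetic
filaments shows no systematic length dependence. Passing tests therefore
certify the estimators (recovery of imposed rotations, closures,
openings, cluster counts and census composition), not any property of
real filaments.

### GDP-mode interfaces are "somewhat closed"

Closure translates the C-domain toward the N-domain, and the lower
subunit's C-domain is the interface-facing domain, so a relaxed lower
subunit partially opens its upper interface (~980 Å² buried). GDP-mode
closed clusters consequently classify mostly intermediate/open rather
than closed, and the GDP-IF1 angle category is typically undersampled at
default sizes. This mirrors the behaviour of GDP-bound filaments, whose
interfaces hover in the 930–1100 Å² range, and is left as-is.

## Problem sizes and numerics

Default analysis sizes — 600-frame ensembles for landscapes and censuses,
2000 frames for modal-angle recovery, 1–5-subunit filaments for the
network model — were chosen as the smallest at which the relevant
estimators stabilise (the histogram mode needs ≈700 in-category samples
for ±0.5° repeatability; funnel counts are stable from a few hundred
frames per cluster). Superpositions exclude reflections by construction;
ties in the highest-occupancy altloc rule resolve to the first conformer;
SASA occlusion uses strict inequality, so exactly coincident spheres do
not occlude each other; the watershed breaks energy ties by processing
order, which only affects zero-measure degenerate grids.

## Known limitations

- Modal-angle recovery degrades for clusters whose interface
  classification is impure (frames drift across the open threshold under
  coordinate jitter); only classification purity, not the decomposition,
  is affected.
- The buried-SASA scale is meaningful only relative to the bead-radius
  configuration; comparing absolute areas across different radius
  settings is not.
- No kinetic quantities (rates, MSMs, dwell times) are computed anywhere.
- XYZ input carries no chain/residue annotation, so filament analyses on
  XYZ trajectories require the annotation to be supplied separately.
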