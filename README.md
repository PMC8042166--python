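# protofil

Trajectory analysis for single-stranded, tubulin-like protofilaments —
FtsZ-style filaments of two-domain subunits — together with a synthetic
trajectory generator with exact ground truth.

FtsZ, the bacterial tubulin homolog, polymerizes head-to-tail into
protofilaments whose assembly and disassembly are steered by the bound
nucleotide. Two conformational coordinates dominate: each **subunit**
switches between a tense (T, open-cleft) and relaxed (R, closed-cleft)
conformation, measured by the distance between its N- and C-terminal
domain centroids; each **interface** between stacked subunits is closed or
open, measured by the buried solvent-accessible surface area. On top of
these, neighbouring subunits twist and bend relative to each other. This
package implements the full measurement pipeline for such trajectories and
a coarse-grained generator that imposes all of these motions with known
ground truth, so every estimator can be validated end to end.

## What it computes

- **Inter-subunit rotations** (`protofil.geometry`): a filament frame is
  anchored on the middle subunit (z along the filament axis, x along the
  preferred bending direction given by the C-domain offset, y = z × x).
  After superposing each frame on the reference middle subunit, the moving
  subunit's Kabsch rotation is decomposed as intrinsic rotations
  z → x → y into (θ1, θ2, θ3): twist about the filament axis and two
  bending angles, in degrees.
- **Buried interface area** (`protofil.surface`): Shrake–Rupley SASA on a
  deterministic Fibonacci sphere lattice;
  `buried = (M₁ + M₂ − M₁₊₂)/2` for subunit SASAs M₁, M₂ and complex SASA
  M₁₊₂.
- **State classification** (`protofil.states`): R iff the inter-domain
  distance drops by strictly more than 2.5 Å from the tense reference
  (T iff ≤ 1.0 Å, indeterminate between); interfaces closed above
  1100 Å² buried, open below 1000 Å². Trimer state strings
  (bottom-middle-top, e.g. `T-T-R`) and the dimer-species census
  (T-T / T-R / R-T / R-R per dimer position, upper-subunit letter first)
  map a trajectory onto filament nucleation pathways.
- **Free-energy landscapes** (`protofil.ensemble`): SVD of flattened
  Cα–Cα distance matrices, projection on the top two singular vectors,
  and F = −ln(P/P_max) in k_BT over that plane, with watershed funnel
  detection (1 k_BT persistence, 2% basin occupancy).
- **Adjusted regression** (`protofil.ensemble`): OLS with the F-test
  evaluated at the decorrelated sample size n_eff = ⌊total time / 1 ns⌋.
- **Elastic-network correlations** (`protofil.anm`): anisotropic network
  model at 15 Å cutoff; residue–residue cross-correlations
  C_ij ∈ [−1, 1] over the 45 lowest non-rigid modes.
- **Synthetic ensembles** (`protofil.synth`): a 3-subunit filament of
  two-domain bead subunits; frames are drawn from conformer clusters that
  impose rotation triples, T→R domain closures (3 Å) and interface
  openings (4 Å), plus Gaussian angle noise and atomic jitter. GTP mode
  has two clusters, GDP mode three. Everything is a pure function of the
  spec (counter-based Philox RNG keyed by seed, frame, and stage).

## Worked example

```python
from protofil.geometry import decompose_interface_rotation
from protofil.states import angle_peaks_by_interface, classify_interface
from protofil.surface import SasaParams, interface_series
from protofil.synth import TrajectorySpec, build_filament, generate_trajectory

base, model = build_filament()                      # straight 162-bead trimer
spec = TrajectorySpec(mode="GTP", n_frames=2000, angle_noise_sd=2.0, seed=11)
traj, truth = generate_trajectory(spec)

params = SasaParams(uniform_radius=spec.template.bead_radius)
angles = [decompose_interface_rotation(traj, model, w, reference=base)
          for w in ("top", "bottom")]
states = [classify_interface(interface_series(traj, model, n, params))
          for n in ("top", "bottom")]
peaks = angle_peaks_by_interface(angles, states, "GTP")
print({k: round(v.mode_deg, 2) for k, v in peaks.items()})
```

prints

```
{'GTP-IF1': -6.29, 'GTP-IF2': -35.61}
```

the modal twist angles of the closed-interface (IF1) and open-interface
(IF2) populations. The generator imposed cluster means of −6.1° (closed)
and −35.7° (open-top) with 2° angle noise, so the pipeline — rotation
decomposition, buried-SASA classification, histogram mode with parabolic
refinement — recovers both populations to within the noise.

The `analysis/` directory holds the numbered study drivers
(`01_simulate.py` … `06_helix_geometry.py`): generate the GTP/GDP
ensembles, classify states and tally the species census, build the
landscapes (two funnels for GTP, three for GDP), trace network-model
coupling across oligomer sizes, regress inter-domain distance against
twist/bend/buried area, and tabulate helix pitch ↔ twist conversions.
Their tables land under `results/`.

A thin CLI mirrors the pipeline: `protofil generate`, `protofil analyze`,
`protofil report`.

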