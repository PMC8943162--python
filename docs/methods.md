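# Methods

## Gaussian mutual information between residue motions

The coupling statistic treats the heavy-atom coordinates of a residue,
after rigid superposition of all frames onto a common reference, as draws
from a stationary multivariate Gaussian. For a coordinate set **X** of
dimension d = 3 × n<sub>atoms</sub> with trajectory covariance C(**X**) —
plain averages over frames, population denominator T — the quasi-harmonic
configurational entropy is H(**X**) = ½ ln |2πe C(**X**)| nats, and the
mutual information of residues A and B is
MI = H(**X**<sub>A</sub>) + H(**X**<sub>B</sub>) − H(**X**<sub>A,B</sub>).
For Gaussians this equals ½ ln(|C<sub>A</sub>||C<sub>B</sub>|/|C<sub>AB</sub>|)
and is non-negative for any PSD covariance (Fischer's inequality), so it
measures linear correlation of motions in information units.

Assumptions worth keeping in mind:

* **Gaussianity.** Only second moments enter. Anharmonic or multimodal
  dynamics (e.g. a residue hopping between rotamers) contribute through
  their covariance footprint only; the statistic underestimates nonlinear
  dependence.
* **Stationarity and a common frame.** Covariances are meaningful only
  after superposition. Per-monomer analyses fit each monomer's TRP-like
  domain Cα atoms (default span 961–1005, configurable) because that
  region is the most rigid part of the pocket-to-pore section; fit noise
  on a flexible selection converts rigid-body error into spurious
  correlated motion for all residues.
* **Finite-sample bias.** The sample MI of truly independent blocks is
  positive with expectation ≈ d<sub>A</sub>d<sub>B</sub>/2T nats. At the
  fixture scale (5-heavy-atom residues, d = 15, T = 300) this floor is
  ≈ 0.4 nats; at T = 50,000 and d = 3 it is ≈ 10⁻⁴. An optional
  frame-shuffling null (seeded) quantifies this per pair.

### Numerical choices

* **Log-determinants** are computed from the eigenvalue spectrum
  (`eigvalsh`), never a raw determinant; eigenvalues are floored at
  `eigenvalue_floor` (default 10⁻⁸ Å²) because the entropy diverges when a
  sample covariance is singular (T < d, duplicated atoms). Flooring is
  reported via `floor_applied`. An eigenvalue below −10⁻¹⁰ relative to the
  spectrum maximum raises an error rather than being masked.
* **Symmetry.** The joint covariance is assembled in topology order —
  canonical for both argument orders — so MI(A,B) and MI(B,A) are
  bit-identical.
* **Clipping.** Sample MI is non-negative up to floor effects; values in
  (−10⁻⁹, 0) from round-off are clipped to 0. Clipping can be disabled.
* **Covariance denominator** is T (plain trajectory averages); the
  unbiased T−1 form is available via `ddof=1`.

### Aggregation

Homotetramer analyses yield one MI matrix per (run, monomer). Matrices are
relabelled onto a canonical chain, combined by entrywise maximum with the
arg-max unit recorded as provenance, and summarised per segment pair as
the arithmetic mean over each residue's best-partner value (both segments'
residues contribute one maximum each). Ranked edge lists break MI ties by
the residue numbers of the pair, ascending, so output is deterministic.

## Pocket state and occupancy

Pocket width is the K610–L667 Cα–Cα distance (defaults; any residue pair
can be supplied). Classification is *closed* iff width < 11 Å — the
boundary value itself counts as open — applied to the raw series: the 2 ns
centred moving average (truncated at edges) exists for plotting only.
Occupancy is the time-weighted pooled closed fraction over all units, each
frame weighted by its spacing to the next (uniform spacing reduces to a
frame count); dispersion is the sample standard deviation (ddof = 1)
across the per-unit fractions. Pooling across all run × monomer units is
the default; a `dispersion_over="runs"` flag pools monomers per run first
and takes the deviation across runs instead. Out-of-pocket ligand
occupancy counts frames whose minimum ligand-to-pocket heavy-atom distance
exceeds a contact cutoff (default 3.5 Å).

## Pore-radius profiling

At each z along the channel axis (user-supplied, else the principal axis
of the pore-lining selection, anchored at its centroid) the profiler
maximises radius(c) = min<sub>i</sub>(‖pos<sub>i</sub> − c‖ − vdW<sub>i</sub>)
over the in-plane offset of the probe centre c. The in-plane objective is
multimodal for discrete atom geometries and unbounded outside the lining,
so the search combines:

* a coarse 0.5 Å seeding grid restricted to the **pore interior** — points
  the lining surrounds azimuthally (largest angular gap of in-plane atom
  directions ≤ π); outside that region clearance grows without bound and
  is not a pore radius;
* Nelder–Mead polish (xatol 10⁻³) from both the best grid point and the
  previous slice's centre, keeping the better optimum, so the centre line
  is followed continuously; after a capped slice the next search restarts
  from the axis.

Negative maxima (occluded slice) report 0; maxima at or above `max_probe`
(default 10 Å) are capped and flagged. Defaults: z-step 0.5 Å, Bondi-type
vdW radii (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) with a documented 1.5 Å
fallback for unknown elements. Absolute radii therefore differ from
curved-pathway tools at the level of the vdW table and the straight-axis
approximation; profiles are comparable across frames and systems analysed
with the same settings, and only qualitatively with other software.
Frame-averaged profiles report the per-slice mean and population standard
deviation.

## Superposition

Weighted Kabsch via SVD with the determinant correction, so a proper
rotation (det +1) is always returned — a mirror-image selection yields the
best proper rotation with nonzero residual rather than a reflection.
Collinear or coincident fit points (fewer than two significant singular
values) raise a degeneracy error. The reference is the first frame by
default or an external structure; aligning an aligned trajectory is a
no-op to 10⁻⁸ Å.

## Synthetic data: what it does and does not emulate

The generators are pure functions of spec + seed (bit-identical reruns,
no global random state) and define the study conditions for every test:

* **Gaussian trajectories** with user covariance: exact oracle for the
  covariance/entropy/MI chain. `gen_coupled_pair` couples matched
  coordinates of two pseudo-residues at correlation ρ, giving analytic
  MI = −(d/2)ln(1−ρ²).
* **Markov pocket widths**: a two-state chain with per-step switch
  probabilities rate·dt (validated dt·rate ≤ 0.1, so the discretised
  stationary distribution equals the continuous-time
  k<sub>oc</sub>/(k<sub>oc</sub>+k<sub>co</sub>)), state means at the
  deposited pocket-open/closed structure widths 15.5/9.4 Å, and Gaussian
  observation noise of 0.7 Å — a typical within-state fluctuation scale
  for a Cα–Cα distance. At 0.7 Å the probability that a closed-state frame
  (mean 9.4 Å) crosses the 11 Å cutoff is Φ(−2.29) ≈ 1%, so
  classification-based occupancy sits within ≈ 0.3 points of the chain's
  stationary fraction; larger noise would bias it visibly.
* **Toy pores**: stacked rings whose slice radius is exactly
  ring radius − vdW when the ring is its slice's nearest constraint.
* **The channel-like fixture**: 4 pseudo-monomer chains carrying the four
  analysed segments with the channel's residue numbering (lid 663–676,
  S1 706–730, S4 842–865, TRP-like/S6 961–1005; 5 heavy atoms per
  residue) on a compact helix-like reference (~50 Å extent — long lever
  arms would let fit noise induce common-mode correlations), independent
  0.5 Å fluctuations, and one planted coupling (default residues 671–988,
  ρ = 0.95 on 3 coordinates, analytic MI 3.49 nats).

None of this is physical dynamics: no membrane, solvent, bonded structure,
time correlation (frames are i.i.d.), or anharmonicity. Passing tests
demonstrate that the estimators recover known ground truth under the
model's own assumptions — they do not validate the Gaussian approximation
on real trajectories, where stride choice, convergence of the covariance,
and alignment quality all matter.

## Problem sizes

Closed-form MI checks use T = 50,000 frames (estimator error < 0.02 nats
at d = 3 per block); occupancy uses 12 units of 1 µs-equivalent at
dt = 0.1 ns (10,000 samples each); the end-to-end pathway fixture uses
300 frames × 4 monomers, where the planted 3.49 nat coupling stands ~8×
above the ≈ 0.4 nat bias floor. These sizes are the package's reference
conditions; all are configurable.

## Known limitations

* Linear (Gaussian) MI only; no k-NN/KSG estimators, transfer entropy, or
  time-lagged analysis.
* The pore axis is straight; strongly curved channels need a pathway tool.
* PDB input only (plus the package's own binary frame container); no
  XTC/DCD codecs. Insertion codes are rejected because residue keys are
  (chain, number) pairs.
* Occupancy dispersion across 12 units understates uncertainty when state
  dwell times are comparable to the unit length.
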