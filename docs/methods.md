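# Methods

This note documents the model, the estimators, and the numerical and
design choices behind `syxsim`, in the spirit of a simulation package's
model documentation.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The particle model

Each Syntaxin-1A molecule is a dimer of two spherical particles joined
by a harmonic bond:

* **Particle 1 (anchor)**, radius `r1 = 3.0 nm`, stands in for the
  transmembrane helix plus SNARE motif.  It is restrained to the
  membrane plane and carries the clustering interaction.
* **Particle 2 (head)**, radius `r2 = 3.3 nm`, represents the bulky
  N-terminal (Habc) domain and interacts only sterically.

Internal units are nm, ns and k_BT (k_BT ≡ 1); force constants are
k_BT/nm² and diffusion coefficients nm²/ns (1 μm²/s = 10⁻³ nm²/ns).

Three potentials define the physics (d is always a centre distance,
`r_xy` the sum of the two radii involved):

1. **Membrane restraint** on the anchor's out-of-plane coordinate:
   `U = ½ k_m d²`, `k_m = 20 k_BT/nm²`.  Anchors stay within
   `sqrt(k_BT/k_m) ≈ 0.22 nm` (1 s.d.) of the plane; heads are not
   restrained and can tilt.
2. **Soft-core repulsion** between head–head and head–anchor pairs:
   `U = ½ k_rep (d − r_xy)²` for `d < r_xy`, zero beyond contact,
   `k_rep = 2 k_BT/nm²`.
3. **Clustering attraction** between anchor–anchor pairs, a
   C⁰/C¹-continuous piecewise-harmonic well of depth `E_a` reaching
   from contact (`r_xy = 6 nm`) to the interaction radius
   `i = r_xy + 2.25 nm`:

   ```
   d <  r        ½ E_a (d − r)² − E_a
   r ≤ d < m     2E_a/(i−r)² (d − r)² − E_a      m = (i + r)/2
   m ≤ d < i    −2E_a/(i−r)² (d − i)²
   d ≥  i        0
   ```

   The repulsive-core stiffness equals `E_a` numerically (in
   k_BT/nm²); the separate `k_rep` applies only to the pure steric
   pairs.  Both are independent configuration fields.

The size ratio `r2/r1 = 1.1` is what limits cluster growth: heads
crowd ("bouquet of flowers") before anchors do, and the ratio controls
the maximal cluster diameter.  Ratios ≤ 1 remove the limit and trigger
a warning.

**Choices the model text leaves open, decided here:**

* *Bond law.*  The two particles are "connected"; we use a harmonic
  bond of rest length `r1 + r2` and stiffness `10 k_BT/nm²`
  (config-exposed, `bond_k`).  A spring keeps the timestep stable and
  mimics rigid-group mechanics at the timescales of interest.
  Intramolecular steric repulsion is excluded — at rest length the
  repulsion is identically zero, and the bond already controls the
  intramolecular distance.
* *Pair strength with a seed.*  The attraction of a pair uses the
  stronger of the two molecules' well depths, so a static seed with
  `E_a = 8 k_BT` attracts bulk molecules at its own strength.
* *Boundary.*  The disk is enforced by a half-harmonic inward wall on
  anchors, `U = ½ boundary_k (ρ − R)²` for `ρ > R`,
  `boundary_k = 20 k_BT/nm²`.  Reflective walls interact badly with a
  5-ns Euler step; a soft wall admits sub-nm overshoot only.
* *Seed geometry.*  A seed is a full, immobile dimer placed at a site
  with no anchor within `i + 2 nm`.

## Integration

The overdamped Euler–Maruyama scheme advances every mobile particle:

```
x(t+dt) = x(t) + (D_p / k_BT) F dt + sqrt(2 D_p dt) ξ,   ξ ~ N(0,1)³
```

with `dt = 5 ns`.  Gaussian increments are pre-drawn in ~4-million
value chunks with numpy's PCG64 generator — several times faster than
scalar draws inside the compiled loop and bit-reproducible for a given
seed.  A run with a fixed `rng_seed` is a hard determinism contract
(asserted in the tests).

Neighbor search uses Verlet pair lists per interaction type
(anchor–anchor, head–head, anchor–head), built from a cell grid with a
1-nm skin and rebuilt whenever any particle has moved more than half
the skin since the last build; this guarantees the pair forces are
identical to an all-pairs evaluation (asserted against a brute-force
kernel and against the pure-numpy reference assembly).  Steps whose
displacement exceeds `r1` are counted and reported as a timestep
warning.

### Diffusion calibration

Experiments report an effective molecular mobility
`D_syx = 0.2 μm²/s`.  For two bonded particles of equal mobility the
centre of mass diffuses at `D_p/2` (internal forces cancel), so the
analytic calibration is `D_p = 2 D_syx`.
`calibrate_particle_diffusion` verifies this against the measured MSD
of a sparse gas of isolated dimers and applies multiplicative
corrections if the measurement falls outside 5%.

One subtlety: the *anchor's* MSD carries a slow transient because the
head swings around the anchor (rotational relaxation of the bond
vector, time scale |r|²/(4 D_p) ≈ 25 μs).  The dimer's diffusion
coefficient is therefore estimated from the centre-of-mass MSD by
default (`fit_diffusion(mode="com")`), which matches the anchor slope
at lags well beyond the transient.  Fits use `MSD = 4 D t + b` with a
free intercept over lags of 10–100 μs.

## Cluster statistics

Two molecules are in proximity when their anchor centres are within
`2 r1 + 1 nm = 7 nm`; a cluster is a connected component of that
relation (transitive closure, singletons allowed).  The proximity rule
is applied to anchors only — head positions fluctuate vertically and
would make the cutoff ambiguous.

**Effective diameter.**  Imaged cluster sizes are FWHM-equivalent
diameters, simulated clusters are member counts; they are mapped by
`d = 2 r1 sqrt(N / φ)` — the diameter of the circle whose area equals
the summed anchor cross sections at packing fraction φ.  φ was
calibrated once from the convex hull (dilated by r1) of large
equilibrium clusters, giving `φ = 0.75`; with this value a 60-nm
cluster corresponds to ≈ 75 molecules, consistent with published
single-molecule estimates for syntaxin microdomains.

**Cluster transport.**  `cluster_diffusion` tracks clusters between
consecutive frames by exact member-set identity and uses only
displacement intervals with unchanged membership, so centroid motion
is transport rather than an artifact of molecules joining or leaving.
Centroids average molecular centres of mass (anchor+head), which are
free of the short-lag head-swing transient that biases anchor-only
positions at 10-μs lags.  D per size bin is the one-lag estimate
`<Δr²>/(4 Δt)`; bins with fewer than 10 observations are reported
missing (NaN), not zero.

**Dissociation and residence.**  A molecule in a cluster (size ≥ 2)
dissociates at frame t+1 when its new cluster shares no member with
its former companions and stays clear of them for 2 consecutive frames
(debouncing; without it the rates scale with the sampling rate because
boundary molecules flicker across the cutoff).  Rates are events per
particle per ms of in-cluster exposure, binned by source-cluster size
and, separately, by the number of anchors within the interaction
radius.  A residence episode extends while the molecule's companion
set overlaps the previous frame's; episodes touching either end of the
trajectory are censored and excluded from medians.  Equilibrium
statistics exclude the first 25% of frames (burn-in).

## Assays

* **FRAP.**  Molecules inside a disc concentric with the domain and
  covering exactly 10% of its area are labelled bleached; labels never
  affect dynamics.  The curve is the fluorescent molecule count inside
  the disc normalized to the pre-bleach count; a closed, ideally mixed
  system plateaus at 0.9.  The test suite validates the
  non-interacting limit against the closed-form Bessel-series solution
  of the radial diffusion equation with a reflecting outer boundary.
* **Membrane coverage.**  The disk is tiled with square compartments
  (vesicle-sized, 40 nm, at full geometry); a compartment is visited
  once any anchor centre lands in it on a sampled frame.  Coverage is
  meaningful from an *equilibrated clustered* state — from a random
  uniform start every compartment is occupied immediately.  At the
  reduced test geometry a 40-nm lattice has only ~35 compartments and
  saturates trivially, so the scaled checks use a proportionally finer
  20-nm lattice (~160 compartments, comparable to the ~180 of the full
  geometry).
* **Seeded aggregation.**  A static `E_a = 8 k_BT` dimer is inserted
  into an equilibrated membrane at an empty site and the first-passage
  time of its cluster to each target size is recorded over replicas;
  targets not reached within a run are right-censored and reported as
  such.  At reduced scale the growth is burst-like — the seed captures
  whole mobile clusters rather than accreting monomers — which makes
  single-replica times heavy-tailed; the tests therefore censor
  first-passage times at the window and assert the energy ordering on
  replica-averaged growth curves of the seed's cluster, which use
  every frame rather than only the threshold crossing.
* **Docking/priming census.**  A 20×20 lattice of 30-nm cells centred
  on the domain axis.  Docking candidates per cell: time-averaged
  anchor count (every syntaxin is docking-competent).  Priming
  candidates: molecules that are free or on a cluster boundary — at
  most 3 neighbors within the interaction radius (interior anchors of
  hexagonally packed clusters have ≥ 5; threshold config-exposed) —
  continuously for ≥ 100 ms while staying within one cell ± a 1-cell
  tolerance ring (sub-cell jitter should not disqualify).  Each
  molecule counts at most once per base cell.

## STED image pipeline

Coordinates are pixel centres, 0-based, with physical distances in nm
(default 10 nm/px).  The pipeline consumes post-deconvolution images;
background handling upstream is a constant-offset subtraction.

* **Detection**: a pixel is a cluster centre iff it attains the
  maximum of the circular window centred on it (diameter 9 px for
  syntaxin, 21 px for BRP) and its intensity is strictly above
  25 a.u.  Plateau tie-break: the pixel must also exceed at least one
  window pixel, and connected equal-valued plateaus contribute their
  centroid pixel only.
* **Sizing**: rings of increasing integer pixel radius are scanned
  until the first ring whose average intensity falls below half the
  centre intensity; all scanned pixels at or above the half-maximum
  form the cluster area, reported as the equal-area circle diameter.
  Spots whose scan would leave the image are flagged and not sized.
  The measure is invariant to intensity scaling and translation.
* **Active zones**: BRP spots are grouped by single-linkage clustering
  at 150 nm; groups of ≥ 4 spots whose least-squares circle fit has
  RMS residual < 30 nm are rings.  The AZ is the filled disk centred
  on the spot centroid with radius = mean spot-to-centroid distance
  + 25 nm padding, accepted when its diameter lies in a plausibility
  band of 150–400 nm.  All constants are arguments.
* **Classification**: a syntaxin cluster is at-AZ iff its centre lies
  inside any AZ disk (closed region — the boundary counts as inside).
  Distances are minima over ring-member BRP spot centres.  Densities:
  AZ count over summed AZ area; outside count over membrane-mask area
  minus AZ area (no mask → outside density omitted with a warning).
  Size-vs-distance summaries use 8 distance ranges (0–25–50–75–100–
  150–200–300–∞ nm).
* **Group comparison**: two-sample t-test on means with significance
  stars at 0.05/0.01/0.001; degenerate zero-variance input is reported
  non-significant with a warning.

## Synthetic data

The image generator emulates the post-deconvolution product of a
two-color acquisition: BRP rings of 230 nm diameter built from 5
discrete 25-nm-FWHM spots, syntaxin clusters with FWHM diameters from
truncated normals (means 80 nm at AZ / 64 nm outside, sd 15 nm,
> 20 nm), Poisson shot noise plus Gaussian read noise on a constant
background.  AZ-group clusters are placed strictly inside their ring
and outside-group clusters ≥ 150 nm away from any ring, so
classification ground truth is unambiguous; a 120-nm minimum cluster
separation keeps detections resolvable by the 9-px window.  Every
rendered object appears exactly once in the ground-truth table, and a
fixed seed reproduces the image bit for bit.

Spots are rendered as **Gaussians** of the nominal FWHM by default,
with a Lorentzian profile selectable.  A pure 2D Lorentzian of the
cluster's own width is not integrable: at realistic densities its
pooled tails lift the inter-cluster baseline to a level where a fixed
absolute threshold fires on noise.  In real deconvolved data the far
tail of a cluster image is governed by the narrow (25 nm) PSF, not by
a Lorentzian of the cluster's width, so the Gaussian blob is the more
faithful emulation of what the detector sees.

What the generator does *not* model: antibody labeling stochasticity
and displacement, depletion/excitation physics, drift, chromatic
offsets, or a vectorial PSF.  Pipeline tests on these images therefore
validate the measurement procedure (detection, sizing, grouping,
classification), not robustness to those instrument effects.

The trajectory generators provide exactly solvable inputs: ideal 2D
Brownian walkers (exact Gaussian increments at the frame resolution,
radial reflection at the wall), frozen configurations with a known
partition, and a two-state exchange process with exponential
binding/unbinding at known rates (bound slots lie within the proximity
cutoff of a permanent core, so connectivity never depends on which
other molecules are bound).

## Study scales used by the test suite

Full-scale replicas of the reference conditions (500 molecules on a
300-nm disk, 5·10⁷ steps × 12 replicas per energy) are deliberately
not run by the suite; the stochastic checks use a density-preserving
reduced geometry of 100 molecules on a 134-nm disk
(`300 · sqrt(100/500)`), 10–20 ms of simulated time per run at the
reference timestep with 3–4 replicas where single-run noise would
swamp the effect, plus a 50-molecule / 95-nm geometry for the
steric-ceiling runs (10⁷ steps) and a 200-molecule / 190-nm geometry
for the free-diffusion FRAP check.  At these scales cluster
coarsening has not reached the fully converged regime; consequently
the suite asserts printed numbers only where they are scale-free
(potentials, diffusion calibration, image analysis, analytic
relations) and directions/orders of magnitude for collective
observables (monotonicity in E_a, exploration slowdown at the AZ
energy, millisecond-scale residence and aggregation).  Passing tests
demonstrate the machinery and the direction of every effect, not the
converged full-scale numbers.

## Known limitations

* The bond spring constant and the head's free tilt are modelling
  choices; only the head-crowding mechanism, not the exact bond
  mechanics, is constrained by the data the model targets.
* Dissociation rates depend mildly on the sampling stride even with
  debouncing; kinetics runs sample every 10 μs.
* Cluster lifetimes are not estimated: above a critical size clusters
  outlive any practical run.
* The effective-diameter map assumes a single packing fraction;
  loosely bound rims of small clusters make it an approximation below
  ~5 molecules.
* The image pipeline shares the usual FWHM caveat: absolute sizes
  inherit label displacement and deconvolution effects, so only
  relative comparisons are meaningful.
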