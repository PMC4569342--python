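# syxsim

Particle-based Brownian-dynamics modelling of Syntaxin-1A nanocluster
formation on the presynaptic membrane, together with the STED
image-analysis procedure used to quantify such clusters relative to
Bruchpilot-defined active zones.

## The scientific problem

Syntaxin-1A, the plasma-membrane t-SNARE of synaptic vesicle fusion,
covers the entire neuronal membrane but organizes into nanoclusters
(~60–100 nm) that are larger and denser at active zones (AZ) than
outside.  A minimal physical model explains both the cluster-size
distributions and the exchange dynamics: each syntaxin is a dimer of
two spherical particles — a membrane anchor (radius r₁ = 3 nm)
carrying a weak homophilic attraction, and a bulky head (r₂ = 3.3 nm)
contributing steric repulsion that caps cluster growth.  The anchors
interact through a piecewise-harmonic well

    U(d) = ½E_a(d−r)² − E_a                     d < r
         = 2E_a/(i−r)²·(d−r)² − E_a             r ≤ d < (i+r)/2
         = −2E_a/(i−r)²·(d−i)²                  (i+r)/2 ≤ d < i
         = 0                                     d ≥ i

with contact distance r = 2r₁, interaction radius i = r + 2.25 nm and
well depth E_a (k_BT).  Raising E_a by a fraction of 1 k_BT tips the
membrane from mostly-free syntaxin to near-total aggregation;
E_a ≈ 4.0 k_BT reproduces the measured cluster sizes outside active
zones and E_a ≈ 4.4 k_BT those at active zones.  The overdamped
dynamics x(t+dt) = x + (D_p/k_BT)F·dt + √(2D_p·dt)·ξ run at dt = 5 ns
with D_p calibrated so the dimer diffuses at the measured
D_syx = 0.2 μm²/s.

The package is aimed at membrane biophysicists and quantitative
neuroscientists who want to (a) simulate weakly interacting membrane
protein clusters and their kinetics (FRAP, exploration, seeded
aggregation, docking/priming censuses), (b) quantify two-color STED
images of such clusters (local-maximum detection, FWHM sizing, ring
grouping, AZ classification, group statistics), and (c) test every
step against synthetic data with exact ground truth.

## Worked example

Simulate a density-preserving membrane patch at the outside-AZ
energy, then look at its cluster statistics:

```python
from syxsim import SimulationConfig, run, build_cluster_table
from syxsim import mean_cluster_size_and_single_fraction, effective_diameter

cfg = SimulationConfig(n_molecules=100, domain_radius=134.0, e_a=4.0,
                       n_steps=2_000_000, sample_stride=10_000, rng_seed=7)
traj = run(cfg)                      # 10 ms of membrane time
ct = build_cluster_table(traj)
mean_size, single_frac = mean_cluster_size_and_single_fraction(traj, cluster_table=ct)
largest = ct.table[ct.table.frame == traj.n_frames - 1]["size"].max()
print(f"mean cluster size {mean_size:.2f}, single fraction {single_frac:.3f}")
print(f"largest final cluster: {largest} molecules "
      f"≈ {effective_diameter(largest, cfg.r1):.0f} nm")
```

prints

```
mean cluster size 3.88, single fraction 0.131
largest final cluster: 18 molecules ≈ 29 nm
```

i.e. after 10 ms most syntaxins are already clustered (only ~13%
remain single) and the largest cluster has reached a 29-nm footprint —
still growing toward the 60–100 nm regime that full-length runs reach.
The same trajectory object feeds the assays (`frap`,
`membrane_coverage`, `aggregation_experiment`, `candidate_census`).

The image side runs entirely on synthetic ground truth:

```python
import numpy as np
from syxsim import ImageSpec, generate_image, detect_and_size, \
    define_active_zones, classify_and_measure

syx, brp, truth = generate_image(ImageSpec(), np.random.default_rng(0))
syx_det = detect_and_size(syx)                 # 9-px window, >25 a.u.
brp_det = detect_and_size(brp)                 # 21-px window
az = define_active_zones(brp_det[["x_nm", "y_nm"]].to_numpy())
det, summary, _ = classify_and_measure(
    syx_det, az, brp_det[["x_nm", "y_nm"]].to_numpy(),
    membrane_mask=np.ones(syx.data.shape, bool))
print(f"{len(az)} active zones, {summary['n_az']} AZ clusters "
      f"(mean {summary['mean_diameter_az_nm']:.0f} nm), "
      f"{summary['n_outside']} outside (mean {summary['mean_diameter_outside_nm']:.0f} nm)")
```

prints

```
4 active zones, 12 AZ clusters (mean 80 nm), 30 outside (mean 61 nm)
```

recovering the generator's 80 nm / 64 nm group means from the rendered
pixels alone.  A command-line interface mirrors the library
(`syxsim simulate|analyze-traj|frap|coverage|seed-agg|census|analyze-image|synth-image|synth-traj`).

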