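# coacwet

Simulation and analysis toolkit for **coacervate–membrane wetting**: how
liquid condensate droplets formed by oppositely charged oligopeptides
(K₁₀/D₁₀-type complex coacervates) spread on lipid membranes, and what that
does to the lipids underneath.

The package is aimed at membrane biophysicists who combine coarse-grained
simulation with quantitative fluorescence microscopy.  It provides, as one
importable library plus thin analysis drivers:

* **`coacwet.model` / `engine` / `builders`** — a generic implicit-solvent
  coarse-grained model in reduced units (1σ ≈ 6.93 Å, k_B = 1): three-bead
  H–T–T lipids with a cos²-tailed attraction of range ω_TT (WCA head
  repulsion, FENE bonds k=30, r∞=1.5) and A₁₀/B₁₀ bead-spring
  polyelectrolytes (self-repulsive WCA, heterotypic LJ attraction
  ε_PP = 1.5, harmonic bonds k=50, r_eq=0.548), integrated by BAOAB
  Langevin dynamics (T*=1.1, damping 50) with numba kernels.  Builders for
  polymer droplets, unilamellar vesicles (~9500 lipids at diameter 50) and
  flat bilayer patches.
* **`coacwet.wetting`** — the wetting algebra
  Φ = (sin θ_e − sin θ_c)/sin θ_v = cos θ_in relating the three apparent
  contact angles to the intrinsic contact angle, Neumann-triangle force
  balance, and extraction of θ_in directly from two-channel cross-section
  images by Canny edge detection and circular-arc regression.
* **`coacwet.dynamics`** — FRAP recovery fits
  y = (I₀ + I_max(x/τ½))/(1 + x/τ½), apparent diffusion
  D_app = r₀²ν/(4τ½), and the displacement-ratio estimator of
  D_bare/D_wet from short-window lipid displacements (Δt* ∈ [0.25, 3.0]).
* **`coacwet.packing`** — per-leaflet area-per-lipid via (periodic or local
  tangent-plane) Voronoi construction, P2 tail order, anionic-lipid
  de-mixing enrichment at the contact region, contact counting and
  chain-level cluster analysis of coacervation.
* **`coacwet.phasor`** — spectral phasor transform
  (G, S) of hyperspectral stacks, two-cursor projection, fluidity
  histograms and their center of mass.
* **`coacwet.synth`** — deterministic generators with ground-truth sidecars
  for every input the pipeline consumes.
* **`coacwet.io` / `cli`** — LAMMPS-dump text trajectories, GRO/XTC
  ingestion (MDAnalysis), TOML run configs, the MARTINI nonbonded-table
  rescaling utility (ε × 1.20, charged DOPS heads exempt), and the
  `coacwet` command-line entry point.

## Worked example

Extract the intrinsic contact angle from a rendered cross-section of a
droplet wetting a vesicle, and compare with the wetting algebra:

```python
from coacwet import synth, wetting

img, truth = synth.gen_wetting_snapshot(theta_in=120.0, noise=0.02, seed=3)
res = wetting.extract_intrinsic_angle(img)
print([round(a.theta_in, 2) for a in res.angles])
# [119.85, 119.85]      <- two contact points, ground truth 120.0

phi = wetting.geometric_factor(wetting.ApparentAngles(90, 30, 240))
print(round(phi, 5), round(wetting.intrinsic_angle(phi), 3))
# -0.57735 125.264
```

Run a sweep (20 snapshots per condition, two angles each — 40 measurements)
with `python analysis/02_wetting_angles.py`:

```
              mean   std  count
theta_true
60.0         59.81  0.15     40
90.0         89.99  0.08     40
120.0       119.91  0.06     40
140.0       139.87  0.03     40
```

i.e. the Canny + arc-regression pipeline recovers the prescribed intrinsic
angle to within 0.2° across the partial-wetting range, independent of the
droplet/vesicle size ratio.

The phasor driver (`python analysis/05_phasor.py`) analyzes a synthetic
two-region LAURDAN-like stack and prints the per-region fluidity center of
mass, e.g. `CM(wetted) = 0.233 < CM(bare) = 0.825`: pixels under the
droplet report the packed (blue-shifted) spectral state.

The mobility driver (`python analysis/03_mobility.py`) first calibrates the
displacement-ratio estimator on Brownian walkers with known D_bare/D_wet,
then measures it on droplet-on-patch simulations at two adhesion strengths:

```
true 1.00 -> plateau 1.005 +/- 0.012
true 1.35 -> plateau 1.377 +/- 0.016
true 1.60 -> plateau 1.607 +/- 0.017
true 1.80 -> plateau 1.807 +/- 0.021
eps_PL = 0.7: D_bare/D_wet plateau 1.158 +/- 0.028
eps_PL = 1.3: D_bare/D_wet plateau 1.684 +/- 0.043
```

Lipids wetted by the droplet diffuse measurably slower than bare-membrane
lipids, the more so the stronger the polymer–head adhesion.

Other drivers: `analysis/01_simulate_patch.py` (thermostat contract on a
128-lipid patch; prints `mean T* = 1.0887 +/- 0.0040 (target 1.1)` with
full lipid retention) and `analysis/04_packing.py` (APL / tail order /
clustering under an adsorbed droplet).

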