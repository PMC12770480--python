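# Methods

This package implements the computational machinery for studying how
biomolecular condensates (complex coacervates of short polyelectrolytes,
the K10/D10 system) wet lipid-bilayer membranes: a generic implicit-solvent
coarse-grained simulator, wetting-geometry quantification, lipid-mobility
estimators, membrane packing/ordering/de-mixing analyses, and spectral
phasor analysis of hyperspectral imaging.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## The generic coarse-grained model

Reduced Lennard-Jones units throughout: sigma is the length unit (about
6.93 Å for this parameterization), epsilon the energy unit, k_B = 1 and all
beads have unit mass.  Time is measured in the derived unit tau; it has no
calibrated mapping to physical time, which is why all dynamical statements
are made as ratios.

**Lipids** are three beads, head-tail-tail (H-T-T), joined by FENE bonds
(k = 30, r_inf = 1.5).  Heads repel everything sterically through the WCA
potential (sigma_HH = sigma_HT = 0.95).  Tail beads carry, on top of a WCA
core with sigma_TT = 1.00, a flat attractive well of depth epsilon_TT = 1
below r_c = 2^(1/6) sigma_TT that decays as -cos^2 over a tunable range
omega_TT.  This broadened attraction is what makes an implicit-solvent
bilayer cohere; omega_TT controls the fluid-gel balance and effective
stiffness.  The published functional form specifies the plateau and cos^2
ramp; the repulsive core below contact is not printed and is implemented as
the WCA core with epsilon 1 (configurable), the convention of the original
three-bead model.  The original model also includes a head-to-second-tail
straightening spring; the source model description lists only FENE bonds,
and we follow it — at the temperatures and omega_TT values used here the
patch remains an intact fluid bilayer without it (verified in the test
suite).

**Polyelectrolytes** are two ten-bead bead-spring chains, A10 and B10, in
equal numbers.  Like beads repel (WCA, sigma_AA = sigma_BB = 0.5); unlike
beads attract through a truncated (unshifted) Lennard-Jones potential with
epsilon_PP = 1.5 and cutoff 2.5 sigma.  Successive beads are joined by
harmonic bonds with k = 50 and r_eq = 0.548.  The harmonic prefactor
convention is U = (k/2)(r - r_eq)^2; the alternative U = k(r - r_eq)^2 is
selectable (`harmonic_half_prefactor` in the config) since the source states
only the constant.

**Cross interactions.**  Polymer-head pairs attract (truncated LJ) with the
tunable well depth eps_PL; polymer-tail pairs are WCA-repulsive.  Cross
sigmas use the Lorentz arithmetic mean (no mixing rule is stated in the
source; this is the standard choice).  (eps_PL, omega_TT) are the two dials
that map membrane composition onto the model: stronger eps_PL means stronger
wetting.  The 5% DOPS analogue is published as eps_PL = 0.7625,
omega_TT = 1.70 and ships as a named preset; the DOPC / 10% / 20% DOPS
pairs were published only as figure annotations unavailable to us, so the
shipped values for those presets are package estimates following the
monotone trend, explicitly flagged `provenance = "estimated"` in
`coacwet/data/presets.toml`.

**Dynamics.**  BAOAB-split Langevin integration; velocity Verlet falls out
when the friction is zero, which is how the energy-conservation contract is
checked (a ~50-bead lipid cluster at dt* = 0.001 drifts < 1e-3 relative
over 1e4 steps).  The published protocol is equilibration at dt* = 0.002
(1e5 steps) and production at dt* = 0.005 (1e7 steps) at T* = 1.1 with
damping timescale 50 (gamma = 0.02).  That damping is deliberately weak, so
a freshly built lattice that is still melting cools faster than the
thermostat can compensate; runs therefore begin with a short
strong-coupling thermalization stage (damping 2.0, 3e4 steps at
dt* = 0.002) before the published equilibration and production stages.
Neighbor lists use cell binning with skin 0.3 sigma, rebuilt when any bead
has moved more than half the skin; the list radius adapts to the species
actually present.  Same seed, same inputs give bitwise-identical
trajectories.

**Desk-scale sizes.**  The published systems (a diameter-50 vesicle with
~9500 lipids, 2000 chains, 1e7 production steps) are reproduced as builders
and protocol defaults, but the test suite and the acceptance script run
128-512-lipid patches with 1e5-step production windows and 60-200-chain
droplets; these sizes were chosen so each analysis has enough statistics to
check its contract while the whole suite stays at desk scale.  The vesicle
packing density (head-surface area per lipid ~1.36 sigma^2) is derived from
the two published numbers (diameter 50, ~9500 lipids).

## Wetting geometry

At the micron scale, three apparent contact angles open from the contact
line (theta_e toward the external solution, theta_c toward the condensate,
theta_v toward the vesicle lumen; they sum to 360 degrees), and the
geometric factor is Phi = (sin theta_e - sin theta_c)/sin theta_v, ranging
from +1 (dewetted) to -1 (complete wetting), with Phi = cos theta_in
defining the intrinsic contact angle — a material property that, unlike the
apparent angles, does not depend on droplet and vesicle sizes.  A
Neumann-style triangle of the droplet surface tension and the two membrane
segment tensions balances at the contact line; `tension_triangle_residual`
measures that balance and the test suite constructs consistent triples by
the sine rule.

**Snapshot extraction.**  Cross-section images (two channels: lipid heads,
polymer density; rendered from simulation slabs or synthetic) are processed
as: Canny edge detection per channel (Gaussian sigma 2 px; hysteresis
thresholds 0.05/0.15 on the max-normalized image — absolute gradient
thresholds proved far more robust to pixel noise than quantile thresholds,
because noise inside the droplet body and the empty background otherwise
floods the edge set); least-squares circular-arc regression (Kasa fit) of
the membrane edge chain and of the droplet free-surface chain (condensate
edges further than a small margin outside the fitted membrane circle); the
two fitted circles are intersected to locate the contact points, and
theta_in is the angle, measured through the condensate, between the
membrane tangent on the wetted side and the droplet-surface tangent.  Each
cross-section yields exactly two angles (left/right contact points), with a
bootstrap-over-edge-pixels uncertainty.  The regression window defaults to
the full edge chain of each interface: on cross-sections the interfaces are
circular arcs, so the global fit strictly dominates a short local window; a
windowed fit remains available.  Synthetic renderings with analytically
prescribed theta_in are recovered to ~0.2 degrees (noise-free and at up to
10% pixel noise), comfortably inside the +-3 degree acceptance band.

Degenerate outcomes are flagged rather than silently numeric: no condensate
boundary at all reports a dewetted cross-section; a condensate boundary
that never leaves the membrane ring reports complete wetting.

**Synthetic geometry.**  The generator places the membrane as a circle and
solves for the droplet circle through two prescribed contact points with
the tangent rotated by theta_in; the droplet surface degenerates to a
straight line when theta_in + footprint half-angle = 180 degrees, so the
generator narrows the footprint for strongly wetting angles.

## Lipid mobility

**FRAP.**  Recovery curves are fitted with
y(x) = (I0 + Imax (x/tau_half)) / (1 + x/tau_half) by nonlinear least
squares; the apparent diffusion constant is D_app = r0^2 nu / (4 tau_half)
with r0 the bleach-spot radius and nu a spot-size correction factor.  The
value of nu used experimentally is instrument-dependent and not printed in
the source; it is a free parameter here — and irrelevant to all reported
quantities, because only ratios are used: tau_wet/tau_bare =
D_bare/D_wet exactly, with r0 and nu cancelling (asserted to machine
precision in the tests).  Fits whose tau_half exceeds ten observation
windows are refused as unconstrained.

**Displacement ratio.**  Coarse-grained time is uncalibrated and contact
residence times are short, so the simulation-side estimator compares mean
squared in-plane head-bead displacements over short windows Delta t*
(grid 0.25 to 3.0) between lipids classified at the window start as
contact (head within 1.5 sigma of any polymer bead; no cutoff is stated in
the source — 1.5 sigma sits just beyond the head-polymer LJ minimum and is
configurable) and far (beyond twice the cutoff; the annulus between is a
buffer excluded from both classes).  Lipids that change class mid-window
are retained (windows are short; a discard policy is available).  The
plateau is the mean over the largest-window third of the grid with a
bootstrap-over-lipids standard error.  On Brownian walkers with known
D_bare/D_wet in {1, 1.35, 1.6, 1.8, 2.5} the estimator is unbiased within
its bootstrap confidence interval at 200 walkers x 500 windows.  On actual
droplet-on-patch simulations (512 lipids, 60 chains) the ratio comes out
above one and grows with eps_PL — the desk-scale counterpart of the
full-scale plateaus (1.35 / 1.6 / 1.8 across compositions), which require
the ~9500-lipid vesicle and 1e7-step trajectories to reproduce
quantitatively.

## Membrane packing and composition

**Leaflets** are assigned by the sign of the head-minus-terminal-tail
vector projected on the local outward normal (+z for patches, radial for
vesicles).

**Area per lipid (APL).**  For flat periodic patches, head beads are
tessellated on the 2D torus by replicating the 3x3 images, so per-leaflet
cell areas tile the box exactly (conservation is checked to 1% on jittered
fluid-like configurations, and is exact on lattices: a^2 for square,
(sqrt(3)/2) a^2 for triangular).  For curved membranes each lipid gets a
local tangent-plane Voronoi cell: PCA over its 12 nearest head neighbors
(k = 12 is robust at wetted-footprint curvatures; configurable) defines the
plane, the neighborhood is projected, and the central cell's polygon area
is the APL; degenerate (collinear) neighborhoods yield NaN with a warning.
The packing summary reports the fraction of cells below a threshold
(0.5 nm^2 for MARTINI-resolution input, where lower APL means tighter
packing).  A grid-binned APL contour map localizes compacted regions on
patches.

**Tail order.**  P2 = (3 cos^2 theta - 1)/2 per lipid, theta between the
head-to-terminal-tail vector and the local normal; +1 aligned, -1/2
in-plane, 0 isotropic (checked against Monte-Carlo sampling).  The source
does not name a scalar order parameter; P2 against the local normal is the
standard nematic choice.

**De-mixing.**  For a lipid species (e.g. the anionic DOPS analogue), the
report gives the fraction of that species in the condensate-facing leaflet
that is contact-labeled, together with the contact region's share of the
leaflet and their ratio (enrichment).  A uniformly mixed leaflet gives
enrichment 1 (binomial null, verified); values well above 1 indicate
sorting into the contact region, the full-scale signature being roughly
half of the anionic lipids in contact.  Bootstrap confidence intervals are
taken over frames.

**Clustering.**  Coacervation is summarized by chain-level single-linkage
clusters: chains are linked when any inter-chain bead pair is within the
cutoff (default 1.5 sigma_AA = 0.75); the largest-cluster fraction is the
phase-separation statistic.  Chain-level (not bead-level) clustering is
reported because the phase transition is about chain condensation.

## Spectral phasor analysis

Each pixel's emission spectrum maps to
G + iS = sum_l I(l) exp(i 2 pi n (l - l_min)/(l_max - l_min)) / sum_l I(l),
with harmonic n = 1 and phase origin l_i = l_min (the source leaves both
symbolic; first harmonic is the standard spectral phasor, both
configurable), discretized by the midpoint rule over channel centers.
Non-negative spectra give |G + iS| <= 1, scaling a spectrum leaves its
phasor fixed, and mixtures fall on the segment between component phasors
with intensity-integral weights — all asserted to numerical precision.

Two-cursor analysis projects each pixel's phasor orthogonally onto the
segment from cursor 1 (fluid extreme) to cursor 2 (packed extreme),
clamped to [0, 1]; off-segment pixels use the perpendicular foot (the
handling is not specified in the source).  The fluidity fraction is
oriented so higher = more fluid (1 at the fluid cursor); histograms use 100
equal bins on [0, 1], normalized to unit mass, summarized by their center
of mass CM = sum_i i F_i / sum F_i.  Pixels below 1% of the maximum
integrated intensity are masked before transforming.  On synthetic
two-region stacks the wetted (packed-shifted) region reproducibly shows
the lower fluidity CM, the direction observed in the imaging experiments.

## Synthetic data: what passing proves

The generators fan a single seed into stable per-generator substreams
(SHA-256 of generator name), so artifacts are bit-reproducible and adding a
generator never perturbs existing fixtures.  Defaults: LAURDAN-like
Gaussian bases at 440 nm (packed) and 490 nm (fluid), width 25 nm, on a
30-channel 416-728 nm axis (a typical solvatochromic shift; the
instrument's actual range is not printed in the source); Brownian walkers
with per-axis step variance 2 D dt; FRAP curves from the fitted model
itself plus Gaussian noise; wetting cross-sections from the exact
two-circle construction.

Synthetic recovery shows the estimators are correct and unbiased under
their own generating assumptions (pure 2D diffusion, ideal two-state
spectra, perfectly circular interfaces, no point-spread function, no
bleaching during recovery).  It does not show robustness to real-data
pathologies — anomalous diffusion, spectral bleed-through, out-of-plane
contact lines, detector artifacts — which is why every threshold involved
is exposed as a parameter rather than baked in.

## Known limitations

* No electrostatics, explicit solvent or ions in the generic model; salt
  effects (e.g. the fully dewetted state) are outside its reach.
* MARTINI-resolution trajectories are analyzed, never generated; the
  nonbonded-rescaling utility (epsilon x 1.20 between polyelectrolyte and
  DOPC head beads, charged DOPS heads exempt) operates on user-supplied
  tables since the underlying force-field table is not shipped.
* The estimated (eps_PL, omega_TT) presets for DOPC/10%/20% DOPS are
  package choices, not published values (see presets.toml provenance).
* Contact-angle extraction assumes the cross-section contains the rotation
  axis; misaligned slabs bias the apparent circles.
* The desk-scale droplet-on-patch mobility run demonstrates direction and
  monotonicity, not the full-scale plateau values.
* Tail ordering under the droplet is geometry-sensitive at desk scale: on a
  small flat patch a strongly adhering droplet indents the membrane and
  tilts the contact lipids, lowering their P2 — the opposite of the
  enhanced ordering seen on large vesicles, where the wetted footprint is a
  shallow spherical cap.  The estimator is validated on analytic and
  Monte-Carlo oracles; trajectory-level ordering claims should be made on
  vesicle-scale systems.
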