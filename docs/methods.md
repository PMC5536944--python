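# Methods

`nanotess` quantifies the lateral organization and mobility of
plasma-membrane (PM) proteins that partition into nanometric domains, of
the kind studied with single-particle-tracking PALM (sptPALM) in plant
epidermal cells. This note describes the models, the estimators, the
numerical conventions, and what the synthetic generator does and does not
emulate.

## Blinking correction (`nanotess.localizations`)

A photoactivatable fluorophore such as mEos emits several temporally
separated bursts before bleaching, so raw localization counts overcount
molecules. The correction merges detections within a spatial search
radius ω and a blinking tolerance τ:

* a **burst** is a maximal chain of detections in consecutive frames, each
  within ω of the burst's running barycentre;
* a **molecule** is a maximal chain of bursts separated by ≤ τ dark frames
  and within ω of the molecule's running barycentre;
* the molecule is replaced by the unweighted barycentre of all member
  detections.

ω defaults to 48 nm, appropriate when the per-frame density of
simultaneously active emitters stays below ~0.5 µm⁻². The merge is greedy
in frame order and deterministic: a detection prefers extending an open
burst over re-igniting a dormant molecule, then the nearest barycentre,
then the lower molecule id; a molecule accepts at most one detection per
frame. This ordering makes the burst decomposition independent of τ, so
the molecule count at τ=0 equals the burst count reported by the
photophysics summary by construction (and conservation of detections is
exact). On instances whose molecules are well separated relative to ω,
the greedy merge coincides with a pairwise union-find over the
spatio-temporal predicate; the test suite checks this equivalence.

τ, when not supplied, is the smallest value covering a configurable
quantile (default 0.9) of the measured off-time distribution
(`select_tau`). On dense clustered data the unlimited-τ pre-merge that
measurement requires can chain distinct molecules, so for simulated data
the recommended τ is the same quantile applied to the known off-time law
(τ=11 frames for the default geometric mean of 5).

The consistency check divides the τ=0 burst count by the mean
blinks/molecule and reports the percent difference from the cleaned
molecule count; values of a few percent indicate a self-consistent merge.

## Voronoï nanodomain segmentation (`nanotess.voronoi`)

Molecule positions seed a Voronoï tessellation clipped to an analysis
region (default: the convex hull of the positions; an explicit polygon can
be supplied). The first-rank local density of molecule *i* is

δ¹ᵢ = (1 + |N(i)|) / (Aᵢ + Σ_{j∈N(i)} Aⱼ),

with N(i) the cells sharing a positive-length edge inside the region and
A the clipped cell areas. The average density is δ_N = N / region area.
Candidates satisfy δ¹ᵢ > 2·δ_N (factor configurable); nanodomains are
connected components of candidates on the adjacency graph, kept when they
have ≥5 molecules and ≥32 nm² of summed cell area. The cluster area is
the sum of member cell areas and the equivalent diameter 2·√(area/π).

Numerical conventions: unbounded cells are closed at a large radius and
clipped, so the clipped areas partition the region to machine precision;
degenerate (cocircular) zero-length ridges are dropped from adjacency;
exact duplicate coordinates are perturbed by a deterministic 10⁻³ nm
jitter keyed on the row index; zero-area cells are flagged and excluded
from density estimates. Diameter summaries report both the arithmetic
mean and the mode of a Gaussian fitted to the diameter histogram
(least-squares on histogram counts, falling back to the mean for small
samples).

**Known estimator bias.** The member-cell-area definition makes measured
cluster sizes systematically larger than the underlying domain: boundary
members' cells extend roughly halfway to the nearest background molecule,
and the first-rank smoothing of δ¹ᵢ recruits an edge ring. On synthetic
fields with 80-nm domains at the default densities, the measured mean
diameter is ≈110 nm even when segmenting noise-free ground-truth
positions, and ≈130 nm after the full merge pipeline at σ = 20 nm.
Percent of molecules in domains and domain density are much less affected
(within ≈10% and ≈5% respectively). Measured diameters should therefore
be read as method-referenced sizes, comparable across conditions analysed
with identical parameters, not as physical domain diameters.

## Trajectories and diffusion (`nanotess.tracking`)

Linking is greedy nearest-neighbour per frame transition: candidate pairs
within `max_disp` are assigned one-to-one in ascending distance order
(deterministic tie-breaks), unmatched detections found new tracks, and no
gap closing is done at the default `max_gap=0`. The time-averaged MSD
uses overlapping windows, lags up to half the trajectory span, and pair
counts length−n. Diffusion coefficients come from OLS on the first 4
lags of MSD(t) = 4·D·t + b with a free intercept (the intercept absorbs
the localization-noise offset ≈ 4σ²); D is clipped at 10⁻⁵ µm²/s only for
log₁₀ representation. Mobility summaries use trajectories strictly longer
than 15 points (20 for maps), report the log₁₀ D histogram, the per-cell
peak as the mean of a normal fit to log₁₀ D, and the lag-wise mean
ensemble MSD. For corral-confined motion the ensemble MSD plateaus at
R², the mean squared distance of two independent uniform points in a disk
of radius R.

## Confocal statistics (`nanotess.profiles`)

SCI = mean of the top 5% / mean of the bottom 5% of a ≥20-sample line
profile (nominally 10 µm), with k = max(1, round(0.05·n)) samples per
slice; it is scale-invariant and equals 1 for a homogeneous membrane, and
it is undefined (error) when the bottom mean is zero, which signals
background-subtracted input. ROI means average pixels whose centres fall
in a 5×5 µm square that must lie fully inside the image. The red/green
ratio (RGM) of di-4-ANEPPDHQ is the per-pixel mean of red/green over the
pixels whose reference-channel intensity reaches the (100−p)th percentile
for p ∈ {100, 10, 5, 2}; masks are nested by construction and the ratio
is invariant under common rescaling of the two channels.

## Monolayer insertion (`nanotess.monolayer`)

Δπ_max versus πᵢ series from Langmuir-trough adsorption experiments are
fitted by OLS; MIP = −intercept/slope (the extrapolated pressure of zero
insertion) and synergy = 1 + slope (the convention of the tensiometry
literature for this assay). A series whose Δπ_max never reaches a
significance floor (default 1 mN/m, configurable) is classified
non-penetrating instead of fitted; a non-negative slope is an error.
Uncertainty on MIP is a pairs-resampling bootstrap 95% percentile
interval. Monte-Carlo calibration at n = 20 points shows the interval
covers the true MIP in ≈89–90% of replicates (slight undercoverage,
insensitive to the noise scale, the resample count and to BCa
correction); the interval should be read as approximate.

## Synthetic generator (`nanotess.simulate`)

The SMLM generator places background molecules as a homogeneous Poisson
process and in-domain molecules uniformly in non-overlapping disks, gives
each molecule 1 + Geometric(p) bursts with geometric on/off times, a
uniform activation frame, and adds isotropic Gaussian localization error
per detection. Defaults define the simulated study conditions: 5×5 µm
field, 200 background molecules/µm² with 37% of molecules in domains
(total ≈317 µm⁻², of the order of a printed per-cell molecule count of
~3×10⁵ spread over a ~10³ µm² epidermal-cell footprint), 2 domains/µm² of
diameter 80 nm, σ = 20 nm, 20,000 frames, p = 0.3 (mean 1.43 blinks, close
to a measured 1.42), mean on-time 3 frames and off-time 5 frames (typical
mEos-scale conventions; real on/off means for any given system should be
measured and substituted). The resulting per-frame active density is
≈0.5 µm⁻², the regime the ω = 48 nm merge assumes.

What the generator does *not* emulate: camera/PSF rendering, detection
misses and false positives, drift, anisotropic precision,
intensity-dependent precision, dye photobleaching gradients, domain size
or occupancy dispersion, and correlated motion during bursts (molecule
positions are static in the SMLM generator; mobility is simulated
separately as free or corral-confined Brownian motion with per-axis step
variance 2DΔt and radial reflection at the corral). Passing recovery
tests therefore demonstrate correctness of the estimators under the
model's assumptions, not robustness to every artefact of real
acquisitions.

Trajectory, line-profile and two-channel image generators are documented
in their docstrings; all generators are bit-deterministic given the
config including its seed.

## Problem sizes

Default test and reporting runs use: 10 (tests) or 5 (report script)
simulated membranes of ~8,000 molecules / ~34,000 detections each for
nanodomain recovery; 1,000 × 30-step trajectories for diffusion recovery;
400 × 60-step confined trajectories for the MSD plateau; 100 paired
profiles for SCI; 50 random ≤30-point instances for the geometry oracle.
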