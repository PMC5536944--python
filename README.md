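# nanotess

Quantification of plasma-membrane protein **nanodomains** from
single-molecule localization microscopy, single-particle tracking,
confocal imaging and Langmuir-monolayer tensiometry.

Membrane proteins such as plant REMORINs organize into ~80-nm lateral
domains of the plasma membrane. Measuring that organization from sptPALM
data requires a chain of careful statistics, each of which this package
implements as a tested, reusable library with a thin CLI:

* **Blinking correction** — detections within a search radius ω (48 nm
  default) and blinking tolerance τ are merged into molecules at the
  barycentre of their bursts; on/off-time and blinks-per-molecule
  distributions and a burst-count consistency check validate the merge.
* **Voronoï nanodomain segmentation** — molecules with first-rank local
  density δ¹ᵢ > 2·δ_N (δ¹ᵢ from the cell + edge-neighbour areas, δ_N the
  region average) form clusters, filtered at ≥5 localizations and
  ≥32 nm²; outputs diameter, % PM surface, % molecules in domains and
  domain density.
* **Mobility** — greedy nearest-neighbour trajectory linking,
  time-averaged MSD, per-trajectory D from MSD(t) = 4Dt + b over the
  first 4 lags, log₁₀D distributions with per-cell normal-fit peaks, and
  ensemble MSD (plateau → R² under corral confinement).
* **Confocal statistics** — Spatial Clustering Index (mean of top 5% /
  mean of bottom 5% of a 10-µm line profile), 5×5 µm ROI means, and the
  di-4-ANEPPDHQ red/green membrane-order ratio over brightest-pixel masks
  (global/10/5/2%).
* **Monolayer insertion** — OLS of Δπ_max vs πᵢ giving the maximal
  insertion pressure MIP = −intercept/slope and synergy factor 1 + slope,
  with a pairs-bootstrap CI.
* **Synthetic data** — a generator with exact ground-truth bookkeeping
  (clustered molecule positions, geometric blinking photophysics,
  Gaussian localization error, Brownian/confined trajectories, clustered
  line profiles and ratio images) so every stage is testable without raw
  microscopy data.

## Worked example

```python
import nanotess as nt

# simulate a 5x5 µm membrane patch: 80-nm domains (2/µm²) holding 37% of
# ~8000 molecules, mEos-like blinking, 20-nm localization precision
gt, locs = nt.simulate_smlm(nt.SmlmSimConfig(seed=1))

mols = nt.merge_molecules(locs, nt.MergeParams(omega=48.0, tau=11))
summary = nt.summarize_photophysics(mols)
print(f"{len(locs)} localizations -> {len(mols)} molecules, "
      f"mean blinks {summary.mean_blinks:.2f}")

vmap = nt.build_voronoi(mols)
clusters = nt.segment_clusters(vmap, nt.local_density(vmap))
stats = nt.nanodomain_stats(clusters, vmap)
print(f"{stats.n_clusters} nanodomains, mean diameter "
      f"{stats.mean_diameter_nm:.0f} nm, {stats.pct_molecules:.0f}% of "
      f"molecules, {stats.density_per_um2:.1f} domains/µm²")
```

```
33407 localizations -> 11524 molecules, mean blinks 1.37
60 nanodomains, mean diameter 124 nm, 33% of molecules, 2.4 domains/µm²
```

The merge collapses ~34k raw detections to ~12k molecule estimates with
the expected ~1.4 bursts per molecule. Segmentation recovers the
simulated domain density (2/µm², here 2.4 on a single field; the 10-seed
average in the test suite is within ~5%) and occupancy (37%, here 33%);
the
measured mean diameter exceeds the simulated 80 nm because cluster area
sums member Voronoï cells, whose boundary cells extend into the
background — a known property of the estimator (see `docs/methods.md`),
which is why diameters are comparable across conditions but are not
deconvolved physical sizes.

The same stages are scriptable from a shell: `nanotess simulate`,
`nanotess clean`, `nanotess cluster`, `nanotess track`, `nanotess sci`,
`nanotess rgm`, `nanotess mip` (see `--help` of each).

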