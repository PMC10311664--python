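# Methods

Conventions: lengths in Å, times in ns, masses in amu, diffusion in Å²/ns
(1 Å²/ns = 10⁻⁵ cm²/s). All generators take explicit integer seeds and are
bit-reproducible.

## Composition design

A particle of diameter *d* (default 400 Å) and mean density 1.025 g/cm³
(seawater; the package must assume a density to set the absolute mass scale)
has total mass `M = ρ · πd³/6`. The builder allocates this mass in a fixed
order:

1. **Water** is pinned to 0.51 of total mass; the water count is
   `0.51·M / 18.02` rounded to an integer. The aqueous volume is taken as
   30 Å³ per water molecule.
2. **Ions** are set from target molarities over that aqueous volume:
   0.4 M NaCl in all systems; systems B and C add 110 mM Mg²⁺, 25 mM Ca²⁺
   and 20 mM K⁺. Cl⁻ is set last so that the particle is exactly
   electroneutral.
3. **Organics** absorb the remaining mass (≈ 0.47–0.48 of total). The
   internal split by system:
   * **A** — fatty acids 93% (lauric:myristic:palmitic:stearic in the mole
     ratio 1:2:4:3), lipase (BCL, 33 kDa) 3%, and a 4% remainder carried as
     an explicitly labelled unresolved organic component (glucose-like
     soluble monomer). The remainder exists because the stated FA and lipase
     shares do not close the budget and most sea-spray organic matter is
     uncharacterized; keeping it explicit preserves both stated shares.
   * **B** — fatty acids 80%, BCL 3%, lipopolysaccharide (LPS, 10 kDa) 17%.
   * **C** — fatty acids 63%, BCL 3%, LPS 17%, glucose 10%, laminarin
     (5 kDa) 7%.

Real-valued counts are converted to integers by largest-remainder rounding
(preserves the total), with at least one molecule per listed component. If
the achieved share of any component deviates from its target by more than a
tolerance (default 0.01 of organic mass, as happens when a large molecule
cannot fit the budget at small diameters), the builder raises a
`CompositionError` naming the offender rather than silently rebalancing.

## Synthetic structures

* **Packed particle**: molecule centres are sampled uniformly in the sphere
  (rejection sampling on the cube). Fatty acids are 2-bead head–tail rods of
  length 12 Å with random orientation; macromolecules (BCL 12 beads, LPS 8,
  laminarin 4) are random-walk chains of 5 Å steps started at their centre.
* **Raft fixture**: `n_patches` sunflower-disc monolayer patches placed on a
  sphere (default radius 150 Å) at mutually separated sites, lipid midpoints
  on the sphere, tails pointing outward (at zero tilt the orientation vector
  equals the outward normal; a `patch_tilt` rotates it). Optionally a core
  aggregate of lipids with a common orientation inside the particle, plus
  uniform water filler. True labels, the surface mask and patch centres are
  returned for exact validation.
* **Brownian water**: an overdamped random walk. At each step a water in the
  radial band `(r_lo, r_hi)` takes a Gaussian displacement with per-axis
  variance `2 D(r) Δt`, using the band it occupied at the step start, and
  reflects off the bounding sphere radially. Displacements are applied to
  absolute coordinates, so zero-D walkers are exactly static.

## Shape descriptors

With bead masses `m_i` and centre-of-mass-relative positions `r_i`, the
gyration tensor is `S = Σ m_i r_i r_iᵀ / Σ m_i`. For eigenvalues
λ₁ ≥ λ₂ ≥ λ₃:

* asphericity `φ = λ₁ − (λ₂ + λ₃)/2` (Å²; 0 for isotropic bodies),
* relative shape anisotropy
  `κ² = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₃λ₁)/(λ₁+λ₂+λ₃)²` ∈ [0, 1]
  (0 isotropic — including the regular tetrahedron, 1 collinear). The
  implementation evaluates the equivalent form `3/2·Σλ²/(Σλ)² − 1/2` as an
  internal cross-check to 10⁻¹².

## Raft clustering

Each fatty acid contributes a 6-D feature `[x, y, z, w·v]` where (x, y, z)
is the rod midpoint, `v = (tail − head)/|tail − head|`, and the orientation
weight `w` (default 10 Å) converts orientation mismatch to distance —
antiparallel neighbours are 2w apart. DBSCAN (scikit-learn) with Euclidean
eps = 12 Å and min_samples = 5 labels rafts; label −1 means unclustered.
Kinetics run the clustering per frame and greedily match labels across
frames by maximal member overlap. **Surface rafts** are clusters whose mean
ellipsoidal coordinate exceeds (2/3)^(1/3) (the outer equal-volume shell)
and whose mean lipid orientation · outward normal exceeds 0.5.

## Ellipsoidal partitioning

The particle body is the minimum-volume enclosing ellipsoid (MVEE) of its
convex hull vertices (scipy `ConvexHull`), computed by Khachiyan's
barycentric coordinate-ascent with tolerance 10⁻³. The fitted centre c,
rotation R and semi-axes (a, b, c) define the dimensionless coordinate
`u(p) = |diag(1/a,1/b,1/c)·Rᵀ·(p − c)|`. Concentric similar ellipsoids at
scales `s_k = (k/N)^(1/3)` split the body into N shells of exactly equal
volume; N = 3 gives core/bulk/surface. Beads with u > 1 count as surface.
Per-class mass percentages across regions (rows summing to 100%) plus an
aggregate organic row form the partition table. An optional robust
pre-filter drops stray beads beyond 1.5× the 90th-percentile radius before
fitting so evaporated waters do not inflate the hull.

## Water transport

The trajectory tail is cut into consecutive slices. By default each slice
contributes one MSD curve from its first frame as the single time origin
(independent slices); `multi_origin=True` averages over every origin within
a slice. The diffusion coefficient is the Einstein-relation slope,
`D = slope/6`, from an OLS fit over a window that by default spans 10–80% of
the curve (falling back to the whole curve for very short slices); slope
standard error, intercept and R² are reported. The radial profile bins
waters into spherical shells by their radius at each slice start and keeps
that membership for the slice, so shell crossings do not mix estimates;
shells empty in every slice report a missing value rather than zero.

## Surface morphology

The surface is the fitted ellipsoid; its area uses Thomsen's approximation
(p = 1.6075). With an area per lipid `a_lipid = 21 Å²` (condensed saturated
monolayer), `N_sites = A/a_lipid`;
`coverage% = 100 · n_surface · a_lipid / A`, and the surface excess is
lipid count / N_sites — *predicted* from all fatty acids, *measured* from
raft-resident ones, making `coverage% = 100 · measured excess` an exact
identity. Raft curvature is the analytic mean curvature of the implicit
ellipsoid surface evaluated at each member's radial footpoint
(`H = (|∇F|²·tr Hess F − ∇F·Hess F·∇F)/(2|∇F|³)`; sphere → 1/R, prolate
pole → a/b²), averaged per raft and combined weighted by raft size.
Atmospheric exposure of a molecule is the fraction of frames in which any of
its beads lies within `d_exp = 3 Å` of the surface along its own radial ray
(`u ≥ 1 − d_exp/R_dir`).

## I/O and pipeline

MDAnalysis handles PDB/GRO/XYZ coordinates and DCD/XTC trajectories.
Component classes are encoded as residue names (FAT/PRO/LPS/SAC/SOL/ION) and
surfactant head/tail beads as atom names HD/TL; third-party files bind
through a YAML *component map* (residue → class, head/tail atom names,
optional per-bead masses). Times convert ps ↔ ns at the boundary.

The pipeline runs generate → shape → cluster → partition → diffuse → surface
from one config; the single seed is fanned out to the generators via
`numpy.random.SeedSequence` (children reduced mod 2³¹). A failing stage
raises a `StageError` naming the stage and listing completed ones; the CLI
maps config errors to exit code 2 and stage errors to 3. Report output
(JSON + CSV) is deterministic: identical runs give byte-identical files.
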