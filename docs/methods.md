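# Methods

`platedot` models a high-density parallel-plate continuous-wave (CW) diffuse
optical tomography (DOT) system for transmission breast imaging and
implements *data self-calibration*: replacing the physical homogeneous
reference phantom scan by a virtual reference constructed from the task scan
itself.

## Physical model

Photon transport in the compressed breast (a 44 mm slab between a source
plate and a detector plate) is described by the CW diffusion equation with a
Robin (partial-current) boundary condition:

    -div(kappa grad Phi) + mu_a Phi = q0        in the slab
    Phi + 2 kappa zeta (n . grad Phi) = 0       on the surface

with diffusion coefficient `kappa = 1/(3 (mu_a + mu_s'))` (mm), internal
reflection factor `zeta = (1 + R_f)/(1 - R_f)`, and `R_f` from the Groenhuis
polynomial fit to the refractive index (default n = 1.33, giving
R_f ≈ 0.47). The speed of light is set to 1: every quantity the pipeline
computes is a ratio of CW amplitudes, in which it cancels.

Sources are isotropic point emitters buried one transport mean free path
(1/mu_s') beneath their surface positions. Detectors read the photon density
at the mirrored interior point divided by 2·zeta (the boundary flux implied
by the Robin condition). Using the same interior coupling functional on both
sides makes transmission amplitudes exactly reciprocal under
source–detector exchange, which the test suite asserts to 1e-10 even for
heterogeneous media. The absolute coupling constant is arbitrary — the
calibration algebra cancels it.

## Discretization

The slab is meshed as a structured lattice with trilinear hexahedral (Q1)
elements; element matrices are Kronecker products of 1D stiffness/mass
matrices, so assembly is exact and cheap. Hexahedra were chosen over a
tetrahedral subdivision deliberately: splitting each cell into six
tetrahedra along a common diagonal introduces a directional bias of several
percent between source–detector pairs that are mirror images of each other,
which directly contaminates the within-distance-class statistics this method
lives on. The Q1 operator has the full reflection symmetry of the lattice.

Two kinds of lattice planes are snapped into the mesh: planes at depth
1/mu_s' under both plates (so point loads land on nodes) and planes at the
optode y/z coordinates (so every source and detector couples to the lattice
identically). With these, the forward solution agrees with the classical
extrapolated-boundary image-source series for an infinite homogeneous slab
to within 2.2% at the default 3 mm cell size (1.0% at 2.5 mm) on pairs at
least two grid pitches from the lateral walls; pairs near the walls
genuinely differ from the infinite-slab solution, which is precisely the
boundary effect the coefficient-of-variation selection targets.

The FEM system (stiffness + absorption mass + Robin boundary mass) is
symmetric positive definite; one sparse LU factorization per absorption
update serves all sources and adjoint sources. Meshes are kept below ~40k
nodes; the default generation and reconstruction meshes use 3 mm cells
(~24k nodes), matching the mesh density of the classical 22k-node
discretization of this geometry.

## Probe geometry and distance classes

Sources form an `n_rows x n_cols` grid (13 mm row pitch, 14 mm column
pitch); each detector sits at the mirror position across the slab. All
I x J source–detector (SD) pairs are enumerated; pairs are grouped into
*distance classes* by their Euclidean separation, keyed by the squared
distance rounded to 1e-6 mm² (exact for these integer-pitch grids). The
full 7x8 system yields 3136 pairs in 56 classes; the 3x4 simulation layout
yields 144 pairs in 12 classes.

Exclusion rules applied before calibration: pairs with an endpoint not
covered by the imaged object, and pairs farther apart than 110 mm (the
dynamic-range limit of transmission measurements). A further *non-boundary
selection* iteratively peels the outermost ring of the source/detector grids
until every class with at least two members has a coefficient of variation
(std/mean) at or below 0.3 — boundary-adjacent pairs see systematically
different flux than central pairs at the same separation and would corrupt
the class maxima. The CoV is computed on whatever measurement set is
supplied (task data in a clinical setting); the selection report records the
data role and the per-iteration CoV profile.

## Calibration

With `task`, `reference` (homogeneous phantom scan) and `predicted` (forward
model of the homogeneous background) sets aligned on the retained pairs:

* reference calibration: `calibrated = task / reference * predicted`.
  Per-channel multiplicative gains applied to both scans cancel exactly.
* virtual reference: within each distance class the *maximum* task amplitude
  is the measurement least affected by localized absorbers; every member of
  the class receives that maximum. The result is the pointwise-smallest
  class-constant set dominating the task, and building it twice is
  idempotent.
* self-calibration: `calibrated = task / estimated * predicted` with the
  virtual reference in the denominator. A global scale on the task cancels;
  calibrated amplitudes never exceed the prediction.

Virtual-reference fidelity is measured as the mean over retained pairs of
`|estimated - reference| / reference` (also reported per class). Amplitudes
at or below 1e-30 in any denominator raise an explicit division-hazard error
naming the pair.

The method assumes the absorbing heterogeneity is small relative to the
homogeneous bulk, so that each class contains at least one nearly
unaffected pair. It degrades when targets are large, when classes are
sparsely populated, or when boundary pairs contaminate the class spread —
all three behaviours are exercised in the test suite.

## Reconstruction

Nodal absorption is recovered by damped Gauss–Newton iterations on
log-amplitude (Rytov-style) residuals; CW transmission spans decades across
44–110 mm separations, and the log transform makes the residual scale-free.
Each iteration solves

    (J^T J + lambda * max(diag(J^T J)) I) delta = J^T r

via the exact measurement-space dual (pairs number in the hundreds, nodes in
the tens of thousands), updates `mu_a` (floored at 1e-5 mm^-1), re-solves
the forward model, and by default rebuilds the Jacobian. The default
settings are lambda = 10 (dimensionless; the `max(diag(J^T J))` scaling
keeps it meaningful across mesh resolutions) and 6 iterations. If the data
residual rises in two consecutive iterations the loop stops early with a
warning rather than failing. mu_s' stays frozen at background.

The Jacobian rows are `d ln(amp) / d mu_a(node)`, assembled by the adjoint
method from the source field and the reciprocal detector field; both the
absorption mass term and the mu_a-dependence of kappa are included, so J is
the exact derivative of the discrete forward operator (finite-difference
agreement to ~0.01%, asserted at 10%). All entries are non-positive.

Image metrics: per-target FWHM of the absorption profile along y through the
target centres (0.5 mm sampling, background = median outside the two target
spans, half-max crossings linearly interpolated) and the two-target contrast
ratio (maximum nodal mu_a in each half of the domain split at the
inter-target midplane). Reported FWHM depends on mesh resolution through the
regularized update: 18.9 / 15.6 / 13.5 mm at 4 / 3.5 / 3 mm cells for the
default phantom; the 3 mm default matches the reference mesh density.

## Spectral unmixing

Multi-wavelength absorption maps are unmixed per node into Hb and HbO2 by
non-negative least squares against a shipped extinction table (compiled
literature molar extinction values at 660/750/840 nm, converted to mm^-1 per
µM; the table is configuration and can be extended with water/lipid
columns). Derived maps: HbT = Hb + HbO2 and StO2 = HbO2/HbT (masked where
HbT = 0). Tumor-to-background contrast is the ratio of region means; the
default tumor region is the set of nodes above half of (max − background) of
HbT with background taken as the median.

## Synthetic data

The generator reproduces the study conditions: a 44 x 130 x 79 mm slab
(x = through-plate axis; the same box is often quoted as 79 x 130 x 44 in
(z, y, x) order), background mu_a = 0.004 mm^-1, mu_s' = 1 mm^-1, g = 0.9,
n = 1.33; two cylindrical targets (R = 7.5 mm, height 10 mm, axis along x)
centred at (17, 45, 42) and (17, 85, 42) mm with mu_a = 0.012 mm^-1 (3x
background); mirrored 3x4 grids centred on the slab face, 44 mm plate
separation. Presets cover the position sweep (three alternative placements
keeping target geometry and 40 mm separation: shifted toward a lateral wall,
shifted along the rows, rotated onto the column axis), the size sweep
(R = 5 / 7.5 / 10 mm), the contrast sweep (2x / 4x) and the full 7x8 layout.

Sessions are corrupted by a channel-gain model: a global scale, log-normal
per-source and per-detector gains (log-sd 0.05 by default when enabled) and
optional multiplicative noise; one realization is applied to both the task
and reference scans of a session, mirroring a single hardware state.
Everything is reproducible from one seed.

Two generators exist. The default is the diffusion FEM forward model (fast,
deterministic). The physics cross-check is a weighted-photon voxel Monte
Carlo on a 1 mm voxelization: Henyey–Greenstein scattering with
mu_s = mu_s'/(1-g), continuous absorption, unpolarized Fresnel
reflection/transmission with total internal reflection at all faces,
Russian roulette below weight 1e-4, cone sources (120° full divergence) and
circular detector apertures (1.5 mm diameter). Energy bookkeeping is exact:
launched + roulette-created = absorbed + transmitted + reflected +
side-escaped + roulette-killed, to float precision. Desk-scale budgets
(1e5–1e6 photons) give per-pair relative standard errors of 5–30%, so MC is
compared to diffusion theory via class-pooled ratios within stated standard
errors, not pairwise. Tests run the MC with g = 0 (same reduced scattering)
where only diffusion-level physics is at stake, because the isotropic walk
needs ~10x fewer steps.

What the synthetic data does *not* emulate: the parabolic breast contour
(the bounding slab plus coverage masks stand in for it), wavelength-dependent
background optics (each wavelength is simulated with the same properties
unless the phantom spec says otherwise), detector shot noise floors, and
inter-scan gain drift. Passing tests therefore demonstrate the calibration
algebra, the estimator's geometry dependence and the reconstruction
machinery — not robustness to every clinical artifact.

## Numerical choices

* Distance grouping tolerance 1e-6 mm² on the squared distance; exact for
  integer-mm pitches, safe to coordinate jitter below ~1e-7 mm.
* Analytic slab series truncated when a full image-pair term falls below
  1e-12 of the running sum.
* Calibration denominator floor 1e-30 (explicit error instead of huge
  ratios).
* Reconstruction mu_a floor 1e-5 mm^-1; Gauss–Newton stops early after two
  consecutive residual increases.
* Ring peeling shrinks any grid dimension with at least 3 active rows/cols;
  when nothing can shrink and a class still violates the CoV threshold, a
  selection-failure error carries the full CoV history.
* Sparse LU (`scipy.sparse.linalg.splu`) on the SPD system; meshes are kept
  under ~40k nodes, which bounds factorization memory.

## Known limitations

* Only mu_a is reconstructed; mu_s' is frozen at background.
* Absolute recovered mu_a is regularization-limited (roughly 20% of the true
  contrast at the default settings, peaks ≈ 0.0055 mm^-1 against a true
  0.012 mm^-1); peak *ratios*, positions and widths are the quantitative
  outputs.
* The virtual-reference error grows monotonically with target radius here
  (2.5% / 4.1% / 6.4% at R = 5 / 7.5 / 10 mm with the deterministic
  generator): a larger absorber shadows some class maxima entirely. Reports
  of this experiment measured with a noisy billion-photon Monte Carlo quote
  a non-monotone radius dependence; the two observations are not
  reconcilable under a deterministic generator, and the monotone behaviour
  is the one this package asserts.
* The probe grids must be planar and mirrored; ring or hemispherical arrays
  are out of scope, as are frequency- and time-domain measurements.
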