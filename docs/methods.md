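# Methods

This note documents the models implemented in `oaphantom`, the parameters
that matter, the numerical choices, and what the synthetic fixtures do and
do not capture.

## Anatomical model

### Label volumes

Phantoms live on a uniform Cartesian grid of unsigned 8-bit tissue codes
(water background, fat, skin, glandular, nipple, muscle, ligament, TDLU,
duct, artery, vein, VTC, necrotic core, PA). Axis 0 runs from the chest
wall to the nipple; the polar angle θ of a vessel entry is measured in the
chest-wall plane from the superior direction. The default voxel size is
0.125 mm — fine enough that typical 0.2–0.5 mm reconstruction grids do not
commit an inverse crime — but every operation accepts coarser grids, and
the test suite and validation studies run at 0.25–1 mm to stay desk-scale.

### Shape sampling

Size/shape parameters are drawn per BI-RADS type from truncated Gaussians
(the maximum-entropy distribution on a bounded interval with given mean and
standard deviation). The superior extent a1t uses TN(59.70, 3.58, 50.77,
71.5) mm for types A/B and TN(50.05, 3.58, 42.9, 57.2) mm for C and D;
the remaining extents are ratio-linked to a1t (a1b/a1t ~ N(1, 0.02),
a2r/a1t ~ N(1, 0.05), a2l/a2r ~ N(1, 0.05), a3/a1t truncated around 0.85),
and four small coefficients (B0, B1, H0, H1) modulate the silhouette
azimuthally. Truncated-normal draws use inverse-CDF sampling, which is
exact and cheap for the mild truncations used here.

### Fixture anatomy

The built-in generator is a deliberately simple parametric stand-in for a
full recursive-partition anatomy engine: a half-superellipsoid with a
closed skin shell (default 1.5 mm), a nipple cap at the apex, a glandular
compartment carved from a smoothed random field biased toward the central
axis and thresholded at the quantile matching the type's density fraction
(6 / 16 / 35 / 55 % for A–D), thin radial ligament septa, and scattered
TDLU clusters with short ducts pointing at the nipple that serve as lesion
candidate sites. It reproduces the tissue inventory, topology (closed skin
shell, interior candidate pool), and volume statistics that the property
modules depend on; it does not reproduce glandular microarchitecture,
Cooper-ligament geometry, or surface texture, so tests passing on fixtures
say nothing about those features of real anatomies. Externally produced
label volumes can be read instead (raw uint8 + JSON sidecar in x-fastest
order, or NIfTI); volumes containing chest muscle must be cropped before
property assignment, since muscle has no property model here.

### Interior vessel trees

Fourteen trees (7 arteries, 7 veins across five anatomical vessel groups)
start at chest-wall entry points given by (θ, d_edge): the root sits on the
ray at angle θ from the silhouette centroid, d_edge mm inside the breast
edge (2 mm for all groups except the intercostals at 24 mm). Growth is a
rejection-sampled random-walk branching model: branches are chains of
capsule segments with direction jitter (cone angle 0.6 rad) and length
proportional to the current radius (factor 4); the root radius is 0.6 mm;
each child's starting radius is U(0.85, 1) times its parent's end radius;
growth stops at 500 branches, when the radius falls below 0.15 mm, when
retry budgets (50 per segment, 1000 per tree) are exhausted, or when the
tree's share of the vascular volume budget is spent. The budget —
0.34 % of breast volume split across trees — is the model's central
calibration: vascular volume scales with the perfused tissue volume, which
keeps the blood-vessel volume percentage stable across breast sizes, and
its value was fixed once so that 20-phantom ensembles with default
parameters reproduce the clinically estimated median vessel-volume
percentage (≈ 0.44 %). Segment placement never overwrites skin, nipple, or
background, and the grown tree graph is retained in metadata for
inspection.

Segment-level growth rules of the original anatomy engines are not public;
this grower reproduces their parameter vocabulary and ensemble statistics,
not their geometry.

### Sub-skin vasculature

Superficial vessels are synthesized by image-processing primitives:

1. uniform random matrix over the chest-wall plane;
2. difference of Gaussian blurs at σ1 = 3.875 mm and σ2 = 6.125 mm
   (band-pass; the two scales set the branch spacing);
3. Otsu binarization (full 256-bin histogram) and 2D skeletonization;
4. replication along the depth axis into a sheet volume;
5. shell = breast-without-skin mask XOR its erosion to the target depth
   (0.375 mm = three single-voxel erosions at 0.125 mm voxels);
6. intersection of sheet and shell — the literal symmetric difference of
   the two sets does not produce curves on the dome, so the geometric
   intent is realized as intersection, with a strict-XOR mode retained for
   fidelity experiments;
7. 3D skeletonization, Gaussian blur at σ3 = 0.219 mm, Otsu binarization,
   restriction to the breast interior;
8. connected components ordered by the azimuthal angle of their centroids
   and labeled alternately artery / vein (deterministic and
   location-dependent; counts need not be even).

Two geometric facts about the defaults deserve note. First, a tube of
nonzero diameter cannot lie strictly inside a 0.375 mm shell, so depth is a
property of the **centerlines**: the skeleton of the final vessel mask lies
in the erosion shell (tests allow one voxel for discretization), while the
inflated tube necessarily extends inward. Second, Otsu binarization of a
blurred 1-voxel centerline cuts close to half maximum, so the emergent
tube diameter is near the blur's FWHM, 2.355·σ3 ≈ 0.52 mm, measured as
twice the mean distance-transform value at skeleton voxels (clipping at
the skin interface biases this measure slightly further down). The
σ3 ↦ diameter mapping is therefore implementation-dependent; the achieved
diameter is reported as computed.

## Lesion model

The viable-tumor-cell mask is a thresholded smoothed radial random field
plus thin radial spicules, rescaled (iteratively, with fixed noise draws)
so its maximum Feret extent matches the requested diameter within a few
percent; irregularity 0 gives an exact voxelized sphere. Necrotic core and
PA shell come from erosion / dilation with spherical structuring elements
of 0.75 mm and 5 mm radius, realized exactly through Euclidean distance
transforms (core = interior distance > 0.75 mm; PA = exterior distance
≤ 5 mm). Lesions smaller than the erosion element get an empty core and
stay all-VTC. Insertion sites are sampled from TDLU/duct voxels (the
biological origin sites of common carcinomas) subject to a clearance test:
the lesion's bounding ball must avoid skin, nipple, muscle, background,
and previously placed lesions; larger lesions are placed first. On
insertion, lesion codes overwrite only fat/glandular/ligament/TDLU/duct,
and each PA voxel records its pre-insertion tissue code in a parallel map
(a single 8-bit label cannot encode "PA over glandular" vs "PA over fat",
and the optical/acoustic inheritance rules need the distinction).

## Functional properties

One draw per tissue per phantom from the embedded distribution table, with
exact ties and complements: glandular shares fat's f_b and f_w; fat's f_f
is the complement to 100 %; the nipple's f_f completes its budget; the
vein's f_b equals the artery's (100 %); the necrotic core shares the VTC's
s, f_w, f_f with f_b = 0; the PA shell shares the VTC's f_w and f_f. Fixed
values: skin s = 98.9 %, f_b = 0.39 %; nipple s = 71.28 %, f_b = 1.35 %.
c_tHb,blood ~ U(1860, 2325) μM corresponds to a normal female hematocrit.
The chromophore budget f_b + f_w + f_f + f_m ≤ 100 % holds by
construction; a guard resamples (bounded retries) if a user-supplied table
produces negative complements. Background water voxels carry f_w = 100 %
so the imaging bowl is optically water.

### Diffusion–reaction smoothing

Oxygen saturation: indicators on skin, artery, vein, and lesion
(VTC ∪ core); fat-group, glandular, and PA voxels take the PDE solution;
the nipple's fixed value is painted outside the solve (the indicator set
omits it). Blood volume fraction: indicators on VTC, core, fat-group,
glandular, artery, and vein; the PA shell is indicator-free so f_b
interpolates smoothly between the lesion and surrounding-tissue targets —
the model of capillaries too fine to resolve at 0.125 mm. Skin and nipple
f_b are piecewise constants outside the solve.

Numerics: 7-point finite-difference Laplacian restricted to the breast
interior; zero-flux boundaries arise by dropping exterior links; the
system is symmetric positive definite when every connected component holds
an indicator voxel (checked; violations raise). Solved by conjugate
gradients to 1e-8 relative residual with a direct-solve fallback;
equivalence with a dense solve is tested on small grids, and the discrete
maximum principle (min target ≤ u ≤ max target) is asserted. The
smoothness parameter μ has units mm² and sets the transition length √μ;
it is not prescribed by the underlying physiology model, so the default
μ = 4 mm² (≈ 2 mm transitions) was chosen as a plausible oxygen-diffusion
scale and is exposed in the configuration. Indicator voxels receive their
targets exactly in the final maps.

## Optical properties

Absorption: μ_a(r, λ) = Σᵢ fᵢ(r)·μ_{a,i}(λ) over oxygenated blood,
deoxygenated blood, water, fat, melanosome, with
μ_{a,oxy/deoxy} = ln(10)·c_tHb·ε_{HbO₂/Hb}(λ), fractions converted from
percent and c_tHb from μM to M. The embedded spectra are compact 25-nm
digitizations of the standard tissue-optics compilations (hemoglobin
extinction, water and lipid absorption, the melanosome power law
μ_a ≈ 1.7·10¹¹·λ^−3.48 mm⁻¹), linearly interpolated and restricted to
700–1100 nm; absolute values of such digitizations differ by a few percent
between sources, so the table is swappable. Near 800 nm the embedded
oxy/deoxy extinctions differ by ≈ 7 %, consistent with the isosbestic
point sitting just below 800 nm.

Scattering: μ_s = μ_s′(λ_ref)/(1−g)·(λ/500 nm)^−b. Tissues with literature
intervals (skin/nipple, vessels, VTC/core) draw (μ_s′, b) from one shared
uniform variate per tissue per phantom — the two parameters are positively
correlated in measured data, and a common variate preserves rank
correlation 1; single-valued tissues (fat-group 0.83/0.617, glandular
1.06/0.52) are deterministic. g and n are piecewise constant per tissue
and wavelength-independent over the NIR window. Water's power-law pair is
fitted at import from an embedded synthetic reference table following the
λ^−4.3 molecular-scattering law (magnitudes ≤ 1e-5 mm⁻¹ — negligible, but
the background stays well-defined). PA voxels inherit μ_s, g, n from their
recorded underlying tissue while their μ_a follows their own functional
values.

## Acoustic properties

Per-tissue-per-phantom draws of sound speed (mm/μs), density (g/mm³), and
attenuation α₀ (dB/MHz^y·mm); the distributions model inter-subject
variability, not intra-tissue texture, so all voxels of a tissue share one
value. Water is fixed at its 37 °C values (1.521, 0.993·10⁻³, 2.2·10⁻⁴);
artery/vein α₀ is fixed at 0.021; the necrotic core shares the VTC row;
PA inherits its underlying tissue. The attenuation exponent y is a
homogeneous per-phantom scalar by breast type (1.1151, 1.1642, 1.2563,
1.3635 for A–D) because common time-domain wave solvers do not support
spatially varying y.

## Validation metrics

Vessel volume percentage = 100 × (artery + vein voxels) / breast voxels.
The ensemble study generates hemispherical phantoms (radii drawn from the
a1t distribution, cycling breast types) with default tree and sub-skin
parameters at 0.5 mm voxels — 20 phantoms run in about two minutes on one
CPU — and summarizes with linear-interpolation quantiles.

Effective attenuation is computed phantom-side with the diffusion-theory
closed form μ_eff = √(3 μ_a (μ_a + μ_s′)), μ_s′ = μ_s (1−g), averaged over
breast tissue. Clinical reference values are instead estimated from
reconstructed images by Beer–Lambert fits to depth-resolved signal decay,
which requires a full simulation/reconstruction pipeline; comparisons
against image-derived values are therefore qualitative.

## Reproducibility

One master seed spawns independent per-stage substreams (anatomy, trees,
sub-skin, lesion, functional, optical, acoustic) in a fixed order, so a
bundle regenerates bit-identically from its config snapshot and changing
one stage's configuration (e.g. lesion count) does not perturb the others.

## Known limitations

- The fixture anatomy and tree grower are statistical stand-ins, not
  replicas of recursive-partition anatomy engines; only ensemble-level
  vascular statistics are calibrated.
- The sub-skin algorithm's σ3 ↦ diameter mapping is threshold-dependent
  (see above); the achieved mean diameter is ≈ 0.51 mm for the default σ3.
- No photon transport, wave propagation, initial-pressure computation, or
  image reconstruction: the package ends at the property maps.
- No lesion-growth biology (vascular co-option, multiple necrotic foci),
  no mechanical compression, no spatially varying attenuation exponent.
- Quantitative s / f_b fields depend on μ and solver resolution, which the
  underlying physiological model does not pin down.
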