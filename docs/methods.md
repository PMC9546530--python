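# Methods

This note documents the models, parameters and numerical choices behind
`synaptomap`, in the spirit of the methods documentation of simulation and
statistics packages: what is modelled, what is assumed, and what passing
tests do and do not demonstrate.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`; voxel sizes are `(dz, dy, dx)` in
micrometres, default `(1.0, 0.2, 0.2)` — the anisotropic sampling of
block-face fluorescence tomography. Voxel `(i, j, k)` covers the half-open
physical box `[i·dz, (i+1)·dz) × …`, so a coordinate exactly on a voxel
boundary belongs to the higher-index voxel, and the centre of voxel `i` is
at `(i + 0.5)·d`. All spot coordinates are physical micrometres; SWC and
CSV columns are explicitly named (`x_um`, `y_um`, `z_um`) to prevent silent
axis transposition (SWC stores x y z, arrays are z y x). Region volumes are
mm³ (1 mm³ = 10⁹ µm³). Densities are puncta·mm⁻³·neuron⁻¹.

## Synthetic data generator

The generator emulates the *statistical* structure of a SypEGFP labelling
experiment, not its optics:

- **Atlas.** An ellipsoid inscribed in the volume stands in for the brain
  mask (label 0 outside); in-mask voxels in x-major raster order are split
  into `n_regions` near-equal contiguous slabs. Block regions keep every
  region volume analytically checkable by voxel counting. The partition is
  deterministic; the `seed` argument is accepted for interface uniformity.
- **Counts.** Per region, the punctum count is Poisson with mean
  `density × volume_mm³ × n_starters` — the generative inverse of the
  density statistic. Poisson is an assumption (real counts are only
  reported as realised values); it provides a defensible variance model and
  a closed-form mean for tests.
- **Placement.** A `1 − cluster_fraction` share is uniform over region
  voxels with uniform within-voxel jitter; the rest forms basket-like
  Gaussian clusters (scale `cluster_radius`, default 5 µm; mean occupancy
  `cluster_mean_size` = 10) around uniform centres, with out-of-region
  draws rejected and resampled. Clustering defaults to off.
- **Rendering.** Each punctum is a 3D Gaussian with the same physical FWHM
  on every axis (default 0.8 µm, the reported scale of the labeled
  presynaptic elements); per-axis σ in voxels is `FWHM / (2.3548 · d)`.
  With dz = 1 µm this means σ_z ≈ 0.34 voxel: the z axis is genuinely
  undersampled, exactly as at the instrument, and a punctum's peak voxel
  value varies up to ~3× with its sub-plane z phase. The default peak
  amplitude is 150 AU over a 100 AU background.
- **Noise.** Poisson photon noise on the signal plus additive Gaussian read
  noise (σ = 10 AU) by default; each is separately switchable. No optical
  aberrations, stitching seams or bleaching are modelled. The background
  sd is √(100 + 10²) ≈ 14.1 AU, so the default render has peak SNR ≈ 10.6.
- **Cohorts.** Control samples draw at the configured densities; "AD"
  samples at densities times a per-region `group_effect`. Each sample gets
  a unit-mean lognormal density multiplier with CV `sample_cv` (default
  10 %, the between-animal variability assumed in the power analysis) and a
  starter count uniform on [1519, 2351], the range reported for the
  labeled cohort. Default group size is 4 per group. Seeds flow from the
  master seed through `numpy.random.SeedSequence` spawning, so each sample
  and stage is independently reproducible; `sample_cohort_densities` is a
  counts-only fast path for large replicate simulations (it draws the same
  Poisson/lognormal model without spatial placement, which the t tests
  never consume).

Because the generator is the test oracle, passing tests demonstrate
*parameter-faithful* behaviour — correct formulas, geometry, calibration —
on data whose point-spread, noise and anatomy are idealised. They do not
certify performance on real fMOST data, whose PSF, autofluorescence and
registration errors are outside this model.

## Detection

A scale-normalised Laplacian-of-Gaussian detector whose two knobs are the
two physical numbers used in the original quantification:

1. background subtraction: minus a Gaussian blur of σ = `background_radius`
   (default 5 µm) per axis, clipped at 0;
2. LoG response at σ = `spot_diameter / (2√3)` — the scale at which the LoG
   response of a blob of diameter D peaks — converted to voxels per axis;
   the physical Laplacian is assembled from per-axis second derivatives
   divided by d², and multiplied by −σ² for scale normalisation;
3. strict-positive local maxima (3³ neighbourhood);
4. threshold: default `5 × (1.4826 · median |response|)`, i.e. five robust
   noise standard deviations. Otsu (on the positive response), quantile and
   absolute policies are available. Otsu was evaluated as a default and
   rejected: with realistic sparsity (< 0.1 % of voxels in puncta) the
   response histogram is unimodal noise and Otsu's threshold falls inside
   it, yielding thousands of false maxima. Five sigmas keeps the expected
   false-maximum rate at the 10⁻⁵/voxel level while retaining blobs down to
   SNR ≈ 5. A bounded multiplicative `threshold_adjust` ∈ [0.95, 1.05]
   mirrors the ≤ 5 % manual adjustment applied in the original analysis;
5. split-touching: greedy non-maximum suppression in physical coordinates
   at `min_separation` (default 1 µm), strongest response first, ties
   broken by lexicographic (z, y, x) voxel order — peaks closer than 1 µm
   merge into the stronger one;
6. sub-voxel localisation: 3-point quadratic interpolation per axis on the
   response, offsets clipped to ±0.5 voxel, disabled at volume borders;
7. intensity: mean raw (pre-subtraction) gray value within a physical
   sphere of radius `spot_diameter / 2`.

Soma detection reuses the same detector with
`spot_diameter = min_separation = soma_diameter` (default 10 µm) and a
background scale of 3 soma diameters; its count is the starter-neuron
denominator. Detection benchmarks (F1 ≥ 0.9 at SNR 5 with ≥ 2 µm spacing,
0.5 µm gate, optimal-assignment matching) are limited mainly by z
undersampling: a punctum centred between z planes carries ~3× less peak
signal, and at SNR 5 a few percent of such puncta drop below any threshold
that still controls false positives.

## Quantification

- `intensity_proportion`: per-region sum of per-punctum mean gray values
  over the whole-brain sum, ×100. The per-punctum reading (rather than
  whole-ROI voxel sums) ties the statistic to detected synapses; both
  interpretations exist in the original description and this one is the
  package default.
- `syp_density`: `count / volume_mm³ / n_starters`, errors on zero
  starters.
- `average_distance` (k = 9): exact k-d-tree nearest-neighbour search; per
  spot the mean distance to its nine nearest same-region neighbours, then
  the unweighted mean over spots. "Within the same spot component" is read
  as "within the same region's spot set". Regions with fewer than k + 1
  spots report NaN — an explicit undefined marker — rather than a
  fabricated value. Coincident puncta contribute zero distances.
- `axis_profile`: histogram over the region's atlas extent along the mapped
  axis (AP→z, DV→y, ML→x by default; the mapping is configurable because
  anatomical axes are a property of the mounting, not of the array), with a
  one-sample Kolmogorov–Smirnov p value against the uniform distribution on
  that extent. Note that uniform-per-volume placement in a non-box region
  is *not* uniform along an axis (the cross-section varies), so a small p
  is expected for curved regions even without biological patterning; the
  test answers "is the 1D marginal uniform", nothing more.

Spots on label 0 (outside the brain mask) are retained in spot tables,
flagged by their label, and excluded from every region statistic.

## Group comparison and similarity

- Region-wise two-sample Student t tests (pooled variance, two-sided) on
  per-starter-neuron densities; Welch available behind `equal_var=False`.
  The multiple-testing family is exactly the region list passed in.
  Degenerate all-equal input yields t = 0, p = 1 by convention.
- Holm–Sidak is implemented from the step-down formula
  `p_adj(i) = 1 − (1 − p(i))^(m−i+1)` on ascending ranks with a running
  maximum for monotonicity and a cap at 1; the statsmodels implementation
  serves as an independent cross-check in the test suite only.
- Similarity: Pearson correlation (Spearman optional) between region
  columns of a samples × regions density table; average-linkage
  hierarchical clustering on 1 − r, flat clusters cut at distance 0.5
  (configurable). Zero-variance or missing columns are errors naming the
  offending region.

Simulation-based calibration (counts-only cohorts, 22 regions of 10⁻³ mm³
at 2 450 puncta/mm³/neuron, n = 4 per group, 10 % CV): the family-wise
error rate over 500 null cohorts stays well under 5 % (the t test is
conservative at n = 4 on lognormal-Poisson densities), and a 50 % density
reduction in 5 regions is flagged in ~98 % of cohorts with ≥ 95 % of
unaffected regions clean.

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use volumes from 16 × 48 × 48
to 64 × 640 × 640 voxels, puncta counts up to ~4 300, and point densities
at or below ~0.008 µm⁻³ — the package's chosen benchmark scale, at which
sub-1 µm chance pairs (irrecoverably merged by the split-touching rule)
stay below ~2 % of puncta. End-to-end density recovery at these sizes is
limited by Poisson sampling of the ground truth itself (sd ≈ λ^(−1/2)),
detector merge losses, and a small false-positive rate; the acceptance
run reports both the max and mean per-region relative error. The
average-distance statistic is validated against an O(n²) all-pairs oracle
up to n = 10⁴ at 10⁻⁹ absolute tolerance. TIFF volumes are written as
unsigned 16-bit (rendered intensities rounded and clipped), SWC and CSV
coordinates at 10⁻⁶ µm precision.

## Known limitations

- The toy atlas has axis-aligned slab regions; nothing is tested against
  curved or disconnected region geometry beyond the ellipsoid mask.
- The PSF is an isotropic-in-physical-units Gaussian; real block-face
  imaging has an asymmetric axial PSF and sectioning artefacts.
- Equivalence with the proprietary tools used on the original data
  (Imaris Spots, the Farsight pipeline) cannot be established; the
  detector is parameter-faithful to the stated settings, not
  output-identical.
- The red-channel model covers blob-like somas only; fiber-like structures
  are not simulated, and no colocalization analysis is provided.
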