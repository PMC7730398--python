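# Methods

This package measures per-cell deformation in softwood micro-CT volumes by
Individual Cell Tracking (ICT): instead of correlating voxel subsets as
digital volume correlation does, it segments every tracheid and wood-ray
lumen, reduces each tube to a one-dimensional profile of cross-section
geometry along its axis, registers cells between load states, and derives
displacement and strain fields from the per-cell geometric changes.  Because
every profile channel (centroid, area, ellipse fit, wall thickness) averages
the contributions of hundreds of boundary voxels, the method resolves
strains far below the voxel size — nanometre-scale displacements at
1.62 µm voxels.

## Coordinate and unit conventions

Axes are (x, y, z) = (R, T, L): radial, tangential, longitudinal (grain).
Coordinates are 0-based voxel indices; physical positions are
`index x voxel_size` in micrometres.  Areas are µm², angles degrees, strains
dimensionless with tension positive.

## The synthetic spruce phantom

Every stage is validated against a generated Norway-spruce-like volume with
exact ground truth:

- **Tracheids.** Axially aligned tubes with rounded-rectangle (superellipse,
  exponent 4) cross-sections on a jittered lattice.  Across the radial
  coordinate one earlywood-to-latewood (EW -> LW) cycle is laid out: lumen
  R-diameter 48 -> 22 µm, R/T aspect 1.6 -> 1.3, wall thickness
  3.4 -> 4.2 µm, ending in a sharp LW/EW discontinuity.  Real growth rings
  are ~1500 µm wide; by default the ring is compressed onto the volume's R
  extent so both cell populations are present at desk scale.
- **Waviness.** Each tube's centreline undulates by ~0.6–0.85 µm over
  60–160 µm wavelengths.  This mirrors real tracheid meander and — equally
  important for validation — spreads the sub-voxel phase of the wall faces:
  a phantom with perfectly grid-aligned flat walls would quantize all
  boundary statistics to the voxel grid and make sub-voxel tracking look
  impossible when it is not.
- **Wood rays.** Radial (X-aligned) lumen tubes, 5–13 µm diameter, grouped
  into clusters of 3–6 tubes stacked along L inside corridors left free by
  the tracheid lattice; cluster count targets a ray voxel fraction of 1%
  (0.5–2% band).  Tube radii are modulated by two incommensurate
  sinusoids (~12% + 8%) as brick-cell texture for axial tracking.
- **Pits.** Hemispherical lumen-side wall indentations (4–8 µm) at
  Poisson-distributed axial positions (2 per 100 µm) break the axial
  symmetry of tracheids; they are the landmarks the axial correlation
  relies on.
- **Rendering.** The air-fraction field is rendered with partial-volume
  anti-aliasing (linear coverage model of the signed boundary distance), so
  the image carries the true sub-voxel position of every interface, then
  blurred to a 3.0 µm FWHM point spread (the instrument classes this
  emulates resolve 2.5–4 µm) and overlaid with a static correlated material
  texture (sd 6 counts, 2-voxel correlation) plus white acquisition noise
  (sd 8 counts) before quantization to 8 bit.  In the blur-free limit the
  image degenerates to hard two-phase voxels and binarization reproduces
  the label mask exactly.
- **Deformation ground truth** is stored as the exact map chain used for
  resampling (affine tensors or compression-band parameters), so
  displacements and strains are analytic, never interpolated.  Affine
  deformations resample the grayscale with cubic interpolation through the
  inverse map; the non-affine compression band prescribes a Gaussian axial
  strain profile of equivalent width `band_width` (total shortening =
  peak x width) with an optional linear cross-grain shear above the band.

What the phantom does **not** emulate: X-ray phase-contrast fringes,
reconstruction artefacts (rings, beam hardening), bordered pit pairs that
genuinely connect neighbouring lumens, resin canals with biological
fidelity, or moisture-driven swelling.  Passing the phantom suite therefore
demonstrates the estimator chain's geometric and statistical correctness at
realistic contrast, resolution and noise — not robustness to every
acquisition artefact of a real beamline.

## Segmentation

1. **Binarization.** Otsu's threshold on the 256-bin histogram (exact
   between-class-variance search; voxels strictly below threshold are
   lumen).  In the two-state workflow both states are thresholded at the
   *reference* state's value: a one-count threshold flip between states
   would bias all areas by ~2 x 10^-3 strain, far above the method's
   sensitivity.  A mild Gaussian denoising (sigma 1 voxel) is applied
   before thresholding in that workflow; warping a noisy reference (the
   synthetic-deformation validation) smooths the static noise
   asymmetrically between states, and equalizing the noise removes that
   bias.
2. **Two-pass detection.** Pass 1 erodes the void mask with a 7-voxel
   Euclidean ball; surviving cores (wide earlywood lumens) are closed
   (diamond, 2 voxels) to bridge pit apertures, labelled (26-connectivity),
   and regrown over the void mask by capped *geodesic* propagation
   (opening-by-reconstruction in spirit, but a thin leak between two lumens
   is split near its midline instead of re-merging the pair).  Pass 2
   re-labels the remaining void voxels and keeps, whole, every component
   that survives a 1-voxel erosion — thin-walled latewood lumens and ray
   tubes fragment under a plain opening, so this pass is a classic
   opening-by-reconstruction.  Pieces of one tube that met over a *wide*
   interface (a substantial fraction of the smaller piece's cross-section)
   are unified; narrow contacts (leaks) stay split.  Components below 500
   voxels are dropped.
3. **Classification.** The principal elongation axis of each label decides
   the category: Z-aligned tubes are tracheids (above 60 µm mean diameter,
   resin canals, which are excluded from deformation statistics), X-aligned
   tubes are rays; labels under 20 voxels stay unclassified.
4. **Wall ownership.** The middle lamella gives no contrast, so every wall
   voxel within 15 µm of a lumen is assigned to its geometrically closest
   lumen (exact Euclidean distance transform).  The resulting per-cell
   territory reaches the mid-wall and yields the skeletonized cross-section
   area and perimeter per slice.
5. **Ray clustering** is single linkage on (T, L) centroid distance
   (<= 20 µm) with >= 30% R-extent overlap.  **Density profiles** average
   the wall indicator per 10 µm slab and are scaled so the volume mean
   equals the specimen's gravimetric density.  **Ray distance maps** are
   Euclidean distances to the nearest ray lumen.

Cells touching a lateral volume face are segmented but excluded from strain
statistics; axial truncation (every tube is cut by the Z faces) is normal.

## Per-cell 1D parameterization

For every cell and axis position, the lumen section must be singly
connected without interior voids (Euler number 1); valid slices record
centroid (c_X, c_Y), area Sigma, perimeter P, skeletonized section
(Sigma_sk, P_sk), a moments-equivalent ellipse (e_a, e_b = 4 sqrt of the
second-moment eigenvalues; e_Psi from +X in (-90, 90], 0 when degenerate),
the mean wall thickness t and the local inclination theta.

Three estimator refinements matter for sub-voxel sensitivity:

- **Densitometric centroid/area.**  Blurring preserves integrals, so the
  partial-volume values of the blurred two-phase image carry the exact
  sub-voxel boundary geometry.  The air fraction
  (I_wall - I)/(I_wall - I_lumen), integrated over the lumen plus a
  2.5-voxel owned-wall band, replaces voxel counting for c_X, c_Y and
  Sigma (the counts are kept in `*_bin` columns).  Shared acquisition noise
  cancels almost exactly in state-to-state differences of these integrals.
- **Sub-voxel mid-wall boundaries.**  The territory boundary between two
  cells is the locus of equal lumen distances; interpolating the distance
  fields along each ownership interface edge locates the true crossing and
  corrects Sigma_sk below the voxel quantum.  Without this, territory areas
  respond to strain only in grid-locked jumps and wall-thickness strain is
  unmeasurable at the 10^-2 level.
- **Metric-boundary exclusion.**  Slices whose territory is truncated by
  the 15 µm ownership cap or by a volume face are flagged (`sk_capped`):
  those outer boundaries are metric, not material, and do not follow the
  deformation, so they are excluded from wall-thickness strain statistics.

**Wall thickness.**  t = 2 (Sigma_sk - Sigma)/(P_sk + P).  On a circular
annulus this returns the ring width exactly (the mean-perimeter
denominator); the (P_sk - P) variant instead returns r_outer + r_inner and
is kept only behind `variant="printed"`.  Both are homogeneous of degree
one, so wall-thickness *strain* under affine deformation is identical
either way.  Note the measured absolute t on the phantom exceeds the
constructed wall thickness: the mid-wall territory includes the interstitial
corner material between four neighbours, which a mean-width formula counts.
Strain ratios are unaffected.

**Inclination.** theta(z) = atan |d/dz (c_X, c_Y)| from cubic smoothing
splines of the centroid tracks.  The spline penalty is set from the
requested resolution via lambda = h^4 / voxel (equivalent-kernel bandwidth
of the cubic smoothing spline), default 50 voxels = 81 µm.

**Oblique reslicing.** Inclined cells can be re-sectioned perpendicular to
the local axis (linear interpolation of the label mask at the 0.5 level),
iterated three times with the maximum relative change of Sigma as the
convergence diagnostic.  For the small-strain accuracy workflows reslicing
is off by default: below ~0.6 degrees the section inflation (1/cos theta -
1 < 5 x 10^-5) is smaller than the noise the extra resampling adds.

## Registration and tracking

Cells are matched by mutual volumetric overlap (both directions >= 50%;
best overlap wins ties).  The axial displacement u_z(z) of a matched pair
maximizes the zero-normalized cross-correlation of the two cells' profile
windows (41 samples = 66 µm for tracheids; 100 samples for rays), with a
3-point parabolic refinement of the correlation peak (skipped when the peak
is exactly 1, so self-tracking is identically zero).  Track points with
peak correlation <= 0.5 are rejected.  Each channel is standardized within
its window before pooling, so channels of different physical units (µm,
µm², degrees) contribute equally; raw pooling is available but lets the
largest-magnitude channel dominate.  For wood rays the correlation pools
only the densitometric channels (c_X, c_Y, Sigma, theta): for their small
cross-sections the voxel-counting shape channels carry grid-locked
discretization error that pulls the correlation peak toward zero shift.

The aligned test profile T_hat(z) = T(z + u_z(z)) (cubic interpolation,
with u_z first smoothed by the same spline family at the strain resolution
so peak jitter is not injected through steep landmarks) yields u_x, u_y
(centroid differences) and the relative channels eps_Sigma, eps_t, eps_a,
eps_b plus the angular differences delta_theta, delta_e_Psi.  For
homogeneous deformations the per-cell ratio of within-cell means
(`eps_sigma_cell`, `eps_t_cell`, computed over uncapped aligned slices) is
the low-noise statistic; per-slice channels remain available for localized
deformation (compression bands).

## Strain fields

Scattered per-cell displacement readings at the lumen centroids are
smoothed in two spline steps sharing one resolution knob h (50 voxels =
81 µm for tracheids, 100 for rays): cubic smoothing splines along the tube
axis per cell, then thin-plate smoothing splines over the in-plane sites
per axial bin (h/2 bin width).  The thin-plate smoothing parameter scales
as n_sites x h² log h — the kernel magnitude at the resolution scale — so
variation below h is damped while the affine part (the spline's unpenalized
null space) passes exactly.  Strains are eps_ij = (d_j u_i + d_i u_j)/2;
the axial normal strain comes from the per-cell spline derivative directly
and survives even when an axial level has too few in-plane sites for a
surface fit.

Ray-cluster deformation is decomposed into the least-squares affine map of
the lumen-centroid lattice (eps_ray = symmetric part minus identity; 1D fit
with a flag when the lattice is collinear) and per-lumen non-affine
residuals u_ray.  Poisson ratios are masked ratios -eps_num/eps_den with a
5x sensitivity floor on the denominator and |eps_den|-weighted averages.
Parameter correlations are Pearson r with two-sided p from the t
approximation.  Densification planes are scored by CNR = |band mean -
background mean| / background sd over a 50 µm band, background taken
outside all candidate bands.

## Accuracy workflows

*Absolute* accuracy resamples the reference volume through known uniform
strains and measures them back through the full chain; *differential*
accuracy deforms an independent second acquisition (stand-in: a fresh
noise realization at the full acquisition noise level, conservative
because the reference noise cannot be removed) and subtracts the chain's
estimate of the undeformed pair.  Errors are reported per parameter, cell
type and level as median (and mean) absolute deviations from the imposed
strain, never a single pass/fail.

## Problem sizes and numerical choices

The accuracy phantoms run at 288 x 288 x 336 voxels (1.62 µm; ~150
tracheids, >= 9 ray clusters) for the acceptance script and the acceptance
test module, and 144-class volumes for unit tests — chosen as desk-scale
study conditions; the strain-error medians at these sizes carry the
per-cell noise analysed above, which would tighten further on
full-experiment volumes with several times more cells and slices.
Randomness flows from one integer seed through named substreams (geometry,
rays, pits, noise); phantoms are bit-reproducible per seed.  Degenerate
inputs (constant images, empty label sets, collinear lattices, fully
masked denominators) raise or warn explicitly rather than returning silent
zeros.

Known limitations: the lumen-area strain channel retains a per-cell noise
floor of ~1 x 10^-4 from state-to-state redefinition of the voxel support
of the partial-volume integrals, so its median absolute error at desk
scale sits at, not below, the 5 x 10^-5 class bound; wall-thickness strain
is only measurable after excluding metric-boundary territories; and the
printed-formula wall thickness variant is non-physical on an annulus (kept
for comparison only).
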