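# Methods

## Problem and measurement model

A locus tagged by DNA FISH appears as a diffraction-limited spot inside a
nucleus whose periphery is visualized by anti-lamin immunostaining. The
quantity of interest is the locus's position relative to that periphery,
reported two ways:

* **3D shortest distance (µm).** The lamin staining is punctate, so the
  detector output in the lamin channel is treated as a point cloud that
  densely samples the nuclear lamina. For a probe spot at physical
  position `x` and lamin points `{l_j}` of the same nucleus, the readout
  is `min_j ‖x − l_j‖` after each voxel coordinate has been rescaled by
  its per-axis voxel size (the z step differs from xy, so rescaling must
  be per axis for the Euclidean distance to be physically correct).
* **2D normalized radial position.** A per-nucleus 2D contour (a closed
  periodic cubic spline traced through ≥5 control points on a maximum
  z-projection, or a projected segmentation mask) is rasterized; the
  Euclidean distance transform assigns each interior pixel its distance to
  the contour, and dividing by the per-nucleus maximum normalizes the map
  to [0, 1] — 0 at the periphery, 1 at the deepest interior point, which
  for a convex nucleus is its centre. The spot's value is read off the map
  by bilinear interpolation. The normalization makes positions comparable
  across nuclei of different sizes.

Distributions are presented as probability histograms whose bar heights
are counts over total (bars sum to one, checked to 1e-12). The
two-condition comparison is deliberately descriptive (n, median, mean,
difference of medians): no hypothesis test is attached.

## Segmentation

Median filter (box 13×13×5 in x×y×z; fine in-plane, coarse axially to
match anisotropic voxels; reflect borders — the edge-including reflection,
which avoids the edge darkening that would bias the global threshold) →
Otsu threshold (exact per-value histogram for integer data; the fast path
is tested against an exhaustive scan of all candidate thresholds; ties
resolve to the lowest qualifying value; binarization rule is
`voxel > threshold`; a constant volume raises a degenerate-input error) →
binary dilation with a 5×5×3 box structuring element → 26-connected
component labelling, discarding components below `min_nucleus_voxels`
(default 500, below any plausible nucleus at the default voxel sizes).

The dilation deliberately grows masks past the nucleus boundary so the 3D
path captures lamin detections sitting on the rim. Because of that
overshoot, the 2D readout normalizes against the *pre-dilation* mask,
whose boundary tracks the actual surface; both masks are carried on the
segmentation result. Segmentation runs on the DNA counterstain by default
(configurable): growing the mask "to cover the lamin staining" only makes
sense if the mask is not lamin-derived in the first place. Touching
nuclei merge into one label; no watershed splitting is attempted.

## Spot detection

DoG band-pass with `σ_large = 1.6 σ_small` per axis (the classic ratio;
`σ_small` defaults to the expected PSF width in voxels). Candidates are
strict 26-neighbourhood local maxima at or above a threshold; when no
threshold is given it is set per volume to `median + k·1.4826·MAD` of the
DoG response (k = 8 for probe-like channels, a conservative false-positive
control for megavoxel volumes; k = 2 for the lamin channel, where dense
sampling matters more than purity). On noiseless volumes the MAD
collapses to zero and the plain standard deviation is used instead.
Candidates are sorted by descending response with lexicographic
tie-breaks, so detection is fully deterministic.

Centre-of-mass refinement uses a window of `2⌈2σ_small⌉+1` voxels per
axis, clipped at borders. The window minimum is subtracted before
weighting: on raw counts a uniform background pulls the centre of mass
toward the window centre. A window with zero residual mass returns the
unrefined coordinate with a flag. Nucleus assignment uses the integer
detection voxel (not the refined coordinate), avoiding label-boundary
ambiguity after sub-voxel shifts; label 0 means "outside every nucleus"
and such spots are excluded from distances but counted in reports.
Coordinates are 0-based (z, y, x) voxel indices; physical coordinates are
index × voxel size (voxel-centre convention).

## Synthetic scenes

The generator states a concrete imaging world and reports its exact
geometry:

* **Nuclei** — non-overlapping axis-aligned ellipsoids (spheres on
  request), semi-axes drawn from a configurable range (default
  1.4–2.2 µm, blastoderm-like), z semi-axis capped so nuclei fit thin
  stacks as a monolayer. Placement is rejection sampling with bounding-
  sphere separation; an unplaceable configuration raises after a bounded
  number of re-draws.
* **DNA channel** — uniform interior fill, blurred by the Gaussian PSF;
  the half-maximum edge of the blurred fill stays on the surface.
* **Lamin channel** — punctate immunostaining modelled as bright dots on
  a jittered quasi-uniform (Fibonacci-lattice) surface lattice at 0.3 µm
  spacing with lognormal brightness (CV 0.3). Each dot is a PSF-shaped
  blob truncated at half the shell thickness, and the staining is clipped
  to the nucleus interior: the lamina lies just beneath the nuclear
  envelope, i.e. within the chromatin boundary, which is also what lets a
  slightly-grown DNA mask cover the staining entirely.
* **Probe channel** — one Gaussian spot per requested
  `(nucleus, r, amplitude)` at the position whose normalized ellipsoidal
  coordinate is `1 − r` along a uniformly random direction (r = 1 centre,
  r = 0 boundary). Ground truth records the exact pre-blur position and
  the exact Euclidean distance to the ellipsoid surface (closed form for
  spheres; bracketed root-finding on the Lagrange condition for
  ellipsoids).
* **Noise** — `Poisson(clean + background) + N(0, read_noise)`, clipped
  and quantized to 16-bit unsigned integers (sCMOS-like). A scene with
  `background = 0` and `read_noise_sd = 0` is rendered strictly
  noiselessly (deterministic rounding, no shot noise), so noiseless
  recovery tests are exact. All randomness derives from one seed; equal
  parameters give bit-identical stacks.

Defaults emulate a widefield 100× acquisition: 0.1 µm xy pixels, 0.3 µm z
step, PSF σ = (0.3, 0.1, 0.1) µm zyx, background 20 counts, read noise
3 counts, spot amplitude 500 counts (peak SNR ≈ 20). None of these are
asserted as the original acquisition's values — they are a stated,
configurable world.

What the generator does **not** emulate: optical sectioning/defocus
structure, chromatic aberration, embryo curvature, mitotic or touching
nuclei, autofluorescence gradients. A green recovery test therefore
establishes that the measurement chain is correct under the stated model,
not that it is robust to every real-world artefact.

## Numerical choices and validation geometry

* `min_distance_3d` uses an exact k-d tree query and is tested to equal
  the exhaustive all-pairs minimum.
* Splines are closed natural-periodic cubics with uniform
  parameterization, densified to ≥8 samples per pixel of arc length
  before polygon filling (pixel centres inside the curve; self-
  intersecting curves are rejected via an exact geometric simplicity
  test).
* Histogram defaults: 20 uniform bins on [0, 1] for normalized positions;
  Freedman–Diaconis for µm distances.
* 3D distance validation uses noiseless spherical nuclei sampled at
  near-isotropic voxels (0.1 µm, confocal-like PSF). Under the default
  widefield anisotropy the axial PSF merges neighbouring lamin dots along
  z-facing directions, thinning the detected cloud to ~0.6 µm gaps there;
  the shortest-distance estimate is then biased upward by up to ~0.3 µm
  for loci very close to the lamina. This is a genuine resolution limit
  of the point-cloud readout, not an implementation artefact; the
  validation scene instead states conditions under which the cloud is
  dense (gap ≈ 0.3 µm), and recovery is verified to 1.5 in-plane voxel
  sizes for spots at r ≥ 0.2.
* The 2D pipeline readout on simulated scenes uses projected pre-dilation
  masks. Because spot directions are uniform in 3D, the projected radial
  position overestimates r (a spot off the equatorial plane projects
  closer to the disk centre); medians shift from a true mean of 0.15 to
  ≈ 0.27 and from 0.45 to ≈ 0.53. The between-condition ordering and
  separation survive this compression, which is exactly what the
  condition-shift validation asserts.

## Known limitations

* Touching nuclei merge (no watershed); densely packed late-blastoderm
  fields need manual ROIs instead.
* The lamin point cloud is detector-dependent: a too-strict threshold
  thins it and inflates 3D distances. The permissive default (k = 2) is
  tuned for dense sampling, not purity.
* Near-lamina loci (within ~2 in-plane voxels of the surface) have 3D
  distance errors dominated by cloud sampling gaps.
* The 2D readout from projections is geometrically biased toward the
  centre for loci measured off their nucleus's equatorial plane; compare
  conditions within one readout, never across readouts.
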