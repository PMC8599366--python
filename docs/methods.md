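# Methods

This note records the models behind `eustrack`, the defaults that matter,
and what the synthetic experiments do and do not demonstrate.

## Coordinate conventions

A right-handed world frame in millimetres (x left→right, y
posterior→anterior, z inferior→superior). `Volume3D` grids are indexed
(x, y, z) with the origin at the centre of voxel (0, 0, 0). Imaging planes
(`ObliqueSliceSpec`) are spanned by orthonormal `u_axis` (image columns) and
`v_axis` (image rows) about a centre point; pixel (i, j) samples the world
point `center + (i·dv − extent_v/2)·v + (j·du − extent_u/2)·u` by trilinear
interpolation, with out-of-volume samples reading 0 (air) so planes near the
volume boundary still render. The 5×5 median filter applied to every
simulated image before feature extraction replicates edges at the border.

## Scatterer phantoms

Tissue is modelled as a uniform point-scatterer cloud whose amplitudes are
standard-normal draws scaled by a local echogenicity factor: 0 inside the
fluid scan channel, 1 in background, and 6 inside the echogenic sphere
targets (region priority channel > sphere > background). The 6× choice
(≈ 15.6 dB) makes the targets clearly brighter than fully developed speckle
after log compression — matching how training-phantom targets actually
present — whereas ≤ 3× leaves them within the speckle variance and makes
centroid-based marker measurement meaningless; contrast is configurable.
The bitmap route for patient-like data maps slice intensity linearly to
[0, 1] (zero stays zero) as the factor, over a 5-mm elevation slab.

The default density is 5 scatterers/mm³, enough for fully developed speckle
at the simulator's resolution cell while keeping a full dictionary build
around a minute on one CPU; production-scale clouds (~10⁷ scatterers) are a
configuration, not a default.

### Training-phantom fixture

Four 5-mm-radius spheres are placed at seeded random azimuths (quadrant
centres ± 20°) and radial stations 34-42 mm from a central 25-mm-radius scan
channel, at axial stations z = 45 + {0, +1, −1, +2} mm. Clustering the
axial stations within a few millimetres is deliberate: the marker-based
evaluation measures *four* sphere centroids in a *single* image, so one
probe plane must intersect all four targets; the 1-2 mm axial stagger keeps
all 120 dictionary planes geometrically distinct. The synthetic volume
variant (`generate_toy_volume`) voxelises the same geometry; the
`abdomen_like` variant adds a hypointense tumour ellipsoid, a bright marker
dot and bright hydrogel blobs on a smooth textured background, with one
mask per structure.

## B-mode simulator

Array-acoustics simulation is replaced by a separable point-spread-function
convolution model — a deliberate fidelity departure. What dictionary
matching consumes is speckle statistics and target geometry, not
diffraction detail, and the convolution model reproduces those at desk
scale:

* **axial**: Gaussian-modulated sinusoid at the centre frequency;
  σ_z = λ·√(2 ln 2)/(π·BW) with fractional bandwidth BW = 0.6;
* **lateral**: Gaussian beam of σ(d) = clip(d·λ/aperture, 0.3, 2.0) mm at
  depth d (an unfocused beam widening with depth);
* **elevation**: Gaussian-weighted slab of 5 mm about the plane.

Scatterers in the slab are deposited onto an RF grid (one line per
scanline, axial samples at λ/8) with linear interpolation between axial
samples; lines are convolved with the axial pulse, envelope-detected via
the analytic-signal magnitude, max-normalised, log-compressed into a 60-dB
dynamic range and mapped to [0, 255]. Max normalisation makes the output
exactly invariant to global scatterer-amplitude scaling. Curvilinear
arrays image in (beam angle, depth) fan coordinates and are scan-converted
by bilinear resampling, with the fan apex one array radius behind the face
and out-of-fan pixels set to 0.

Probe presets: a 128-element 7.5-MHz linear endoscopic array with
0.29 × 0.41 mm elements, and a 159-element curvilinear array of 91.1 mm
radius reconstructed over 128 scanlines. Speed of sound 1540 m/s. A point
target's envelope peak is accurate to within half a wavelength axially
(0.103 mm at 7.5 MHz) and one beam width laterally.

Not modelled: attenuation, transmit focusing/apodization, harmonics,
frequency-dependent scattering, RF export.

## Pose grids

**Phantom.** The probe rides the scan channel, so every candidate plane is
normal to the channel axis and centred on it: per target, 10 plane
positions at 5-mm intervals centred on the target's axial station (offset
indices −5…+4), each at in-plane rotations {0°, +15°, −15°} about the
channel axis (the probe twisting in the channel rotates the image
direction). Order is target → rotation → offset, so dictionary indices are
reproducible; 4 targets × 30 poses = 120 entries. The offset range is a
choice — only the 5-mm interval and the per-target count of 30 are given
constraints.

**Patient MRI.** Per candidate injection point, seven oblique planes: the
axial plane tilted ±15° about the patient right-left axis and about the
posterior-anterior axis (mimicking radial scanning), plus the perpendicular
plane spanned by the R-L and axial axes with rotations {0°, ±15°} about the
axial axis (mimicking linear scanning). The usual six-point set (two
injection points, two neighbours each) yields 42 planes.

## Haar feature family

Eight base templates over a square support: vertical/horizontal
two-rectangle edges, vertical/horizontal three-rectangle lines, a
four-rectangle checkerboard, a centre-surround square, a diagonal
two-rectangle split, and a full-support average. Edge templates come in
three split-proportion variants (1/4, 1/2, 3/4). Positive rectangles carry
weight +1; negative rectangles are scaled by area so that every template
except the full-support average responds exactly 0 to a constant image (at
the 1/2 split this reduces to the classic ±1 weighting). The average
template intentionally keeps a coarse brightness channel at the cost of
exact invariance to additive intensity offsets; drop it (template ids 0-6)
if that invariance matters.

Scales are dyadic: support = 8·2^s pixels for s ∈ {0, 1, 2, 3}; larger s
means a larger support capturing coarser anatomy with fewer coefficients.
Translations tile the image with stride equal to the support
(configurable). Images are resized (bilinear) to a fixed 128×128 matching
resolution, so target and dictionary vectors are index-aligned; on that
grid the default family has 4080 coefficients (3072/768/192/48 per scale).
All responses are evaluated from a single integral image — entry (i, j)
holds the sum over rows ≤ i, cols ≤ j, so any rectangle sum costs four
lookups — and the vectorised evaluator is verified feature-by-feature
against explicit rendered-mask dot products.

## Matching

Within each scale block the zero-mean NCC is computed independently and the
match score is the arithmetic mean over blocks; the best pose is the argmax
over valid dictionary entries, ties broken toward the lower index. Reading
the normalisation count as "per scale level" keeps the 48 coarse
coefficients from being drowned by the 3072 fine ones; a single
whole-vector NCC and a non-centred cosine variant are available as
switches. A constant (zero-variance) block scores 0 by convention — a
featureless block carries no evidence. Targets are preprocessed exactly as
dictionary images (median filter, resize) before extraction, which makes
the self-match score exactly 1.

## Marker evaluation

Because no real probe frame is available, the synthetic "target EUS image"
is a dictionary pose re-simulated with an independent scatterer seed plus
additive Gaussian pixel noise of 5% of the intensity range — independent
speckle, same anatomy. Sphere markers are detected automatically (the
manual equivalent would be a human marking target centres): threshold at
median + 3·1.4826·MAD of the tissue pixels (those above half the image
median, excluding the anechoic channel), discard components under 2 mm²,
keep the expected number of largest components, take centroids in mm,
named in azimuth order about the image centre. Plain Otsu thresholds are
available but land inside the speckle bulk on log-compressed images and
are not the default. Error convention: matched − target, x lateral, y
axial.

In configuration sweeps, a matched image in which the expected markers
cannot be detected (e.g. a plane missing the targets entirely) records a
saturated error of half the plane extent rather than aborting the sweep.

## What the synthetic experiments show

With the default configuration the pipeline retrieves the correct pose (or
a geometrically adjacent plane 1-2 mm away) for noisy re-seeded targets,
and all four marker displacements stay below 1 mm per axis. This shows the
multi-scale Haar/NCC retrieval is sound under speckle decorrelation and
pixel noise at a known pose. It does not show robustness to real-probe
effects absent from the simulator — attenuation, reverberation, tissue
deformation, probe pressure, miscalibrated geometry — nor performance on
patient anatomy, where structures are subtler than echogenic spheres.
Neighbouring dictionary planes one millimetre apart can produce
near-identical images; the matcher may return either, which is within the
evaluation's error bound but means "exact index" accuracy saturates at the
grid's geometric resolution.

## Numerical choices

* RF axial sampling at λ/8; scatterer deposits linearly interpolated
  between axial samples (keeps peak localisation well under λ/2).
* Lateral deposits truncated at 3σ around the nearest scanline.
* Log compression floor at 10⁻¹² of the peak; empty scatterer sets render
  as the uniform minimum-intensity image rather than erroring.
* Tie-breaks: argmax with stable sort toward lower dictionary index.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); dictionary builds derive per-pose seeds
  from a `SeedSequence`, making every artefact bit-reproducible.
* Sweeps reuse one rendering of the dictionary images across basis
  configurations — simulated images do not depend on the feature basis.
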