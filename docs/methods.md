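# Methods

`usimgen` generates annotated, clinical-like 2D B-mode ultrasound
sequences of in-plane needle insertions from 3D voxel volumes, and ships
the two companion tools such datasets are made for: a detection
evaluation metric (mAP over an IoU-threshold sweep) and a
homography-based fine-positioning method. This note documents the models,
the defaults and why they were chosen, what the synthetic phantoms do and
do not emulate, and the numerical choices that matter.

## Image formation model

The simulator is a linear pulse-echo model for a convex array, built
around a point-scatterer description of tissue:

1. **Scatterer maps.** A 2D gray-scale template slice `I_gb` (intensities
   normalized to [0, 1]) supplies the echogenicity. Random template
   pixels become point scatterers; the reflection coefficient `C_b` of a
   scatterer is the intensity of its source pixel (linear mapping — the
   simplest monotone choice, and the only structure the simulator
   consumes). Sampling is without replacement over pixels with a uniform
   sub-pixel jitter, so positions are continuous and free of grid
   artifacts. The number of scatterers is Poisson with mean
   `density × area / λ²`, with the area taken over the template's valid
   field of view. Default densities: 6 /λ² for the background and
   10 /λ² for the needle at the full probe profile. Needle scatterers
   fill the inserted rectangle (entry→tip × diameter) and draw their
   coefficients uniformly from `[max(C_b)/4, max(C_b)]` — strong relative
   to tissue, which is what renders the shaft bright. Uniformity within
   the band is an assumption; it is configurable.
2. **Transmit model.** One diverging wave per frame, virtual source at
   the array's center of curvature. This makes the transmit delay of a
   point at range r straight ahead of the center element exactly `r/c`,
   so on-axis round trips are `2r/c` — a property the tests pin down.
   A multi-line focused transmit was considered and dropped: nothing
   downstream consumes it and a single transmit keeps a full dataset
   render on one CPU in minutes.
3. **Pulse and receive model.** Gaussian-windowed sinusoid at the center
   frequency with 60% fractional −6 dB bandwidth; far-field hard-baffle
   directivity (sinc in the element width, taken as 0.9× pitch); `1/r`
   spreading on both legs; optional frequency-independent attenuation in
   dB/cm/MHz (off by default). Echoes are accumulated on the sample grid
   over a ±4σ pulse window, which keeps the simulation linear in the
   reflection coefficients to machine precision.
4. **IQ and beamforming.** Complex demodulation at the center frequency
   with a 5th-order zero-phase Butterworth low-pass (cutoff 0.8× the
   demodulation frequency: removes the 2f term, passes the envelope
   band). Delay-and-sum interpolates each element's baseband trace
   linearly at the two-way travel time and rotates the phase back by
   `exp(+2πi f τ)`; uniform receive apodization.
5. **Display.** Envelope → `20 log10(env/max)` → clip to `[−DR, 0]` →
   affine map to [0, 255]. The dynamic range DR ∈ {25, 30, 35} dB is a
   display-stage choice, so the three renderings of a frame share one
   scatterer realization and one beamformed image. Scan conversion
   resamples the polar sector bilinearly onto a Cartesian grid; pixels
   outside the sector are 0.

### Probe parameterization

Defaults model a C3-class convex abdominal probe: 192 elements, 73°
field of view, 0.46 mm pitch, design center frequency 4 MHz (mid-band of
a 2–6 MHz probe), c = 1540 m/s, sampling at 4× the upper band edge
(25.6 MHz). The curvature radius is not published for this probe class;
it is derived so the full aperture arc subtends the field of view,
giving ≈ 69 mm. A *fast profile* (32 elements, shallower max depth)
exists for tests and quick runs; it changes aperture and runtime, not
the physics.

## Synthetic phantoms

Downstream stages consume only voxel intensities as echogenicity, so the
phantoms target statistics, not anatomy:

* **Lesion volume** (CT-phantom-like): band-limited noise background
  (smoothed white noise, mean 0.35, σ 0.08) with six non-overlapping
  quasi-spherical inclusions at 2.5× background intensity by default;
  masks for two of them, mirroring source data in which only a subset of
  lesions is annotated. Inclusions are ellipsoids with volume-preserving
  axis jitter (ratios within 20% of a sphere), so mask voxel counts
  track the analytic sphere volume — a property the tests exploit.
* **Heart-like volume** (MRI-like): a single low-contrast target
  (≤ 1.3× background mean — the source data' defining feature is poor
  contrast, for which no number is published; 1.3 is a configurable
  bound) whose cross-section drifts, dilates and changes outline across
  ≥ 8 consecutive slices via low-order angular harmonics with slowly
  varying coefficients.
* **Fiducial layout**: 9 spheres of mean diameter 8.1 mm in a
  130 × 80 × 90 mm box, diameters normal with 0.3 mm spread,
  non-overlap by rejection; a single fiducial is centered.

What these phantoms do **not** emulate: organ boundaries and acoustic
interfaces, speed-of-sound or attenuation heterogeneity, shadowing and
reverberation, breathing motion, needle bending. Passing tests therefore
demonstrate that the pipeline's geometry, statistics and annotations are
correct — not that a detector trained on these images transfers to
clinical data.

## Pre-processing

Template extraction selects the contiguous window of `n` slices (8 by
default) maximizing total target-mask area — "most visible" made
concrete as mask area. Intensities are min-max normalized per window,
not per slice, so echogenicity is comparable across a dynamic sequence.
The crop zeroes everything outside a circular sector (apex top-center by
default, 73°, 45 mm depth). The depth default is the one genuinely free
parameter: at 4 MHz and 6 scatterers/λ², a 73°/45 mm sector yields
≈ 52,000 background scatterers, consistent with the tens-of-thousands
scale this class of simulation operates at. Coarse voxel grids (~1 mm)
are upsampled (bilinear; masks nearest-neighbour) before scatterer
sampling, since source pixels must outnumber scatterers.

## Dataset assembly

An intervention is 48 frames: frame k uses template `k mod 8` (cycling;
a ping-pong option exists) and the needle tip at step k of a straight
trajectory with an angle drawn uniformly in [40°, 60°]. Scenario 1
(heart-like) runs 20 interventions on dynamic backgrounds; scenario 2
(lesion-like) runs 14 interventions each on a single static slice, with
frame-to-frame variation coming entirely from the per-frame re-draw of
the background scatterers. With three dynamic ranges this yields exactly
2,880 and 2,016 images.

Annotation conventions: the needle tip sits exactly at the *left-bottom
corner* of its square box (display coordinates, y down: corner =
(min-x, max-y)); box side defaults to 24 px and must lie in [20, 30] px;
boxes that would be clipped at the border are rejected and the frame
flagged, never shrunk. Target boxes are tight boxes of the masks after
the same geometric transform as the image. Internally boxes are stored
as COCO xywh (top-left), so export is a direct serialization. The 80%
train split is a uniform per-image draw (`round(0.8 N)`), with an
optional per-intervention grouping to avoid frame leakage.

## Detection metric

Greedy score-descending matching (ties by insertion order), each ground
truth matched at most once, match requires IoU ≥ threshold; AP is the
COCO-style 101-point interpolated area under the PR curve; mAP averages
over thresholds 0.50:0.05:0.95 and over the classes present in the
ground truth with equal weights. Conventions for empty sets: empty GT
with no detections → 1.0; empty GT with detections → 0.0. No
max-detection caps or area ranges are applied. The test suite checks the
implementation against an independently written brute-force evaluator on
random small scenes (agreement within 0.01) and verifies that a
jittered-ground-truth oracle detector traces a monotone mAP-vs-jitter
curve.

## Homography calibration and reach decision

The world↔image map is a 3×3 homography estimated by the direct linear
transformation with Hartley similarity normalization on both point sets
(pre-conditioning; without it the DLT design matrix is badly scaled for
mm-scale coordinates). A near-2D nullspace of the design matrix (second
smallest singular value < 1e−9 × largest) is rejected as a degenerate
configuration. On noiseless correspondences the recovery is exact to
≈ 1e−15 relative; with σ mm of image noise the world-frame reprojection
RMSE lies in [0.5σ, 2σ].

For the reach decision, one straight trajectory per available holder
angle (default five, in (0°, 90°)) is sampled over the needle length in
the world frame and projected into the image; projective maps preserve
straight lines, which the tests verify as a line-fit residual. The
target point is the detected box's center (the natural aim point; which
point of a detected box to aim at is otherwise unconstrained). The
decision is reachable iff some trajectory sample within the needle
length passes within the tolerance of that center; ties between angles
break toward the smaller angle.

The in-vitro accuracy of this method depends on a physical rig (probe,
holder, motion capture) and is outside what synthetic data can
establish; the noise-consistency property above is the substitute the
package can honestly compute.

## Numerical choices and degenerate inputs

* Poisson-drawn scatterer counts, capped at the number of source pixels;
  requesting a mean above the pixel count is an error, not a silent cap.
* All randomness flows from `numpy.random.SeedSequence` spawning: one
  config seed → per-intervention → per-frame streams, so runs are
  bit-reproducible while frames stay independent.
* All-zero beamformed images render all-black instead of dividing by a
  zero envelope maximum.
* `tip == entry` produces an empty needle map (zero inserted area); a
  tip behind the entry point is a geometry error.
* Mask resampling between grids is nearest-neighbour through physical
  coordinates; bounding boxes are computed after resampling, never
  transformed directly.

## Problem sizes used by the test suite and acceptance script

Dry-run dataset assembly runs at the full preset scale (2,880 + 2,016
records). Rendered checks use the fast probe profile with reduced
scatterer densities (0.2 /λ² background, 2 /λ² needle — about 1,700 +
300 scatterers per frame) and a 96×96 beamforming grid; physics probes
use single- and few-scatterer maps where the expected answer is known in
closed form. The full-density scatterer statistics are still exercised
directly on full-size templates, where sampling is cheap even though
rendering would not be.

## Known limitations

* The simulator is in the family of research pulse-echo simulators
  (Field II, SIMUS) but is not bit-compatible with them; only physical
  invariants (echo timing, localization, linearity, speckle statistics)
  are matched, not any particular tool's waveforms.
* No elevation dimension, nonlinear propagation, multiple scattering or
  reverberation; no needle deflection model.
* Speckle from the fast profile's sparse maps is not fully developed;
  the Rayleigh-statistics check uses a dedicated dense map.
* The mAP values reported for trained detectors on real in-vitro data in
  the literature are not reproducible here by design — they require a
  trained network and physical acquisitions. The package evaluates
  detectors; it does not train them.
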