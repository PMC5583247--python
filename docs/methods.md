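# Methods

This note documents the models, estimators and numerical choices behind
`rsomotion`, what the synthetic worlds do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and timing conventions

Indices are 0-based; sinograms are `[ss][fs][t]` (slow axis outermost),
volumes `[x][y][z]` with `x` the fast axis and `z` depth (downward
positive). Time sample 0 coincides with the laser pulse, and optoacoustic
propagation is **one way** (light in, sound out): `depth = t·c`, not halved
as in pulse-echo ultrasound. The virtual focal point of the focused
detector sits `focal_length` below the detector plane, so an on-axis source
at depth `z` arrives at `t = z/c` regardless of focal length. Defaults:
`c = 1500 µm/µs` (soft tissue; the source instruments never state a value),
sampling 500 MHz, `n_t` sized to cover the focus plus 2 mm of tissue.
Motion sign convention, used everywhere: **positive offset = surface
farther from the detector = later arrival**.

## Forward model

The simulator treats the focused detector as a virtual point detector at
its focus: a source at distance `r` below the focus arrives at
`t_focal + r/c`, restricted to the acceptance cone
`tan θ = aperture/(2·focal length)`, with amplitude `∝ f/(f+r)` (1/distance
from the detector, normalised to ≈1 at the focus). This makes the forward
model *exactly* consistent with the delay-and-sum beamformer — deliberate:
residual reconstruction error then measures motion and estimator error, not
model mismatch.

Sources:

* **Spheres** (capillary loops, vessel segments): a uniformly absorbing
  sphere radiates the analytic N-wave, `p(t) = −t/(r/c)` for
  `|t| ≤ r/c`, odd-symmetric with leading compression. Vessels are chains
  of spheres at 10 µm spacing.
* **Surface sheet**: the melanin layer is discretised into point sources at
  half the scan step (below the scan sampling, so its wave front is
  continuous in the Huygens sense); per-point amplitude is normalised by
  patch area, making the result pitch-independent. Each point radiates a
  small-radius (5 µm) N-wave.
* **Lens artifact**: the same surface points, delayed by an extra 600 µm
  and scaled by `artifact_gain` (default 0.5× the surface amplitude),
  radiate a one-cycle 2 MHz Gabor wavelet — the centre of the 1–3 MHz
  band in which the footprint appears. The artifact is added **after** the
  detector band filter, because physically it is generated inside the
  detector (shear waves in the acoustic lens exciting lateral piezo modes)
  and is recorded despite lying far below the acoustic detection band; a
  literal band-limitation of everything would erase the very footprint the
  hairy-skin tracker needs.

The detector band response is a zero-phase order-3 Butterworth bandpass
(`|H| ≤ 1`, so energy never grows); acquisition noise is white Gaussian.
Motion is sampled on the acquisition timeline `t = (ss·n_fs + fs)/PRR` as
`A·sin(2πf·t + φ)` plus Gaussian jitter, evaluated once per B-scan in
`per_bscan` mode (the clinical regime: motion between, not within,
fast-axis sweeps) or per A-scan. Everything is seeded and bit-reproducible.

**Not emulated**: acoustic attenuation and dispersion, refraction at
coupling interfaces, optical fluence, speckle, detector directivity beyond
the cone, hair shafts. A green test therefore establishes that the
*algorithm* recovers the motion it is designed for under realistic
kinematics, band structure and noise — not that it survives every
confounder of in-vivo data.

## Surface detection

**Hairless** (`detect_surface_hairless`): per-A-scan Hilbert-envelope
argmax → robust full 2-D quadratic fit `t̂(fs, ss)` (6 coefficients,
iteratively reweighted least squares with Huber weights, 2 reweighting
passes — so the slab follows anatomy, not motion outliers or a bright
vessel that captures a minority of argmaxes) → re-detection restricted to
`t̂ ± slab_half_samples` (default 50). Precondition: the stratum-corneum
echo dominates and is separated from deeper structures; an all-zero input
or a peak less than 4× the median envelope raises `NoSurfaceError`.

**Hairy skin** (`detect_surface_lowfreq`): exponential bandpass 1–3 MHz
(frequency-domain window, unity in-band with `exp(−Δf/rolloff)` skirts,
rolloff 0.5 MHz, exactly zero-phase) → envelope → coarse time segmentation
by the maximal-energy sliding window (default 2 µs ≈ 3 mm) over the
scan-averaged envelope → per-A-scan argmax inside that interval. Absence
gates: in-band RMS below 10⁻⁶ of the raw RMS, or a scan-averaged envelope
whose maximum is less than 2× its median (band-limited noise averaged over
all scan points is flat), raise `NoFootprintError`.

**Sub-sample refinement.** The envelope argmax is the coarse stage; the
sub-sample estimate comes from phase-coherent cross-correlation against a
scan-averaged template (the standard RF speckle-tracking estimator): traces
are aligned by their integer argmax, averaged into a complex analytic
template, and each trace's delay is the integer correlation peak minus
`∠C/2πf₀` with `f₀` the template's spectral centroid. Rationale: the
1–3 MHz envelope is ~0.5 µs wide, so a plain (even least-squares) parabolic
envelope fit jitters by ~2 samples at 20 dB SNR — an incoherent estimator
near its own bound — while the carrier phase localises the same waveform to
~0.4 samples (≈1 µm). Offsets below one sample matter at 4 µm axial
resolution. Cycle slips are prevented by the integer search window (a
quarter period of the band edge) around the coarse peak.

## Correction

The synthetic smooth surface is a separable uniform moving average with
spans 200 (ss) × 10 (fs) pixels — the spans reported to work best
clinically — clamped to the grid when the scan is smaller. Spans are used
exactly as given (even sizes follow scipy's origin convention, half a pixel
towards smaller indices); edges use reflective padding, avoiding offset
bias where the breathing phase is arbitrary. Offsets are
`dz = (t_detected − t_smoothed)·c/f_s`, estimated per A-scan (median
aggregation per B-scan is available for fast scans).

Applying the correction, primary form: each scan point's focal point moves
to `focal_length − dz` in sample coordinates. The sign is fixed by the
forward model — shifting all sources by `+dz` is identical to shifting the
focus by `−dz` — which makes the corrected-geometry reconstruction exact.
The alternate form advances each A-scan by `dz/c` via an FFT phase ramp
(band-limited interpolation, preserving wideband content). The two forms
agree in localization and peak amplitude, but not voxel-for-voxel: the time
shift mis-times off-axis contributions by `(1−cos α)·dz`, up to ~0.9
samples at the f/1.1 cone edge for `dz = 30 µm`; the measured voxelwise
difference scales linearly with `dz` (~5 % at 3 µm, ~23 % at 30 µm on
20–180 MHz content). Offsets beyond a configurable 500 µm sanity bound
raise `SuspiciousMotionError`.

## Reconstruction and metrics

Virtual-detector delay-and-sum with delays `t_focal ± |v − focus|/c`
(+ below / − above focus), uniform apodization, cone gating, linear
interpolation into the A-scan, Hilbert-envelope magnitude along depth after
summation (preserving interference rather than rectifying first). Default
voxel pitch: scan step laterally, `c/(2f_s)` (1.5 µm) axially; the
benchmarks use 3 µm axially, still above Nyquist for the 180 MHz band edge,
to keep runtimes in minutes. The inner loop is numba-compiled with a
pure-numpy reference implementation cross-checked in the tests.

Sub-band splitting uses zero-phase order-3 Butterworth bandpasses
(20–60 / 60–180 MHz and 14–42 / 42–126 MHz presets). Equalization divides
each sub-band volume by its own 99.9th percentile (robust to single hot
voxels — the unspecified alternative, the maximum, is fragile) and clips to
[0, 1]; equalization is done in 3-D, not per MAP.

CNR per depth plane is `20·log₁₀(R_max(z)/noise_max)` with `noise_max` the
maximal amplitude above the skin surface minus a 30 µm guard band (our
choice; it excludes high-band surface side lobes, though the low band's
~37 µm axial main lobe necessarily straddles it). Planes without signal are
NaN, an identically zero noise region is an error. Line-profile FWHM
samples bilinearly, detects peaks above 20 % of the profile maximum, and
interpolates the half-maximum crossings linearly; neighbouring peaks whose
valley stays above half maximum merge into one plateau width.

## Spectral analysis

Per-voxel non-negative least squares unmixes co-registered per-wavelength
reconstructions against a chromophore extinction matrix (closed-form exact
solution for two chromophores, scipy NNLS otherwise; residual returned).
`sO2 = HbO2/(HbO2+Hb)`, voxels with total below `epsilon` flagged invalid.
Vessels are segmented at strictly greater than 20 % of the cuboid maximum
(Heaviside with strict inequality), and sO2 is averaged across the vessel
diameter slice-by-slice with the binary mask as the only weight; empty
slices are invalid, never interpolated. Each wavelength is motion-corrected
independently before unmixing (each shows its own artifacts), and the
1–3 MHz artifact band is filtered out before reconstruction, as is standard
— it only serves surface tracking. The bundled extinction table is a
synthetic, representative-shape fixture (labelled as such in its
docstring); it is an input, replaceable by a measured table.

## Benchmark worlds (the stated experiments)

* **Capillary resolution / CNR** (`experiments.motion_benchmark`,
  `presets.nevus`): 80×80 scan at Δ = 20 µm, 20–180 MHz / f-1.1 geometry,
  six 20 µm-radius spheres 300 µm below a flat melanin surface, breathing
  40 µm at 15 cycles/min plus 3 µm per-B-scan jitter, seeds 1–5. PRR
  500 Hz (not stated for this experiment; chosen so the 12.8 s scan holds
  ~3.2 breathing cycles, consistent with the slow effective pixel rates of
  high-resolution scanning). Reported: max over targets and seeds of the
  lateral FWHM ratio uncorrected/corrected in the high sub-band (profiles
  along the slow axis — per-B-scan motion blurs across, not within,
  B-scans), and max over depth and seeds of the CNR improvement per band.
* **Noise reference**: white-noise sd is set 20 dB below the peak echo of
  the *capillary targets* (25 dB for the vessel world), not the global
  sinogram peak. The specular melanin sheet is ~100× stronger than a
  capillary point echo; a global 20–30 dB reference would put the
  structures under study below the noise floor — a world in which
  capillary-resolving mesoscopy images could not exist at all. The
  surface-tracking worlds, where the surface itself is the structure under
  study, use the global peak.
* **Motion recovery / round trip** (`surface_recovery`, `round_trip`):
  compact 32×64 scan, flat surface, breathing ~8 cycles across the slow
  axis, 20 dB SNR; estimated offsets vs. injected trace, both detection
  methods; then correct via the time-shift form and re-estimate. The
  hairless variant carries no lens artifact (its regime is a clean,
  separable surface echo).
* **sO2 stability** (`so2_benchmark`, `presets.vessel_grid`): two
  wavelengths (560/578 nm of the fixture table), a 50 µm-radius vessel
  along the slow axis at sO2 = 0.65, independent breathing phase and
  jitter per wavelength, 30 µm amplitude, seeds 1–5; corrected profiles
  are compared with truth, uncorrected vs. corrected peak-to-peak
  fluctuation per seed.

## Known limitations

* Single-scatter, lossless acoustics; no fluence model — unmixing accuracy
  on real multi-wavelength data would additionally require fluence
  correction.
* Lateral (x/y) motion, within-B-scan warping and inter-frame registration
  are out of scope; the correction is purely axial, as is the method it
  implements.
* The absolute surface position tracks the envelope peak of the patch
  echo, which lags the geometric wavefront by a few samples; this constant
  cancels in the detected-minus-smoothed difference and is irrelevant to
  the correction.
* `detect_surface_lowfreq` assumes one dominant footprint interval; strong
  late reverberations inside the 2 µs window would bias the coarse
  segmentation.
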