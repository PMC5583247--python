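# rsomotion

Motion correction for raster-scan optoacoustic mesoscopy (RSOM), with a
forward simulator, virtual-detector delay-and-sum reconstruction, and the
quantitative metrics (CNR, FWHM, sO2 profiles) needed to evaluate the
correction.

## The problem

RSOM scans a focused ultrasound detector over the skin on a fast (fs) and a
slow (ss) raster axis, recording one A-scan per laser pulse and
reconstructing the 3-D absorption map tomographically. A 250×250-point scan
at a 1 kHz pulse rate takes about a minute, during which breathing (up to
~30 cycles/min) and micromotion move the skin vertically relative to the
detector by tens of micrometres — enough to destroy the ~4 µm axial /
~20 µm lateral resolution, blur capillary loops beyond recognition, and
corrupt multi-wavelength oxygen-saturation readings.

The correction exploits the melanin-rich skin layers, whose ultrasound wave
front leaves a trackable footprint in the raw 3-D sinogram:

1. **Detect** the motion-corrupted surface per scan point — either from the
   stratum-corneum echo inside a robust 2-D parabolic segmentation slab
   (hairless skin), or from the characteristic 1–3 MHz lens-artifact
   footprint ~600 µm below the surface (hairy skin), isolated with an
   exponential bandpass filter.
2. **Smooth** the detected surface with a 200 (ss) × 10 (fs) pixel moving
   average — the artificial continuous surface a motionless scan would
   have produced.
3. **Correct**: the per-scan-point difference, converted to micrometres by
   the one-way time-of-flight `dz = Δt·c`, is the vertical skin motion;
   reconstruction displaces each scan point's virtual focal point by `−dz`
   (equivalently, advances the A-scan by `dz/c`).

Reconstruction is a virtual-detector (SAFT) delay-and-sum: voxel delays are
`t_focal ± |v − focus|/c` inside the acceptance cone set by the f-number,
followed by Hilbert-envelope detection, with low/high frequency sub-bands
(20–60 / 60–180 MHz or 14–42 / 42–126 MHz) equalized and overlaid red/green.

Because the human datasets behind the original experiments are not public,
the package ships a forward simulator (melanin surface sheet with the
lens-artifact footprint, spherical capillary/vessel absorbers radiating
N-wave pulses, sinusoidal breathing plus jitter, detector band response,
noise) so every stage is testable end to end against known ground truth.

## Worked example

Library use (statsmodels-style model/results):

```python
from rsomotion import MotionCorrection, beamform, presets, sample_motion, simulate_sinogram

setup = presets.nevus()                      # 80x80 RSOM100 scan, 6 capillary targets
motion = sample_motion(setup.motion, setup.geometry, seed=1)
sino = simulate_sinogram(setup.phantom, setup.geometry, motion=motion)

res = MotionCorrection(sino, method="lowfreq").fit()
print(res.summary())
vol = beamform(sino, offsets=res.offsets)    # corrected reconstruction
```

Or the end-to-end CLI demo (48×48 scaled scan):

```bash
rsomotion demo --preset nevus --seed 1 --out-dir demo_out
```

which prints (output of this exact command):

```
Motion correction results
=============================================
surface method     : lowfreq
scan grid          : 48 (ss) x 48 (fs), step 20 um
smoothing spans    : 200 (ss) x 10 (fs) px
offset RMS         :    26.92 um (8.97 samples)
offset peak-to-peak:    93.97 um
offset mean        :   -0.433 um
dominant motion    :     13.0 cycles/min
=============================================
band  max_cnr_uncorrected_db  max_cnr_corrected_db  max_delta_cnr_db  seed  offset_rms_um
 low                  7.9108                5.3098            6.4098     1        26.9178
high                  2.7722                7.9966           13.1803     1        26.9178
```

Reading it: the tracker recovered a 94 µm peak-to-peak breathing motion
(~13 cycles/min estimated from the offset series, vs. 15 injected on this
short 4.6 s scan), and correcting the detector geometry raised the
contrast-to-noise ratio by up to 13 dB in the high sub-band, where motion
blur hurts most. The demo directory holds the sinogram, surface maps,
offset map, four sub-band volumes, the red/green overlay MAP and the
metrics CSV.

Other subcommands — `simulate`, `detect-surface`, `correct`, `reconstruct`,
`metrics`, `so2` — each re-runnable from their on-disk HDF5/TIFF/CSV
inputs; see `rsomotion --help`.

## Acceptance benchmark

`scripts/acceptance.py` recomputes the headline gains from scratch — it
simulates the capillary-loop experiment (six 20 µm-radius spheres 300 µm
deep, 80×80 scan at 20 µm step, 40 µm breathing at 15 cycles/min plus 3 µm
per-B-scan jitter, five consecutive seeds), runs the full
detect → smooth → correct → sub-band reconstruction pipeline with and
without correction, and measures:

* `t1` — max fold-improvement of lateral capillary FWHM (high sub-band),
* `t2` — max CNR improvement over depth in the high sub-band (dB),
* `t3` — the same in the low sub-band (dB).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runs in about a minute on one CPU.
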