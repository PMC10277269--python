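# usimgen

Synthetic, annotated, clinical-like 2D interventional ultrasound images
from 3D volumes — plus the evaluation and calibration tools that go with
them.

Training detectors for needle-tip and target localization in ultrasound
(US)-guided interventions is blocked by a lack of annotated
interventional data. `usimgen` addresses this for researchers in
US-guided robotics and interventional imaging by simulating whole
needle-insertion sequences: a pre-operative 3D volume (MRI/CT-like, or
one of the built-in synthetic phantoms) supplies speckle texture and
target anatomy, an artificial needle supplies the tool, and a pulse-echo
simulator renders B-mode frames whose annotations come for free from the
known geometry.

## What it computes

**Image formation.** A template slice `I_gb` is turned into a map of
point scatterers: random pixels with reflection coefficients
`C_b = I_gb(pixel)` at a density of 6 per squared wavelength; the
inserted part of the needle (⌀ 1.52 mm, 200 mm) is filled at 10 /λ² with
coefficients `C_n ~ U[max(C_b)/4, max(C_b)]`. A convex array (192
elements, 73° field of view, 2–6 MHz band) transmits a single diverging
wave; each element receives

```
rf_e(t) = Σ_i  C_i · D_e(θ_i) / (r_tx r_rx) · p(t − τ_tx(i) − τ_rx(i, e)),
```

with `p` a Gaussian-windowed sinusoid at 4 MHz. The RF is IQ-demodulated,
delay-and-sum beamformed on a sector grid, log-compressed to a dynamic
range DR ∈ {25, 30, 35} dB (`20·log10(env/max)`, clipped to [−DR, 0],
mapped to [0, 255]) and scan-converted.

**Datasets.** Two presets: *scenario 1* — 20 interventions on a
low-contrast, slice-to-slice-varying heart-like target, 8 template
slices cycled under a 48-step insertion at 40–60°, 3 dynamic ranges
(2,880 images); *scenario 2* — 14 interventions on static lesion-like
slices whose frames differ through per-frame scatterer re-draws
(2,016 images). The needle tip is annotated as the left-bottom corner of
a 20–30 px bounding box; targets get tight mask boxes; export is
COCO JSON with an 80/20 split.

**Evaluation.** `detect_eval` scores any detector with mean average
precision averaged over IoU thresholds 0.50:0.05:0.95 (COCO 101-point
interpolation) and over the needle/target classes.

**Fine positioning.** `reach` estimates the planar homography `H`
between an external (motion-capture) frame and the US image frame by the
direct linear transformation with Hartley normalization, projects
candidate needle trajectories (one per mechanical holder angle) into the
image via `p^u ≃ H p^o`, and decides whether a detected target box is in
reach of the needle.

## Worked example

```python
from usimgen import config as cfgmod
from usimgen import detect_eval as de
from usimgen.dataset import split

cfg = cfgmod.scenario1_preset(seed=0)
cfg.n_interventions, cfg.n_frames = 2, 6        # reduced for the example
manifest = cfgmod.run_scenario(cfg, out_dir="demo", dry_run=False)
print(f"records: {len(manifest)}")

train, test = split(manifest, 0.8, seed=0)
print(f"train/test: {len(train)}/{len(test)}")

gts = [a for r in manifest.records for a in r.annotations]
for j in (0.0, 3.0):
    dets = de.jitter_oracle_detections(gts, j, seed=0)
    print(f"mAP[0.50:0.95] at {j:.0f} px jitter: "
          f"{de.map_over_thresholds(dets, gts):.3f}")
```

Output:

```
records: 36
train/test: 29/7
mAP[0.50:0.95] at 0 px jitter: 1.000
mAP[0.50:0.95] at 3 px jitter: 0.589
```

The 36 records are 2 interventions × 6 frames × 3 dynamic ranges, each a
rendered PNG in `demo/` with needle and target annotations
(`demo/annotations_coco.json`). The mAP lines score a synthetic "oracle
detector" (ground-truth boxes plus positional jitter): exact boxes give
a perfect 1.000, and 3 px of jitter on 24 px boxes already costs ~0.4 of
mAP under the strict high-IoU thresholds — the metric behaves as it
should.

The same pipeline is scriptable from the shell:

```bash
simgen scenario1 --out out/ --dry-run        # 2,880-record manifest, no rendering
simgen scenario2 --out out2/ --dry-run       # 2,016 records
simgen eval --gt gt.json --dets dets.json    # mAP of a detections file
simgen calibrate --pairs pairs.csv --out H.json
simgen reach --h H.json --target bbox.json --tolerance 2
```

## Layout

- `usimgen.phantom` — synthetic 3D volumes (lesion-like, heart-like) and
  fiducial layouts; NIfTI I/O.
- `usimgen.preprocess` — salient-slice selection, sector cropping,
  template resampling.
- `usimgen.scatterers` — background and needle scatterer maps, insertion
  trajectories.
- `usimgen.ussim` — probe model, RF simulation, IQ demodulation,
  delay-and-sum, B-mode, scan conversion.
- `usimgen.dataset` — interventions, annotations, COCO export, splits.
- `usimgen.detect_eval` — IoU / AP / mAP and the oracle detector.
- `usimgen.reach` — DLT homography, trajectory prediction, in-reach
  decision.
- `usimgen.config` / `usimgen.cli` — scenario presets and the `simgen`
  command line.

See `docs/methods.md` for the models, defaults, and known limitations.
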