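# slovasc

Retinal vessel morphometry for en face infrared-reflectance scanning laser
ophthalmoscopy (SLO) images.

SLO localizer images are captured alongside nearly every OCT scan and show
the superficial retinal vasculature at high contrast over a ~30° field of
view (~9 mm, so 768 px ≈ 11.72 µm/px), yet they are routinely discarded.
`slovasc` turns a grayscale SLO image plus a segmentation (user-supplied,
manually corrected, or a built-in classical baseline) into quantitative
vascular parameters per vessel class (all-vessel / artery / vein) and region
of interest, for researchers linking retinal vascular phenotypes to ocular
and systemic disease.

## What it measures

For a binary vessel map *V*, its skeleton *S*, and vessel segments
(skeleton paths whose end points are bifurcations or arteriovenous
crossings):

- **Vessel density** — |V ∩ ROI| / |ROI|.
- **Fractal dimension** — Minkowski–Bouligand box counting: FD = −slope of
  log N(s) vs log s over dyadic grid sizes s.
- **Global caliber** — |V| / |S| (pixels; microns when the spatial scale is
  known).
- **Local caliber** — per-segment mean width from the Euclidean distance
  transform (2·EDT at skeleton points, evaluated on a 4× upsampled mask),
  length-weighted across segments.
- **Tortuosity density** — the Grisan segment measure
  TD = (n−1)/n + (1/L)·Σᵢ(Lᵃᵢ/Lᶜᵢ − 1), where the segment is split at
  curvature-sign inflections into n sub-arcs with arc/chord lengths
  Lᵃᵢ/Lᶜᵢ and L is the total arc length; a straight segment scores 0.
- **CRAE / CRVE / AVR** — central retinal artery/vein equivalents from the
  six widest segments by iterative Knudtson pairing,
  ŵ = k·√(w₁² + w₂²) with branching coefficients k = 0.88 (arterioles) and
  k = 0.95 (venules), and the ratio AVR = CRAE/CRVE.

Regions of interest are the whole image (always) plus, for disc-centered
images, the standard peripapillary annuli around the fitted optic-disc
ellipse of diameter D: zone B (0.5D–1D from the margin, i.e. radii
[D, 1.5D]) and zone C (0D–2D, radii [0.5D, 2.5D]). Density, FD and global
caliber are whole-image metrics; local caliber and tortuosity density are
computed in every ROI; CRAE/CRVE/AVR attach to artery/vein/all rows in
every ROI.

The package also ships:

- a **synthetic scene generator** (`slovasc.synthetic_data`) producing
  SLO-like images with exact masks and analytically known widths, arc
  lengths and tortuosities, so the whole pipeline is testable offline;
- **reproducibility statistics** (`slovasc.evalstats`): Dice, rank-based
  AUC, MAE, Bland–Altman limits of agreement, consistency ICC(3,1) with
  F-based CI, and the per-eye measurement-noise statistic λ (within-eye SD
  as a percentage of between-eye SD);
- a **batch pipeline and CLI** with process logs, overlay visualizations,
  a collated CSV (optional XLSX mirror), and a manual-correction loop: save
  `<stem>_labels_corrected.png` next to a saved mask and re-run to recompute
  that image's measurements.

The deep segmentation networks of production tools are out of scope; the
segmentation stage is pluggable, with a deterministic classical baseline
(multiscale Hessian ridge filter, smoothed-minimum fovea search, bright-blob
disc detection) standing in so everything downstream can be exercised.

## Worked example

```python
from pathlib import Path
from slovasc import synthetic_data as sd, pipeline as pl
from slovasc.io_formats import PipelineConfig

# a disc-centered synthetic right eye, written with its ground-truth masks
spec = sd.default_scene_spec(location="disc", laterality="right", seed=7)
image, truth = sd.generate_scene(spec)
sd.write_scene(image, truth, Path("scenes"), "demo_eye", scale_um_per_px=11.71875)

cfg = PipelineConfig(masks_dir="scenes")
records, log, artifacts = pl.run_single(Path("scenes/demo_eye.png"), cfg, Path("out"))
```

This prints (via the record fields) the following, on this exact scene:

```
status: ok, rows: 9
location=disc, laterality=right, disc D=114.296 px
whole-image all-vessel: density=0.0650, FD=1.364, global caliber=105.4 um
zone B artery: local caliber=78.2 um, tortuosity density=0.374, CRAE=122.0 um
zone B vein:   local caliber=102.2 um, tortuosity density=0.263, CRVE=184.6 um
```

Nine rows = 3 vessel classes × 3 ROIs (whole, zone B, zone C): a
disc-centered image gets the peripapillary zones, and metrics are in microns
because the scale (11.71875 µm/px) was supplied. The veins read wider than
the arteries (the generator draws arteries at 0.8× vein width), which is why
CRVE > CRAE. The same analysis runs from the shell:

```bash
slovasc synth --n-scenes 5 --location disc --seed 7 --out-dir scenes --scale 11.71875
slovasc analyze --input scenes --output out --masks-dir scenes
slovasc repro out1/collated_metrics.csv out2/collated_metrics.csv --out repro.csv
```

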