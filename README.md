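# octavd

Episcleral vessel-density quantification and longitudinal sector analysis
for anterior-segment OCT angiography (AS-OCTA).

## The problem

Trabecular bypass MIGS devices (e.g. a Schlemm's-canal microstent spanning
~90° of one quadrant) are meant to increase aqueous humour outflow into the
episcleral venous plexus. AS-OCTA images that plexus non-invasively: each
eye is scanned in six corneolimbal sectors (superior, superior-nasal /
inferior-temporal, nasal, inferior-nasal, inferior, temporal), and each en
face angiogram is reduced to a **vessel density**

```
VD = 100 · P / A
```

where `P` is the number of pixels classified as vessel and `A` the scan
area in pixels. Following surgery, the VD of the implant-carrying sector is
compared longitudinally against two fixed opposing control sectors of the
same eye (superior-nasal implant → inferior + temporal controls;
inferior-nasal → superior + temporal; inferior-temporal → superior +
nasal), with the Wilcoxon signed-rank test at each follow-up visit against
baseline and the Friedman test across the follow-up series.

`octavd` implements that entire measurement chain for researchers working
with en face AS-OCTA exports:

1. **preprocess** — directional FFT bandpass: removes horizontal
   motion-stripe artifacts (full-width rows from eye motion with the
   tracker off) and large-scale illumination gradients;
2. **segment** — median + Gaussian denoising, multiscale Hessian (Frangi)
   vesselness with bright-vessel convention
   `V = exp(−R_B²/2β²)·(1−exp(−S²/2c²))` for λ₂ < 0, and local adaptive
   thresholding with small-object removal;
3. **quantify** — whole-frame and dye-mask-restricted VD (for validation
   against intra-operatively trypan-blue-labelled outflow vessels);
4. **cohort_stats** — the sector design: control assignment, index-sector
   selection, exact/approximate Wilcoxon signed-rank, tie-corrected
   Friedman with an exact permutation option, mean differences with
   paired-t 95% CIs;
5. **phantom** — a synthetic generator (vessel networks, OCT speckle,
   motion stripes, cohort-level effect simulation) so every stage is
   testable with known ground truth and no patient data.

## Worked example

```python
import numpy as np
from octavd import (PipelineConfig, VesselParams, NoiseParams, make_phantom,
                    fft_bandpass, segment_vessels, vessel_density,
                    simulate_cohort, serial_analysis)

# 1. a phantom angiogram with known ground truth
scene = make_phantom(VesselParams(), NoiseParams(), seed=1,
                     eye_id="eye001", sector="superior_nasal",
                     layer="episcleral", visit="pre", implant=True)
print(f"ground-truth VD: {scene.truth_vd:.1f}")

# 2. the image pipeline
cfg = PipelineConfig()
filtered = fft_bandpass(scene.image.pixels, cfg.preprocess)
mask = segment_vessels(filtered, cfg.segment)
print(f"pipeline VD:     {vessel_density(mask):.1f}")

# 3. longitudinal cohort analysis on a simulated 25-eye cohort
cohort = simulate_cohort(seed=1)
rep = serial_analysis(cohort)
m1 = rep.report["groups"]["implant"]["wilcoxon_vs_baseline"]["month1"]
print(f"implant month 1: mean difference {m1['mean_difference']:.2f} "
      f"(95% CI {m1['ci95'][0]:.2f} to {m1['ci95'][1]:.2f}), "
      f"p = {m1['p_value']:.3f}, n = {m1['n']}")
```

prints

```
ground-truth VD: 25.0
pipeline VD:     25.0
implant month 1: mean difference -1.93 (95% CI -3.30 to -0.56), p = 0.010, n = 23
```

The phantom's vessel network covers exactly 25.0% of the frame; the full
preprocess → segment → quantify chain recovers 25.0 VD units on this seed.
The simulated cohort carries an implant-sector VD drop from 25.6 at
baseline to 22.5 at month 1 with realistic between-eye and measurement
noise; the within-eye paired Wilcoxon test detects it (p = 0.010 on 23
pairs) while control sectors stay null.

## Command line

```
octavd simulate --outdir phantoms --seed 3 --n-images 6   # cohort CSV + phantom TIFFs
octavd segment  --in scan.tif --out mask.tif              # one image -> 0/255 mask
octavd quantify --manifest manifest.csv --out vd.csv      # manifest -> VD table
octavd analyze  --vd-table vd.csv --layer episcleral      # longitudinal statistics
octavd run      --manifest manifest.csv --outdir out      # the whole chain
```

Every run writes its fully resolved YAML configuration and the package
version next to its outputs.

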