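# sff-imaging

Spectral Fiedler field (SFF) contrast mapping for B-mode ultrasound cine
sequences.

Contrast agents that accumulate slowly in tissue — echogenic liposomes in a
tumor, for instance — produce subtle intensity changes that direct
pixel-by-pixel subtraction of a baseline frame cannot separate from gain
drift, bright static artifacts (skin line, reverberation) and speckle noise.
This package maps each grayscale frame into a *texture-contrast* image
instead: every pixel's neighborhood is converted into a graph whose nodes
are the neighborhood's columns, connected where the radial-basis similarity

&nbsp;&nbsp;&nbsp;&nbsp;ω<sub>ij</sub> = exp(−‖x<sub>i</sub> − x<sub>j</sub>‖² / 2σ²) ≤ r,

and scored by the Fiedler value λ₂ — the smallest non-zero eigenvalue of the
normalized graph Laplacian 𝓛 = D<sup>−1/2</sup>(D − S)D<sup>−1/2</sup>.  The
more the local pixel intensities vary, the more connected the graph and the
larger λ₂.  Low-pass filtering the per-pixel λ₂ matrix **C** gives the SFF
map **F**; contrast change at time t is **V**<sub>t</sub> = **F**<sub>t</sub> −
**F**<sub>0</sub> against the pre-injection baseline, after rigid motion
compensation by exhaustive normalized-cross-correlation ROI tracking.
Because a static bright structure has the same connectivity at every time
point, it cancels in **V**<sub>t</sub> even though it dominates a raw
difference image.

The package provides, as library modules and an `sff` command line:

- `sff.spectral` — patch graphs and their Fiedler values;
- `sff.transform` — whole-frame SFF maps, variation maps, ROI quantification
  and the conventional-subtraction baseline;
- `sff.motion` — rigid NCC tracking with feature-rich ROI fallback and
  median-intensity time series;
- `sff.downstream` — vessel-center extraction from **V**<sub>t</sub>, a 2-D
  point-source diffusion estimate of relative drug penetration, and
  two-sample t-test group comparisons;
- `sff.phantom` — a seeded synthetic speckle cine generator (accumulating
  blobs, static artifact bands, rigid motion, ground truth) so every stage
  is testable without animal data;
- `sff.pipeline` / `sff.cli` — end-to-end orchestration and I/O.

## Worked example

Generate the pinned synthetic acquisition, run the full pipeline, and
quantify the tumor ROI:

```python
import numpy as np
from sff import RunConfig, ROIMask, default_phantom_config, generate_cine
from sff.pipeline import run_pipeline

run = generate_cine(default_phantom_config(seed=1))
result = run_pipeline(
    run.frames, run.times, RunConfig(),
    ROIMask(mask=run.truth.tumor_roi, label="tumor"),
)
q = result.quantification
print(q[["frame_index", "sff_contrast", "percent_increment",
         "conventional_percent"]].iloc[[0, 10, 39]])
```

prints

```
    frame_index  sff_contrast  percent_increment  conventional_percent
0             0      0.744603           0.000000              0.000000
10           10      0.744664           0.008245             -0.685190
39           39      0.774520           4.017792              7.122268
```

Over 2 s of simulated accumulation the spectral ROI contrast rises 4%
against its pre-injection value, the mean-intensity quantifier 7% — but the
*origin* of the two signals differs: the spectral increment comes from the
accumulating blob, while a large share of the intensity change is gain
jitter and the bright band (at frame 10 the intensity quantifier has even
moved the wrong way).  The per-region signal-to-background comparison below
makes this difference quantitative.  The same pipeline is available from a
shell:

```
sff simulate --seed 1 --out sim/
sff run --input sim/cine.tif --roi tumor.json --out out/
```

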