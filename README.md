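# oralmark

Quantitative imaging biomarkers of oral mucosa from endoscopic optical
coherence tomography (OCT).

Oral lesions progress from benign changes through grades of dysplasia to
carcinoma, and early distinction between them is hard: benign lesions can
look like dangerous ones, and picking the most pathologic biopsy site
within a large lesion is guesswork under white light.  Endoscopic
rotary-pullback OCT images centimeters of mucosa in 3-D, but the volumes
are far too large for frame-by-frame expert reading.  `oralmark` turns
segmented OCT volumes of the lateral/ventral tongue into seven per-A-line
biomarkers that summarize subsurface tissue state for clinical researchers
working on biopsy-site selection and margin delineation:

| Category | Biomarker | Units |
|---|---|---|
| Morphologic | epithelial depth | µm |
| Morphologic | loss of epithelial–stromal boundary (per volume) | % |
| Attenuation | overall attenuation coefficient μ | mm⁻¹ |
| Attenuation | epithelium μ | mm⁻¹ |
| Attenuation | stroma μ | mm⁻¹ |
| Stratification | epithelial–stromal: (μ_E − μ_S)/(μ_E + μ_S) | a.u. |
| Stratification | intraepithelial: (μ_UE − μ_LE)/(μ_UE + μ_LE) | a.u. |

Attenuation is estimated depth-resolved under the single-scattering
round-trip model P(z) ∝ exp(−2μz): each pixel's linear power is normalized
by the integrated power beneath it, with a fitted geometric tail closure
for the truncated integral.  Where the epithelial–stromal boundary cannot
be segmented — increasingly common with disease grade — the entire
visualized depth (down to 6 dB above the noise floor) is treated as
epithelium and the A-line is flagged; the flagged fraction is itself a
biomarker.  Per-volume medians, taken over the azimuthally eroded
tissue-contact mask with artifacts excluded, feed a routed statistical
protocol (Shapiro–Wilk normality gate, then paired/unpaired t or
rank-based tests).

Because clinical volumes are not redistributable, the package includes a
seeded two-layer speckle phantom generator (dark epithelium over bright
stroma, multiplicative exponential speckle, additive noise floor,
loss-of-boundary regions, bubble shadows, contact-edge taper) with exact
ground truth, so the full measurement chain is testable end to end.
See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a speckled phantom of healthy-looking contralateral tissue
(160 µm epithelium, μ_e = 1.20 mm⁻¹, μ_s = 3.97 mm⁻¹), run the pipeline on
its ground-truth segmentation, and reduce to per-volume medians:

```python
from oralmark import phantom as ph, biomarkers as bm

vol, truth = ph.generate(ph.preset("contralateral", seed=1))
maps = bm.compute_all(vol, truth.surfaces, truth.masks)
s = bm.volume_summary(maps, truth.masks, role="contralateral")
for k, v in s.medians.items():
    print(f"{k:12s} {v:8.3f}  [{bm.BIOMARKER_UNITS[k]}]  (n={s.counts[k]})")
```

prints

```
depth_um      160.000  [um]  (n=12288)
mu_overall      3.602  [mm^-1]  (n=12288)
mu_epi          1.199  [mm^-1]  (n=12288)
mu_stroma       3.921  [mm^-1]  (n=12288)
es_strat       -0.532  [a.u.]  (n=12288)
ie_strat        0.001  [a.u.]  (n=12288)
loss_pct        0.000  [%]  (n=12288)
```

The medians recover the generating parameters: depth exactly, both layer
attenuation coefficients within 2% despite speckle, no spurious boundary
loss, and the expected strongly negative epithelial–stromal stratification
(stroma scatters more than epithelium) with near-zero intraepithelial
stratification (the phantom epithelium is optically uniform).  `n` counts
retained A-lines — the central 50% of each azimuthal contact run.

The same workflow is available from a shell:

```sh
oralmark simulate --profile contralateral --seed 1 --out sim/
oralmark compute  --volume sim/volume.tif --surfaces sim/surfaces.json \
                  --masks sim/masks --out maps/
oralmark summarize --maps maps/ --masks sim/masks --role contralateral \
                   --table table.csv
oralmark compare  --table table.csv --design paired --out report/
```

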