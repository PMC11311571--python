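# Methods

`oralmark` quantifies subsurface changes of oral mucosa (lateral/ventral
tongue) in endoscopic rotary-pullback OCT volumes.  Given a calibrated
intensity volume and per-A-line layer-surface segmentations, it computes
seven biomarkers — two morphologic, three attenuation, two stratification —
as en face maps, reduces each volume to per-biomarker medians, and compares
groups of volumes statistically.  A seeded two-layer phantom generator
provides ground truth for every stage, so the whole pipeline is testable
without clinical data.

## Geometry and preprocessing

Volumes are indexed (frame θ, pullback y, depth z).  Axial samples are
optical path length; physical depth divides by the refractive index of the
immersion medium (water, n = 1.333, configurable).  Before analysis each
frame is resampled to 10 µm square pixels in (y, z) with separable
not-a-knot cubic-spline ("bicubic") interpolation; interpolation runs on the
stored dB scale.  The not-a-knot boundary condition reproduces locally
polynomial data exactly up to the frame edges, which B-spline prefilter
implementations with constant/reflect padding do not.

Stored intensity is assumed calibrated dB; a sidecar flag `scale: linear`
converts linear power on load as 10·log10(P).  Conversion back to linear
power for attenuation estimation is P = 10^(I/10).

## Region definition

Per frame, the noise floor is the mean of the Gaussian-smoothed bottom 25
depth rows (250 µm), restricted to A-lines that contain tissue (an
epithelium surface).  The "5-pixel Gaussian kernel" is realized as a 2-D
kernel with σ = 1 px truncated to a 5×5 support (≈99% of mass inside) and
reflective borders; whether smoothing is 1-D or 2-D, and whether the 6 dB
comparison is made on smoothed or raw intensity, are genuinely open choices
— this package smooths in 2-D and thresholds the smoothed profile, both
stated here so phantoms and analysis agree.

The visualized region of an A-line runs from the epithelium top to the
first *sustained* drop below noise floor + 6 dB.  "Sustained" means k = 3
consecutive sub-threshold pixels, which rejects single-pixel speckle dips;
the bottom is capped at Z − 25 so the visualized region never overlaps the
noise-floor estimation window.  If the signal is sub-threshold already at
the surface the region is empty.

Region masks follow from the two surfaces: epithelium E = [top, boundary),
stroma S = [boundary, bottom).  Where the boundary is not resolvable the
entire visualized depth is treated as epithelium, S is empty, and the
A-line carries a loss-of-boundary flag — the fraction of such A-lines is
itself a biomarker, because boundary destruction accompanies invasion.
The epithelium splits into upper/lower halves (halves, not thirds, because
healthy epithelium spans only ~20–30 px here); an odd pixel count gives the
extra pixel to the upper half (arbitrary but fixed).

To mitigate "edge effects" — apparent thickening and boundary loss where
the probe grazes tissue tangentially at the azimuthal limits of contact —
per-volume medians retain only the central 50% of each azimuthal contact
run (runs shorter than 2 frames keep one frame so thin strips still
contribute).

## Depth-resolved attenuation

The attenuation coefficient μ (mm⁻¹) follows the single-scattering
round-trip model P(z) ∝ exp(−2μz).  The depth-resolved estimator divides
each pixel's signal by the remaining integrated signal beneath it.  Two
variants are provided:

* ratio form: μ[i] = I[i] / (2(Δ·Σ_{j>i} I[j] + T)) — the familiar
  linearized estimator; it carries an O(μΔ) discretization bias
  (≈ +2% at μ = 2 mm⁻¹, +4% at μ = 4 mm⁻¹ for Δ = 10 µm);
* log form (default): μ[i] = ln(1 + Δ·I[i]/(Δ·Σ_{j>i} I[j] + T)) / (2Δ) —
  exact on noiseless exponentials at any μΔ.

T closes the truncated tail of the sum with a geometric series,
T = Δ·I[N−1]·r/(1−r), r = exp(−2·μ_tail·Δ), with μ_tail from a log-linear
least-squares fit over the last m = 10 px (100 µm) of the visualized
region; for small μΔ this reduces to the textbook I[N−1]/(2μ_tail).  A
non-decaying tail fit falls back to the uncompensated sum and is flagged.

Pipeline conditioning before estimation: the per-frame noise-floor power is
subtracted in the linear domain (otherwise the additive floor flattens the
apparent decay near the visualized bottom, biasing μ low by tens of
percent there), and a 5-A-line lateral moving average of linear power
suppresses speckle (per-pixel exponential speckle enters the log estimator
with a negative bias of order 2μΔ per unit variance; averaging n A-lines
divides that variance by n).  Both are standard practice and configurable
(`PipelineConfig`).  Negative estimates are clipped to zero.  No
confocal/PSF correction is applied; absolute μ values are therefore
system-specific.

Region reduction: per A-line, μ is averaged (mean, matching the mean en
face projection convention) over the visualized depth ("overall"), the
epithelium, and the stroma; the stroma entry is missing on loss-of-boundary
A-lines.

## Stratification

For each A-line, stratification is (μ_a − μ_b)/(μ_a + μ_b) ∈ [−1, 1]:
epithelial–stromal (E vs S) and intraepithelial (upper vs lower half).
It is computed per A-line from the region means and then summarized by the
median — not as the ratio of summary medians — because the feature is
defined per A-line; on published per-patient median pairs the two routes
agree to two decimals, which the acceptance checks exploit.  Swapping the
regions negates the value exactly.

## Per-volume summary and statistics

Each biomarker reduces to one median per volume over the eroded contact
mask, excluding artifacts, and (for lesion volumes) restricted to the
labelled lesion area; missing entries are skipped.  The loss-of-boundary
percentage is computed once per volume (loss ∧ ¬artifact over tissue ∧
¬artifact) and passed through.

Statistical routing: Shapiro–Wilk (α = 0.05) on the pooled per-volume
medians of a feature decides parametric vs non-parametric.  Paired designs
use the one-sample t test on differences or the Wilcoxon signed-rank test;
unpaired designs use Welch's t test or the Mann–Whitney U test; missing
pairs drop pairwise.  Two naming conventions are deliberately resolved:
"Welch's paired t test" is implemented as the one-sample t on paired
differences (an unequal-variance correction is undefined for a single
difference sample), and the paired non-parametric comparison is the
signed-rank test (a rank-sum test would ignore pairing).  Identical paired
samples yield p = 1 rather than an error.  For future-progression
analysis, lesions are normalized by subtracting the patient's contralateral
median; unmatched patients are excluded and logged.  Auxiliary tests:
Spearman's ρ against age, Levene's test for variance homogeneity, and a
two-sided Grubbs outlier test (t-distribution critical value).  p values
are reported uncorrected at a fixed 0.05 threshold, reflecting the
hypothesis-generating framing.

## Phantom generator

The phantom emulates a two-layer mucosa in linear power,
P(z) = B_layer · exp(−2∫μ dz), with:

* layer interfaces quantized to the pixel grid so generated membership,
  path lengths, and truth surfaces agree exactly;
* fully developed speckle as multiplicative unit-mean exponential noise in
  intensity (unit mean preserves the expected decay, so attenuation
  recovery is unbiased in expectation);
* a deterministic additive noise floor in linear power (default −50 dB)
  applied before dB conversion, which makes the 6 dB rule meaningful;
* loss-of-boundary regions where the stromal backscatter step is
  suppressed and epithelium-like decay continues to the floor;
* bubble artifacts as 30 dB-shadowed vertical stripes;
* contact loss outside the contact mask (floor-level signal) plus a linear
  dB roll-off taper (default 6 frames, 20 dB) at the ends of each contact
  run, a minimal model of edge effects sufficient to exercise the erosion.

Backscatter amplitudes: stroma 1.0; the epithelium default derives from
the single-scattering consistency condition that backscattered power is
proportional to the scattering coefficient — on the discrete grid,
B ∝ 1 − exp(−2μΔ) (≈ 2μΔ) — giving a darker epithelium under a brighter
stroma and making depth-resolved estimates unbiased in the upper layer
too.  An explicit `backscatter_epi` overrides this; departures from
proportionality bias upper-layer estimates by roughly the proportionality
mismatch, a documented limitation of all estimators of this family.

Presets encode reported group medians as study conditions: `contralateral`
(160 µm depth, μ_e = 1.20 mm⁻¹, μ_s = 3.97 mm⁻¹, no loss),
`observation_lesion` (280 µm, μ_e = 1.45, μ_s = 3.70, 6% loss, bubbles, a
central lesion label), and `intervention_lesion` (400 µm nominal depth,
μ_e = 1.60, μ_s = 3.10, boundary unresolvable over 77% of tissue
A-lines).  Values not reported anywhere (surface offset 50 µm, floor
−50 dB, taper geometry, backscatter scale) were fixed once at values
typical of endoscopic oral OCT.  Default grids are 64 frames × 512
A-lines × 220 depth px (2.2 mm) — deep enough that the bottom 25 rows are
signal-free, which the noise-floor rule silently requires — and keep
full-pipeline runs to a few seconds; tests use 4 × 16 × 240 where per-pixel
access suffices.

What the phantom does **not** emulate: rete pegs/papillae texture, keratin
layers (which real segmentations misattribute to epithelium), catheter
sheath rings, non-uniform rotational distortion, the confocal/PSF axial
envelope, depth-correlated speckle, or refraction at oblique incidence.
Passing recovery tests therefore demonstrates the correctness of the
measurement chain under the stated model, not robustness to those real-data
effects.

## Numerical and degenerate-case choices

* Half-open depth intervals [top, bottom); 0-based indices throughout.
* In-memory intensity is float32 (matching the 32-bit TIFF interface), so
  write/read round-trips are bit-identical; internal computation is
  float64.
* A boundary segmented below the visualized bottom yields an empty stroma
  without a loss flag; a boundary at or above the top is rejected.
* Stratification with both region means zero is missing, not ±∞.
* Noise-floor-subtracted power is clipped at a tiny positive value before
  logs.
* Constant samples route as non-normal (Shapiro's W is undefined there).
* Phantom generation with the same spec and seed is bit-identical
  (`numpy.random.default_rng(seed)` is the only randomness source).

## Known limitations

Attenuation values are not corrected for confocal effects and are not
comparable across optical systems.  The loss-of-boundary rule inflates
epithelial depth and epithelium μ in exactly the most pathologic regions;
downstream users should interpret those biomarkers jointly with the loss
percentage.  The statistical module implements the routing protocol but
deliberately makes no multiplicity correction.
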