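# Methods

This note documents the models implemented in `phenocount`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions adopted where a design
was genuinely open.

## Synthetic fluorescent image model (`simgen`)

Each cell is a pair of concentric ellipses: a nucleus and, per expressed
marker channel, a larger cytoplasm. Geometry is parameterised by an
area-equivalent radius `r` and an eccentricity `e`
(semi-axes `a = r/(1−e²)^¼`, `b = r·(1−e²)^¼`, so the painted area is
always `π r²`); both are jittered multiplicatively by a uniform factor
`1 ± variation`. Defaults follow standard high-content-screening
simulation settings: nucleus `r = 13 px`, `e = 0.5`, variation 0.1;
cytoplasm `r = 18 px`, `e = 0.5`, variation 0.3; per-cell marker level
drawn from N(0.5, 0.2²) truncated at ±3 SD and clipped to [0, 1].

**Placement and clustering.** A cell is "clustered" with probability
25% (the default): it attaches at a distance of 1.2–1.5 nucleus radii to
a parent *of its own phenotype* — populations are laid down one
phenotype at a time, as population-based cell simulators do, so colonies
are clonal. Clustered nuclei therefore touch and partially overlap but
never interpenetrate (a minimum spacing of 1.2 radii is enforced against
all cells). Non-clustered cells are placed uniformly with full
separation, so that with clustering disabled every scene is trivially
segmentable. If a requested scene cannot be placed within 200 attempts
per cell, a `PlacementError` is raised.

**Rendering.** Painted intensities are combined by per-pixel maximum,
multiplied by a smooth texture field (spectrally synthesised band-limited
Gaussian noise with correlation length 6 px, a `1/(1+f/f₀)` low-frequency
roll-off at `f₀ = 0.0025` cycles/px, relative amplitude 0.2), offset by a
0.05 autofluorescence background, blurred by a 1 px Gaussian PSF, and
degraded by additive Gaussian CCD noise of variance 1e-4. All channels of
one FOV derive from a single seeded generator, so identical
`(spec, seed)` reproduce bit-identical pixels.

**Phenotype registry.** Twenty phenotypes are pre-registered: the
nucleus-only class (all imaged markers negative), three single-marker
positives, nine two-marker patterns (three channel pairs × {++, +−, −+}),
and seven non-all-negative three-marker patterns. The registry is an
ordinary mapping and can be replaced for assay-specific panels (e.g. the
CTC/CHC panel over CD45/E-cadherin/vimentin). The reference image set
generates four groups of FOVs — one-marker, two-marker and two
three-marker groups, cycling channels so the whole registry is exercised —
with per-FOV per-phenotype counts drawn Poisson(5); 100 FOVs per group
gives the 400-FOV reference scale.

**Forgeries and anomalies.** Splice forgeries paste 1–3 connected
components of a donor mask at uniform positions in a target; the tamper
mask marks exactly the pasted pixels, so the output equals the target
bit-for-bit outside it. For detector training the donor is rendered under
a different condition (no texture, 4× CCD noise), mirroring splicing
across image sets. Anomaly modes are this package's own definitions of
grossly out-of-distribution inputs: `blank` (all zero), `saturated`
(≥ 99% of pixels at maximum with residual readout speckle), `noise`
(i.i.d. uniform) and `off_modality` (smooth ramp). What the generator
does **not** emulate: out-of-focus z-stacks, bright-field realism,
uneven illumination, spectral bleed-through, and real stain morphology —
results on it bound algorithmic behaviour, not real-microscope accuracy.

## Binarisation (`binarize`)

Preprocessing uses bilateral denoising (spatial σ = 3 px, range σ = 0.1
of the dynamic range) and CLAHE (8×8 tiles, clip limit 0.01); both are
exposed in `EnumerationConfig`. Histograms always use 256 bins; 16-bit
images are analysed on a rescaled 8-bit view.

All 16 thresholding methods operate on that histogram behind one
registry. The convention throughout is *pixel ≥ T ⇒ foreground*, and
ties in an objective break toward the lower intensity. Iterative
formulations (iterative selection, Li) are evaluated exactly at every
candidate split rather than by fixed-point iteration, which makes the
exhaustive-search equivalence hold by construction and removes
initialisation sensitivity. Intermodes/Minimum smooth the histogram with
a 3-tap mean until exactly two maxima remain (≤ 10 000 iterations; a
histogram that never becomes bimodal raises a degenerate-histogram
error). `huang2` evaluates the same fuzziness objective as `huang` on a
fully vectorised path. The Rényi entropy method uses order α = 2.
Zero-variance classes are excluded from the minimum-error criterion with
an explicit variance floor (1e-6) so float noise cannot fake a
zero-variance logarithm.

**Correction factor.** The learned multiplier `c` on the Triangle
threshold is regressed (random forest by default; other families behind
the same interface) on the 166-feature descriptor. Training labels `c*`
are obtained by grid search over [0.2, 3.0] in steps of 0.05, minimising
pixel disagreement between `img ≥ c·T_raw` and a truth mask — computed
exactly from cumulative histograms inside/outside the mask. Reported
errors come from an 80:20 split; predictions are clipped to the grid
range. How the reference training labels were originally derived is not
specified anywhere; this grid-search definition is normative for this
package.

**Watershed.** Markers are local maxima of the Euclidean distance
transform smoothed with σ = 1 px, with a minimum peak separation of 5 px
(≈ 0.4 of the default nucleus radius); flooding runs on the negated
smoothed transform. On ideal overlapping disc pairs this resolves centre
distances down to ≈ 0.9 r.

**Degenerate channels.** A channel whose 99.9th percentile is within
0.05 of its median is treated as background-only and yields an empty
mask: CLAHE would otherwise stretch pure sensor noise into spurious
structure.

## Features (`features`)

The descriptor is `[7 | 63 | 96]`: seven statistics of the normalised
256-bin histogram (mean, SD, skewness, kurtosis, energy, entropy in
bits, smoothness `1 − 1/(1+σ_n²)` with σ_n on [0, 1]-scaled
intensities); the same seven on each block of a 3×3 partition
(remainder pixels go to the *first* row/column blocks, e.g. a 10-px side
splits 4/3/3); and four moments (mean, variance, skewness, kurtosis) of
the magnitude response of 24 Gabor filters — wavelengths
{2.0, 2.5, 3.0, 3.5} px/cycle × orientations {0°…300° in 60° steps},
σ_x = 0.56 λ, aspect ratio 0.5, truncated at 3σ. Orientations θ and
θ+180° give identical magnitude responses for a real Gabor pair; all six
are still computed so the 166-length contract holds. Convolution is done
in the frequency domain with cached kernel FFTs (circular boundary);
kurtosis is non-excess, and skewness/kurtosis of a zero-variance
distribution are defined as 0.

## Phenotyping rules (`phenotyper`)

Morphology filter: keep 200 ≤ area ≤ 2000 px and eccentricity ≤ 0.8
(second-moment ellipse eccentricity in [0, 1)); both bounds are
magnification-dependent and exposed in the configuration. Cytoplasmic
masks are products of binary marker masks with inversion for
negative-pattern channels. The area-ratio filter grows a region from
each masked object's centroid in both the masked and the filtered
nucleus image and removes objects with ratio < 0.6 (strict); region
growing respects watershed object borders, and masked pieces are split
along them, so a piece never straddles two separated nuclei. A seed that
lands on background in the filtered image removes the object with a
warning. Blob detection is connected-component labelling
(8-connectivity by default); a nucleus counts toward a phenotype when a
surviving masked piece of it exists. Equivalent diameter is
`2·√(area/π)·pixel_size`. Thumbnails are 120×120 px crops centred on the
cell with mirrored border padding.

With `k` markers the `2^k` full patterns partition the image, so on
well-separated scenes the per-pattern counts sum exactly to the number
of surviving nuclei; on clustered scenes a nucleus whose pixels straddle
a pattern boundary can fail the ratio filter for every pattern, so the
sum can fall below the nucleus count — this is the dominant loss mode.

## Forensics (`forensics`)

**Robust PCA.** Features are first standardised robustly (median centre;
scale = max(MAD, 0.3·SD) — the floor prevents near-discrete features
from exploding ordinary variation into pseudo-outliers). The fit is
projection-pursuit trimming (Stahel–Donoho outlyingness over 250 random
pair directions, keep the `⌈αn⌉` least outlying), eigen-decomposition of
the trimmed covariance, then a reweighted minimum-covariance-determinant
step on the k-dimensional scores. Score distance uses the MCD
covariance with the χ²ₖ(0.975) cutoff; orthogonal distance uses the
Wilson–Hilferty approximation — OD^(2/3) treated as normal with robust
(median/MAD) moments — at the 0.975 quantile. The 2×2 rule on
(SD, OD) yields regular / good-leverage / orthogonal-outlier /
bad-leverage; *bad leverage ⇔ anomaly*. Defaults k = 1, α = 0.70.

**Detectors.** Tampering: random forest (300 trees). Synthetic images:
cubic-kernel SVM behind a standard scaler. Both report held-out
sensitivity/specificity/accuracy from a stratified 80:20 split and are
seed-reproducible. Decisions are single-target (three independent
flags), with the 0.5 default decision rule.

**Localization.** Per-block noise SD is estimated from the eigenvalue
tail of the covariance of sliding 7×7 patches (stride 2): the median of
the smallest half of the eigenvalues, robust to low-rank structure in
the block. The coarse 64×64 grid is Ward-clustered with the cluster
count in 1–5 chosen by the gap statistic (uniform reference over the
observed range, 50 replicates; one cluster ⇒ all pristine). The fine
32×32 stage re-clusters blocks inside the coarse tampered region plus a
one-coarse-block margin, choosing the count by silhouette. The class
with the fewest pixels is tampered; a class covering more than half the
image is never reported, and the bounding box is half-open
`[x0,x1)×[y0,y1)` in 0-based pixel coordinates.

## Evaluation statistics (`evalstats`)

* **Percentage error**: per (FOV, phenotype) unit `|y−x|/x·100`,
  zero-reference units excluded with a warning; pooled mean ± SD.
* **Detection metrics**: greedy nearest-first centroid matching, a pair
  matching when within the truth cell's nucleus radius (configurable
  fixed radius otherwise). TP/FN from the truth side, FP from unmatched
  predictions; TN are non-target-phenotype truth cells not claimed by a
  target prediction — a convention this package defines, since cell-level
  specificity has no canonical 2×2 in the literature. CIs are percentile
  bootstrap over FOVs.
* **Passing–Bablok**: slope = shifted median of pairwise slopes
  (identical pairs dropped, slopes of −1 excluded, vertical pairs at
  ±∞), offset K = #slopes < −1; rank-based CIs; intercept =
  median(y − b·x). Pre-tests: Kendall's τ and a cusum linearity check —
  residual signs scored ±√(m/l), accumulated along the line ordering,
  compared with the 5% Kolmogorov–Smirnov bound 1.36.
* **Bland–Altman**: bias ± 1.96 SD with t-based CIs
  (SE(LoA) = SD·√(1/n + 1.96²/(2(n−1)))).
* **Gwet's AC1**: chance agreement `pe = Σ π_q(1−π_q)/(Q−1)` with the
  linearised variance estimator and a t-quantile CI truncated to
  [−1, 1]; Landis–Koch band reported. Applied to counts, each exact
  count is a nominal category by default (dichotomisation is the
  caller's choice upstream).
* **Count models**: Poisson, NB2, zero-inflated Poisson and ZINB with a
  2-level enumeration-method factor on both the count (log link) and the
  inflation (logit link) parts; lowest AIC wins, ties to the simpler
  family; non-convergent families are excluded with a warning. IRRs are
  exponentiated count-part coefficients with Wald CIs.
* **Diagnostics**: Mann–Whitney AUC; optimism by bootstrap-refitted
  logistic models (default B = 10 000); Youden cutoff maximising
  sens + spec − 1 with ties to the lowest cutoff (decision rule
  score ≥ cutoff); 2×2 metrics with percentile-bootstrap CIs
  (default B = 1000) and an optional LOOCV variant that re-selects the
  cutoff on every fold (a resubstitution mode is the `B=0`, fixed-cutoff
  call).

## Problem sizes

The reference enumeration benchmark uses 100 FOVs of 512×512 px
(4 groups × 25), about 2000 cells, chosen so that the full chain runs in
a few minutes on one CPU while keeping per-phenotype counts at the
reference scale of ~100 units per phenotype group. Detector benchmarks
use 1000 pristine/forged 112×112 px pairs; anomaly calibration uses 60
clean FOVs. These sizes are package defaults, adjustable via the
respective function arguments.

## Known limitations

* Heavily clustered nuclei (centre distance below ≈ 0.9 radii) merge
  into single blobs that no distance-transform watershed separates; the
  morphology filter then either counts the blob once or rejects it on
  eccentricity. This is the main sensitivity loss (~5–10% of cells at
  25% clustering).
* The area-ratio filter removes cells whose nucleus straddles a
  phenotype-mask boundary; in dense mixed-phenotype neighbourhoods this
  biases counts downward.
* The anomaly screen flags only bad-leverage points, as specified by the
  underlying model; with k = 1 an anomaly that happens to project near
  the robust centre along the single retained component would not flag.
* The synthetic-image detector is trained on generator renderings, not
  on real micrographs; its held-out performance says nothing about
  real-vs-synthetic discrimination in the wild.
* Count-model fitting of ZINB is fragile when the data are not actually
  zero-inflated (boundary estimates); such fits are reported as failed
  and excluded from AIC selection.
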