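# Methods

## The stratification model

A strain elastogram displays relative tissue stiffness as a color overlay;
by the convention adopted here, red codes hard tissue and blue soft tissue.
`elastocad` quantifies lesion stiffness from such an image and a reader's
lesion ROI in four steps:

1. **Color space.** The 8-bit RGB frame is converted to CIELab. The RGB
   working space is assumed to be sRGB with D65 white and the 2° observer —
   vendors do not document the encoding of exported frames, and sRGB is the
   de-facto default for screen captures and consumer formats. The a\* axis
   (green negative, red positive) is the stiffness-relevant coordinate.
2. **Thresholding.** An Otsu threshold is computed from the a\* values of
   ROI pixels only. Restricting to the ROI matters: hardness is defined
   *within the mass*, and surrounding tissue would shift the threshold.
   The histogram uses 256 equal-width bins spanning the observed ROI a\*
   range (8-bit practice; configurable via `n_bins`). The threshold is the
   upper edge of the last low bin, and a pixel is hard iff a\* ≥ threshold;
   ties therefore go to the hard class, making results deterministic.
   Among equal-variance splits the lowest threshold is returned.
3. **Hard-area fraction.** q = (hard ROI pixels) / (ROI pixels).
4. **Classification.** soft iff q < 50%; hard iff q > Z; intermediate
   otherwise. Both boundaries (q = 50% and q = Z) fall in the intermediate
   class — the intermediate band is read as the closed interval [50%, Z].
   Z defaults to 0.75; 0.70, 0.75, 0.80 and 0.90 are the values of
   clinical interest, and `visual_classify` is the Z = 0.90 rule used for
   visual BI-RADS-style readings.

### Degenerate and unimodal ROIs

Otsu's criterion presumes two classes. Two failure modes are handled
explicitly:

- **Constant a\*** (e.g. a uniformly colored ROI): the threshold is
  undefined; the ROI is labelled by the sign rule — hard iff a\* > 0, the
  red side of the achromatic axis — and flagged `degenerate`.
- **Unimodal a\***: an all-soft or all-hard lesion with pixel noise has a
  single a\* cluster, and a raw Otsu split would cut it in half (q ≈ 0.5
  for an all-soft mass — the worst possible answer). The pipeline
  therefore checks Otsu's effectiveness ratio η = between-class variance /
  total variance at the chosen split. For a single Gaussian cluster the
  best achievable η is 2/π ≈ 0.64 regardless of its variance, while any
  genuine two-cluster structure with the package's color defaults scores
  far higher, so a split with η below `min_separation` (default 0.75) is
  treated as uninformative and the per-pixel sign rule is applied instead.
  This keeps q continuous through the extremes: a lesion with a handful of
  red pixels gets q ≈ their fraction rather than ≈ 0.5.

`min_separation` trades false splits against false merges. At the default
jitter the within-cluster a\* spread is ≈ 3–7 units against a ≈ 86-unit
cluster gap, so η at a true split exceeds 0.95 once the minority class
holds ≈ 1% of the ROI; values of 0.7–0.8 behave identically in practice.

## Agreement statistics

- **Cohen's κ** (unweighted) on the 3-point scores, per reader pair.
  Weighted variants are out of scope; "kappa" unqualified means the
  unweighted statistic. The degenerate case p_e = 1 (both raters constant,
  identical marginals) is defined as κ = 1 when the ratings agree
  elementwise and is an error otherwise.
- **ICC** over all readers on the continuous hard fractions, as the
  two-way random-effects, absolute-agreement forms ICC(2,1) (single
  measures) and ICC(2,k) (average measures) of Shrout & Fleiss, computed
  from the two-way ANOVA mean squares (via `pingouin.intraclass_corr`).
  Reader panels are treated as a random sample of raters; absolute
  agreement, not consistency, is what matters when a fixed cutoff is
  applied to each reader's q.
- **Lin's CCC** on the hard fractions, per reader pair, with population
  (1/n) moments: ρc = 2·cov / (var_x + var_y + (mean_x − mean_y)²). The
  fractions q are the only continuous per-reader quantity, so CCC is
  computed on them rather than on the 3-point labels.
- **Verbal bands**: slight [0, 0.2), fair [0.2, 0.4), moderate [0.4, 0.6),
  substantial [0.6, 0.8), excellent [0.8, 1.0]. Boundary values belong to
  the upper band (0.8 is "excellent"); negative (below-chance) values are
  reported as "slight".
- **Area concordance**: for an ordered reader pair (x, y) the ratio
  area_x/area_y categorizes the first reader's segmentation as smaller
  (< 0.8), larger (> 1.2) or equal (variation under 20%; the boundaries
  count as equal). The rule is scale-invariant, so pixel vs physical areas
  are interchangeable. Percentages are reported to one decimal with
  standard rounding — note 11/83 prints as 13.3%.

## Diagnostics

Hard masses are positive for malignancy; soft and intermediate are
negative (malignancy is associated with high cellularity and peritumoral
desmoplasia, hence stiffness). Sensitivity and specificity come from the
standard 2×2 table. The AUC is the empirical Mann–Whitney statistic (wins
plus half ties over all positive/negative pairs, equal to the trapezoidal
area under the ROC curve) of the 3-point ordinal score against truth —
mirroring a reader-score evaluation; pass continuous q to `roc_auc`
directly for a q-based AUC. Raising Z can only demote predictions from
positive to negative, so across a cutoff sweep sensitivity is
non-increasing and specificity non-decreasing, a property the test suite
checks on every generated cohort.

## The phantom generator

Phantoms exist so that every stage is testable against exact ground truth
without clinical images. A phantom is an elliptical (or blob-shaped) ROI
of ~2000 px in a 128×128 frame on a neutral gray background; exactly
round(f · area) ROI pixels take the hard color and the rest the soft
color, before per-channel Gaussian jitter (sd 10, clipped to [0, 255]).
The realized pre-jitter fraction round(f·area)/area is recorded to the
pixel. "speckle" scatters hard pixels uniformly; "split" makes one
contiguous hard block — both produce identical a\* histograms, so they
exercise Otsu identically.

Default colors are red (220, 30, 30) for hard and a cyan-cast blue
(30, 170, 220) for soft. The soft tone was chosen for its a\*: under
sRGB/D65 it sits at a\* ≈ −18, on the green side of the axis, giving an
≈ 86-unit a\* gap to the hard red (a\* ≈ +68). A fully saturated RGB blue
would not do: its a\* is ≈ +64 — pure blue lies on the *red* side of the
a\* axis — which would defeat the red-vs-blue separation the pipeline
relies on. On-screen elastogram soft tones, which blend toward green/cyan
and are never pure blue, are consistent with this choice.

Cohorts draw true hard fractions per class from Beta distributions —
malignant Beta(8, 2) (mean 0.8), benign Beta(2, 8) (mean 0.2): overlapping
but separable, so cutoff sweeps are non-trivial. The default cohort size
is 31 malignant / 52 benign, a realistic single-centre biopsy series.
Simulated readers re-segment the reference ROI by a level-set grow/shrink
(ranking pixels by signed distance to the boundary, plus smoothed noise
for contour irregularity) to a per-reader target area; defaults R1 × 0.85,
R2 × 1.25, R3 × 1.00 encode the observation that experienced readers
segment tighter margins. All randomness descends from the single cohort
seed through `numpy` seed sequences; no global state is touched.

**What phantoms do not emulate:** vendor color maps with a continuous
blue-green-red ramp, B-mode texture and speckle statistics, partial-volume
mixing at lesion margins, compression artifacts, and anatomically shaped
lesions. Passing the phantom suites shows the arithmetic and the color
logic are correct under the stated color model — not that the fixed
cutoffs transfer to any particular scanner's output.

## Numerical choices and degenerate inputs

- Otsu ties: first (lowest) maximizing split; hard-class ties at the
  threshold go hard.
- `classify_mass` rejects q outside [0, 1]; `agreement_band` rejects
  values above 1 and maps negatives to "slight".
- Empty ROIs, degenerate truth vectors (single-class), constant rating
  matrices and non-positive areas raise `ValueError`s naming the problem.
- AUC with all-tied scores returns 0.5 (every pair contributes half).
- Problem sizes in the validation suites — 500 random instances for the
  oracle-equivalence checks, 200 phantoms for label recovery, one 83-lesion
  cohort for the monotonicity sweep — are large enough that the checked
  rates are stable to well under a percentage point across seeds.

## Known limitations

- The sRGB assumption is untestable against vendor hardware from here; a
  different working space shifts a\* values but not the architecture.
- Agreement statistics are point estimates; no confidence intervals or
  significance tests (and no Fleiss' κ for the three-reader joint case).
- The CAD is a fixed rule on q; there is no learning, and no strain-ratio
  or shear-wave quantification.
- ROI transfer between B-mode and elastogram frames is modelled as
  identity on one grid; real dual displays may need registration.
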