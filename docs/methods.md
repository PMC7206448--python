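# Methods

`msbiotype` implements the reference-panel workflow used in MALDI-TOF MS
biotyping of whole organisms: raw linear-mode profile spectra of acid-soluble
proteins (2–20 kDa) are reduced to centroided peak lists, every blinded test
sample is scored against a panel of replicate reference spectra with a
composite similarity score, scores are averaged per reference population, and
the top-scoring population is the identification call. Downstream statistics
(PCA ordination, per-column one-way ANOVA, Tukey HSD) quantify how distinct
the populations are. A population-structured spectrum simulator provides
ground-truth data for end-to-end validation.

## Preprocessing chain

A raw spectrum enters as paired (m/z, intensity) arrays restricted to
2–20 kDa. The chain is:

1. **Resampling** to a uniform 1 Da grid (linear interpolation). Flat
   structuring elements and fixed-width filters assume even spacing.
2. **TopHat baseline subtraction**: the grey-scale morphological opening
   (erosion then dilation with a flat element, default width 400 Da) is
   subtracted from the trace. The opening is the slowly varying envelope
   that fits under the signal without containing features narrower than the
   element, so peaks (FWHM ≈ 12 Da here) survive while chemical-noise
   background is removed. The residual is non-negative and the operation is
   idempotent.
3. **Savitzky–Golay smoothing** (window 21 points, polynomial order 3).
   Reproduces polynomials up to the chosen order exactly; undershoot is
   clipped at zero.
4. **Centroid peak detection**: local maxima of the smoothed trace with
   SNR ≥ 3 are kept; each peak's m/z is the intensity-weighted centroid of
   its contiguous above-half-maximum region (FWHM centroiding), its
   intensity the apex height. At most 100 peaks are kept, by descending
   intensity.
5. **Normalization**: intensities are divided by the tallest peak, so peak
   heights are relative and comparable across spectra of different absolute
   signal.

**Noise estimation.** The SNR reference is σ = 1.4826 × MAD of the
baseline-subtracted trace, computed *before* smoothing. Two details matter.
First, the MAD must be taken before the smoothed trace is clipped at zero:
clipping zeroes roughly half the noise points and biases the MAD low, which
in early development admitted dozens of spurious SNR ≈ 3 detections per
spectrum. Second, the raw-trace σ (not the smoothed-trace σ) is the right
threshold reference: smoothing barely attenuates real peaks, which are much
wider than the filter, but pulls white-noise excursions to well below 3σ of
the raw noise, so the threshold separates the two populations of maxima
cleanly.

**Mass calibration.** For time-domain data the TOF law t = a·√(m/z) + b is
fitted by least squares to calibrant peaks (the standard 3.6–17 kDa
calibrant masses are bundled as a default) and inverted as
m = ((t − b)/a)²; the residual RMS is reported in Da after
back-transformation. Real vendor raw files carry no accessible time-domain
data here, so calibration is exercised on simulated times only.

## Composite similarity score

Two normalized peak lists — reference R (n_R peaks) and test T (n_T peaks) —
are compared through a one-to-one matching M within mass tolerance

    tol(m) = tol_const + tol_ppm · 10⁻⁶ · m      (defaults 2 Da, 1200 ppm)

The matching maximizes the number of matched pairs and, among
maximum-cardinality matchings, minimizes Σ|Δm/z|. It is computed as a
rectangular assignment problem (`scipy.optimize.linear_sum_assignment`) in
which infeasible pairs carry a prohibitive cost and a tiny index-ordered
epsilon makes exact ties resolve to the lower reference index. An exhaustive
enumeration oracle over all one-to-one matchings verifies optimality on
small instances in the test suite.

Three values in [0, 1] follow:

* v₁ = |M| / n_R — fraction of reference peaks with a partner,
* v₂ = |M| / n_T — fraction of test peaks with a partner,
* v₃ — peak-height symmetry: the mean over matched pairs of
  min(I_R, I_T)/max(I_R, I_T) on normalized intensities (a geometric-mean
  variant is available; the arithmetic mean is the default as the simplest
  statistic with the right range and lower variance).

The composite score is

    S = log₁₀(1000 · v₁ · v₂ · v₃),  clamped below at 0,

so a perfect self-match gives exactly 3 and any product ≤ 10⁻³ gives 0.
Guideline interpretation bands: 2.300–3.000 highly probable species-level
identification (very close relatedness), 2.000–2.299 secure genus / probable
species (close), 1.700–1.999 probable genus (intermediate), 0.000–1.699 no
reliable identification (low relatedness).

**Tolerance default.** Linear-mode mass error grows roughly proportionally
with mass, hence the constant-plus-ppm form. If single-spectrum mass
reproducibility is ~300 ppm (the simulator default), the difference between
two independently acquired spectra has σ ≈ √2 · 300 = 424 ppm; the ppm term
is set at ~3σ of that pairwise drift (1200 ppm). A tighter window (600 ppm
was tried first) silently rejects 10–15% of *true* matches at the high-mass
end and converts instrument drift into classification noise — measurably
degrading blind-test accuracy between near-identical populations.

## Identification and accuracy

Each test sample is scored against every reference replicate (quadruplicate
per population by default), scores are averaged per reference population
(arithmetic mean), and the population with the highest average is the call.
Ties within `tie_tol` (default 0, i.e. exact equality) are reported
explicitly. Blind-test accuracy gives 1 credit to an untied correct call and
1/|tied set| when the true population is in the tied set, so a single
two-way tie containing the truth contributes 0.5 — the convention that makes
fractional totals such as 19.5/24 meaningful. Percentages are rounded to the
nearest integer for reporting.

Two summary statistics describe panel structure: the **cognate average**
(mean of each test sample's score against its own population's references)
and the **bidirectional non-cognate average** for a focus population (mean
over that population's test samples against all other reference columns,
pooled with all other populations' test samples against the focus column).

## Downstream statistics

* **Feature matrix.** Peaks are assigned to fixed 3 Da bins across
  2–20 kDa; a bin holds the maximum normalized intensity of the peaks
  falling in it and all-zero bins are dropped. Binning is the minimal
  peak-alignment scheme for unsupervised analysis.
* **PCA** runs on the mean-centred but *unscaled* matrix ("all peaks
  weighted equally" — variance scaling would inflate quiet bins), via
  `sklearn.decomposition.PCA` with a deterministic sign convention (largest
  |loading| positive). An eigendecomposition oracle checks scores,
  loadings and explained-variance fractions in the tests.
* **One-way ANOVA** of the per-test-sample population-averaged scores,
  grouped by the samples' true population, is computed per reference
  column as the classical between/within sum-of-squares decomposition with
  p from the F distribution. With 24 samples in 4 groups this gives
  df = (3, 20). Zero within-group variance is handled explicitly (F = 0
  when all group means coincide, +inf otherwise). `scipy.stats.f_oneway`
  serves as the independent oracle in the tests.
* **Tukey HSD** at α = 0.05 uses `statsmodels` studentized-range pairwise
  comparisons; the compact letter display is derived from the significance
  map by the insert-and-absorb algorithm, so letters and pairwise calls can
  never disagree.

## Synthetic studies

The simulator generates ground-truth peak templates for k populations with a
prescribed pairwise shared-peak structure, then renders noisy replicate
spectra.

**Templates.** Peaks are typed by the subset of populations carrying them;
per-subset counts are obtained by solving a small linear program whose
equality constraints are the pairwise overlap targets and per-population
totals, then rounding (the default structure has an exact integer solution).
Realized overlaps are verified within ±0.05 of target; infeasible structures
(e.g. triangle violations) raise a constructive error. Distinct peaks get
masses uniform in the window interior with a ≥30 Da minimum separation
(beyond the matching tolerance, so shared/unique status survives
preprocessing) and base intensities uniform in [0.1, 1]; shared peaks share
both mass and base intensity across populations.

**Default design** mirrors a 4-population blinded study: 4 reference + 6
test samples per population (16 + 24 spectra); test order is shuffled and
truth is kept in a separate map, consulted only at the accuracy step. The
default overlap structure is graded — populations 1 and 2 near-identical
(0.9), population 3 intermediate (0.75 to 1 and 2), population 4 divergent
(0.4 to all) — two sister populations, a cousin, and an outlier.

**Rendering.** Each retained template peak (Bernoulli dropout, default
p = 0.1 per replicate) becomes a Gaussian of σ = 5 Da at a mass jittered by
N(0, 300 ppm · m) with log-normally perturbed intensity (CV = 0.25); a
smooth exponential-decay chemical baseline (5% of the strongest peak,
decay constant a quarter of the window) and white noise (0.5% of the
strongest peak) are added. An optional ceiling models detector saturation
as a pointwise minimum — flat-topped peaks, idempotent. Random streams are
keyed by (study seed, population, replicate index), so templates, every
replicate and the blinding shuffle are independently reproducible, and
replicate streams differ across populations even at equal replicate
indices.

**Peak richness.** Templates carry 80 peaks (default). This is the
peak-rich regime in which reference-panel biotyping is reliable: typical
linear-mode intact-protein peak lists run 60–100 peaks, and with a 0.9
overlap between sister populations the 8 population-specific peaks per
sister are what carry the discrimination. Sparser templates (40 peaks were
tried during development) leave only 4 discriminating peaks, and a 10%
dropout then produces an irreducible ~0.4% per-call error floor
(probability that ≥3 of the 4 unique peaks drop out of a test spectrum) —
a sparse-spectrum failure mode rather than a property of the scoring
method.

**What the simulator does not model.** Isotope envelopes (unresolved in
linear mode at these masses), detailed MALDI plume/ionization physics,
mass-dependent resolution, correlated (chemical) noise structure, and the
asymmetric saturation artefacts of real detectors (pulse distortion,
dead-time suppression of later ions, shot-to-shot variability in which
peaks saturate). The last point matters for interpreting the clipping
sweep: symmetric pointwise clipping applied to both reference and test
panels preserves peak *positions*, and identification here is driven by
match counts, so simulated accuracy degrades only mildly (often not at
all) as the ceiling drops — the sweep asserts monotone non-increase, not a
specific loss. Passing clipping tests therefore show robustness of the
scoring chain to flat-topped peaks, not a quantitative reproduction of
real saturation losses.

## Problem sizes and numerical choices

* Simulated studies run on an 18 001-point 1 Da grid; a full study
  (40 spectra, 384 scored pairs) takes ~0.25 s, so validation sweeps use
  10 seeds (accuracy/ordering) and 20 seeds × 4 ceilings (clipping).
* Score-table arithmetic on the bundled benchmark table is exact to its
  printed 3 decimals; ANOVA F values are asserted to ±0.01.
* Matching-cost tie-break epsilons (10⁻⁷ per reference index, 10⁻¹⁰ per
  test index) are far below any physical mass difference and only order
  exact ties.
* Degenerate inputs: empty peak lists score 0 against anything; an empty
  spectrum yields an empty peak list (not an error); single-population
  matrices make the bidirectional non-cognate average undefined (error).
* The smoothing window (21 points at 1 Da) spans roughly 1.8× the peak
  FWHM; order 3 preserves peak height to within ~1%.

## Known limitations

* Vendor acquisition folders (fid/acqu) are not parsed; open formats only
  (two-column text, mzML read-only for MS1 profile arrays).
* The composite score is this package's own implementation of the published
  description of the commercial score; no attempt is made to match the
  proprietary implementation bit-for-bit, and the matching tolerance and
  symmetry statistic are documented assumptions, configurable in
  `ScoringConfig`.
* PCA input vectorization for the commercial software is unpublished; the
  binned peak matrix used here asserts qualitative cluster structure only,
  not published ordination coordinates.
* Accuracy claims on synthetic data transfer to real spectra only insofar
  as the noise model captures reality; the dominant unmodelled effects are
  listed above.
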