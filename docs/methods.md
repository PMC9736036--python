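# Methods

This note documents the statistical model, the synthetic-data assumptions,
and the numerical conventions used throughout `reimsdx`. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The classification problem

A REIMS acquisition produces one negative-ion mass spectrum per tissue
"burn"; a biopsy sample yields one to several burns, and each patient
contributes one research sample. The analysis must answer, per sample:
normal or malignant endometrium? The informative signal is the
glycerophospholipid/ceramide profile in the 600–1000 m/z window, where
cancer tissue shows elevated phosphatidic acids (PA),
phosphatidylethanolamines (PE, including plasmalogens),
phosphatidylserines (PS) and ceramides, reflecting up-regulated membrane
lipid biosynthesis in proliferating tissue.

## Preprocessing chain

Order: background subtraction → lock-mass correction → quality filter →
binning → TIC normalisation → per-sample representative.

* **Background subtraction** removes a constant per-spectrum level, the
  10th intensity percentile, clipping at zero. This suppresses chemical
  baseline without touching peak shape.
* **Lock-mass correction.** Time-of-flight mass scales drift slowly. Each
  spectrum's drift is estimated from the internal reference PA(36:2)
  ([M−H]⁻ = 699.49703 Th, printed as 699.497): the most intense point
  within ±0.5 Th, refined to sub-grid precision by a quadratic fit to
  log-intensity at the apex and its two neighbours (exact for a sampled
  Gaussian). The spectrum is rigidly shifted by −drift. When the spectrum
  also covers the external reference (leucine enkephalin, 554.26202 Th),
  a two-point linear (slope, offset) recalibration is used instead.
  Spectra with no usable lock-mass peak are flagged and left uncorrected.
  Reference values are computed from elemental formulas at full precision
  rather than stored at printed precision, so a drift-free spectrum is
  corrected by exactly zero.
* **Quality filter.** The noise-to-signal statistic is p95/median of the
  intensity vector (ε-guarded), with a cutoff of 5, plus a positive-TIC
  floor. A signal-bearing profile spectrum has a near-zero median (most
  grid points are baseline) and passes easily; a baseline-dominated
  acquisition has p95 ≈ median and fails. Both the statistic's cutoff and
  the TIC floor are config-exposed, since vendor software states the
  criterion but not a formula.
* **Binning.** Half-open bins [600.0 + 0.1k, 600.0 + 0.1(k+1)), k = 0…3999;
  a point at exactly 1000.0 is excluded, and a small epsilon in the floor
  index guards against float round-off at bin edges (600.1 must land in
  bin 1, not bin 0). Binning conserves total in-range intensity exactly.
  Bins are labelled by their lower edge ("mz_722.5" covers 722.5–722.6).
  The coarse 0.1 Da bins double as peak alignment: residual calibration
  error after lock-mass correction (≤5e-3 Th under default noise) is far
  inside one bin.
* **TIC normalisation** divides by the bin sum, making intensities relative
  proportions; all-zero vectors pass through flagged un-normalised.
  Normalising after binning (rather than before) is a config choice; the
  two differ only by the intensity outside 600–1000 m/z.
* **Representative spectrum.** A sample's passing, normalised burns are
  averaged element-wise and re-normalised — one feature vector per sample,
  so downstream sample size equals patient count. A sample with zero
  passing burns is dropped (logged), mirroring how fluid-dominated
  biopsies fall out of a real analysis.

## PC-LDA and validation

With p = 4000 bins and n ≈ 10² samples, LDA cannot be fitted in bin space.
PCA (mean-centred, deterministic sign convention: each component's
largest-magnitude loading is positive) reduces to k components; the
default k is the smallest number explaining ≥95% of variance, capped at
n − 2. This cap/threshold is the single most consequential free choice of
the pipeline, so it is recorded in every model report and exposed in every
interface. LDA then uses the pooled within-class covariance with **equal
priors** — deliberate, so the 85:59 class imbalance does not shift the
boundary toward "normal"; frequency priors are a config option. A
numerically singular covariance (condition number > 1e10) receives a ridge
of 1e-6·trace/dim, logged and flagged in the report. Prediction assigns
the nearer class mean on the single discriminant axis; an exact tie goes
to "normal", favouring specificity in a screening context.

**Leave-one-patient-out validation** is the honest unit of validation for
clinical spectra: all of a patient's samples are held out together and
PCA + LDA are refitted from scratch each fold (anything less leaks the
held-out patient into the component space). The implementation asserts
per fold that no held-out sample or patient id appears in the training
index. Metrics use cancer as the positive class; ratios with zero
denominators are reported as NaN, never as 0.

The **learning curve** draws k patients per class (k = 5…32 by default)
without replacement, 20 seeded iterations per k, testing on all remaining
samples, and reports mean ± SD of accuracy, sensitivity and specificity.
Draw seeds descend from one root seed via `SeedSequence.spawn`, so the
whole table is reproducible.

## Univariate discovery

Per-bin two-group Kruskal–Wallis tests run on the representative spectra
(testing individual burns would pseudo-replicate within patients). The H
statistic is computed vectorised across bins with the tie correction
C = 1 − Σ(t³−t)/(n³−n); p comes from the χ²(1) upper tail; all-constant
bins get p = 1. Multiplicity is controlled with Benjamini–Yekutieli
rather than plain Benjamini–Hochberg because adjacent spectral bins are
strongly positively dependent and a peak spreads over neighbouring bins;
BY's harmonic inflation c(m) is valid under arbitrary dependence. The
fold change is log₂(median_cancer / median_normal) — oriented so
cancer-elevated lipids are positive — with a zero median replaced by the
bin's smallest positive value (bins with no positive value are undefined
and excluded; dropping such bins outright is available by config).
Selection requires q ≤ 0.001 **and** |log₂FC| ≥ 1, sorted by q then |FC|,
ties by m/z.

## Lipid annotation

Annotation is fully offline. Neutral monoisotopic masses are summed from a
fixed atomic-mass table (C 12, H 1.00782503, N 14.00307401, O 15.99491462,
P 30.97376163, Cl 34.96885268); adduct m/z are M − 1.00727646 for [M−H]⁻
(proton removed, electron kept) and M + 34.96885268 + 0.00054858 for
[M+Cl]⁻ — the ~0.5 mDa electron term is invisible at the ±0.1 Th matching
tolerance but applied consistently. The bundled panel holds the curated
endometrial species (with chain assignments where MS/MS supports them)
plus ~190 common even-chain diacyl PC/PE/PA/PS/PG sum compositions; only
even fatty-acyl chains are admitted, the usual mammalian prior.

MS/MS refinement counts observed daughter ions matching a candidate's
predicted fatty-acyl carboxylate anions [RCOO]⁻ (fatty acid minus a
proton; e.g. 20:4 → 303.233). Ether ("O-"), plasmalogen ("P-") and
sphingoid chains yield no carboxylate; sum compositions get support 0,
never an error. Candidates re-rank by (support desc, |mass error| asc).
This resolves genuinely isobaric cases: diacyl PE(16:0/20:4) and the
hydroxylated plasmalogen PE(P-16:0/20:4)(12OH) share one elemental
formula and can only be separated by the 255.23 palmitate fragment.
Two curated ambiguities are kept visible rather than resolved: the
722.54 peak matches the plasmalogen PE(P-16:0/20:4) — the diacyl
PE(16:0/20:4) sits 16 Da away at 738.51 and cannot be the precursor —
and a 750.57 peak is mass-consistent with PE(P-18:0/20:4) but not with
diacyl PE(18:0/20:4).

## The synthetic cohort generator

The generator emulates the *structure* of a REIMS endometrial cohort, not
any particular dataset:

* **Cohort shape.** 85 normal / 59 cancer patients by default; cancer
  subtypes (endometrioid low/high, serous, carcinosarcoma, clear cell),
  presentation and tissue-quality grades drawn from a fixed composition
  table with realistic marginals. One sample per patient; burns per sample
  uniform on {1..5} (median 3 over a cohort).
* **Spectra.** Dense profile grid (0.01 Th over 595–1005). Each panel
  species contributes a Gaussian peak (σ = 0.02 Th) at its theoretical
  adduct m/z plus the spectrum's rigid drift (uniform ±0.03 Th). Peak
  heights are lognormal: class mean + per-patient biological offset
  (SD 0.35) + per-burn noise (SD 0.25) in natural-log units. Baseline
  noise is Gaussian clipped at zero (SD 0.5); the whole spectrum scales by
  a lognormal TIC factor (σ = 0.3).
* **Class effect.** The nine curated discriminant lipids get a +1
  natural-log shift of mean intensity in cancer (≈ e ≈ 2.7-fold); the
  ~40 background species are class-neutral. Because spectra are
  TIC-normalised downstream, raising nine species depresses every other
  normalised bin; background abundance is therefore set ≈4.5× higher per
  species than the discriminant set, keeping that distortion near
  −0.11 log₂ units so planted bins sit at ≈ +1.3 log₂ (comfortably above
  the selection threshold of 1) and background bins far below it. No
  per-lipid effect sizes exist to copy from real data, so acceptance rests
  on parameter *recovery* — the pipeline must find what was planted —
  not on reproducing any published accuracy.
* **Degraded spectra.** With probability 0.15 a burn is generated
  baseline-dominated (peaks ×0.02, elevated baseline), which the QC filter
  should reject; a sample losing all burns is flagged poor and drops out,
  reproducing realistic sample attrition.
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in a fixed order; identical configs give byte-identical
  cohorts.

What the generator does **not** emulate: isotope envelopes, mass-dependent
(non-rigid) calibration error beyond the optional linear term, detector
saturation, inter-batch intensity drift, within-class biological
heterogeneity of real endometrium (secretory vs atrophic, polyps), or
MS/MS spectra (fragment lists are tabulated directly). Passing tests
therefore demonstrate that the pipeline's machinery is correct and
well-calibrated on data with the assumed structure — not that any given
accuracy will transfer to real tissue.

## Problem sizes and calibration checks

The acceptance tests run at the cohort scales the pipeline targets: drift
recovery over 100 seeded spectra (tolerances 1e-3 Th noise-free, 5e-3 Th
under default noise); null calibration over 20 seeds of a 40+40-patient,
zero-effect cohort (mean LOPO accuracy must stay in 40–60%, per-bin
type-I error in 3–7% at p < 0.05, BY discoveries ≤5% at q ≤ 0.05);
parameter recovery over 10 seeds of the default 85/59 cohort (mean LOPO
accuracy ≥80%, ≥8 of 9 planted bins selected, a planted peak counting as
recovered within ±0.1 Th to allow for bin-edge straddling); and a 35+35
learning-curve cohort (28 sizes × 20 iterations, final accuracy ≥ initial).

## Known limitations

* The number of PCs is chosen by explained variance, not nested
  cross-validation; with very small training sets the 95% target can keep
  nearly n − 2 components, relying on the LDA ridge for stability.
* The QC statistic presumes profile-mode spectra with many baseline
  points; heavily centroided input with few points makes p95/median
  behave differently (binning itself is centroid-agnostic).
* The two-point linear recalibration assumes at most affine mass error;
  genuinely nonlinear ToF drift is out of scope.
* Fold-change ε substitution at zero medians makes |log₂FC| for
  near-absent species sensitive to the smallest observed value; the
  joint q-threshold keeps such bins from being selected on fold change
  alone.
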