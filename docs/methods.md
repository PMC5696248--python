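# Methods

`mrmpanel` re-implements, as a tested and reusable pipeline, the procedure
used to develop a plasma-protein multimarker panel for the early detection
of pancreatic ductal adenocarcinoma (PDAC): multiple-reaction-monitoring
(MRM-MS) transition quantitation with stable-isotope-dilution ratios,
multi-criteria marker verification filters, an anchored combinatorial
panel search with SVM classification and paired-ROC selection (DeLong and
McNemar tests at a fixed specificity), and scenario-based validation of
the frozen panel against the established clinical marker CA19-9.

Because the clinical plasma dataset behind the original study is not
public, the pipeline ships with a synthetic multi-center cohort generator
that reproduces the statistical structure the method assumes.  All
claims the test suite makes are claims about recovery of *planted* signal
from that generator, not about clinical performance.

## The synthetic cohort

### Groups, centers, demographics

The generator emulates a 1008-sample validation population: 401 PDAC, 349
normal controls (NL), 149 other cancers (OC: breast/colon/thyroid) and
109 benign pancreatic disease (PB), spread over five clinical centers
with the per-center sample counts, AJCC stage distributions, age/BMI
moments and sex ratios of the study's demographics table.  Age, sex and
BMI are generated but deliberately unused by the classifier (the study
handled them by blinding and blocked randomization, not modeling).

Preparation batches are assigned by blocked randomization: within each
clinical group, samples are dealt round-robin over `n_batches` (default
12), so each batch's group composition deviates from the global
composition by less than one sample per group.

### CA19-9

CA19-9 (U/mL) is log-normal within each control group, calibrated to the
reported per-center medians and dispersions.  The demographics table
labels its dispersion column "MAD", but the printed values exceed the
median for every PDAC center, which is impossible for a true median
absolute deviation of a positive variable; we read it as the **mean**
absolute deviation about the mean and invert the log-normal identity
`E|X − EX| = 2·EX·(2Φ(σ/2) − 1)` to obtain the log-scale σ per center
(σ ≈ 0.6 for controls, 1.6–2.4 for the cancer centers).

In PDAC, CA19-9 is a three-component mixture:

* **non-expressors** (default 12.5%, the reported 10–15% of patients who
  lack the Lewis-A antigen): drawn from the control distribution and
  flagged in the ground truth;
* **low expressors** (default 22.5%): also control-distributed, not
  flagged — these are genuine expressors who present within the normal
  range;
* **elevated expressors**: log-normal truncated above the 37 U/mL
  clinical normal range, with the log-location solved (per center) so the
  overall mixture median matches the configured median.

The two control-like fractions sum to 0.35, matching the study's observed
share of test-set cancer cases inside the CA19-9 normal range (29 of 80).
This construction reproduces three reported conditions simultaneously:
overall CA19-9 AUC ≈ 0.82 against controls, AUC ≈ 0.5 within the normal
range, and the in-range case fraction.  Values are clamped at
configurable assay bounds (default 1.2 and 10,000 U/mL) with explicit
censor flags, and a configurable fraction (default 2%) is set missing
(flagged, never silently zero).

### MRM markers and transition-level data

Each marker is a protein with one proteotypic peptide and (default) three
transitions.  Per-sample latent log-abundance is normal within each group
(`group_loc`, `group_scale`); the relative level (light:heavy ratio) is
`exp(latent)`.  The default marker set is LRG1 (up in PDAC), TTR (down in
PDAC) and 20 null decoys.  The informative effect size defaults to a
single-marker AUC of 0.73 (log-scale shift `±√2·σ·Φ⁻¹(0.73)`): with 35%
of cases CA19-9-blind, the reported panel AUC (0.93) next to the anchor's
(0.83) requires the two protein markers to supply a combined AUC ≈ 0.81
in that subset, i.e. ≈ 0.73 per marker under independence.

Transition peak areas follow a stable-isotope-dilution model: heavy (SIS)
areas are `H·r_t` (spike level × transition response) with small
technical noise (default CV 2%); light areas are
`exp(latent)·H·r_t` × multiplicative replicate noise (default CV 8%, a
typical within-assay figure for a scheduled MRM platform; the study does
not report one).  Transition responses are drawn once per peptide (or
configured) and recorded in the ground truth.  A β-galactosidase-like
external-standard channel is emitted alongside for external-standard
normalization.

**Interference** is injected per (peptide, transition) pair with
probability `interference_rate` as an *additive light-channel-only* bias
comparable to the clean signal, with replicate-level jitter — the
signature that interference-detection exploits is precisely the
light-vs-heavy discordance this creates.  Batch-affected markers apply a
configurable fold change to odd-numbered batches.  The generator never
simulates chromatograms or retention time; it starts at integrated peak
areas.

### What the generator does not emulate

Real plasma MRM data have correlated markers (shared pathways, shared
depletion artifacts), heteroscedastic and intensity-dependent noise,
missingness that is abundance-dependent rather than random, retention-time
drift, and batch effects that touch many analytes at once.  Passing
recovery tests on this generator therefore demonstrates that the
*pipeline logic* is correct and calibrated — not that the thresholds
would perform identically on clinical data.

## Quantitation

For each peptide, the **signature transition** is chosen once globally:
the transition with the largest total light area over all samples and
replicates (ties break to the lexicographically smallest id), so a
peptide's quant series is internally comparable.  The relative peptide
level is the signature transition's light:heavy ratio (or
light:external-standard in external mode), averaged over replicates; the
replicate CV is the sample SD (n−1) over the mean of the *untransformed*
ratios, the convention a 10% CV cutoff refers to.  Zero light area is a
flagged below-detection zero; an absent or zero denominator is a flagged
missing value, never an exception and never a silent zero.

## Verification filters

All filters are computed independently on the full input, so the
surviving set does not depend on rule order.

* **Replicate CV**: a peptide fails when its median per-sample replicate
  CV exceeds 10%.
* **Reference range**: fails when the median relative level lies outside
  the open interval (0.1, 10).  The median across samples (rather than a
  per-sample rule) is used for robustness; a fraction-in-range variant
  can be built from the same per-sample levels.
* **Interference detection**: per peptide-sample, each transition's
  fractional contribution to the total light area is compared with its
  contribution to the total heavy area by a paired t-test across
  replicates; the replicate CV of the transition's light:heavy ratio is
  checked against 0.20.  An additive contamination inflates the affected
  transition's light contribution and passively deflates its siblings,
  so significant discordance is attributed only to positively shifted
  transitions — this keeps the deflated siblings unflagged and still
  catches doubly contaminated peptides.  A transition is declared
  interfered when flagged in more than 20% of evaluable samples; a
  peptide fails when its signature transition is interfered.  Thresholds
  (p < 0.05, CV > 0.20, 20% of samples) are package conventions exposed
  in `QCConfig`; the original interference-detection publication's exact
  thresholds are not adopted verbatim.
* **Confounders**: Kruskal–Wallis tests of each peptide's level against
  clinical center and against batch, run in the control group only (so
  disease effects cannot masquerade as nuisance effects),
  Benjamini–Hochberg-adjusted across peptides per factor; fail when
  either adjusted p < 0.05.  A factor with one observed level is skipped
  with a warning.
* **Single-marker screen**: orientation-free AUC (max(AUC, 1−AUC)) per
  configured comparison; the gate keeps peptides strictly above 0.60 in
  NL-vs-PDAC.  Which pairwise comparison gates survival is configurable
  because the original three-group screening criterion is two-class at
  heart.

## Statistical core

* **AUC** is the Mann–Whitney statistic with ties counted ½, identical to
  the trapezoidal area under the empirical ROC.
* **DeLong's test** uses the placement-value (structural-components)
  estimator of the paired AUC covariance and a two-sided z-test; a zero
  variance of the difference returns p = 1 with a degenerate flag.  The
  suite verifies it against a naive double-loop implementation (1e−12)
  and a 10,000-resample paired bootstrap.
* **Fixed-specificity cutoffs**: the cutoff is the smallest threshold
  whose training specificity reaches the target (achieved specificity may
  overshoot with tied controls, which is why reported specificities like
  0.921 or 0.944 exceed the 0.90 target); predictions are `score ≥
  cutoff`, and the cutoff transfers frozen to test cohorts.
* **McNemar's test** on discordant counts (b, c) is exact-binomial below
  b+c = 25 and asymptotic chi-squared above, *without* continuity
  correction: in null simulations at the discordant counts this pipeline
  sees, the corrected statistic rejects at 3.0–3.5% versus the nominal
  5%, while the uncorrected one is calibrated (4.8–5.0%).  The cases-only
  scope compares sensitivities at matched specificity; a whole-cohort
  scope is available for diagnostic-homogeneity use.
* **PPV** is `Se·P(D) / (Se·P(D) + (1−Sp)(1−P(D)))`, prevalence default
  12.9 × 10⁻⁵ (pancreatic-cancer prevalence in Korea); a zero denominator
  is defined as 0.

## Panel search and selection

Candidates are all marker subsets containing the anchor (CA19-9), sizes
2–3 by default (the exhaustive 1–5 sweep is configuration, not default).
Classifier features are log-scale: log10 of measured CA19-9 (censored
values at their clamp) and natural log of the MRM ratios.  All candidates
are evaluated on one shared complete-case sample set and one shared
stratified 5-fold assignment so the paired tests are valid; rows dropped
for missingness are counted in the result attributes.

The classifier is a two-class SVM (default linear kernel, C = 1 — the
smallest-assumption reading of the dual decision function; kernel and C
are configurable).  Markers are standardized with training-fold
statistics only, and standardization is refit per fold (leak-free).  The
continuous decision value Σαᵢyᵢ⟨x,xᵢ⟩+b is used for ROC construction; the
sign function is applied only at the frozen cutoff.

Raw SVM decision values are not comparable across folds (each fold's
model carries its own offset), so each fold's out-of-fold scores are
centered at that fold's own fixed-specificity training cutoff before
concatenation.  A pooled score of zero then corresponds to the frozen
training cutoff in every fold: pooled AUC, pooled sensitivity at cutoff
zero, and the paired tests are all computed on this vector.  Without the
centering, pooled AUCs are biased several points low and
sensitivity-at-cutoff is not defined at all.

Selection is two-stage, computed on the cross-validated training scores
(selection on a held-out test set is available behind a flag but is
methodologically leaky):

1. AUC gain over the anchor ≥ 0.07 **and** DeLong p < 0.05;
2. sensitivity gain at 90% specificity > 0.10 **and** McNemar
   (cases-only) p < 0.05.

Survivors are ranked by cross-validated AUC, then sensitivity gain, then
marker names; the output is invariant to marker input order.

A caveat worth stating: the thresholds 0.07 and 0.10 are the gains the
original study *observed* for its final panel (0.931 vs 0.826, and
exactly +0.100 in sensitivity).  A candidate panel whose true gains equal
those of the published panel therefore sits on the selection boundary and
survives stage 2 only about half the time under resampling; the
selection event is intrinsically near-threshold, which the planted-panel
replication study makes visible.

## Validation design

The cohort splits 4:1 into training and test, stratified by group, stage
(within PDAC) and center, deterministic under a seed; strata of one
sample go to training with a warning.  Other-cancer samples are reserved
wholly for the test set, mirroring the study's training composition (316
PDAC / 88 PB / 280 NL, no OC).  The panel model and both decision
cutoffs (panel and anchor) are frozen on training data before any
test-set contact — byte-identical model files with or without the test
set present are an explicit acceptance check.

Eight scenarios mirror the published comparison table: control vs PDAC,
control vs stage I/II PDAC, other-cancer vs PDAC, benign vs PDAC, and the
four corresponding low-CA19-9 variants, where the restriction
(measured CA19-9 < 37 U/mL) applies to cases *and* controls before
scoring, with one global frozen cutoff throughout (consistent with the
identical sensitivities reported across scenarios).  Censored CA19-9
values participate at their clamped value; samples missing any panel
feature are excluded and counted.  Each scenario reports AUCs,
sensitivity/specificity at the frozen cutoffs, paired DeLong and McNemar
p-values, and PPVs; scenarios with under two samples in a class are
flagged unevaluable rather than failing the run.

## Replication studies and problem sizes

`mrmpanel.studies` packages the seeded simulation experiments used by the
acceptance tests and `scripts/acceptance.py`:

* *Null calibration*: 1000 replicates of n = 100 independent-noise
  cohorts; DeLong and McNemar should reject at 5% within binomial
  tolerance.
* *QC recovery*: 180-sample cohorts with 5 planted high-CV markers
  (20% vs 8% replicate CV), 5 out-of-range markers, 3 two-fold
  batch-shifted markers among 37 clean ones, and a companion cohort with
  interference injected at rate 0.1 over 50 peptides × 3 transitions.
  Interference runs on its own replicate so one injected defect's flags
  are not charged against another filter's false-flag rate.
* *Panel recovery*: the study-scale cohort (≈687 training samples after
  the 4:1 split) with LRG1/TTR planted among 20 decoys; and signal-free
  null cohorts on which any selected panel is a false positive.
* *Scenario pattern*: cohorts at 3× the study group sizes.  At study
  scale the low-CA19-9 test subset holds only ~28 cases, so its AUC
  carries a sampling SD of ~0.065 and a ±0.1 band around 0.5 is missed by
  chance alone in ~15% of replicates; at 3× (~85 subset cases) the same
  band is a ~99% event and the check measures the generator, not shot
  noise.

## Known limitations

* One peptide per protein; the peptide-vs-protein funnel bookkeeping of
  the original study is not reproduced.
* The original funnel's survivor counts (26/12/14 peptides) depend on the
  unavailable clinical data and are reproduced only against synthetic
  ground truth.
* The immunoassay channel is an emulated second measurement (monotone
  transform plus noise at a configurable log-scale correlation), not a
  model of ELISA chemistry.
* Marker levels are generated independently given the class; correlated
  marker panels, where combination gains are smaller, are not covered by
  the default studies.
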