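# Methods

This note records the models implemented in `lipomet`, the defaults and
why they were chosen, what the synthetic generators emulate (and do not),
and the numerical conventions used where the underlying analysis left a
choice open.

## Study design and data model

Four postharvest regimes are compared — A (baseline), B (hot–humid holding
alone), C (100 MPa HPP + holding), D (500 MPa HPP + holding) — with three
biological replicates each (12 samples). The targeted layer is a
49-species free-fatty-acid (FFA) concentration table in ng mg⁻¹ fresh
weight; the untargeted layer is a features × samples abundance matrix with
per-feature annotation (MSI confidence level, chemical superclass, lipid
class). All untargeted statistics run on the MSI level 1–2 subset;
level 3–4 features are retained for reporting only.

## Targeted layer

**Calibration.** Area ratios y against nominal concentration x are fit by
weighted least squares minimising Σ wᵢ(yᵢ − a·xᵢ − b)² with wᵢ = 1/xᵢ or
1/xᵢ², the standard remedies for the proportional (constant-relative-
error) noise of GC–MS quantification; 1/x² is the default because the
synthetic fixture's noise is exactly proportional to concentration. The
reported R² is weighted: 1 − SSE_w/SST_w about the weighted mean.
Back-calculated concentrations below zero are clamped to 0 and flagged.
The fresh-weight content formula C_con = Cs·V1·V2/(M·V3) uses V1 in mL and
V2, V3 in µL (their units cancel); defaults V1 = 0.16, V2 = 1000,
V3 = 800.

**QC gate.** accuracy = mean/nominal in [0.80, 1.20] and RSD ≤ 0.20, all
bounds inclusive (the stated ranges are inclusive ranges). Retention-time
QC passes iff every marker deviation is strictly under 30 s; the RT model
regresses observed on reference retention time (the fitting direction is
not dictated by the workflow; observed-on-reference is the choice here and
is configurable by swapping arguments).

**Regime statistics.** Totals are sums over *detected* species
(concentration > 0 in ≥ 1 sample); undetected species contribute zero
rather than being imputed. Group comparisons use one-way ANOVA followed by
Tukey HSD. Pairwise Tukey p-values come from the studentized-range
distribution (Tukey–Kramer statistic, numerical CDF via
`scipy.stats.studentized_range`); compact letters are built by the
insert-and-absorb construction, which represents the pairwise decision
matrix exactly: two regimes share a letter iff they are not significantly
different at α = 0.05 (two-sided throughout). SEM = sample SD/√n.
Saturation classes follow double-bond count (SFA 0, MUFA 1, PUFA ≥ 2);
percentages are of the detected-species total; O/L is the 18:1/18:2
concentration ratio, undefined (flagged) when linoleic is zero.

## Chemometrics

**Preprocessing.** log2(abundance + 1) elementwise, then column
autoscaling (mean-centre, unit variance) — the conventional default for
PCA/OPLS-DA in this software family. Autoscaling a feature column across
samples is the same operation as the per-feature "row-wise Z-score" used
for heatmaps. Zero-variance features are dropped with a warning.

**PCA** is the SVD of the centred scaled matrix; R²X per component is
component variance over total variance. Equivalence with a covariance
eigendecomposition (up to sign) is enforced by test at 1e-6.

**Top-variable clustering** ranks features by variance of log2(x+1)
(ties broken lexicographically by feature id for determinism), Z-scores
the top-k block per feature, and clusters both axes agglomeratively with
Euclidean distance and average linkage (no linkage is dictated; both are
configurable).

**OPLS-DA.** The class response is a single ±1 column for two classes and
centred per-class indicator columns otherwise. Each orthogonal round
computes the joint covariance-maximising weight w (dominant left singular
vector of XᵀY), derives the orthogonal weight w_o = p − (wᵀp)w from the
X-loading p, and deflates X by the orthogonal component. Predictive
components are then extracted by NIPALS PLS2: one component for a binary
model, n_classes − 1 (the rank of the centred indicator matrix) for the
global model. Defaults: one orthogonal component for pairwise models
(`auto` adds components while Q² improves by > 0.01). R²X(cum) is
1 − residual SS/total SS after removing orthogonal plus predictive
structure (verified against explicit reconstruction at 1e-9);
R²Y(cum) analogously on Y.

**VIP** over predictive components:
VIP_j = √(p · Σ_a SSY_a w_ja² / Σ_a SSY_a) with SSY_a = (t_aᵀt_a)·‖c_a‖².
Because each weight vector has unit norm, mean(VIP²) = 1 identically —
enforced by test at 1e-6.

**Q²** comes from k-fold cross-validation (default 7, round-robin
assignment in sample order; with 12 samples and the canonical A1..D3
ordering the folds are class-balanced; leave-one-out available via
`cv_folds=12`). Within each fold the entire orthogonal + predictive
structure is refit on training samples only (training-mean centring), and
Q² = 1 − PRESS/SS with SS measured about the training means. Q² ≤ R²Y on
every model tested, and the pairwise screen never consumes Q²
(`compute_q2=False`).

Two small-sample properties of cross-validated Q² are worth stating
because they bound what the synthetic benchmarks can show. (i) On
pure-noise data (n = 12) the null Q² distribution centres below zero but
retains a positive tail of roughly 10–20 % of seeds: chance separations
supported by most of the 12 samples survive fold deletion. (ii) When the
feature count far exceeds the sample count *and* features are mutually
independent, held-out predictions attenuate toward zero, so Q² of even a
well-separated model is modest; the global 4-class model on the default
synthetic metabolome (2,142 features, most of them independent noise)
reaches Q² ≈ 0.2–0.5 rather than the near-1 values typical of real,
strongly correlated metabolome matrices. Neither property affects the
screening rule, which uses VIP, fold change and the t-test only.

**Permutation test.** Labels are permuted uniformly n times (default
200); the model is refit with identical structure; R²Y and Q² are recorded
against the absolute correlation between permuted and original dummy-coded
labels; the R²/Q² intercepts are the values at zero correlation of
least-squares lines through all permuted points plus the unpermuted model
at correlation 1. A negative Q² intercept and an original Q² exceeding
every permuted Q² support validity. Fewer than 20 permutations triggers an
instability warning.

## Screening and tiers

A feature passes a contrast iff VIP > 1 (strict), |log2FC| ≥ 1
(inclusive) and p < 0.05 (strict) — boundary semantics as stated.
log2FC is computed on raw group means (second regime over first); when
either mean is zero, both receive an epsilon of 1e-3 × the smallest
positive abundance in the table. The p-value is a two-sided pooled-
variance Student t-test on raw abundances (Welch is an option); with
n = 3 per group the pooled variant is the conventional default and the
transform is treated as a visualisation device. VIP comes from a fresh
two-class OPLS-DA (1 predictive + 1 orthogonal component) per contrast on
the autoscaled log2(x+1) matrix of the two groups.

Tiers over the six canonical contrasts: the shared core is the
intersection of the three A-referenced pass sets; a feature is B/C/D-
specific when it passes exactly one A-referenced contrast; recurrence is
the pass count over all six (≥ 5 defines the robust-marker tier);
direction consistency is evaluated only over A-referenced contrasts the
feature passed (a single pass is trivially consistent); max VIP / min p
are taken over the A-referenced contrasts.

## Integration

The signature score of a feature set is the per-sample mean of member
Z-scores (autoscaled log2(x+1)) — an operational definition, since
"module score" admits many conventions; an empty signature is an error,
never zero. Spearman coupling uses exact average-rank rho; for n ≤ 12 the
two-sided p is a seeded Monte-Carlo permutation p (default 1e5 vectorised
rank-correlation resamples, add-one corrected) because the t
approximation is unreliable at these sample sizes; BH-FDR is applied
within the whole signature × metric family
{total, SFA%, MUFA%, PUFA%, oleic%, linoleic%, O/L}.

Superclass enrichment tests each tier × superclass 2×2 table against the
discriminant-union background with the two-sided Fisher exact test
(sum of tables at most as probable as observed); odds ratios take a
Haldane 0.5 correction when any cell is zero (flagged); BH-FDR within
each tier.

The elastic-net classifier is multinomial logistic regression with
l1_ratio 0.5 (saga), repeated stratified threefold cross-validation
(default 20 repeats), features standardised on training folds only,
penalty strength chosen by an inner stratified twofold search on the
training fold, and all metrics (Accuracy, Macro-F1, one-vs-rest
Macro-AUC, row-normalised confusion) computed from pooled out-of-fold
probabilities; fold bookkeeping is exported so the no-leakage property is
assertable. Features are ranked by mean |coefficient| across classes,
folds and repeats.

## Lipid channels

The channel map is total and deterministic: PC/PE/PG/PI/PS/PA/CL → GPL;
LPC/LPE/LPG/LPI/LPS/LPA (plus "L"-prefixed GPL codes and a configurable
alias list) → Lyso-GPL; TAG/DAG/MAG → neutral; anything else is reported
as unmapped, never dropped. A regime's channel total is the mean over
replicates of the within-sample feature sum, making totals invariant to
replicate count (regime-wise *sums* would not be). log2 fold-changes are
against the baseline regime (exactly 0 at baseline; NaN-flagged if the
baseline total is zero), clipped at ±4 for display with the raw value
retained in a log10 audit view whose signs always agree with the clipped
view. The composite indices are explicitly operational: hydrolysis index
= mean Lyso-GPL Z − mean GPL Z per sample; acyl-editing index = mean Z
over both membrane channels. These channel summaries are semi-
quantitative, annotation-derived evidence, not absolute lipid
quantification.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated.

**Targeted preset.** 49 species (21 SFA, 8 MUFA, 20 PUFA by acyl
descriptor); 7 long-chain polyunsaturates are undetectable (zero
everywhere), leaving 42 detected. Regime totals are fixed at 247.50,
220.47, 380.59 and 2401.41 ng mg⁻¹; unsaturated fractions at 63.29 % (A),
64.25 % (B), 71.50 % (C) and 79.87 % (D) — A and D are reported values,
B and C interpolate the trend. Within each pool, oleic (18:1) carries
60 % of the unsaturated mass and linoleic (18:2) 27 % (oleic-dominant,
O/L ≈ 2.2, the oil-tea profile); palmitic and stearic dominate the
saturated pool; remaining mass is spread over minor species. Noise is
multiplicative log-normal with CV 2 % (concentrations are positive and
reported CVs small, so log-normal avoids negative draws); per-species
regime means beyond the printed totals/fractions are a modelling choice,
not data.

**Planted metabolome.** 2,142 features (1,338 at MSI level 1, 804 at
level 2 — levels 3–4 are excluded from statistics and therefore not
simulated). Planted tiers are per-regime log2 offsets from a log-normal
base abundance (median 1e5), with 5 % multiplicative noise and a random
sign flip of each planted feature's whole profile (70 % up):

| tier | n | profile (A,B,C,D in log2) | passes |
|---|---|---|---|
| shared core, equal shift | 20 | 0, 2, 2, 2 | A–B, A–C, A–D |
| shared core, all-distinct | 5 | 0, 2.5, 4, 6.5 | all six |
| B-specific | 47 | 0, 2, 0, 0 | A–B, B–C, B–D |
| C-specific | 45 | 0, 0, 3, 0.7 | A–C, B–C, C–D |
| D-specific | 138 | 0, 0, 0.6, 2.5 | A–D, B–D, C–D |
| five-of-six | 24 | 0, 0, 2.5, 4 | all but A–B |

so the recovered tiers are 25 shared-core, 47/45/138 specific and
29 recurrent (≥ 5/6) with 5 features in all six contrasts. Two deliberate
design points: (i) the 0.6/0.7 secondary shifts on the C/D-specific
tiers, and the sub-threshold lipid-channel trends below, emulate the
correlated pressure response of real data; their |log2FC| sits ≥ 5
within-noise SDs below the screening gate, so tier counts are recovered
exactly (verified over 20 seeds). (ii) The per-tier primary effects
(2.0–3.0, all above a 1.5 floor) induce a strict variance ordering
(all-distinct > five-of-six > C > D > B/core), which places the
C/D-co-shifted features in the top-100-variance set and reproduces the
observed clustering topology — holding-only samples (A, B) splitting from
the pressure-treated ones (C, D) — a topology that is unreachable if all
tiers share one effect size, because the 138 D-specific features then
dominate the top-variance set and force a D-versus-rest split.

118 features carry lipid-class labels with sub-threshold channel trends
(log2 offsets over A,B,C,D): GPL 0/−0.08/−0.30/−0.70,
Lyso-GPL 0/+0.08/+0.30/+0.70, neutral 0/+0.05/+0.18/+0.35 — membrane
signals fall and lyso signals rise with pressure, strongest under
500 MPa. Superclasses are drawn from ten classes with proportions
patterned on the level-1 annotation set; channel features are labelled
"Lipids".

**Calibration fixture.** Six levels (10–500 ng mL⁻¹), per-analyte slopes
in 0.004–0.02, area-ratio noise proportional to concentration (scale 2 %,
the regime 1/x² weighting is designed for), six QC injections at
100 ng mL⁻¹; a per-analyte bias multiplier can force QC failures. The
default fixture passes the QC gate for all 49 analytes.

**What the generators do not emulate.** Feature–feature correlation
beyond the planted co-shifts (real metabolomes are strongly correlated —
this is why the synthetic global Q² is modest, see above), annotation
uncertainty, missingness mechanisms other than hard non-detection,
batch/injection-order drift, and chromatographic artefacts. Passing tests
therefore demonstrate correctness of the statistical machinery under the
declared structure, not robustness to those real-data pathologies.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (generators refuse to
run without one); the acceptance script derives independent sub-seeds
below 2³¹ from a single `--seed` via `numpy.random.SeedSequence`. Default
problem sizes — 12 samples, 2,142 features, 200 permutations, 20
classifier repeats, 1e5 Spearman resamples — run the whole pipeline in
seconds on one core and are the sizes at which all reported recoveries
were measured.

## Known limitations

Tukey letters are a display of the pairwise decision matrix; with highly
irregular decision patterns the letter display remains exact but can need
several letters. The permutation intercepts are linear extrapolations and
inherit the usual caveats at small n. The elastic-net analysis is
supportive, not primary evidence: 12 samples give wide uncertainty on any
cross-validated metric. The O/L ratio is undefined when linoleic acid is
absent and is reported as NaN with a flag rather than imputed.
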