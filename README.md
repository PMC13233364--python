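# lipomet

Dual-layer postharvest lipid metabolomics in Python: a tested, reusable
implementation of the analysis chain used to study how high-pressure
processing (HPP) reshapes early lipid mobilization in oil-tea
(*Camellia oleifera*) seeds during a hot–humid holding window.

The experimental design compares four postharvest regimes, each with three
biological replicates: **A** (untreated baseline), **B** (hot–humid holding
alone, 35 °C / 95 % RH / 12 h), **C** (100 MPa HPP before holding) and
**D** (500 MPa HPP before holding). Two measurement layers feed the
analysis:

- a **targeted layer** — GC–MS quantification of 49 free fatty acids
  (FFAs) on a fresh-weight basis, and
- an **untargeted layer** — an annotated LC–MS metabolome restricted to
  MSI level 1–2 features for all statistics.

## What the package computes

**Targeted quantification** (`lipomet.targeted`). Weighted linear
calibration of analyte/internal-standard area ratios
(w = 1/x or 1/x²), back-calculation, and the fresh-weight content formula

```
C_con = Cs · V1 · V2 / (M · V3)        [ng mg⁻¹ FW]
```

with V1 = 0.16 mL, V2 = 1000 µL, V3 = 800 µL; QC gating at 80–120 %
accuracy and RSD ≤ 20 %; detection filtering; regime mean ± SEM summaries
with one-way ANOVA and Tukey HSD compact letters; and FFA-derived metrics
(SFA/MUFA/PUFA fractions, oleic/linoleic shares, the O/L ratio).

**Chemometrics** (`lipomet.chemometrics`). log2(x+1) transform and
autoscaling; PCA; hierarchical clustering of the 100 most variable
features; OPLS-DA with per-feature VIP scores
(VIP_j² averages 1 by construction), R²X/R²Y/Q² summaries, and a
200-label-permutation validity test with R²/Q² intercepts.

**Discriminant screening** (`lipomet.screening`). Six pairwise contrasts
(A–B, A–C, A–D, B–C, B–D, C–D) under the unified rule
**VIP > 1 ∧ |log2FC| ≥ 1 ∧ p < 0.05**, then tier assembly: the shared core
(passing all three A-referenced contrasts), B/C/D-specific discriminants,
recurrence counts over all six contrasts (≥ 5 defines the robust-marker
tier), direction consistency, and UpSet intersection counts.

**Integration** (`lipomet.integration`). Spearman coupling of signature
scores to the FFA metric family with Benjamini–Hochberg FDR; superclass
enrichment of tiers against the discriminant background (two-sided Fisher
exact, Haldane-corrected odds ratios); and multinomial elastic-net
classification of the regimes from the FFA matrix under repeated
stratified threefold cross-validation, scored strictly out-of-fold
(Accuracy, Macro-F1, Macro-AUC, confusion matrix, coefficient ranking).

**Lipid channels** (`lipomet.channels`). Membrane glycerophospholipid
(PC/PE/PG/PI/PS/PA/CL) vs Lyso-GPL vs neutral acylglycerol (TAG/DAG/MAG)
channel totals per regime, baseline-referenced log2 fold-changes clipped
at ±4 with a log10 audit view, the Lyso/GPL ratio, and per-sample
composite hydrolysis / acyl-editing indices.

**Synthetic data** (`lipomet.synth`). First-class generators that encode
the study conditions — regime FFA totals of 247.50 / 220.47 / 380.59 /
2401.41 ng mg⁻¹ with ~2 % within-regime CV and 7 of 49 species
undetectable; a 2,142-feature metabolome with planted discriminant tiers
(25 shared-core, 47/45/138 regime-specific, 29 recurrent markers of which
5 separate every pair) and sub-threshold membrane-lipid channel trends —
so every downstream stage is testable end to end with known ground truth.

## Worked example

```python
from lipomet import PlantConfig, generate_untargeted
from lipomet.screening import run_all_contrasts, assign_tiers

table, truth = generate_untargeted(PlantConfig(seed=1))
tiers = assign_tiers(run_all_contrasts(table, table.design))
print(int(tiers["core_a"].sum()),
      tiers["specific_to"].value_counts()[["B", "C", "D"]].tolist(),
      int((tiers["recurrence"] >= 5).sum()))
```

prints

```
25 [47, 45, 138] 29
```

— the screen recovers the planted structure exactly: 25 metabolites pass
all three baseline contrasts (the shared core), 47/45/138 are specific to
the B/C/D contrasts, and 29 recur in at least five of the six contrasts.
The `examples/` directory holds one narrative script per capability
(targeted quantification, screening, chemometric validation, integration,
lipid channels); each builds its own input, runs the method and explains
the numbers it prints.

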