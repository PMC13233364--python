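"""Targeted FFA layer: calibration, QC gating and regime statistics.

Builds the default synthetic calibration fixture and concentration table,
fits weighted calibration curves, gates the QC injections, and summarises
total free fatty acids per regime with ANOVA and Tukey letters.
"""

import numpy as np

from lipomet import CalibrationFixture, SampleDesign, generate_calibration, generate_targeted
from lipomet.targeted import (
    calibration_qc_ledger,
    detection_filter,
    ffa_metrics,
    regime_summaries,
)

# --- weighted calibration + QC ledger -------------------------------------
fixture = CalibrationFixture()
points, qc, _ = generate_calibration(fixture, seed=1)
ledger = calibration_qc_ledger(points, qc, fixture.qc_nominal, weighting="1/x2")
print(f"QC ledger: {int(ledger['pass'].sum())}/{len(ledger)} analytes pass "
      f"(accuracy 80-120%, RSD <= 20%)")
print(ledger.head(3).round(4))

# --- concentration table: detection and regime statistics ------------------
table, _ = generate_targeted(seed=1)
design = SampleDesign.default()
detected = detection_filter(table)
print(f"\nDetection: {int(detected.sum())} of {len(detected)} species seen in >=1 sample")

total = regime_summaries(table, design, per_species=False)["total"]
print(f"\nTotal FFA one-way ANOVA p = {total.anova_p:.3g}")
print(total.stats.round(2).assign(letter=[total.letters[r] for r in total.stats.index]))
# Regime D carries a step-change FFA burden (unique Tukey letter); A-C stay
# two orders of magnitude lower.

m = ffa_metrics(table)
unsat = (m["MUFA_pct"] + m["PUFA_pct"]).groupby(design.regime_of()).mean()
print("\nUnsaturated fraction (MUFA+PUFA, % of detected pool):")
print(unsat.round(2).to_string())
# The mobilised pool is unsaturation-enriched: ~63% in A rising to ~80% in D.
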