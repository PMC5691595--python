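"""Relative gene-expression fold change by the 2^-ddCt method.

Ct values for a melanin-biosynthetic gene (e.g. TYR) are normalized
against a housekeeping gene within each condition; the fold change is
2 to the minus ddCt, so one cycle of earlier amplification in the
treated condition doubles the inferred expression.
"""

from herbnetpharm import QpcrMeasurement, ddct_fold_change_replicates

treated = [
    QpcrMeasurement("t1", "TYR", ct_target=23.1, ct_reference=18.0, condition="treated"),
    QpcrMeasurement("t2", "TYR", ct_target=23.4, ct_reference=18.2, condition="treated"),
    QpcrMeasurement("t3", "TYR", ct_target=22.9, ct_reference=17.9, condition="treated"),
]
control = [
    QpcrMeasurement("c1", "TYR", ct_target=25.0, ct_reference=18.1, condition="control"),
    QpcrMeasurement("c2", "TYR", ct_target=24.8, ct_reference=18.0, condition="control"),
    QpcrMeasurement("c3", "TYR", ct_target=25.2, ct_reference=18.2, condition="control"),
]

report = ddct_fold_change_replicates(treated, control)
print(f"{report.gene}: fold change = {report.fold_change:.2f} "
      f"(treated vs control, mean-dCt method)")
print(f"per-pair folds span {min(report.replicate_folds):.2f} - "
      f"{max(report.replicate_folds):.2f} across {len(report.replicate_folds)} pairings")
# A fold change > 1 means the gene is up-regulated in the treated cells.
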