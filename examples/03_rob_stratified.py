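"""Risk-of-bias stratified contrasts: separating bias from language.

The `bias_confounded` scenario plants NO language effect, but trials
rated high/unclear on the blinding-of-participants domain have their
true odds ratio multiplied by 0.5, and that rating is far more common
among Chinese-language trials (97% vs 51%).  The naive language contrast
therefore drifts below 1, while the ROB-stratified design attributes the
inflation to the biased trials.
"""

from metaror import make_fixture, run_analysis_preset

dataset = make_fixture("bias_confounded")

overall = run_analysis_preset(dataset, "language_overall").rows[0].pooled
print(f"naive language ROR: {overall.ror:.2f} "
      f"(95% CI {overall.ci_low:.2f} to {overall.ci_high:.2f})")
print("  ...below 1 even though no language effect was planted: the "
      "imbalanced risk of bias confounds the contrast.\n")

print("high/unclear vs low risk, within each language stratum:")
report = run_analysis_preset(dataset, "rob_within_language")
for row in report.rows:
    if row.rob_domain != "blinding_participants_personnel":
        continue
    if row.pooled is None:
        print(f"  {row.stratum}: no review with both strata")
    else:
        print(f"  {row.stratum}: ROR {row.pooled.ror:.2f} "
              f"(95% CI {row.pooled.ci_low:.2f} to {row.pooled.ci_high:.2f}), "
              f"{row.k_reviews} reviews")
print("A ROR below 1 here means trials with high/unclear risk on the "
      "driver domain overestimate the effect -- matching the planted 0.5.")
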