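"""Disease-association statistics on a planted cohort.

Runs the four-group one-way ANOVA with Tukey post hoc on per-sample program
scores, and correlates the surface-protein biomarker channel with the
physician-global VAS disease-activity score.
"""

from gepnet import SyntheticConfig, simulate_cohort
from gepnet.association import (program_activity_anova,
                                score_activity_correlation)

ds = simulate_cohort(SyntheticConfig(
    n_cell_types=3, genes_per_type=200, programs_per_type=3,
    cells_per_sample_per_type=30, activity_effect=2.0, seed=4,
))
scores = ds.truth.true_sample_usage
activity = set(ds.truth.activity_programs())

out = program_activity_anova(scores, ds.clinical)
anova = out[out["test"] == "anova"].set_index("unit")
print("four-group ANOVA per program (planted activity module marked *):")
for prog, row in anova.iterrows():
    star = " *" if prog in activity else ""
    print(f"  {prog}: F = {row['statistic']:6.1f}  p = {row['p']:.2e}{star}")
# Only the activity-module programs should show large F: their per-sample
# intensity was shifted by 2 latent SD per ordered disease-group step.

adt = ds.adt.join(
    ds.cell_metadata.set_index("barcode")["sample_id"]
).groupby("sample_id").mean()
corr = score_activity_correlation(adt, ds.clinical, family="biomarker")
row = corr.iloc[0]
print(f"\nbiomarker channel vs VAS: Spearman rho = {row['statistic']:.2f} "
      f"(p = {row['p']:.2e})")
# The ADT channel is an affine readout of the activity-module intensity, so
# a strong positive rank correlation with VAS is the planted expectation.
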