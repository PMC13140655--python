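"""Recompute the cohort statistics from the bundled reference table.

Loads the published per-participant network-similarity values of a
12-participant hypoxia cross-over study and runs the repeated-measures
ANOVAs and the symptom tests on them.
"""

from breathnet.datasets import (EXERCISE_PHASE_COLUMNS, REST_EXERCISE_COLUMNS,
                                REST_PHASE_COLUMNS, load_similarity_table,
                                symptom_counts)
from breathnet.stats import chi_square_vs_control, rm_anova_gg

table = load_similarity_table()
print("group mean WJSI:",
      table[REST_EXERCISE_COLUMNS].mean().round(3).to_dict())

for label, cols in [("rest-exercise", REST_EXERCISE_COLUMNS),
                    ("rest-phase   ", REST_PHASE_COLUMNS),
                    ("exercise-phase", EXERCISE_PHASE_COLUMNS)]:
    res = rm_anova_gg(table[cols])
    print(f"RM-ANOVA {label}: F({res.df_effect:.2f},{res.df_error:.2f}) = "
          f"{res.F:.2f}, p = {res.p:.4f}, eta2p = {res.eta2p:.3f}"
          f"{'  (GG-corrected)' if res.corrected else ''}")

counts, n = symptom_counts()
chi = chi_square_vs_control(counts["CTR"]["symptoms"],
                            counts["HY2"]["symptoms"], n)
print(f"symptoms HY2 vs control: chi2({chi.df}) = {chi.chi2:.1f}, "
      f"p = {chi.p:.3f}")
# eta2p is the fraction of (effect + error) variance explained by the
# condition factor; the chi-square compares the severe-hypoxia symptom
# rate against the control-arm rate.
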