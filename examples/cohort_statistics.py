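"""Cohort workflow: outlier screen, mixed ANOVA and Bonferroni post hocs.

Simulates control (NTG) and overexpressing (TG) groups whose generating
amplitudes differ by 40%, fits each subject's cosinor, screens the values
with ROUT (Q=5%), and runs the mixed-design ANOVA (genotype between
subjects, outcome measure within subjects) with a planned contrast.
"""

from dataclasses import replace

import pandas as pd

import circarun as cr
from circarun.stats import bonferroni_posthoc, mixed_anova, rout_outlier_screen

presets = cr.genotype_presets("rcan1_panel")
design = {
    "NTG": (replace(presets["NTG"]["LD"], n_days=7), 12),
    "TG": (replace(presets["TG"]["LD"], n_days=7), 12),
}
recs = cr.simulate_cohort(design, seed=11)

fits = [cr.cosinor_fit(rec, 24.0) for rec in recs]
meta = pd.DataFrame([{
    "subject_id": r.subject_id, "genotype": r.genotype, "sex": r.sex,
    "age_group": r.age_group, "condition": r.condition} for r in recs])
table = cr.rhythm_parameters_table(fits, meta)

for (geno, measure), grp in table.groupby(["genotype", "outcome_measure"]):
    flags = rout_outlier_screen(grp["value"].to_numpy(), q=0.05)
    if flags.any():
        print(f"ROUT flagged {flags.sum()} value(s) in {geno}/{measure}")

anova = mixed_anova(table, between=["genotype"], within=["outcome_measure"])
print(anova.effects.to_string(index=False))

amp = table[table["outcome_measure"] == "amplitude"]
posthoc = bonferroni_posthoc(amp, [("NTG", "TG")])
print(posthoc.to_string(index=False))

# A significant genotype x outcome-measure interaction with a significant
# NTG vs TG amplitude contrast reproduces the designed 40% amplitude gap.
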