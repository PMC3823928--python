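"""Generate a synthetic MS data mart and its MS-Center subset.

The generator draws overdispersed EHR count features from a latent
disease indicator and a latent severity scale, then marks a subset of
true-MS patients as clinic patients with EDSS, disease duration,
category (RR/SP/PP) and brain parenchymal fraction.
"""

import numpy as np

from ehrms import GeneratorConfig, generate_center_subset, generate_datamart

cfg = GeneratorConfig(n_patients=5000, seed=1)
cohort = generate_datamart(cfg)
center = generate_center_subset(cohort, cfg)

ms = [r for r in cohort if r.ms_label]
icd = np.array([r.codified_counts["ms_icd"] for r in ms])
q1, med, q3 = np.percentile(icd, [25, 50, 75])
print(f"patients: {len(cohort)}, true MS: {len(ms)}, center subset: {len(center)}")
print(f"female fraction: {np.mean([r.sex == 'F' for r in cohort]):.2f}  (target 0.73)")
print(f"MS diagnosis codes per MS patient: median {med:.0f} [Q1-Q3 {q1:.0f}-{q3:.0f}]")
print(f"median follow-up: {np.median([r.followup_years for r in cohort]):.1f} years")
prog = [r.edss for r in center if r.category != "RR"]
rr = [r.edss for r in center if r.category == "RR"]
print(f"mean EDSS, progressive {np.mean(prog):.2f} vs relapsing-remitting {np.mean(rr):.2f}")
# progressive patients sit in the upper severity range, so their EDSS is higher
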