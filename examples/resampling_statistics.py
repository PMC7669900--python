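"""Group comparisons with pooled-bootstrap t-tests and Fisher's exact test.

Builds per-condition trauma samples from the calibrated presets, screens
normality (Lilliefors), runs all-pairs bootstrap t-tests with Bonferroni
correction, and compares two insertion-success rates with Fisher's test.
"""

from retroprobe import stats as S
from retroprobe import synthetic as syn
from retroprobe.presets import TRAUMA_PRESETS

groups = {}
for k, label in enumerate(["PI-50@187.5", "PaC-50@187.5", "Si-60@187.5"]):
    p = TRAUMA_PRESETS[label]
    mean, sd = p.hole_area_params
    groups[label] = syn.gen_condition_samples(mean, sd, n=16, seed=100 + k)

print("per-condition ITA summaries (16 shanks each):")
print(S.summarize_conditions(groups)[["n", "mean_sd", "median"]])

lil = S.lilliefors_test(groups["PI-50@187.5"], n_mc=5000, seed=0)
print(f"\nLilliefors normality screen (PI-50): D = {lil.statistic:.3f}, p = {lil.p_raw:.3f}")

res = S.pairwise_posthoc(groups, B=10000, seed=7)
print("\nBonferroni-adjusted bootstrap-t p-values:")
print(res["p_adjusted"].round(4))
print("\nsignificance stars:")
print(res["stars"])

# success-rate contrast: the two anomalous groups vs their wide/narrow partners
fisher = S.fisher_exact(S.ContingencyTable2x2(a=31, b=33, c=56, d=4))
print(
    f"\nFisher's exact test, PaC-100 (31/64) vs PaC-50-like (56/60): "
    f"p = {fisher.p_raw:.2e} {S.significance_stars(fisher.p_raw)}"
)
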