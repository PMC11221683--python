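"""Affected-myofibril ratios with exact binomial CIs and a proportion test.

Simulates per-image myofibril counts for two genotype-like conditions
(10-15 myofibrils per image; a myofibril is "ruptured" with probability
0.25 in one condition and 0.05 in the other), pools the counts, and
compares the two pooled ratios with the continuity-corrected two-sample
proportion test.
"""

from wingsync import pooled_affected_ratio, simulate_phenotype_counts, \
    two_proportion_test

mutant = simulate_phenotype_counts(20, {"ruptured": 0.25}, seed=1)
control = simulate_phenotype_counts(20, {"ruptured": 0.05}, seed=2)

r_mut = pooled_affected_ratio(mutant, "ruptured")
r_ctl = pooled_affected_ratio(control, "ruptured")
test = two_proportion_test(r_mut.k, r_mut.n, r_ctl.k, r_ctl.n)

print(f"mutant-like : {r_mut.k}/{r_mut.n} ruptured = {r_mut.p_hat:.3f} "
      f"(95% CI {r_mut.ci_low:.3f}-{r_mut.ci_high:.3f})")
print(f"control-like: {r_ctl.k}/{r_ctl.n} ruptured = {r_ctl.p_hat:.3f} "
      f"(95% CI {r_ctl.ci_low:.3f}-{r_ctl.ci_high:.3f})")
print(f"2-sample proportion test: X-squared = {test.statistic:.3f}, "
      f"df = {test.df}, p = {test.p_value:.2e}")
# A small p-value says the two pooled ratios differ beyond sampling noise.
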