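"""The univariate statistics layer on cohort metadata.

Geometric means with confidence intervals and one-tailed t-tests on
log-transformed exposure levels, chi-square on gender, Mann-Whitney on a
metabolite between dosing groups, and Spearman correlation with an injury
score — the battery that accompanies the multivariate models.
"""

import numpy as np

from nmrmetab import (
    CohortDesign,
    chi_square,
    geometric_mean_ci,
    mann_whitney,
    simulate_cohort,
    spearman,
    t_test,
)

design = CohortDesign(n_per_class={"case": 31, "village_control": 17}, seed=19)
_, table, _ = simulate_cohort(design)
df = table.df

al_case = df.loc[df.class_label == "case", "al_level"].to_numpy()
al_ctrl = df.loc[df.class_label == "village_control", "al_level"].to_numpy()
for name, vals in (("cases", al_case), ("village controls", al_ctrl)):
    gm, lo, hi = geometric_mean_ci(vals)
    print(f"geometric mean urinary AL, {name:17s}: {gm:6.1f} (95% CI {lo:.1f}-{hi:.1f})")
tt = t_test(al_case, al_ctrl, log_transform=True, tail="one")
print(f"one-tailed t-test on log(AL): t = {tt.statistic:.2f}, p = {tt.p_value:.4f}")

gtab = [[int((df.loc[df.class_label == c, "gender"] == "M").sum()),
         int((df.loc[df.class_label == c, "gender"] == "F").sum())]
        for c in ("case", "village_control")]
cs = chi_square(gtab)
print(f"gender chi-square: chi2 = {cs.statistic:.2f}, p = {cs.p_value:.3f}")

# mouse-style comparison: a metabolite level between two dosing groups and
# its rank correlation with an injury score
rng = np.random.default_rng(0)
al_only = np.exp(rng.normal(0.0, 0.4, 10))
al_ddt = np.exp(rng.normal(-0.3, 0.4, 10))
mw = mann_whitney(al_only, al_ddt)
print(f"Mann-Whitney between dosing groups: U = {mw.statistic:.0f}, p = {mw.p_value:.3f}")
injury = np.clip(np.round(2 + 2 * np.log(al_only) + rng.normal(0, 0.8, 10)), 1, 5)
sp = spearman(al_only, injury)
print(f"Spearman with injury score: rho = {sp.statistic:.2f}, p = {sp.p_value:.3f}")
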