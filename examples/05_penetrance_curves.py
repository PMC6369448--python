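"""Age-dependent penetrance: population carriers vs clinical referrals.

Simulates carriers of a diabetes-associated variant at 10% cumulative
incidence by age 40 (the population-cohort view) and a clinically
ascertained cohort at 75% by 40 (the referral view), estimates both
Kaplan-Meier curves, and reads penetrance at age 40 off each - the
ascertainment contrast that makes population-based minimum-penetrance
estimates so valuable.
"""

import numpy as np

from popvar import simulate as sim, survival as sv

rng = np.random.default_rng(8)
cohorts = {
    "population_carriers": (800, ((40.0, 0.10), (73.0, 0.28))),
    "clinical_probands": (60, ((40.0, 0.75), (73.0, 0.95))),
}
curves, raw = [], {}
for label, (n, knots) in cohorts.items():
    onset = sim.draw_onset_ages(rng, n, knots)
    censor = rng.uniform(37, 73, n)
    event = np.isfinite(onset) & (onset <= censor)
    ages = np.where(event, onset, censor)
    raw[label] = (ages, event)
    curve = sv.kaplan_meier(ages, event, cohort_label=label)
    curves.append(curve)
    est = sv.penetrance_at_age(curve, 40)
    print(f"{label}: penetrance by 40 = {100 * est.penetrance:.1f}% "
          f"(95% CI {100 * est.ci_low:.1f}-{100 * est.ci_high:.1f}%), n = {n}")

stat, p = sv.logrank_test(*raw["population_carriers"], *raw["clinical_probands"])
print(f"Log-rank test between the two cohorts: chi2 = {stat:.1f}, p = {p:.2e}")

table = sv.compare_cohort_curves(
    curves, at_ages=[40.0, 50.0, 60.0],
    clinical_label="clinical_probands", population_label="population_carriers",
)
print("\nPenetrance by age and cohort:")
print(table.round(3).to_string(index=False))

# Population carriers come out near 10% penetrant by 40 while the
# clinical cohort sits near 75%: same variant, opposite ascertainment
# biases. The population figure is a minimum-penetrance estimate.
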