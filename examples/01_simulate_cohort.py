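"""Generate a synthetic pessary-fitting cohort and write it to CSV.

The generator draws 9 fitting and 6 non-fitting participants over the
78-variable measurement grid (8 anatomical parameters x 3 manoeuvres x up to
4 pessary conditions).  Measurements of the same parameter are correlated
across conditions; six designated variables differ between the groups by a
standardized effect; a small fraction of cells goes missing at random.
"""

from pessaryfit import default_effect_profile, generate_cohort, write_cohort

profile = default_effect_profile()  # effect 1.5 SD on six informative keys
cohort = generate_cohort(n_fitting=9, n_nonfitting=6, profile=profile, seed=1)
write_cohort(cohort, "synthetic_cohort.csv")

print(f"participants: {cohort.n}  ({cohort.n_per_outcome()})")
print(f"measurement grid: {cohort.measurements.shape[1]} variables")
n_missing = int(cohort.measurements.isna().sum().sum())
print(f"missing cells: {n_missing} of {cohort.measurements.size}")
print("informative variables (larger in the fitting group):")
for key in sorted(profile.informative_keys):
    print(f"  {key}")
# Each printed key is parameter__manoeuvre__pessary; these six are the
# variables the downstream VIP ranking should rediscover.
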