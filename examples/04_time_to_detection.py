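"""Censored time-to-detection analysis on a synthetic survey table.

Generates a survey table with the balanced study design (32 ponds x 2
years x 3 windows x 3 methods, 30-minute cap), drops never-detected
ponds, selects an accelerated failure time model by AIC, reports
predicted mean times to detection, and runs the ratio-statistic
permutation test for the year effect.
"""

import numpy as np

from bellwether import (
    FIELDLIKE_PARAMS,
    filter_ever_detected,
    generate_field_surveys,
    permutation_test,
    select_model_aic,
    survival_curves,
)

surveys = generate_field_surveys(
    params=FIELDLIKE_PARAMS, rng=np.random.default_rng(42)
)
included, excluded = filter_ever_detected(surveys)
print(f"{surveys['detected'].sum()} detecting surveys; "
      f"{included['pond'].nunique()} of 32 ponds ever detected "
      f"({excluded['pond'].nunique()} excluded)")

best, aic_table = select_model_aic(included)
print(f"\nminimum-AIC model: {aic_table.iloc[0]['terms']} "
      f"(AIC {best.aic:.1f}, next best {aic_table.iloc[1]['aic']:.1f})")

for var in sorted(best.levels):
    tab = best.predicted_mean_ttd(var)
    print(f"\npredicted mean time to detection by {var} (minutes):")
    for cat, row in tab.iterrows():
        print(f"  {cat:>12s}: {row['mean_ttd']:5.1f}  (SE {row['se']:.1f})")

res = permutation_test(
    included, "year", n_perm=500, rng=np.random.default_rng(7),
    terms=set(best.terms) | {"year"},
)
print(f"\npermutation test for year: ratio statistic "
      f"{res.observed_statistic:.2f}, p = {res.p_value:.3f} "
      f"({res.n_perm} resamples)")

curves = survival_curves(best, "year", times=np.array([0.0, 10.0, 20.0, 30.0]))
print("\nmodel survival curves S(t) by year (fraction of surveys still "
      "running):")
print(curves.round(3).to_string())

# A ratio statistic near 3 with a tiny p-value says detection took
# several times longer in the bad year; the lower survival curve marks
# the year in which surveys succeeded fastest.
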