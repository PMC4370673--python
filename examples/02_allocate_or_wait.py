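"""The allocate-or-wait decision for one field season.

At the start of a season a bellwether pond (a known, monitored
population) is surveyed and its larval detectability q is read off.
p_best = F(q)^(y-1) is the probability that none of the remaining years
will be better; the budget is released when p_best exceeds 0.4.
"""

from bellwether import (
    DEFAULT_ANCHORS,
    DecisionState,
    decide,
    fit_beta_from_percentiles,
    p_best,
)

dist = fit_beta_from_percentiles(*DEFAULT_ANCHORS)

print("q      years_left   p_best   decision")
for q in (0.15, 0.25, 0.35, 0.41):
    for years_left in (5, 3, 1):
        state = DecisionState(years_remaining=years_left, observed_output=q)
        print(
            f"{q:.2f}   {years_left:>10d}   {p_best(dist, state):6.3f}"
            f"   {decide(dist, state).value}"
        )

# A mediocre year (q = 0.25) is worth waiting out early in the study
# but triggers allocation when few years remain; the final year always
# allocates because p_best = 1 by construction.
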