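# bellwether

Temporally adaptive survey design for rare species whose detectability
swings from year to year.

Many elusive species — the motivating case is the marbled salamander
(*Ambystoma opacum*), a pond-breeding amphibian surveyed through its
larvae — are far easier to detect in some years than others, and those
swings are often correlated across a whole region. A survey program
with a fixed budget of site visits can then do markedly better by
*waiting for a good year*: monitor one or two "bellwether" sites with
known populations, and release the survey budget only when the current
year looks unlikely to be beaten. `bellwether` provides the pieces of
that workflow for conservation planners and quantitative ecologists:

- **Calibration** — fit a Beta(α, β) distribution of annual
  detectability from two (value, percentile) anchors by forcing the
  CDF through both points, e.g. detection probabilities 0.17 and 0.41
  at the 9th and 91st percentiles.
- **Decision rule** — given this year's observed bellwether output `q`
  and `y` remaining study years (current one included),

  ```
  p_best = F(q; α, β)^(y−1)
  ```

  is the probability that no remaining year will be better; allocate
  the whole remaining budget when `p_best > 0.4` (threshold
  configurable, plus a two-threshold partial-allocation variant).
- **Campaign simulator** — Monte-Carlo campaigns in which each pond's
  annual detectability is a weighted average `p_i = c·g + (1−c)·l_i`
  of a shared global draw `g` and independent local draws `l_i`, with
  correlation weight `c`; sweeps the full correlation × bellwether-count
  grid and reports mean/sd detection counts per cell.
- **Time-to-detection analysis** — accelerated failure time regression
  (Weibull / exponential / log-normal) for 30-minute right-censored
  survey durations, exhaustive AIC model selection over main effects
  and two-way interactions, predicted mean time to detection per
  category by marginal standardisation, and a permutation test whose
  statistic is the max/min ratio of those predicted means.
- **Synthetic data** — a generator for the balanced 32-pond × 2-year ×
  3-window × 3-method survey design with censoring, used by the tests
  and usable as a fixture for any survey pipeline.

## Worked example

```sh
python examples/03_campaign_simulation.py
```

```
non-adaptive baseline: 22.8 ponds detected (sd 4.6)
adaptive, 1 bellwether, correlation 1: 29.0 (sd 8.0)  -> +27%

mean detections (rows: bellwether ponds, cols: correlation)
      c=0.00  c=0.25  c=0.50  c=0.75  c=1.00
nb=0    22.9    22.8    22.9    22.8    22.8
nb=1    22.7    23.1    24.8    27.3    29.4
nb=2    22.4    23.1    25.0    27.2    29.1
```

With a 400-survey budget over 5 years and 20% pond occupancy, the
non-adaptive design (budget split evenly across years) detects about
23 occupied ponds per campaign. When annual detectability is strongly
correlated across the region, spending one survey a year on a single
bellwether pond and releasing the budget in the first good year raises
that to about 29 — roughly a quarter more detections for the same
budget. With no regional correlation the bellwether signal is
uninformative and adapting only costs surveys; more than one bellwether
pond adds essentially nothing at any correlation.

The survival-analysis side has its own walkthrough
(`examples/04_time_to_detection.py`): it generates a synthetic survey
table, drops never-detected ponds (17 of 32 retained under the default
preset), selects an AFT model by AIC, prints predicted mean times to
detection per year/method/window with standard errors, and runs the
permutation test (e.g. year ratio statistic 2.68, p < 0.002).

There is also a thin CLI mirroring the library
(`bellwether calibrate | decide | simulate | grid | synth |
fit-survival | permtest`), e.g.

```sh
bellwether decide --q 0.41 --years-left 2
```

## Layout

| path | contents |
| --- | --- |
| `src/bellwether/calibration.py` | beta calibration from percentile anchors |
| `src/bellwether/decision.py` | p_best and the allocate-or-wait rules |
| `src/bellwether/simulator.py` | campaign Monte Carlo and grid sweep |
| `src/bellwether/survival.py` | censored AFT fits, AIC selection, permutation test |
| `src/bellwether/synthetic.py` | balanced survey-table and monitoring-series generators |
| `src/bellwether/io.py`, `cli.py` | CSV schemas and the command-line layer |
| `docs/methods.md` | modelling assumptions, defaults and limitations |
| `examples/` | narrative scripts, one per capability |
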