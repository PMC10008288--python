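# envregimes

Windowed **environmental-regime indices** for ecologists who sample a
biological community at discrete dates but measure the environment (stream
discharge, nutrient concentration, temperature, dissolved oxygen, ...) at a
much finer, regular cadence. A single snapshot value — or even a plain mean
over the preceding interval — misses how variable, pulse-ridden, or fast-
changing the environment was before each sample. `envregimes` turns each
pre-sample window into 11 elementary indices covering three facets of the
regime:

| Facet | Code | Definition (per window) | Unit |
|---|---|---|---|
| magnitude | MA1 | mean | variable's unit |
| | MA2 | median | variable's unit |
| | MA3 | coefficient of variation, 100·s/x̄ (s with n−1) | % |
| | MA4 | skewness, m₃/m₂^{3/2} | — |
| frequency | ML1 | # low pulses: values below the window's 25th percentile | time steps |
| | MH1 | # high pulses: values above the 75th percentile | time steps |
| | EL1 | # extreme-low pulses: below the 10th percentile | time steps |
| | EH1 | # extreme-high pulses: above the 90th percentile | time steps |
| rate of change | RC | mean successive change, mean(xₜ₊₁ − xₜ) | unit / step |
| | RH1 | # positive successive changes | time steps |
| | RL1 | # negative successive changes | time steps |

Pulse thresholds are percentiles of the *window's own* values (the
hydrologic 25/75 and 10/90 convention), so "high" always means high relative
to the focal period. By default each window spans the days **between two
successive sampling dates** (`BetwSamT`, half-open on the left, inclusive of
the sampling date); fixed look-backs of any length in the series' native
step (e.g. 7 or 14 days, the `days_bf` idiom) are available alongside or
instead.

## Worked example

Simulate a year of synthetic daily discharge plus a 13-date schedule (the
first date is the study-initialization anchor; the other 12 are sampling
events), then compute the regime table:

```sh
envregimes simulate --seed 42 --out-series hydro.csv --out-dates dates.txt
envregimes compute --series hydro.csv --samples dates.txt --out regimes.csv
```

`regimes.csv` has 12 rows (one per sampling event) and 12 columns
(`SampleDate` plus the 11 indices). First rows and columns:

```
SampleDate  BetwSamT.MA1  BetwSamT.MA2  BetwSamT.MA3  BetwSamT.MA4  BetwSamT.ML1  BetwSamT.MH1
2019-02-01         13.60         11.23         63.90          3.23             8             8
2019-03-05         51.27         21.81        151.27          3.46             8             8
2019-04-02         18.48         11.86         93.07          2.81             7             7
2019-04-30         11.77          9.69         66.39          3.21             7             7
```

Reading the first row: in the ~31 days between initialization and the first
sample, discharge averaged 13.6 (median 11.2 — right-skewed, MA4 ≈ 3.2,
because of spiky pulses), fluctuated with a CV of 64%, and spent 8 days
below its own 25th percentile and 8 above its 75th. These columns are ready
to use as predictors in a community-ecology model alongside the snapshot
variables.

The same pipeline from Python:

```python
from envregimes import FixtureSpec, simulate_series, simulate_schedule, compute_regimes

spec = FixtureSpec(seed=42)
series = simulate_series(spec)
schedule = simulate_schedule(spec, series)
table = compute_regimes(series, schedule)   # 12 x 11 DataFrame in table.data
```

Multiple variables (wide or long CSV) and multiple windows batch into one
flat table with `<variable>_<window>.<code>` columns, e.g.
`--windows BetwSamT,7,14`. `envregimes summarize` writes a five-number
summary per index column across sampling dates. Tie handling at pulse
thresholds, the percentile interpolation rule, the skewness estimator,
signed vs. absolute rate of change, and timepoints vs. runs pulse counting
are all configurable via a YAML file (`--config`); see `docs/methods.md`.

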