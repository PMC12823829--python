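# ohca-survival

Scenario modelling of survival after out-of-hospital cardiac arrest (OHCA)
as a function of emergency response time.

Survival after cardiac arrest is extremely time-sensitive: each minute of
delay before treatment lowers the chance of survival by a roughly constant
fraction, with published estimates of 5–12% per minute. Ambulance response
times differ enormously between urban and remote municipalities — in Norway
from about 10 minutes in Bergen to over 30 minutes in island communities —
which translates directly into survival disparities. This package is for
EMS analysts, epidemiologists and digital-health researchers who want to
quantify what *earlier emergency calls* (for example, prompted by wearable
or home-monitoring alerts) would be worth in survival terms across such
cohorts.

## Model

Survival at delay *t* minutes follows exponential decay

```
S(t) = S₀ · (1 − r)^(t − t₀)
```

with per-minute decline rate *r* (default 0.07, the midpoint of the 5–12%
literature range), baseline survival *S₀* (default 1) and reference time
*t₀* (default 0). A call placed Δ minutes earlier shifts the effective
delay to max(T − Δ, 0) for a municipality with mean response time T; the
survival gain is reported in percentage points, 100·(S(T−Δ) − S(T)).
Stochastic variability is propagated by Monte Carlo: n draws of
S(t) + ε, ε ~ N(0, σ), clipped to [0, 1], summarised by their mean and the
2.5th–97.5th percentile simulation interval. A synthetic-data module
generates municipality cohorts (lognormal response times per geography
category) and noisy survival observations, and recovers *r* by a log-linear
least-squares fit for identifiability checks.

## Worked example

The bundled cohort holds four Norwegian municipality mean response times
(Bergen 10.2, Tokke 16.6, Lurøy 32.8, Sørfold 22.6 min). Running

```bash
ohca-survival table
```

prints

```
municipality category  response_min survival_0 survival_1 survival_5 survival_10
      Bergen big city          10.2      47.7%      51.3%      68.6%       98.6%
       Tokke mountain          16.6      30.0%      32.2%      43.1%       61.9%
       Lurøy   island          32.8       9.3%       9.9%      13.3%       19.1%
     Sørfold    rural          22.6      19.4%      20.9%      27.9%       40.1%

municipality  gain_pp_1  gain_pp_5  gain_pp_10
      Bergen      3.590     20.866      50.858
       Tokke      2.256     13.114      31.963
       Lurøy      0.696      4.047       9.865
     Sørfold      1.460      8.484      20.680
```

(relative-gain columns omitted here for width). Reading the first row:
with a 10.2-minute mean response, baseline survival is 0.93^10.2 = 47.7%;
a call placed five minutes earlier raises it to 0.93^5.2 = 68.6%, a gain
of 20.9 percentage points. Remote Lurøy gains far less in absolute terms
(4.0 pp at Δ=5) despite the same relative improvement — the structural
disadvantage of long baseline delays.

The same numbers are available as a library:

```python
from ohca_survival import (DecayParams, read_municipalities,
                           bundled_municipalities_path, build_scenario_table)

cohort = read_municipalities(bundled_municipalities_path())
table = build_scenario_table(cohort, DecayParams(r=0.07), deltas=[1, 5, 10])
print(table.to_percent_frame())
```

Other subcommands: `curve` (deterministic curve), `simulate` (Monte Carlo
curves with bands, optional `--plots`), `sensitivity` (sweep *r* over
0.05–0.12), `synth` (synthetic cohorts/observations). See
`ohca-survival --help`.

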