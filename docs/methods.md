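# Methods

## Survival-decay model

Survival probability after out-of-hospital cardiac arrest is modelled as
exponential decay in the delay *t* (minutes) from the emergency call to
treatment:

S(t) = S₀ · (1 − r)^(t − t₀)

- **r** — per-minute decline fraction, in [0, 1). Default 0.07, the
  midpoint of the commonly reported 5–12% per-minute range. It is a
  *configured* parameter, not estimated from data: the pipeline is meant as
  a transparent comparison framework, and the `sensitivity` sweep
  (default grid 0.05–0.12) shows how conclusions move with it.
- **S₀** — survival fraction at the reference time, in (0, 1]. Default 1.
- **t₀** — reference time in minutes, default 0.

Two parameterizations are possible: an absolute one (S₀ = 1, t₀ = 0, so a
municipality with mean response time T has baseline survival (1 − r)^T)
and a relative one (t₀ set to each municipality's T with a per-municipality
S₀). The absolute one is the default because it is closed under the
earlier-call shift and needs no per-municipality baseline inputs; the
relative form remains available through `DecayParams`.

An earlier-call scenario with shift Δ ≥ 0 evaluates S at the effective
delay max(T − Δ, 0). The delay cannot become negative, so survival is
capped at S₀ and the result carries an explicit `capped` flag rather than
raising — shifts beyond T are meaningful inputs in sweeps, not errors.
Gains are reported in percentage points (100·(S(T−Δ) − S(T))); a relative
gain column is also provided since the two tell different stories for
remote municipalities (equal relative gains, very unequal absolute ones).

Percent rendering rounds half-up at one decimal; unrounded fractions are
always written alongside (in `run_metadata.json`) so no downstream
comparison depends on rounding.

## Monte Carlo simulation interval

For every point of a time grid, `n_iter` draws S(t) + ε with
ε ~ Normal(0, σ) are clipped to [0, 1] and summarised by their mean and a
percentile pair (default 2.5th–97.5th, a *simulation interval*: the band
containing 95% of the noisy draws, not a confidence interval for S).
Defaults: `n_iter` = 10,000, σ = 0.02 on the probability scale. σ is a
free illustration parameter — the noise depicts generic stochastic
variability, not physiological uncertainty — and is echoed into every
output for provenance. An alternative `time` mode perturbs the delay
instead (ε in minutes, delay floored at 0) for users who prefer noise on
the timing axis; probability mode is the default since the band is then
exactly symmetric around the curve away from boundaries.

Numerical choices:

- One seeded PCG64 generator per simulate call; the noise matrix is drawn
  in a single block with grid points in row order, so a given seed yields
  bitwise-identical summaries across runs and platforms with the same
  generator.
- σ = 0 short-circuits to the deterministic curve exactly (no float drift
  through the mean).
- Percentiles use linear interpolation between order statistics
  (numpy's `linear` method), stated so that results are reproducible
  bit-for-bit; the test suite checks them against a sort-based brute force
  on the identical draws.
- Clipping to [0, 1] happens **before** summarising. This biases the mean
  toward the interior where the curve lies within a few σ of a boundary
  (worst case σ/√(2π) ≈ 0.008 at S = 1 with σ = 0.02); where
  S ∈ [3σ, 1 − 3σ] the truncation bias is below 10⁻⁵ and the MC mean
  tracks the deterministic value within the CLT bound 4σ/√n.

## Synthetic data and rate recovery

The generator emulates the two inputs the analysis consumes.

*Cohorts*: municipalities with category labels (big city / mountain /
rural / island by default) and strictly positive, right-skewed response
times. Response times are lognormal — the simplest strictly positive
right-skewed family — with a configurable median per category (defaults
10, 17, 23 and 33 minutes, centred on the four observed values) and a
common log-scale standard deviation (default 0.35, giving a realistic
~±2× spread between quiet and bad days). Only category-level means are
publicly available, so these distributional choices are conventions for
testing, not claims about any real EMS system: passing tests show the
pipeline handles data *with this structure* correctly, not that the model
fits registry microdata. Incident-level variation, seasonality and weather
are deliberately not modelled.

*Observations*: pairs (t, clip(S(t) + ε, 0, 1)) with ε ~ Normal(0, σ),
matching the Monte Carlo noise model.

*Recovery*: although r is configured in the analysis, it should be
identifiable from such data. The estimator fits log(s_obs) = a + b·t by
ordinary least squares and returns r̂ = 1 − exp(b) with a delta-method
standard error (se = exp(b)·se_b). The log-domain fit was chosen over
nonlinear least squares for transparency (closed form, no initialisation
or convergence concerns). Observations at the [0, 1] boundary are excluded
from the fit — the log transform is undefined at 0 and clipped values are
biased — and counted in a returned diagnostic (`n_excluded`). Near the
boundaries the surviving interior observations are themselves truncated,
so r̂ acquires a bias that vanishes as σ → 0; at the default test scale
(σ = 0.01, 200 observations over 0–30 min) the estimator recovers
r = 0.07 within ±0.01 in ≥95% of replicates. Degenerate inputs (fewer than
two interior observations, or all at one delay) raise rather than return a
meaningless slope.

## Input/output conventions

Municipality CSV columns: `name`, `type`, `response_min` (aliases like
`municipality`/`category`/`response_time_min` are accepted). National
response-time tables are published with decimal commas, so "10,2" parses
as 10.2 and the delimiter is auto-detected among comma, semicolon and tab
with an explicit override. Non-positive response times, missing columns
(named in the error) and duplicate municipality names are rejected;
malformed numbers report their row index.

Every run emits `run_metadata.json` containing the resolved configuration
— municipalities, decay parameters, shift list, Monte Carlo settings with
seed and generator name, package version — plus the unrounded scenario
fractions. `run_from_metadata` rebuilds the scenario table from this file
alone, so any output is reproducible from its own metadata. Plots are
flag-gated (`--plots`) and matplotlib is imported lazily, keeping the core
pipeline free of graphics dependencies.

## Problem sizes

The bundled analysis is desk-scale by construction: four municipalities,
41-point time grids, 10,000 Monte Carlo iterations, and a 100-replicate
recovery study with 200 observations each. The full test suite and the
reproduction script each run in seconds on one CPU.

## Known limitations

- No covariate adjustment (bystander CPR, defibrillator access, care
  quality); the decay rate is a single scalar shared across municipalities.
- The Gaussian probability-scale noise is illustrative; it is not an
  empirically informed uncertainty model, and clipping biases summaries
  near survival 0 or 1.
- Municipality *means* stand in for incident-level response-time
  distributions; survival at the mean is not the mean survival under a
  skewed distribution (Jensen's inequality), so cohort-level figures are
  comparative, not predictive.
- The recovery estimator is consistent only away from the [0, 1]
  boundaries; heavy clipping (large σ or S near 0) biases r̂ downward.
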