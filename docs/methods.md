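# Methods

This note documents the statistical procedures implemented in `infradian`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions adopted where the
underlying methodology leaves them open.

## Data model and selection

The unit of analysis is the menstrual cycle: the first day of bleeding is
the cycle time marker, and a cycle's length (whole days) runs up to and
including the day before the next onset. A `CycleSeries` is one woman's
ordered lengths anchored to her first onset date; onset dates of later
cycles are always *derived* from the anchor plus the cumulative lengths,
never stored independently, which makes date inconsistencies impossible by
construction.

Selection (`apply_selection`) reproduces the conventions of large
cycle-series databases: a series is stopped at the cycle *preceding* the
first cycle longer than 60 days (the over-long cycle typically marks a
pregnancy or a recording gap, so it and everything after it are dropped),
and series shorter than a minimum count are removed — 18 cycles for
actogram/wavelet statistics, 13 (one year) for the autocorrelation
analysis; 7 may be used for sparser cohorts at reduced precision. The
`[28, 30]`-day sensitivity subset keeps women whose *mean* series length
lies in the closed interval, compared as an exact rational; the
alternative reading (restricting individual cycles of 28–30 days) is
deliberately not implemented, since the per-woman-mean version is what the
published subset tables describe. Pooled quartiles use type-7 (linear
interpolation) quantiles.

## Actogram decomposition

For lengths d₁…dₙ with mean μ̂, the offsets cₖ = Σᵢ≤ₖ(dᵢ − μ̂) give each
onset's phase relative to a perfectly periodic rhythm of period μ̂. Two
identities are used as invariants: cₙ = 0 exactly (deviations from the
sample mean sum to zero), and trend + band + residual = offsets
(the residual is defined by subtraction).

*Trend.* Nadaraya–Watson Gaussian kernel regression over cycle index.
The bandwidth is set so the kernel's full width at half maximum is 12
cycles (σ = 12/(2√(2 ln 2)) ≈ 5.1 cycles), i.e. an effective ±6-cycle
window at half height — "about a year" of cycles. Weights are
renormalized at the series ends (no padding), so constants are preserved
exactly and straight lines in the interior to ~3σ of the edges.

*Band.* The asymmetric Christiano–Fitzgerald filter (statsmodels
implementation) passing periods of 3–12 cycles. The upper edge matches
the trend window (oscillations shorter than a year); the lower edge sits
above the 2-cycle Nyquist floor. The CF filter is linear and returns a
full-length output; its pass-band gain on an interior sinusoid is within
~20 % of unity and Nyquist content is attenuated below ~15 % RMS, which
the test suite verifies with injected signals.

*Wavelets.* One wavelet = one full oscillation: a pair of adjacent
opposite-sign runs of the band component between zero crossings. Runs are
paired in order of occurrence (first with second, third with fourth); an
unpaired terminal run is dropped. Duration is the total span in cycles —
pairs spanning fewer than 4 cycles are discarded as irregularities — and
amplitude is the maximum one-sided excursion max |band| within the
wavelet, chosen over peak-to-peak because the "amplitude ≥ 3 days"
screening criterion reads as a one-sided excursion.

*Context labels.* A cycle is a *jump* when its length exceeds the
reference period by more than `jump_threshold` (default 5 days; abrupt
lengthenings in real series are typically ≥ 10 days, so 5 separates them
cleanly from oscillatory excursions of ≤ 3 days). A wavelet is
`after_jump` when a jump falls within the two cycles before it or inside
its first half; `with_fluctuations` when the residual RMS inside it
exceeds its amplitude (the "oscillation" is then mostly unstructured
variability); otherwise `stable`. The three labels partition the set.

## Autocorrelation with a permutation null

Per woman, the divisor-n estimator
ρₖ = Σᵢ(dᵢ−d̄)(dᵢ₊ₖ−d̄) / Σᵢ(dᵢ−d̄)², k = 1…6, and the partial
autocorrelation φₖₖ by Durbin–Levinson on the ρ sequence (identical to the
last coefficient of the order-k Yule–Walker solve; the test suite checks
this equivalence against a direct Toeplitz solve and against statsmodels).
Divisor-n is the standard time-series convention and guarantees a valid
correlation sequence for the recursion. Constant series are flagged
(NaN) and excluded from averages; the averaging across women is
unweighted.

The null: within each woman, cycle lengths are exchangeable if there is
no serial dependence. Each of `n_perm` (default 5000) replicates
independently and uniformly permutes every woman's series, recomputes the
per-woman statistics and averages across women. Each woman's permutation
stream derives from the master seed and her rank in `woman_id` order, so
results are invariant to cohort file ordering. The two-sided p-value at
each lag is the add-one rank of the observed average in the null sample,
taken on the nearer tail and doubled (capped at 1): p ≥ 2/(n_perm+1) by
construction, and ties count as exceedances. z-scores use the null
sample's mean and SD (ddof = 1). Bonferroni across the six lags controls
the family at 0.05 — i.e. 0.025 per side as the bilateral convention. No
de-trending precedes the ACF: the permutation null is exchangeability of
the recorded lengths themselves.

The per-replicate computation is vectorized over (replicates × women ×
lags); a 5000-replicate run on several hundred women takes seconds, and
the calibration study in the acceptance tests (200 cohorts of 100 women ×
20 iid cycles at 500 replicates) runs in ~15 s.

## Lunar phase and circular tests

Phase is arithmetic: angle = 360° · frac((t − t₀)/29.53059 d) with t₀ the
reference new moon 2000-01-06 18:14 UTC, and onset dates taken at civil
midnight (no time-of-day or time-zone modelling — the resulting error is
bounded by half a day, ~6°). A constant synodic period drifts from a true
ephemeris by under ±0.6 d, small against the 3.69-d sector width; both
period and epoch are overridable in `LunarConfig`.

The eight sectors are 45° wide and *centered* on the principal phases
(new-moon sector [337.5°, 22.5°)). This centered-bin convention, combined
with the grouped Rayleigh using unit vectors at sector centers, is
validated by reproducing the published chi-square and Rayleigh p-values
(0.0214/0.0056 European, 0.0952/0.0226 North American) exactly from the
published count tables; the per-cycle Rayleigh is therefore computed on
binned angles, not continuous ones.

Rayleigh p-values use the finite-sample correction
P = e^(−Z)[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)], clamped to
[0, 1] (clamps are logged). The per-woman Rayleigh first takes each
woman's circular mean onset angle (undefined and excluded when the
resultant length is < 10⁻⁹) and applies the same test to those angles,
removing the within-woman clustering of cycles.

The Monte Carlo shift test mirrors the coupling hypothesis's natural
null: each replicate adds an independent uniform integer offset in
{0,…,29} days to every woman's whole series, which uniformises its lunar
placement while preserving all internal structure. For each sector the
observed count is ranked within the `n_iter` simulated counts. The rank
uses the tie-midpoint convention r = (#{sim<obs} + (#{sim=obs}+1)/2)/(n_iter+1):
because the simulated counts are discrete, counting ties wholly as
exceedances would bias null ranks low and break the uniform-rank property
the calibration suite checks; the midpoint rank is exactly mean-unbiased
under exchangeability. Sectors are flagged at 0.025 per tail; Bonferroni
across the eight sectors is off by default (matching how such per-phase
tables are usually reported) and available as a flag.

Circular smoothing for display places a von Mises kernel (κ = 1/bw²,
bw in radians — the large-κ circular-SD match, default 30°) at each
sector center; the density integrates to the total count.

## Synthetic generator

`generate_series` superimposes, around a per-woman mean period μ:
a sinusoid (amplitude A days, period P cycles, random phase), an AR(1)
residual rᵢ = φ·rᵢ₋₁ + εᵢ with Gaussian innovations of SD σ, and
Bernoulli phase jumps adding J days with per-cycle probability q; lengths
are rounded half-up to whole days and clipped at a 10-day physiological
floor (clips logged). This reproduces the three qualitative regimes of
real actograms — stability with occasional jumps, stability with
multi-cycle oscillations, rapid random fluctuation — with interpretable
parameters, but it is a phenomenological stand-in, not a fitted model of
ovarian dynamics: real series also show age trends, skewed length
distributions, and non-stationary variance that the generator omits.
Passing calibration/power tests on this generator therefore demonstrates
the *statistical machinery* is correct and well calibrated, not that real
cohorts will show any particular effect.

Defaults describe a typical mid-reproductive-age woman: μ = 29.3 d (the
population mean cycle length), σ = 2 d (within-woman variability),
A = 1.5 d over P = 8 cycles (mild relative coordination), φ = 0.3,
q = 0.02 with J = 15 d (rare abrupt lengthenings), 24 cycles (two years).
Cohort-level heterogeneity draws each woman's μ from N(29.3, 2.0).

Lunar coupling is applied by *placement*: a target angle is drawn from
vonMises(μ_phase, κ) and the series start date is shifted by the whole
day in {0,…,29} bringing the first onset phase closest to it (κ = 0
degenerates to a uniform 0–29-day shift — exactly the shift-test null).
Lengths are never altered. Coupling therefore concentrates first onsets;
later onsets disperse as the woman's phase random-walks, which is the
realistic behaviour of weak entrainment. The coupled study condition used
in the power checks sets μ = 29.53 d (women whose endogenous period
matches the synodic month — the subpopulation a lunar synchronizer could
plausibly hold in phase), σ = 2 d, κ = 2, 24 cycles, 200 women; null
calibration cohorts use 100 women × 12–20 cycles. Problem sizes in the
calibration suites (200 cohorts, 500 replicates) were chosen to keep
Monte Carlo error on rejection rates near ±1.5 % while the whole suite
runs in well under a minute per study.

Seeding: every stochastic routine takes an explicit seed; per-woman
sub-seeds derive from `numpy` `SeedSequence` spawning, so cohorts are
bit-reproducible and independent of generation order.

## Numerical conventions and edge cases

- Rounding of simulated lengths: half-up (`floor(x + 0.5)`), matching
  day-resolved records.
- Degenerate inputs raise typed errors: series of < 2 cycles cannot form
  an actogram; < 12 / < 6 cycles leave trend/band NaN-filled; constant
  series are zero-variance-flagged in the ACF; empty cohorts and
  zero-count phase tables are rejected.
- Boundary conventions are inclusive where an interval is written as
  closed: amplitude flags at ≥ 3 days, the [28, 30] mean-length subset at
  both ends.
- All p-values are clamped to [0, 1]; permutation and rank p-values use
  add-one rules and cannot be 0 or 1 exactly (midpoint ranks lie strictly
  inside (0, 1)).

## Known limitations

- The arithmetic lunar phase ignores the ±0.3-d variation of the true
  synodic month and time zones; adequate at 45° sector resolution, not
  for finer angular work.
- Wavelet pairing starts at the first sign run, so a series beginning
  mid-oscillation can shift all pairings by one half-cycle; durations are
  unaffected beyond ±1 cycle.
- The `with_fluctuations` label depends on the residual of the particular
  trend/band decomposition; it is a heuristic screen, not a formal test.
- The generator's AR(1)-plus-sinusoid structure cannot represent
  intermittent (on/off) coupling or period switching between new and full
  moon reported in some observational work; the shift test itself is
  agnostic to such structure.
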