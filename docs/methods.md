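# Methods

## Model

The interior copy number `n` of a tagged protein in a region of interest
(ROI; a focal adhesion) out of a conserved total `nTot = nIn + nOut` is a
continuous-time Markov birth–death process. The two channels are a gain from
the exterior pool, proportional to `nOut`, and a loss proportional to `nIn`.
The chemical master equation for this linear process satisfies detailed
balance, its stationary distribution is binomial, and its mean has the exact
closed form

    nIn(t) = [nIn(t0)·(kOut + kIn·e^(−kT·(t−t0)))
              + nOut(t0)·kOut·(1 − e^(−kT·(t−t0)))] / kT

with turnover rate `kT = kIn + kOut` and stationary interior fraction

    n̄ = kOut / kT.

Given the two quantities an exponential fit of a FRAP/FLAP curve yields —
`kT = |R0|` and the plateau `n̄` — the decomposition is exact:
`kOut = n̄·kT`, `kIn = kT − kOut`.

### Rate-labeling convention

In this parameterization the stationary interior fraction carries `kOut` in
the numerator, so in the *dynamics* the interior-gain propensity is
`kOut·nOut` and the interior-loss propensity is `kIn·nIn`. This is the
convention under which the published per-protein rate tables, the closed-form
trajectory, and the inversion are mutually consistent (one can verify that
the closed form above solves dnIn/dt = kOut·nOut − kIn·nIn, and that the
printed exit rates equal n̄·kT row by row), and the package follows it
everywhere — the simulator's channels included, so that simulated ensembles
reproduce the analytic curves and plateaux. Readers used to the two-state
binding convention (stationary fraction `kOn/(kOn+kOff)`) should read `kOut`
here as the rate constant that populates the ROI at steady state. The package
applies the convention uniformly rather than per-formula, which keeps every
derived quantity (fixed points, relaxation rates, simulated plateaux)
internally consistent.

### Modality conventions

FRAP curves start at `nIn(0) = 0` (interior bleached) and recover to `n̄`;
FLAP interior-decay curves start at `nIn(0) = nTot` (interior photoactivated)
and decay to `n̄`. For FLAP the plateau read-off supports two
interpretations: the default treats the measured plateau as the stationary
*exterior* value and takes `n̄ = nTot − plateau` by conservation; the
`exterior_plateau=False` option reads the plateau as the interior value
directly, which is the correct choice for interior-decay curves generated by
the model itself (they plateau at `n̄`). Parameter-recovery utilities on
model-generated FLAP data use the latter.

## Fitting

`y(t) = y0 + A·e^(R0·t)` is fitted by Levenberg–Marquardt least squares
(scipy), deterministically: the start is `y0 ← y(T_end)`, `A ← y(0) − y(T_end)`,
`R0 ←` the slope of `log|y − y0|` over the first half of the samples; five
restarts perturb the initial `R0` by ×{1, ½, 2, ¼, 4} and two
growth-oriented starts anchor `y0` at the first sample with `R0 > 0`. The
converged candidate with the lowest SSE wins. A best fit with `R0 ≥ 0` is
rejected (both modalities demand a decaying exponential term); an amplitude
sign violating the modality (FRAP requires `A < 0`, FLAP `A > 0`) raises a
warning rather than an error, since normalized interior FLAP traces decay
like a recovery's complement. Noiseless exponential data in the relevant
rate range (5–90 ×10⁻³/s) are recovered to SSE < 1e-12.

### Plateau estimator

Two estimators of `n̄` are provided. `plateau="fit"` (the pipeline default)
uses the fitted asymptote `y0`: it is exact in the noiseless limit and
unbiased even when acquisition ends before the plateau is reached (at
kT = 11.3×10⁻³/s a 300-s acquisition reaches only 96.6% of the plateau, so a
tail read-off would be biased low by ~3.4%). `plateau="tail"`
(`stationary_concentration`) is the literal mean of the last `m` samples
(`m = 1` by default, configurable because plateau noise makes `m > 1` more
robust); it matches the traditional read-off and is retained for
compatibility with that practice. Uncertainties: σ(kT) is the least-squares
standard error of `R0`; σ(n̄) is the standard error of `y0` (fit mode) or
the fit's residual standard deviation over √m (tail mode). σ(kIn), σ(kOut)
follow by first-order propagation assuming independence:
σ_out = √((n̄·σ_kT)² + (kT·σ_n̄)²), σ_in = √(((1−n̄)·σ_kT)² + (kT·σ_n̄)²).
Propagation from the printed per-protein inputs reproduces most published
uncertainty values; it is reported as "propagated", not guaranteed to match
every printed digit.

## Replicate screening and averaging

Each replicate is fitted individually and screened on its `R0` by the Tukey
interquartile fence: with type-7 (linear-interpolation) quartiles,
`UCL = Q3 + 1.5·IQR` and `LCL = Q1 − 1.5·IQR`; replicates outside the fence
are dropped. (The lower fence uses the minus sign — the standard rule; a plus
sign would make the lower limit exceed Q1 and reject nothing below the bulk.)
Screening requires at least four replicates; a zero-IQR sample of equal
values loses nothing, and the result is invariant to input order. The
surviving replicates are averaged pointwise on their common time grid
(truncating to the shortest common prefix), and the *average curve* is
refitted to produce the reported `kT` and `n̄` — per-replicate fits serve
outlier detection only, since replicate-specific `y0` and `A` shifts make
averaging the curves preferable to averaging rate estimates.

## Cross-validation

Repeated K-fold cross-validation over replicates: per repetition the
replicate indices are shuffled with a seeded generator and split into K folds
(sizes differing by at most one). For each fold, rates are estimated from the
training folds' average curve and the closed-form prediction is scored by
MAPE against the validation fold's average curve (per-replicate scoring is an
option; average-curve scoring matches the averaging philosophy above).
MAPE = 100·mean(|pred − obs|/|obs|) over points with |obs| > 1e-12 — the
exact zero at t = 0 of an ideal recovery curve is excluded. Interpretability
bands (lower edges inclusive): <10% highly accurate, 10–20% good, 20–50%
reasonable, ≥50% inaccurate; below 20% the model is considered suitable.
Results aggregate repetitions (default 100) with mean and standard error and
are exactly reproducible given the seed.

## Stochastic simulation of perturbations

Perturbed interaction models add channels proportional to the focal protein's
interior count: a destabilizing partner (loss of the talin–vinculin
interaction) adds interior loss `kIn^V·nIn`; a retention partner
(actomyosin, entered through the α-actinin entry rate) adds interior gain
`kIn^A·nIn`, with the gain propensity zeroed at `nIn = nTot` so the conserved
total is never exceeded (the uncapped linear equation conserves nothing and
would grow without bound). Two recruiting partners are additive. Stability
requires a positive mean relaxation rate `kT + Σloss − Σgain > 0` and is
enforced at construction. Mean-field fixed points, used as analytic
references:

| model          | relaxation rate | stationary fraction    |
|----------------|-----------------|------------------------|
| base           | kT              | kOut/kT                |
| vinculin loss  | kT + kIn^V      | kOut/(kT + kIn^V)      |
| actomyosin gain| kT − kIn^A      | kOut/(kT − kIn^A)      |

With the published talin FRAP rates (kIn = 7.8, kOut = 7.2 ×10⁻³/s) and
partner rates kIn^V = 5.2, kIn^A = 6.1 ×10⁻³/s, the plateau ordering is
0.356 < 0.481 < 0.809 and the relaxation-rate ordering is reversed: faster
talin turnover without vinculin, increased retention with actomyosin. (The
talin FLAP-derived reference rates are not in the published main table; the
FRAP values are the default and both are configurable.)

The simulator is an exact Gillespie SSA on integer states (exponential
waiting times from the total propensity, proportional channel choice, ±1
updates); absorbing states terminate a walk early and the last state is
carried forward. Ensembles (default 1000 runs) sample each trajectory onto a
regular grid by last-observation-carried-forward — the exact semantics of a
piecewise-constant jump process — normalize by `nTot`, and report per-point
mean and standard error; each run draws from an independent child of the
ensemble seed. The system size defaults to `nTot = 1000` molecules (outputs
are fractions; the underlying experiments are normalized and state no copy
number) — large enough that the mean-field reference is accurate to O(1/nTot)
while 1000 runs complete in seconds.

## Synthetic data generator

Traces are the closed-form mean for the chosen modality on a regular grid
(default 10-s sampling to 300 s, matching the acquisition the model targets)
plus additive i.i.d. Gaussian intensity noise, default σ = 0.02 on the
normalized scale — consistent with the visual scatter of published normalized
curves; no published noise model exists. The generator emulates replicate
scatter in intensity only: it does **not** simulate acquisition
photobleaching, bleach-spot geometry, detector shot noise (intensity-dependent
variance), immobile fractions, or diffusion-limited early recovery. Passing
recovery/cross-validation tests on this generator therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to those real-data effects. Planted outliers for screening
tests scale both rates by a chosen factor (preserving `n̄`, changing `kT`).

## Numerical choices and problem sizes

- Exponent clipping at ±700 in the fit model prevents overflow during
  optimizer excursions; fences and quartiles use numpy's default (type-7)
  percentile rule; rate-table round trips hold to 12 significant digits.
- Internal consistency of a `DynamicRates` record (`kIn + kOut = kT`,
  `n̄ = kOut/kT`) is enforced to 1e-9 relative.
- Test problem sizes: SSA/analytic agreement uses 1000 runs × nTot = 1000;
  plateau agreement is asserted at 900 s (base) / 800 s (perturbed), horizons
  chosen so the deterministic transient (e.g. 0.562·e^(−kT·t)) is below one
  ensemble standard error and the comparison tests the stochastic mean rather
  than the known transient. Parameter recovery uses 20 traces × 50 seeds at
  σ = 0.02; cross-validation 20 traces, K ∈ {3, 5, 10}, 100 repetitions at
  σ = 0.03.
- Degenerate inputs fail loudly: constant traces, non-monotone time columns,
  fewer than four points or replicates, unstable partner rates, plateaux
  outside [0, 1] by more than 0.1.

## Known limitations

- The closed form covers the base two-channel model only; perturbed models
  are handled by simulation plus the mean-field reference.
- Single-exponential fitting: no multi-exponential, anomalous-diffusion,
  immobile-fraction, or bleach-geometry corrections; no image processing or
  ROI extraction.
- The FLAP exterior/interior plateau ambiguity (above) must be resolved by
  the caller when analyzing real FLAP data; normalization practice
  (pre-bleach ROI vs whole-cell total) likewise varies and both references
  are exposed.
- Partners enter only through their entry-rate constants (no joint
  multi-species simulation of partner copy numbers).
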