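# Methods

## Dilution schemes

Two built-in 96-well layouts cover the common ways of diluting a stock for a
standard curve.

The **geometric** scheme builds column 1 by direct dilution at fractions
1, 7/8, 3/4, 5/8 of stock (rows A, C, E, G, each duplicated in the row
below), then halves the concentration column to column through column 10.
Its transfer list solves the serial-dilution volume balance: with a per-well
final volume `V` and fold `f`, columns 2–10 are prefilled with solvent
`V_p = V`, column 1 is prepared at working volume `V + V_t`, and
`V_t = V_p/(f−1)` is carried from each column to the next (mix step at every
destination) and finally discarded from column 10 — for `f = 2`, `V = 200 µL`
this gives `V_p = V_t = 200 µL`. Errors in any transfer propagate to all
downstream columns.

The **linear** scheme fills every well directly from solute and solvent
reservoirs: two identical blocks (columns 1–5 and 6–10) each carry the 20
ratios 1.00, 0.95, …, 0.05, descending over the distinct row pairs
column-major, so every well's error is independent. Solvent is dispensed
before solute. All reservoir volumes are multiples of a minimum safe
increment (default 10 µL); a target that is not reachable on that grid is a
hard error naming the well — volumes are never silently rounded. Because a
block has exactly 4 row-pairs × 5 columns = 20 slots, the step parameter
must satisfy 1/step = 20; other steps raise a configuration error rather
than produce a partially filled block.

Both schemes reserve columns 11–12 for 16 blanks (pure diluent, ratio 0)
and hold 200 µL per well after execution.

## Simulator

`execute_instructions` keeps exact solute/solvent bookkeeping per well while
perturbing each transfer volume `v` to `gain·v + N(0, (cv·v)²) + offset`,
clipped at zero. The error classes map onto the failure modes of a pipetting
robot:

| parameter | meaning | default |
|---|---|---|
| `independent_cv` | per-transfer volume noise, fraction of `v` | 0 |
| `constant_offset` | additive µL on every transfer | 0 |
| `systematic_gain` (+ scope) | multiplicative bias on all/solute/solvent volumes | 1 |
| `reservoir_concentration_error` | fractional stock mis-preparation | 0 |
| `carryover_excess` | extra µL on each column-to-column transfer | 0 |
| `contamination_prob`, `droplet_volume` | stray droplet of carried liquid diverted to a uniformly random well | 0 |
| `transient_prob/scale/decay` | per-repeat multiplicative excursions | 0 / 0 / 0.5 |
| `measurement_noise_sd` | OD read noise | 0 |
| `curvature` | γ in `g(c) = c/(1+γc)` | 0 |

All-zero parameters give an ideal, bit-deterministic execution that
reproduces every target ratio exactly — the anchor for all recovery tests.
Randomness comes from one seed; per-instruction generators are spawned from
a `SeedSequence` so edits to one parameter do not reshuffle unrelated draws.
Wells are assumed perfectly mixed, so aspiration removes solute and solvent
proportionally; a contamination droplet is subtracted from the dispensed
volume so liquid is conserved.

The renderer produces `A_i(λ) = (1+e_it)·g(c_i)·S(λ) + B(λ) + ε` on the
350–650 nm / 2 nm grid. The default solute spectrum is a carotenoid-like
triplet with Gaussian components at 458, 488 and 524 nm (sd 11/11/12 nm,
heights 0.70/1.00/0.82) — centers at the known lycopene-in-DMSO peaks,
widths and heights chosen once so the triplet stays resolved at 2 nm
sampling while the valleys remain shallow, as in real carotenoid spectra.
The baseline defaults to a flat 0.04 OD, matching typical blank readings.
`aging_flatness` mixes the peaked spectrum toward a single broad hump,
emulating the qualitative peak loss of aged mixes; it acts on spectral shape
only and is deliberately separate from the response curvature γ. Transient
excursions `e_it` trigger per repeat with probability proportional to
concentration (the artifact is concentration-linked solubility), add a
half-normal excess scaled by `transient_scale`, and decay geometrically at
rate `transient_decay` — so excursing wells regress toward the trend over
successive readings and may re-trigger.

Magnitudes for carryover and contamination are order-of-magnitude
placeholders — no quantitative measurements of these effects exist to
calibrate against — and should be set per study.

### What the generator does and does not emulate

It reproduces the error *structure* (independence vs. column-to-column
correlation, ratio-dependent relative error, repeat-transient dynamics) on
exact mass balance, which is what the analytics consume. It does not model
fluid dynamics, viscosity-dependent aspiration, evaporation, temperature,
multi-solute chemistry, or instrument export dialects. Tests passing on
synthetic plates therefore validate the estimators' correctness and
detection power under known ground truth — not the chemistry of any
particular assay.

## Spectrum model

The decomposition minimizes

    Σ_{i,λ} (M_{iλ} − αᵢ S_λ − B_λ)² + w·Σ_λ (B_λ − blankmean_λ)²

subject to `S, B, α ≥ 0`. The penalty form (squared deviation from the blank
mean, weight `w = 1` by default) keeps every subproblem closed-form: the fit
alternates exact clipped least-squares updates — per-well `αᵢ`, per-
wavelength `S_λ`, and the penalized per-wavelength baseline
`B_λ = (Σᵢ(M_{iλ} − αᵢS_λ) + w·blankmean_λ)/(n + w)` — each of which cannot
increase the objective, so the trace is provably nonincreasing. Iteration
stops when the relative objective change drops below `tol = 1e-8` (at most
500 iterations). Warm start: `B` from the blank mean, `S` from the
blank-subtracted scan of the highest-target well, `α` by one least-squares
pass — near-feasible, and on data generated by the model itself it converges
essentially immediately.

Because `(S, α) → (S/k, kα)` leaves the data term unchanged, the reported
`S` is normalized to 1 at a reference wavelength (the spectrum maximum by
default; any wavelength, e.g. the 524 nm peak, can be requested) with `α`
rescaled compensatingly. With `w → ∞` the baseline is pinned to the blank
mean; with `w = 0` the baseline can absorb signal at wavelengths where the
solute is dark — both limits are exercised in tests. Wavelengths with zero
variance receive no special-casing. The objective is nonconvex in the joint
variables; on a small instance the alternating fit agrees with a
general-purpose bound-constrained optimizer to 1e-6, but convergence to the
global optimum is not guaranteed in general.

## Error assessment

The workflow is: (1) regress response (absorbance at a chosen wavelength,
default the 524 nm peak, or the spectrum model's α coefficients) on the
targeted dilution ratio; (2) invert the model to estimate each well's
realized ratio; (3) map residuals and relative errors
(residual/target, undefined for blanks) across the plate. Global metrics
are Pearson/Spearman between estimated and targeted ratios (the raw
response can be paired instead via `metrics_on`) and RMSE, defined
**on the dilution-ratio scale** over sample wells. Blanks never enter the
fit or the RMSE; their estimated ratios are still reported.

Robust fits use iteratively reweighted least squares with the Huber norm
(tuning constant 1.345 on an MAD scale). Degree-2 inversion takes the real
root on the monotone branch covering `[0, x_max]`; a fitted quadratic whose
vertex falls inside the calibration range raises an error rather than
guessing a branch. Estimates outside `[−0.1, 1.1·x_max]` are flagged, not
clipped.

Self-calibration has a known blind spot: a bias applied uniformly to every
transfer is absorbed into the fitted slope and is invisible to the residuals.
A *solute-only* volume gain `g`, however, distorts ratios nonlinearly —
`r' = g·r/(1+(g−1)·r)` — and `implied_solute_gain` inverts this mass balance
per well; fitting the response model on a matched bias-free plate and
inverting the biased plate's measurements recovers the injected gain as the
mean implied volume bias. Averaging ratio-scale relative errors directly
would understate it (analytically `0.05·E[(1−r)/(1+0.05r)] ≈ 2.3%` for a 5%
gain on the linear layout), which is why recovery is done on the volume
scale where the bias is defined.

### Stratified trends and jump flags

Per-column (or per-row) linear trends are compared against the plate-wide
model. A stratum is flagged as a *jump* when more than half of its points
sit where the stratum fit's 95% confidence band fails to overlap the global
model's 95% confidence band. Rationale: a correlated error confined to part
of the plate (e.g. carryover compounding along a serial dilution) leaves
each column internally tight but displaced, so the bands separate; under
independent well noise the stratum band is wide and overlap is retained.
Flagging raw points against the global *prediction* band was considered and
rejected: with a compounding error every column deviates, the global
residual scale inflates proportionally, and the prediction band swallows
its own misfit — the rule cannot fire at any carryover magnitude. The
band-overlap rule detects a 20 µL carryover excess (a 10% per-column fold
error) in essentially every seeded simulation while keeping the false-flag
rate under independent 2% volume noise below the nominal 5%. A small
absolute tolerance (1e-9 of the response scale) prevents spurious flags on
exactly deterministic data. The 0.5 fraction threshold and the 95% level are
exposed as parameters.

## Repeat filtration and calibration

Technical repeats of one well are aggregated by fitting a robust trendline
on all pooled (target, value) pairs and keeping, per well, the repeat whose
value deviates least from it (ties to the lowest repeat index). Unlike a
median, this suppresses transient excursions entirely as long as one
uncorrupted reading exists. The default is a single pass — pooled fit, one
selection; an opt-in `iterate` mode refits on the selected values until the
selection stabilizes (≤10 passes). By construction the filtered plate's
RMSE-to-trend is bounded by every individual repeat's, and the output never
contains a value absent from the input repeats. Filtration is per run;
pooling across runs happens afterwards.

`RunMetadata` converts ratios to absolute concentration
(`C = C₀ · working_factor · ratio`, e.g. a 4/100 working dilution of a
0.5 mg/mL stock), keeping stock bookkeeping entirely out of the ratio-scale
analytics. The final calibration curve is a degree-1 or degree-2 robust fit
on the pooled points; its quality metrics reuse the inversion workflow on
the concentration scale.

Aggregate spectra are averaged after per-spectrum normalization; peaks are
local maxima with prominence ≥ 5% of the aggregate maximum and ≥ 10 nm
separation — enough to resolve the 458/488/524 nm triplet at 2 nm sampling
without picking up noise wiggles. Spectral drift over a stability series is
summarized by the Pearson similarity of each timepoint's plate-mean spectrum
to the first, plus the retention of the initial peak height at its original
wavelength (baseline included, so an all-baseline endpoint reports
`B(λ_peak)/A₀(λ_peak)`).

## Problem sizes and numerical choices

Stochastic claims (bias recovery, jump detection and false-flag rates,
filtration benefit) are evaluated over 20 seeded simulations of full
96-well plates with 151-wavelength scans — enough for stable majority/mean
statistics while keeping the whole suite and the acceptance script in the
tens of seconds. The realistic noise scenario is 1% transfer CV, 1 µL
constant offset and 3 mOD read noise; the transient scenario adds
trigger probability 0.15, scale 0.6 and decay 0.5 over 6 repeats. Volumes
computed from float ratios are snapped to the validated increment grid to
avoid 1-ulp dust in instruction files. Ties in peak normalization (flat
spectra) fall back to no scaling; a flat spectrum yields zero peaks, not an
error.

## Known limitations

- Single-solute decomposition only; no uncertainty quantification on
  `S`/`B`/`α`.
- Self-calibrated assessment cannot see uniform all-transfer biases
  (inherent to the regression-inversion design).
- The alternating spectral fit guarantees monotone objective descent, not
  global optimality.
- Between-plate meta-analysis (agreement across runs/instruments beyond
  simple pooling) is out of scope.
- Plate-reader export dialects are limited to the package's own wide/long
  CSV; vendor-native files must be converted upstream.
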