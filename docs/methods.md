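# Methods

## Melting-curve model

The soluble fraction of a thermally denaturing protein is modeled as

    f(T) = (1 − p) / (1 + exp(−(a/T − b))) + p

with `a > 0` (°C units), `b > 0` (dimensionless) and plateau
`p ∈ [0, 1)`, strictly decreasing in `T`. Temperatures are degrees
Celsius throughout, including inside the `a/T` term; switching to Kelvin
would rescale the fitted `a` and `b` but leaves the Tm/slope behavior
qualitatively unchanged, so the Celsius convention is fixed rather than
configurable.

The melting point is defined on the normalized scale as the half-maximum
crossing `f(Tm) = 1/2` (not the midpoint between 1 and the plateau),
giving the closed form `Tm = a / (b + ln(1 − 2p))`. Curves with
`p ≥ 1/2` never reach half-maximum: their Tm is undefined and the protein
is excluded with the reason recorded, as is any curve whose crossing
would fall at a non-physical (non-positive-denominator) temperature. The
inflection slope is evaluated where `a/T − b = 0`:
`df/dT = −(1 − p)·b²/(4a)`. Both closed forms are property-tested against
a 0.001 °C dense-grid root scan and a central finite difference.

### Fitting

Bounded nonlinear least squares (scipy `least_squares`, trust-region
reflective, analytic Jacobian) with box bounds `a ∈ [100, 20000]`,
`b ∈ [1, 400]`, `p ∈ [0, 0.49]`. A 5×5×3 multi-start grid over
`(a, b, p)` is seeded from a coarse Tm guess (the first gradient
temperature where the relative abundance drops below 0.5): five
log-spaced `a` values, five `b` values bracketing `a/Tm_guess`, plateaus
{0, 0.15, 0.3}. Every start is scored by its initial residual sum of
squares; the best-ranked starts (3 by default) are refined with tight
tolerances (`ftol = xtol = 1e−12`, `gtol = 1e−10`, ≤ 400 evaluations).
The smallest refined residual wins; ties within a 1e−9 relative band are
broken by the smallest `a`. Screening the grid rather than refining all
75 starts keeps whole-proteome fitting tractable without measurable loss:
on noise-free admissible curves, parameter recovery to 1e−3 relative
error is 100% in the test battery, and the refinements found by larger
start sets are identical on the outlier cases examined.

Curves with fewer than 8 of 10 finite points are flagged unfittable
(three free parameters need that margin to stay well-determined), as are
essentially constant profiles (no transition). Both come back as
non-converged fits with a reason, never exceptions; infinite abundances
are a validation error.

### Quality filtering

Proteins whose fitted curve has `|inflection slope| < 0.06` are excluded
as flat (low Tm reproducibility). The boundary value passes: the filter
excludes *below*-threshold slopes. By default all four curves of a
protein must pass (strictest reading); a `vehicle`-curves-only mode is
available. An optional R² gate exists but is off by default — the screen
specifies only the slope filter.

## ΔTm screening criteria

With two replicates per condition, replicate pairing is by index: drug
replicate i is compared with vehicle replicate i, and the control shift
is vehicle 1 − vehicle 2. (An alternative `min` pairing that takes the
smaller-magnitude drug-vs-vehicle difference per replicate is available
for conservative use.) A protein passes when

1. `slope_pass` — all curves pass the flat-slope filter;
2. `sign_concordant` — `ΔTm₁·ΔTm₂ > 0` (a zero shift counts as
   discordant);
3. `exceeds_control` — `min(|ΔTm₁|, |ΔTm₂|) > |ΔTm_ctrl|`, compared in
   magnitude because a signed comparison would be asymmetric between
   stabilization and destabilization.

Failures record the first failing criterion in that order. The
fold-change score is the per-temperature
`−log2(mean drug / mean vehicle)` relative abundance ratio; its
largest-magnitude entry (sign kept) is thresholded symmetrically at ±1,
boundary inclusive. Ratios are floored at 1e−6 and floored entries
counted per record, keeping the score finite for vanishing abundances.
The score is an abundance fold change, heatmap-compatible per
temperature; a log fold change of the temperature difference itself is
not well-defined, and both the score and its cutoff are configurable for
users who prefer a different ranking statistic.

Candidates are ordered by |score| descending, ties by |ΔTm₁ + ΔTm₂|
descending, then protein id; excluded proteins follow in id order, and
the run summary reports the narrowing at each stage (input → fittable →
slope pass → criteria pass → candidates).

## CETSA validation

Band-intensity series are normalized per replicate to the lowest
temperature, then analyzed as a balanced two-factor design (treatment ×
temperature with interaction) via ordinary least squares; the classical
ANOVA table (statsmodels) is reported, and a textbook sums-of-squares
decomposition serves as the independent oracle in the tests. Unbalanced
tables are rejected rather than silently re-weighted; single-replicate
cells and all-zero within-cell variance raise a degenerate-design error.

Per-temperature vehicle-vs-drug comparisons are Welch t-tests on the
per-cell variances, Bonferroni-adjusted by the number of temperatures.
The per-cell choice is deliberate: multiplicative band noise makes
ratio-normalized values strongly heteroscedastic across temperatures, and
the classical pooled-residual-MS posttest understates the variance of the
cold cells — measured at ~22% family-wise error under the simulator's
null versus 2% for the Welch form. Condition-wise melting fits of the
mean normalized series give the CETSA ΔTm estimate.

## Synthetic experiments

The generator draws, per protein, a vehicle melting point
`Tm ~ Normal(52, 4²) °C`, an inflection-slope magnitude
`~ Uniform(0.03, 0.4)` per °C and a plateau `~ Uniform(0, 0.3)`, then
inverts these to `(a, b, p)` in closed form. The slope range deliberately
includes curves below the 0.06 filter threshold, as in real lysates, so
the flat-slope exclusion path is exercised. Spiked targets receive a
signed shift with `|ΔTm| ~ Normal(4, 1²) °C` (destabilized negative,
stabilized positive), injected by re-solving `b` at fixed `a` and `p` —
the curve translates without changing steepness, matching the observed
destabilization phenotype. Per-replicate biological variability enters as
Tm jitter (sd 0.3 °C), which gives the vehicle-vehicle control shift its
realistic nonzero spread. Measured abundances are
`base × f(T) × exp(ε)`, `ε ~ Normal(0, 0.03²)` i.i.d. per point, with
base intensities log-uniform over [1e5, 1e8] to exercise normalization.
Draws that place any curve's Tm outside 30–75 °C are redrawn (up to 100
times, then a configuration error). All randomness flows from one seeded
generator; identical configs give bit-identical tables.

What the generator does **not** emulate: peptide-level rollup, TMT ratio
compression, co-isolation interference, missing-not-at-random dropout,
between-channel loading differences, or correlated (batch) noise. Passing
tests therefore demonstrate correctness of the fitting and screening
logic under the stated noise model, not robustness to every artifact of
real TMT data.

## Measured operating characteristics

Problem sizes follow the package's standard benchmark settings: the
closed-form oracles run on 1000 random admissible curves; recovery runs
on 500 proteins with 50 spiked targets; the null control on 5 seeds ×
1000 proteins. On these conditions the test suite asserts: closed-form
Tm within 0.002 °C of the grid oracle and slope within 1e−6 of the finite
difference; spiked-target recall ≥ 0.9 at the ΔTm-screen stage among
targets whose true curves are evaluable (true |slope| ≥ 0.06 — truly flat
targets are excluded by the filter by design); |ΔTm bias| < 0.1 °C and
RMSE < 0.5 °C; null candidate rate ≤ 2%; zero truth-table mismatches on
10,000 random triplets; ANOVA F statistics within 1e−8 of the oracle.
`scripts/acceptance.py` recomputes all of these from scratch at any seed.

## Known limitations

* Tm estimates degrade at the gradient edges: targets whose shifted
  melting point falls near or beyond 66.8 °C (or below 37 °C) are poorly
  determined, which dominates the tail of the ΔTm error distribution.
* The ΔTm error floor is set by the replicate jitter itself (sd 0.3 °C in
  the mean of two replicate shifts), so per-protein shifts below ~1 °C
  are not reliably separable from the control shift with two replicates.
* Only per-protein scaling to the reference temperature is performed; no
  cross-channel (median or total-intensity) normalization is applied
  before fitting.
* The screen is a ranking, not an error-controlled test: no
  proteome-wide FDR is computed for Tm shifts.
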