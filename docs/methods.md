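# Methods

## Model and assumptions

A neuronal process ("axon") is idealised as a one-dimensional tube of
length *L* µm.  It contains *m* microtubules, modelled as axis-parallel
line segments ("sticks") of length *h* µm — no curvature, no 3D packing,
no dynamics.  Stick positions are uniform and independent.  A transverse
section at coordinate *s* counts the sticks whose coverage interval
contains *s*; that integer count X is the observable.

Two placement conventions are implemented:

* **circular** (default): stick starts are uniform on [0, *L*) and
  coverage wraps modulo *L*.  Each stick crosses any section with
  probability exactly *p = h/L*, independently, so X ~ Binomial(m, h/L)
  with E(X) = mh/L and Var(X) = mh/L(1 − h/L) at every section position.
  This convention realises the idealised crossing probability with no
  edge effects and is the one the moment formulas assume.
* **linear**: starts are uniform on [0, *L* − *h*], so sticks never
  protrude.  For a section at *s* the crossing probability is
  (min(s, L−h) − max(s−h, 0))/(L−h): equal to h/(L−h) on the interior
  [h, L−h] and tapering linearly to 0 at the ends.  For h ≪ L this is
  ≈ h/L.  Real axons are not periodic, so this convention is kept for
  sensitivity analysis; a full-length stick (h = L) is degenerate and its
  start is forced to 0.

Coverage intervals are half-open [a, a+h), a measure-zero choice made so
boundary hits are unambiguous and simulations are bit-reproducible.

The count distribution is binomial, not Poisson.  For h ≪ L the
Binomial(m, h/L) law is close to Poisson(mh/L), but the variance formula
mh/L(1 − h/L) is the binomial one, and at the crossing probabilities
relevant here (p ≈ 0.7) the Poisson approximation would be badly wrong;
the implementation is therefore exact-binomial throughout.

## Method-of-moments fit

Inverting the two moment equations gives

    p̂ = 1 − s²/x̄,   m̂ = x̄/p̂,   ĥ = p̂·L,

defined (feasible) exactly when 0 < s² < x̄.  Feasibility is decided on
that data condition directly rather than on the floating-point value of
p̂, which can round to 1 when s²/x̄ underflows.  Overdispersion
(s² ≥ x̄) is reported as a diagnosis, not an error: the count under any
fixed-m independent-stick model is Poisson-binomial
(Var = Σpᵢ(1 − pᵢ) ≤ Σpᵢ = mean), so s² > x̄ is evidence of
between-animal variation in m, and no mixture of stick lengths can
produce it.  Converting p̂ to ĥ requires the user to supply *L*; the
package never assumes a numeric axon length outside its examples, which
use *L* = 100 µm as a convenient round figure for an ALM-scale process.

Uncertainty for a feasible fit is available by parametric bootstrap
(`bootstrap_moment_fit`): resample Binomial(round(m̂), p̂) counts, refit,
report percentile intervals; infeasible resamples are counted rather than
silently dropped.

## Discrimination rule: more vs longer microtubules

A higher mean count only pins down the product inequality
m₂h₂ > m₁h₁.  The variance separates the two factors: if only the number
changed (h₂ = h₁, m₂ > m₁), both moments scale with m, so the implied
comparison-group variance is σ₁²·μ₂/μ₁ > σ₁².  The verbal argument is
codified as an explicit, deliberately conservative decision rule
(`discriminate_change`), with every intermediate statistic exposed so
users can apply their own thresholds:

1. One-sided Welch test of μ₂ > μ₁.  Not significant at α (default
   0.05) → `no-change`.
2. Otherwise compute the number-only variance prediction σ₁²·μ₂/μ₁.
3. If the observed comparison variance is below the reference variance
   (point estimate) *and* a one-sided F-test finds no support for
   σ₂² > σ₁² — the increase a number-only change requires —
   → `length-favored`.
4. Otherwise, if the observed variance falls in the two-sided (1 − α)
   normal-theory acceptance band around the prediction
   ((n₂−1)s²/σ² ~ χ²) → `number-consistent`; else `indeterminate`.

The gates (significance level, point comparison plus F-test, χ² band) are
this package's operationalisation of a qualitative argument; they are not
a canonical procedure, which is why the raw statistics are always
returned.  Swapping the two groups reverses the one-sided alternative, so
the mirrored comparison reports `no-change` rather than a mirrored
verdict — the rule is directional by construction.

## Summary-statistics tests

All two-sample inference runs from (mean, sd, n) triples, since
per-section counts are often published only in that form.

* **Welch t** (default) with fractional Satterthwaite df (never
  truncated); a pooled-variance t is available by flag.  On the worked
  example (67, 9, 8) vs (85, 5, 8) Welch gives one-sided p = 2.23×10⁻⁴
  and a one-sided 95% lower confidence bound of 11.46 for the mean
  difference; pooled would give 1.1×10⁻⁴ and 11.63.  The Welch numbers
  are the ones that reproduce the conventionally reported "2×10⁻⁴" and
  "11" after rounding, which is why Welch is the default.
* **Confidence bounds** are reported unrounded; presentation rounding is
  left to the caller.
* **Variance-ratio F-test** with F = s₁²/s₂² on (n₁−1, n₂−1) df, normal
  theory.  Groups are never silently reordered; the direction is set by
  the `alternative`.  On the worked example F = 81/25 = 3.24 on (7, 7) df
  gives one-sided p = 0.0719.  This figure is sometimes quoted as 0.1
  after coarse rounding; the package reports the exact value, and the
  test suite pins it against a Monte-Carlo simulation of the null.

Degenerate inputs (both groups constant and equal) return the neutral
p-value (0.5 one-sided) with an explanatory note instead of NaN.

## Synthetic-data generator

`synthetic` generates labelled section-count tables with the dispersion
structure real cross-animal TEM data shows:

* **Per-animal microtubule number** m: fixed, a two-point mixture on
  {⌊µ⌋, ⌈µ⌉} (hits a non-integer mean with minimal variance), or
  gamma-Poisson (negative binomial) parametrised by mean and variance.
  Between-animal variation in m is the only overdispersion mechanism
  offered, because it is the only one that can work: length heterogeneity
  keeps the count Poisson-binomial and hence underdispersed.
* **Stick length** h: fixed or uniform on [lo, hi] ⊆ (0, L].
* **Sectioning**: `serial` ladders at a fixed increment (default 3.2 µm,
  the serial-TEM spacing the design emulates; the first section gets a
  seeded uniform offset in [0, increment) unless anchored), or `random`
  positions.  Random mode defaults to one freshly simulated animal per
  section — the "random sections from different animals" design under
  which records are independent — with a same-animal mode for
  sensitivity analysis.

For fixed h the marginal moments obey the law of total variance,
mean = E[m]p̄ and variance = E[m]p̄(1−p̄) + p̄²Var(m) with p̄ = h/L; the
generator's `population_moments()` computes these analytically (including
the E[p²] correction for random lengths) and the test suite checks large
simulations against them.

Two shipped scenarios anchor examples and tests:

* **wild-type-like**: targets population moments (67, 81) — overdispersed,
  so a gamma-Poisson m is calibrated by solving E[m]p̄ = 67 and
  E[m]p̄(1−p̄) + p̄²Var(m) = 81 at a user-chosen p̄ (default 0.7,
  matching the mutant fit; with L = 100 µm this gives E[m] ≈ 95.7,
  Var(m) ≈ 124.3, h = 70 µm).  Calibrations needing Var(m) < E[m] are
  outside the gamma-Poisson family and rejected before any sampling.
* **mutant-like**: fixed m = 120 (the nearest integer to the 120.42
  moment fit) with h = L·85/120, giving population mean exactly 85 and
  binomial variance 24.79 — marginally below the 25 of the summaries it
  emulates, a deliberate price for keeping m integral and fixed; at the
  10⁴-section sizes used for calibration checks the difference is well
  inside Monte-Carlo noise.

What the generator does *not* emulate: TEM imaging noise, finite section
thickness, microtubule curvature or fasciculation, spatial trends in m
along the axon, or correlations between h and m.  Passing tests therefore
show that the *inference machinery* is correct under the model's own
assumptions, not that real axons satisfy those assumptions.

## Randomness and determinism

All randomness flows from a single integer seed through
`numpy.random.SeedSequence`.  Each simulated animal gets its own spawned
substream, so enlarging `n_animals` extends a table without reshuffling
earlier animals, and the full generate → summarize → test chain is
bit-reproducible per seed.  Monte-Carlo checks in the test suite use
fixed seeds and 3–4-standard-error acceptance bands.

## Problem sizes

Calibration and recovery checks use 10,000 sections (sampling error
≈ 0.05 counts on the mean, ≈ 1.4% on the variance — comfortably inside
the 5% recovery tolerance); verdict-frequency simulations use a few
hundred replicates of small designs, sized so the binomial standard error
of a frequency is ~2–3 percentage points.

## Known limitations

* The discrimination rule is a codified heuristic, not a likelihood-based
  test; its error rates under model misspecification are only what
  `power_simulation` measures for the scenarios you give it.
* The moment fit uses two sample moments and inherits their small-n
  noise; with n = 8 sections the bootstrap intervals on (m̂, ĥ) are wide.
* The F-test and the χ² acceptance band assume approximately normal
  counts; at the m ≈ 100, p ≈ 0.7 regime of the examples the binomial is
  close to normal, but for small m the band is only approximate.
* Serial sections of one animal share sticks: their counts are dependent,
  and the summary tests (which assume independent sections) should be
  applied to serial data with caution.
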