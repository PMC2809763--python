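# mtsticks

Stochastic "sticks-in-a-tube" modelling of axonal microtubule
cross-section counts.

Transmission electron microscopy (TEM) of a neuronal process yields, per
transverse section, the number of microtubules crossing that section.  A
genotype with a *higher* mean count has either more microtubules, longer
microtubules, or both — the single-section count cannot tell them apart.
This package implements the minimal stochastic-geometry model that can:
it simulates section counts, derives their moments, fits the model by the
method of moments, and codifies the variance argument that discriminates
a change in microtubule **number** from a change in microtubule
**length**.  It is aimed at anyone interpreting per-section polymer or
filament counts from serial or random EM sections.

## The model

An axon is a tube of length *L* (µm) containing *m* microtubules, each an
axis-parallel "stick" of length *h* (µm) placed uniformly at random.
Under the circular placement convention (start uniform on [0, *L*),
coverage wrapping modulo *L*) every section sees each stick independently
with probability *p = h/L*, so the per-section count is

    X ~ Binomial(m, h/L),   E(X) = mh/L,   Var(X) = (mh/L)(1 − h/L).

Two consequences drive all the inference:

1. **Underdispersion bound.** For *any* fixed-*m* independent-stick model
   (even with a mixture of lengths) the count is Poisson-binomial, so
   Var(X) ≤ E(X).  Observed variance *above* the mean therefore signals
   between-animal variation in *m*, not stick geometry.
2. **Number-only scaling.** If only *m* changes (*h* fixed), both mean and
   variance scale with *m*: a mean rising from μ₁ to μ₂ forces the
   variance to rise to σ₁²·μ₂/μ₁.  A mutant whose variance *falls* while
   its mean rises is therefore better explained by longer microtubules.

The method-of-moments fit inverts the two moment equations:
p̂ = 1 − s²/x̄, m̂ = x̄/p̂, ĥ = p̂·L, feasible exactly when 0 < s² < x̄.

A `linear` convention (sticks may not protrude past the axon ends, with
explicit edge-effect formulas) is provided alongside the default
`circular` one; see `docs/methods.md`.

## Worked example

Eight ALM-neuron sections per genotype gave wild-type counts with mean 67
and sd 9, and elongator-mutant counts with mean 85 and sd 5.  Are the
extra crossings due to more microtubules or longer ones?

```sh
$ mtsticks test -a 67 9 8 -b 85 5 8
t_statistic=4.944980302
t_df=10.94517117
t_p_one_sided=0.0002228372166
mean_diff=18
ci_lower=11.45988263
ci_upper=inf
ci_confidence=0.95
F_statistic=3.24
F_df1=7
F_df2=7
F_p_one_sided=0.07185399293
```

The mutant mean is higher (one-sided Welch p ≈ 2.2×10⁻⁴, i.e. 2×10⁻⁴ to
one significant figure; the one-sided 95% confidence bound for the mean
difference is ≈ 11.5 counts).  The variance-ratio test (F = 81/25 = 3.24
on 7,7 df) gives one-sided p ≈ 0.072, so equality of variances is not
rejected at the 5% level.

```sh
$ mtsticks discriminate --wt 67 9 8 --mut 85 5 8
verdict=length-favored
mean_t_statistic=4.944980302
mean_p_one_sided=0.0002228372166
product_inequality_m2h2_gt_m1h1=True
predicted_variance_number_only=102.761194
observed_mut_variance=25
F_mut_over_wt=0.3086419753
F_p_one_sided=0.9281460071
...
```

A number-only change would have pushed the mutant variance up to
81·85/67 ≈ 102.8; instead it *fell* to 25, with no support for a variance
increase — hence the verdict `length-favored`: the data are better
explained by longer microtubules than by more of them.

Fitting the model to the mutant summaries (taking *L* = 100 µm):

```sh
$ mtsticks fit --mean 85 --sd 5 --n 8 -L 100
p_hat=0.7058823529
feasible=True
m_hat=120.4166667
h_hat_um=70.58823529
```

about 120 microtubules each covering ~71% of the axon.  The same fit on
the wild-type summaries reports `feasible=False`: with s² = 81 > x̄ = 67
the counts are overdispersed, which no fixed-*m* model can produce — the
wild-type sections (taken from different animals) mix animals with
different microtubule numbers.

The same computations are available in Python
(`mtsticks.welch_t_summary`, `mtsticks.discriminate_change`,
`mtsticks.fit_moments`, …), together with a simulator
(`mtsticks.simulate_experiment`, `mtsticks.synthetic`) and a Monte-Carlo
power analysis (`mtsticks.power_simulation`).

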