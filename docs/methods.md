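# Methods

## The dancefloor mixture model

A honeybee colony's foraging trips are modelled as a two-component
mixture distinguished by how the forage site was found. Scouting bees
leave the hive on an approximately straight search path, so the
distance to the first resource encountered — and hence the waggle-run
duration reported on return — follows an exponential law (the 1-D
nearest-neighbour distance for randomly placed resources). Recruited
bees instead follow dances and, through the dancefloor's positive
feedback toward profitable sites, converge on the best resources in the
two-dimensional neighbourhood of the hive; the nearest-point distance
in 2-D follows a Rayleigh law. Both laws are modified in the same two
ways before they meet data:

* truncation below at `m`, the minimum recorded waggle-run duration
  (shorter runs cannot be decoded reliably);
* a linear taper `(1 − a x)₊` arising from linearising, at the edge of
  the reportable range, the function that maps a trip's profitability
  into the number of dance circuits performed: trips near the maximum
  duration `1/a` are advertised less, so their densities fall linearly
  to zero there.

With `x₊ = max(x, 0)`:

```
f_s(x) = a_s M_s⁻¹ b_s e^{−b_s a_s (x−m)} (1 − a_s x)₊      on [m, 1/a_s)
f_r(x) = M_r⁻¹ 2π a_r² b_r x e^{−π b_r (a_r x)²} (1 − a_r x)₊  on [m, 1/a_r)
P(x)   = p f_s(x) + (1 − p) f_r(x)
```

`1/a_s` is the maximum scout waggle-run duration, `a_s b_s` the
intensity of resources found by scouts, `a_r² b_r` the intensity of
high-quality resources reported by recruits, and `p` the fraction of
scout trips; `1 − p` is the *waggle dance use*. Setting `m = 0` and
removing the taper recovers the pure Rayleigh `2πλx e^{−πλx²}` with
`λ = a_r² b_r`.

### Normalising constants

`M_s = (1 − a_s m) − b_s⁻¹(1 − e^{−b_s(1 − a_s m)})`.

For the recruit component, direct integration of the unnormalised
integrand over `[m, 1/a_r]` (substituting `u = a_r x`, then integrating
`2πb·u e^{−πbu²}` and `2πb·u² e^{−πbu²}` separately) gives

`M_r = (1 − a_r m) e^{−π b_r (a_r m)²} + [erf(a_r m √(π b_r)) − erf(√(π b_r))] / (2 √b_r)`.

The erf argument must be `a_r · m · √(π b_r)`; a superficially similar
variant with `a_r √(π b_r m)` circulates but does **not** normalise the
density (quadrature errors of a few percent), and the test suite checks
both facts against adaptive quadrature. Closed-form antiderivatives of
both integrands also give exact component CDFs, used for
complementary-cumulative plots and verified against quadrature at
1e−8.

### Sampling

Mixture draws pick their component with probability `p`, then sample
the component by rejection: the proposal is the exact truncated base
distribution (inverse-CDF truncated exponential for scouts, inverse-CDF
truncated Rayleigh for recruits) and the acceptance probability is the
taper `(1 − a x)/(1 − a m)`. This is exact and vectorised; the
empirical CDF of 10⁵ draws matches the closed-form CDF to sup-distance
< 0.01.

## Fitting and model selection

Two nested variants are fitted per hive:

| variant    | free parameters            | k |
|------------|----------------------------|---|
| individual | `a_s, b_s` (`p` fixed at 1)| 2 |
| collective | `p, a_s, b_s, a_r, b_r`    | 5 |

`m` is fixed at the observed minimum duration and not counted as a free
parameter. Model selection uses `AIC = 2k − 2 ln L` and Akaike
weights; exact ties go to the simpler (individual) model. Waggle dance
use is `1 − p̂` from the collective fit.

### Optimisation

Likelihoods are maximised with Nelder–Mead on transformed parameters:
`a_s·max(x)` through a logit (the scout support must cover the data,
otherwise some observation has zero density and the log-likelihood is
−∞), `p` through a logit, and `b_s`, `b_r` and `a_r·max(x)` through
log-scale maps onto bounded intervals. 32 Latin-hypercube starts are
screened by log-likelihood and the best 4 polished with Nelder–Mead
(`xatol` 1e−8); the collective fit additionally polishes a start
anchored at the individual optimum — which guarantees the nested
inequality `ln L_collective ≥ ln L_individual` up to optimiser
tolerance — and three moment-based "hump" starts that place the
recruit mode at a low quantile of the data with matching intensity
`λ = 1/(2π·mode²)`. The hump starts matter when the recruit fraction
is small: the likelihood then has a broad-recruit local optimum a few
nats below the sharp-hump global one, and a quantile-matched start is
the cheap way to land in the correct basin. All starts are
deterministic, so a fit is a pure function of the data.

### Why the parameter space is bounded

With `m` equal to the smallest observation, the mixture likelihood is
unbounded: one component can spike at the support edge (`b → ∞`
concentrates all of its mass at `m`, where a data point sits) while the
other component carries the remaining observations — the textbook
degeneracy of mixture MLE. The parameter space is therefore kept
compact: `b_s ∈ [0.1, 100]`, `b_r ∈ [0.5, 100]`,
`a_r·max(x) ∈ [0.02, 2]`. The recruit lower bound additionally encodes
a model assumption: the derivation of the Rayleigh component presumes a
sizable intensity of high-quality resources, and below `b_r ≈ 0.5` the
Gaussian factor barely decays inside the support, degenerating the
component into a free-form bump `x(1 − a_r x)` with no Rayleigh
character — which both destabilises `p̂` near its boundaries and lets
the mixture absorb misspecified data the goodness-of-fit test should
reject.

### Identifiability caveats

`a_r` and `b_r` are individually weak: away from the taper the recruit
density depends on them mainly through `λ = a_r² b_r`, so only `λ` (and
`p`, `a_s`, `b_s`) should be interpreted quantitatively. Near `p = 1`
the scout fraction itself is weakly identified when the scout component
is steep, because a broad tapered Rayleigh can closely mimic a decaying
exponential; AIC still selects the individual model there, but `p̂` may
sit well inside the interior with negligible likelihood gain. Recovery
of `p` is hardest at `p = 0.9` (few recruit observations), where the
broad-recruit local optimum described above competes with the true
one; with the hump starts the median absolute error at n = 2000 stays
near 0.02–0.03 across the grid.

### Goodness of fit

Each fit is checked with a bootstrapped two-sample Kolmogorov–Smirnov
test: a sample of the data's size is drawn from the fitted mixture, the
two-sample KS statistic computed, and its null distribution obtained by
resampling both samples with replacement from the pooled values (1000
replicates by default; the statistic is evaluated only at the ends of
tie groups, so ties introduced by resampling are handled exactly; the
p-value uses the `(r + 1)/(B + 1)` convention). Under the true model
these p-values are uniform (checked by decile chi-square over 200
replicates). A hive where both variants fail at α = 0.05 is reported
as having *no acceptable fit*.

### Pooled comparisons

For a group of hives (e.g. a landscape class), both variants are also
fitted to the concatenated durations (`m` becomes the global minimum),
and the summed per-hive best AIC is compared with the pooled best AIC.
A large positive difference — pooled minus summed — is evidence that
waggle dance use genuinely varies between hives rather than reflecting
one shared foraging regime.

## The synthetic-study generator

`generate_study` emulates a field campaign: 20 hives, 141 decoded
dances each (≈ 2800 total), hive-specific scout fraction `p` drawn
uniformly on [0.1, 0.9] unless given, shared component parameters, and
half the hives labelled urban / half agri-rural. Defaults:

| parameter | default | meaning |
|-----------|---------|---------|
| `a_s` | 0.1 s⁻¹ | scout runs range up to 10 s (sites out to several km) |
| `b_s` | 0.5 | dance rate depends only weakly on distance for scouts |
| `a_r` | 0.08 s⁻¹ | recruit taper; mostly inert (`1/a_r` ≫ typical runs) |
| `b_r` | 39 | `λ = a_r²b_r = 0.25`: recruit hump mode ≈ 0.8 s |
| `m` | 0.2 s | minimum decodable waggle run |

These values are chosen so that a generated hive shows the pronounced
recruitment shoulder that collective hives show in decoded field data,
with AIC margins at n ≈ 141 of the same order of magnitude (single
digits to a few tens). With strongly overlapping components the
mixture becomes statistically unidentifiable at field sample sizes —
a property of the model, not of the optimiser — so passing recovery
tests here demonstrate the method *given* a detectable imprint; they do
not show that every real hive's imprint is detectable. The generator
draws i.i.d. durations: it does not emulate decoding noise, observer
error, or within-season nonstationarity. Duration↔distance calibration
is linear and user-supplied (`duration_to_distance`); no calibration
constants are built in.

## The agent-based simulation

The simulator justifies the component laws rather than fitting data.
A circular landscape of radius 2.5 km holds Poisson-many (mean
`area/5000 m⁻²` ≈ 3927) resource patches, uniform in area
(`ρ = r√U`), each with quality uniform on [0, 10]. One hundred bees
forage for 100 iterations, half scouts and half recruits:

* **Scouts** draw a fresh random path each iteration — U{1..10}
  segments, each with uniform heading and length U(0, r/2), chained
  from the hive — and search a 10 m-wide rectangular corridor along
  each segment (point-in-rectangle by projection onto the segment
  frame). Among resources found, the one nearest the hive is reported
  to the dance pool if its quality exceeds 5.
* **The dance pool** is the multiset of dances performed in the
  previous iteration: scout reports plus recruit re-advertisements.
* **Recruits** sample one dance per iteration with probability
  proportional to the advertised resource's profitability — quality ×
  distance — times its multiplicity in the pool, visit it, and
  re-advertise it next iteration. Multiplicity is the amplification
  loop: resources danced for often are sampled more often.
* **Turnover**: with probability 1.5/100 per step, one random patch is
  replaced by a fresh one elsewhere; dead patches drop out of the pool.

Trips are binned every 5 steps. Recorded scout distances fit the
shifted exponential better than the Rayleigh form, and recruit
distances the reverse — the analytic MLEs are `λ̂ = 1/x̄` and
`λ̂ = 1/(π x̄²)` on min-shifted distances, with the shifted zero
excluded from both log-likelihoods since the Rayleigh density vanishes
there.

Two design points deserve emphasis. First, profitability is the
*product* of quality and distance by default. Weighting by quality per
unit distance (`quality/ρ`, available as
`profitability_mode="inverse_distance"`) seems more natural for a
central-place forager but collapses recruits onto the closest patches
and produces an exponential-looking recruit distribution; the nearness
bias is already supplied by scouts reporting their nearest find, and
the distance factor keeps mid-range profitable sites represented,
yielding the Rayleigh-shaped recruit law the mixture model assumes.
Second, units: patch coordinates are in km while the resource density
is per m², i.e. ≈ 3900 patches rather than the ≈ 0.004 a naive same-
unit reading would give; the 10 m corridor width then makes scout
encounter rates realistic (a handful of finds per path).

## Problem sizes and tolerances

Density normalisation is verified by adaptive quadrature (50 random
valid parameter sets, tolerance 1e−7). Recovery checks use 20 seeds
per point with n = 2000 for estimation error and n = 141 — the
per-hive scale of decoded field datasets — for AIC selection rates.
Simulator conclusions pool 20 seeded default-configuration runs
(~150 000 trips). KS calibration uses 200 replicates at n = 141 with
1000 bootstrap resamples each. The acceptance script derives every
random stream from the single `--seed` argument and recomputes all
quantities at run time.

## Known limitations

* Waggle dance use is identified only through the shape contrast of
  the two components; hives whose scout and recruit distributions
  overlap strongly are intrinsically uninformative about `p` at field
  sample sizes.
* The free-parameter count (k = 2 vs 5) treats `m` as data-determined;
  analyses that count it as free would shift every AIC by 2 without
  changing any comparison within this package.
* The KS test uses the fitted model's own sample, not a
  parametric-bootstrap re-fit per replicate; p-values are calibrated
  under the true model but mildly conservative when parameters are
  estimated from small samples.
* The simulator is schematic: no energetics, no continuous flight
  dynamics, no dance-circuit counts beyond the profitability weighting,
  and a single resource type.
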