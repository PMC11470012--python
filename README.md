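# wagglemix

**How much of a honeybee colony's foraging is collective?**

Honeybee foragers advertise food sources with the waggle dance: the
duration of the waggle run encodes the distance to the site. A hive's
dancefloor therefore carries a statistical imprint of *how* its foragers
found their food. Trips to sites discovered by independent scouting
produce waggle-run durations with a (truncated) **exponential**
signature — the first resource encountered along a roughly straight
search path — while trips to sites learned from dances ("recruit"
trips) carry a (truncated) **Rayleigh** signature, the distance to the
nearest profitable site in the two-dimensional neighbourhood of the
hive. `wagglemix` fits the resulting two-component mixture to decoded
waggle-run durations and estimates **waggle dance use**, the fraction of
foraging trips driven by recruitment.

It is aimed at behavioural ecologists with per-hive tables of decoded
waggle-run durations, and at modellers who want the agent-based
foraging simulation that motivates the two component distributions.

## The model

For durations `x ≥ m` (with `m` the minimum recorded duration):

* scout component (exponential with a linear taper, support `[m, 1/a_s)`):

  `f_s(x) = a_s M_s⁻¹ b_s exp(−b_s a_s (x − m)) · (1 − a_s x)₊`,
  `M_s = (1 − a_s m) − b_s⁻¹ (1 − e^{−b_s (1 − a_s m)})`

* recruit component (Rayleigh with the same taper, support `[m, 1/a_r)`):

  `f_r(x) = M_r⁻¹ 2π a_r² b_r x exp(−π b_r (a_r x)²) · (1 − a_r x)₊`,
  `M_r = (1 − a_r m) e^{−π b_r (a_r m)²} + [erf(a_r m √(π b_r)) − erf(√(π b_r))] / (2√b_r)`

* dancefloor mixture: `P(x) = p f_s(x) + (1 − p) f_r(x)`, where `p` is
  the fraction of scout trips and `1 − p` is the waggle dance use.

Two nested variants are fitted per hive by maximum likelihood
(multistart Nelder–Mead on transformed parameters): an **individual**
model with `p = 1` (2 free parameters) and a **collective** model with
`p` free on `[0, 1]` (5 free parameters; `m` is fixed at the data
minimum). The variants are compared with AIC (`2k − 2 ln L`) and Akaike
weights, and each fit is checked with a bootstrapped two-sample
Kolmogorov–Smirnov test against a sample drawn from the fitted model.

## Worked example

Generate one synthetic hive with known ground truth (`p = 0.35`, 141
decoded dances — a typical per-hive sample) and fit it:

```python
from wagglemix import WaggleRunMixture, StudyConfig, generate_study

study = generate_study(StudyConfig(n_hives=1, per_hive_n=141,
                                   p_by_hive=[0.35], seed=11))
res = WaggleRunMixture.from_dataset(study[0]).fit(kind="collective")
print(res.summary())
```

```
Waggle-run duration mixture
==============================================
Hive:                     hive01
Model:                    collective
No. observations:         141
Free parameters:          5
Log-likelihood:           -170.427
AIC:                      350.854
Converged:                True
----------------------------------------------
p (scout fraction):       0.3351
waggle dance use (1-p):   0.6649
a_s (1/s):                0.1190
b_s:                      0.9275
a_r (1/s):                0.2605
b_r:                      3.4322
m (s, fixed):             0.2068
==============================================
```

The fitted scout fraction `p ≈ 0.34` recovers the generating value
0.35: about two-thirds of this hive's trips are recruitment-driven.
Comparing against the individual model:

```python
cmp = WaggleRunMixture.from_dataset(study[0]).fit_compare()
print(f"delta AIC = {cmp.delta_aic:.2f}, selected = {cmp.selected}, "
      f"waggle dance use = {cmp.waggle_dance_use:.3f}")
# delta AIC = 6.09, selected = collective, waggle dance use = 0.665
```

A positive ΔAIC (here 6.09) means the collective model is the more
parsimonious description — this hive's dancefloor carries a detectable
recruitment "hump".

From the shell, the same pipeline runs on any CSV with `hive_id` and
`duration_s` columns:

```bash
wagglemix synth --out study.csv          # synthetic 20-hive study
wagglemix fit study.csv --seed 1 --out report.json
wagglemix simulate --seed 1 --out trips.csv   # agent-based simulation
wagglemix pool study.csv --by site_class
```

## The simulator

`wagglemix.run_simulation` implements the agent-based model behind the
component distributions: scouts search a circular landscape (radius
2.5 km, ~3900 Poisson-placed resource patches) along random
multi-segment paths with 10 m-wide search corridors and report their
nearest find to the dance pool; recruits sample the pool in proportion
to resource profitability and re-advertise what they visit. Fitting
the analytic MLEs to the recorded trip distances reproduces the
dichotomy: scout trips are better fit by an exponential, recruit trips
by a Rayleigh distribution.

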