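# isotroph

Inference of **foraging habitat** and **trophic position (TP)** for a large
pelagic predator from intrinsic isotope tracers, built around the Gulf of
Mexico yellowfin-tuna system: zooplankton stations define two regional
isotopic baselines (a high-δ¹⁵N northern shelf shaped by denitrification and
a low-δ¹⁵N central-southern basin dominated by N₂ fixation), and consumer
tissues are read against those baselines.

The package is aimed at trophic ecologists who have (a) a table of consumer
bulk δ¹³C/δ¹⁵N values, optionally with amino-acid δ¹⁵N (phenylalanine and
glutamic acid), and (b) a table of baseline (zooplankton) stations with
coordinates and bulk isotope values.

## What it computes

**Isoscapes and baselines.** Station values are interpolated onto a raster
by inverse-distance weighting (power 2, search radius = 5 cell sizes), and
each labelled region is summarised into a baseline (n, mean, SD per
isotope). A least-squares calibration δ¹⁵N_Phe = a·δ¹⁵N_bulk + b extends the
phenylalanine baseline to stations without amino-acid measurements.

**Foraging-habitat apportionment.** A two-source Bayesian mixing model: for
isotope *j* of consumer *i*, with *p* the proportion of source 1,

    x_ij ~ N( p·μ′₁ⱼ + (1−p)·μ′₂ⱼ ,  p²σ′₁ⱼ² + (1−p)²σ′₂ⱼ² + ε_j² )

where primes denote baselines shifted by the trophic enrichment factor
(TEF) and widened in quadrature, p ~ Dirichlet(1,1), ε_j ~ half-Cauchy(1‰).
The posterior is sampled by adaptive Metropolis MCMC (10,000 iterations ×
4 chains, 1,000 burn-in by default) and validated against an exhaustive
grid-quadrature posterior.

**Trophic position**, three ways:

* bulk, single baseline (Post): `TP = (δ¹⁵N_consumer − δ¹⁵N_base)/TEF_N + TP_base`
* compound-specific (Chikaraishi): `TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β)/TDF + 1`
  with β = 3.4 ± 0.9‰ and literature TDF presets (6.3 ± 0.4 captive tuna,
  5.7 ± 0.3 wild teleosts)
* a Bayesian two-baseline model sampling TP and the baseline mixture α
  jointly from both elements (C and N)

The closed-form estimators carry first-order (delta-method) propagated SDs;
the Bayesian estimator reports an equal-tailed 95% credible interval.

A synthetic-data module generates stations, calibration pairs and consumers
with known ground truth, so the whole chain is testable without any
external data.

## Worked example

```python
from isotroph import *

spec = ScenarioSpec(seed=7)            # two-region scenario, true p = 0.55
stations = gen_stations(spec)
consumers = gen_consumers(spec)

north = compute_region_baseline(stations, "north")
south = compute_region_baseline(stations, "central_south")
print(f"north baseline:  n={north.n}  d15N = {north.d15N_mean:.2f} +/- {north.d15N_sd:.2f}")
print(f"south baseline:  n={south.n}  d15N = {south.d15N_mean:.2f} +/- {south.d15N_sd:.2f}")

post = TwoSourceMixingModel(consumers, spec.source_set(), MixingConfig(seed=7)).fit()
print(post.summary())

est = tp_bulk(10.081, RegionBaseline(region="north", n=28, d13C_mean=-21.3,
                                     d13C_sd=0.9, d15N_mean=6.0, d15N_sd=3.1),
              get_tef("madigan-muscle"))
print(est)
```

prints

```
north baseline:  n=28  d15N = 6.68 +/- 3.02
south baseline:  n=61  d15N = 2.76 +/- 0.90
Two-source mixing posterior (mode [95% interval]):
  north: 55.2% [48.1-61.8%]
  central_south: 44.8% [38.2-51.9%]
  R-hat: p=1.002, eps_d13C=1.001, eps_d15N=1.003
TP_bulk = 4.1
```

The recovered mixing mode (55.2%) brackets the generating truth (p = 0.55):
the model reads the consumers' isotope values as a little over half
northern-baseline nitrogen. The bulk TP line evaluates a consumer at
10.081‰ against a 6.0‰ baseline with a 1.9‰ TEF: about two trophic steps
above the zooplankton (TP 2), i.e. TP ≈ 4.1 — a mid-level pelagic
carnivore.

There is also a CLI (`isotroph simulate | calibrate-phe | isoscape | mix |
tp | run`); `isotroph run --config run.yaml` executes the full chain
(data → baselines → calibration → isoscapes → mixing → TP) and writes
per-stage CSV/JSON artifacts plus a reproducibility manifest.

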