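# Methods

This note records the models implemented in `isotroph`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish.

## Data model

Two tables drive everything. *Consumer records* hold one tuna × tissue
(muscle or liver) measurement set: bulk δ¹³C and δ¹⁵N (‰, vs. VPDB / air
N₂), optional curved fork length (cm), C:N ratio, and δ¹⁵N of phenylalanine
(Phe, the canonical *source* amino acid) and glutamic acid (Glu, the
canonical *trophic* amino acid). *Station records* hold one zooplankton
station: coordinates in decimal degrees, bulk isotopes of the 335–1000 μm
fraction, optional Phe δ¹⁵N of the >2000 μm fraction, and a baseline-region
label (`north`, `central_south`, or `outside`).

C:N ratios above 3.5 flag potential lipid bias in δ¹³C, but no arithmetic
correction is ever applied — at the lipid contents typical of these tissues
a correction would move δ¹³C by well under 1‰, and flag-only behaviour
keeps the measured values authoritative.

## Isoscapes and baselines

Inverse-distance-weighted interpolation with power 2 and a search radius of
five cell sizes mirrors the standard GIS workflow for zooplankton
isoscapes. Distances are planar Euclidean in decimal degrees (the default
of the common GIS tools at basin scale); great-circle central angles are a
config option. Cell size defaults to 0.25° — the original raster resolution
is not recorded anywhere, so isoscapes are reproducible in pattern, not
cell-for-cell. A station within 10⁻⁹ degrees of a cell centre snaps the
cell to the station value (this also removes the 1/d singularity), and IDW
is therefore an exact interpolator at stations.

Baselines summarise labelled stations with the arithmetic mean and the
n−1-denominator sample SD per isotope. Explicit station labels are the
canonical region definition; the latitude-threshold (26° N) and polygon
rules are geometric approximations for unlabelled data, with boundaries
counting as inside. The baseline trophic level defaults to 2 (zooplankton
as primary consumers).

## Bulk → Phe calibration

δ¹⁵N_Phe tracks bulk δ¹⁵N closely (sitting ≈2‰ lower); a single basin-wide
OLS line of Phe on bulk predicts Phe where CSIA-AA was not run. The
regression direction is deliberate — bulk is the predictor — and no
errors-in-variables correction is applied, since the line is used only for
prediction at observed bulk values. Measured Phe always overrides a
prediction, and predictions are flagged (`phe_source = predicted`).

## Two-source mixing model

The likelihood is the classical two-source, two-tracer mixing formulation
(the SIMMR/SIAR family): consumer values are normal around the p-weighted
corrected source means, with variance combining p²-weighted source
variances and a per-isotope residual ε_j. Priors: p ~ Dirichlet(1,1)
(uniform), ε_j ~ half-Cauchy(1‰) — weakly informative on the permil scale.

Sources are corrected by `prey_offset_steps` × TEF per isotope before
mixing, with each step adding the TEF variance in quadrature. The default
is 1 step (the conventional source-plus-TEF correction). An alternative
reading — prey at trophic position 3.2 versus a baseline at 2, i.e. 1.2
steps — is supported via the same parameter rather than silently resolved,
because published apportionments rarely state which was used.

TEF presets (‰): muscle ΔC 1.8, ΔN 1.9 ± 0.4; liver ΔC 1.2, ΔN 1.1; plus a
muscle variant with ΔC 1.1 ± 0.6 used by the Bayesian TP configuration.
Values are the captive Pacific bluefin tuna estimates standard for tuna
tissues.

**Sampling.** Adaptive Metropolis on (logit p, log ε_C, log ε_N): the first
half of burn-in runs component-wise random-walk updates with Robbins–Monro
scale tuning, the second half switches to joint Gaussian proposals with the
empirical covariance of the warm-up draws, and the proposal is frozen at
the end of burn-in. Defaults: 10,000 iterations × 4 chains, 1,000 burn-in.
Chains are seeded by spawning a NumPy `SeedSequence` from one master seed,
so runs are draw-for-draw reproducible. Convergence is summarised by
rank-normalised split R̂ (via ArviZ); any parameter above 1.1 attaches a
warning to the result rather than raising.

Internally the two sources are put in a canonical order (descending mean
δ¹⁵N) and mapped back on output, so relabelling the caller's sources flips
the reported proportion draws *exactly* — a cheap, strong invariant.

**Oracle.** With two sources the proportion is scalar, so the posterior can
be tabulated exhaustively: ε_C and ε_N are marginalised on a 121-point
log-spaced quadrature grid under the same half-Cauchy prior, and the
p-density is normalised by trapezoidal integration. The sampler is required
(in tests) to match this oracle within 0.02 in sup-CDF distance.

**Summaries.** Mode = argmax of a Silverman-bandwidth Gaussian KDE on a
512-point grid over [0,1]; interval = equal-tailed 2.5–97.5% quantiles
(published "mode 95%" reports rarely say HDI vs. equal-tailed; equal-tailed
is the simpler, quantile-stable choice). Both sources are summarised from
the same draws (source 2 = 1 − p), so reported percentages always sum
to 100.

## Trophic position

*Bulk (Post).* `TP = (δ¹⁵N_x − δ¹⁵N_base)/TEF_N + TP_base`. The delta-method
SD combines the analytical SD of the consumer measurement (0.2‰), the
baseline SD, and the TEF SD, assumed independent:
`sqrt[(σ_cons² + σ_base²)/Δ² + (δ_cons − δ_base)²σ_Δ²/Δ⁴]`.

*CSIA (Chikaraishi).* `TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β)/TDF + 1`, β = 3.4 ±
0.9‰ (aquatic photoautotrophs). Analytical SDs default to 0.5/0.4‰
(Phe/Glu). The analogous delta-method SD applies. Liver CSIA TP requires a
liver TDF that must be supplied by the user — the one published liver
feeding study does not print a transferable value, so there is deliberately
no default.

*Bayesian two-baseline.* For consumer i, with α the northern share and λ
the baseline trophic level:

    δ¹⁵N_i ~ N( α·μN₁ + (1−α)·μN₂ + ΔN·(TP−λ), σN )
    δ¹³C_i ~ N( α·μC₁ + (1−α)·μC₂ + ΔC·(TP−λ), σC )

Priors: TP ~ U(λ, 10); α ~ Beta(1,1); baseline means normal with the
regional mean and its *standard error* (encoding the n baseline
observations, as the hierarchical two-baseline TP packages do); TEFs normal
with their stated SDs when positive, fixed otherwise; residual SDs
half-Cauchy(1‰). Defaults: 20,000 iterations × 2 chains, 2,000 burn-in.
TP is computed per fish and averaged for report tables (rounded to one
decimal); per-fish values are exported.

**Error-propagation accuracy.** The delta method is first-order. Against
10⁶-draw simulation its SDs agree to 2% when the TEF coefficient of
variation is ≈10%, but at a TEF CV of 21% (0.4‰ on 1.9‰) the linearisation
under-estimates the simulated spread by 2–4%. Note that the simulated
*variance* of a ratio with a normal denominator does not converge at all
(the denominator has mass near zero), so simulation comparisons use the
central 68.27% quantile range, which equals the SD for a Gaussian.

## Synthetic data

`ScenarioSpec` defaults place synthetic runs in the study system's numeric
regime: northern baseline δ¹⁵N 6.8 ± 2.6‰ / δ¹³C −21.3 ± 0.9‰ (n = 28),
central-southern 2.7 ± 0.9‰ / −20.1 ± 0.8‰ (n = 61), calibration line
0.87·bulk − 2.74 with 0.5‰ noise, 72 consumers, true mixing proportion
0.55, true TP 4.2, and the muscle TEF preset. Station boxes (26–30° N vs.
18–25° N, 98–82° W) are a caricature of the real region split — synthetic
geometry only.

Consumers are drawn from the mixing model's own likelihood (mean *and*
variance), so fitting a generated scenario is a correctly specified
inference problem; this is what makes the coverage checks (true proportion
inside the 95% interval in ≥90% of seeded replicates) meaningful. Amino
acids are built so the Glu/Phe equation returns the generating TP exactly
when noise is zero. What the generators do *not* emulate: spatial
autocorrelation within regions, seasonal baseline movement (of order
≤0.5‰ in this system), tissue-turnover dynamics, and any non-Gaussian
structure in real baselines — so passing tests establish the inference
machinery, not field performance on real tables.

A second module, `synthetic_study`, produces *stand-in* tables whose group
summary statistics (group sizes, means, sample SDs, and the calibration
slope/intercept/correlation) match the published study tables exactly, via
affine standardisation of Gaussian draws. The underlying per-fish and
per-station tables were published only as word-processor supplements, so
these stand-ins are the closest machine-readable reconstruction; any
statistic depending only on the matched moments is exact, everything else
(skew, outliers, spatial texture) is synthetic.

## Known limitations

* Reproduction of the published *mixing-model apportionment* is not
  achievable from the printed summaries: the pooled muscle δ¹⁵N (10.08‰)
  lies above even the TEF-corrected northern source mean (8.7‰), so this
  likelihood family places the muscle mode at 78–92% north for every
  correction variant we examined, not at the published ≈55%. The published
  run evidently used inputs or corrections that were not printed; the
  corresponding checks in `tests/test_acceptance.py` assert the published
  intervals and currently fail, intentionally.
* The Bayesian TP reproduction is sensitive to which carbon TEF is meant
  (1.8‰ in the methods-style preset vs. 1.1 ± 0.6‰ in the Bayesian-row
  preset); the two readings bracket the published 4.2 from below (≈3.8)
  and above (≈4.8), and both are available as presets.
* Posterior modes from KDE have a grid resolution of ~0.002 in p.
* The pipeline assumes one consumer table per tissue per run; multi-tissue
  joint models (shared α across tissues) are out of scope, as are >2-source
  mixtures, concentration dependence, and isotope routing.

## Problem sizes used in the checks

Coverage checks run 50 seeded replicates at n = 72 consumers with reduced
chain lengths (3,000 × 4 for mixing, 5,000 × 2 for TP) — enough for stable
95% intervals, chosen to keep the whole suite fast; oracle-equivalence
uses 20,000-iteration runs on 10-consumer fixtures; Monte-Carlo
propagation checks use 10⁶ draws.
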