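# Methods

## Kinetic model

The reaction modelled is electrophilic aromatic substitution (S_EAr) of a
π-excess heterocycle by a cationic electrophile, proceeding through a
Wheland-type σ-complex:

    Nu + E⁺  ⇌(k₁ / k₋₁)  I⁺  →(k₂)  product

With the nucleophile in large excess (≥ 20× the electrophile, enforced by
`ExperimentDesign`), the electrophile sees a constant nucleophile
concentration and the relaxation is pseudo-first-order. Applying the
quasi-steady-state approximation (QSSA) to the unstable intermediate I⁺:

    k_obsd = k₁ · k₂/(k₋₁ + k₂) · f(pH, pKₐ) · [Nu]_total

where f = 1/(1 + 10^(pKₐ−pH)) is the free-base fraction of the nucleophile
(only the unprotonated amine reacts; this is the only reading under which
the tabulated k → k₁ arithmetic is consistent, and it is verified
numerically in the tests). When re-aromatization is fast (k₂ ≫ k₋₁) the
partition factor is 1 and k_obsd = k₁·f·[Nu]. The kinetic-isotope ratios
k_H/k_D ≈ 1 justify that regime for the study system.

`simulate_mechanism_ode` integrates the full three-species linear system
(LSODA, rtol 1e−11, atol 1e−16·[E]₀) without the QSSA; tests confirm mass
balance to better than 1e−9 and agreement of the electrophile decay with
the QSSA exponential within 1% whenever (k₋₁ + k₂) ≥ 100·k_obsd.

## Synthetic traces and campaigns

A stopped-flow trace is A(t) = A∞ − (A∞ − A₀)·exp(−k_obsd·t) plus i.i.d.
Gaussian noise. Defaults, chosen to emulate the study conditions:

| parameter | default | rationale |
|---|---|---|
| nucleophile concentrations | 0.004–0.028 M (5 levels) | the experimental ladder spans 10⁻³–2.8×10⁻² M |
| electrophile concentration | 5×10⁻⁵ M | pseudo-first-order excess ≥ 80× |
| pH | 1 and 2 | the two experimental acidity levels |
| pKₐ | 3.38 | conjugate acid of the aminothiophene |
| A₀, A∞ | 0.02, 0.80 | visible-band adduct absorbance on a 1 cm path |
| noise | σ = 0.002 AU, Gaussian, i.i.d. | simplest model consistent with the reported regression quality (r > 0.97) |
| time grid | 200 points over 5/k_obsd | captures > 99% of the relaxation |

Campaign ground truth follows the reactivity relation
log₁₀ k₁ = s_N(E + N), so the end-to-end chain (traces → k_obsd → k → k₁ →
(N, s_N)) can be scored against known parameters. One integer seed per
campaign; each trace draws noise from a deterministically spawned
substream (`numpy.random.SeedSequence`), so campaigns are bit-reproducible.

What the generator deliberately omits: instrument drift and dead time,
photobleaching, diazonium decomposition side reactions, ionic-strength and
temperature variation (held constant in the experiments), and biphasic
relaxations. Recovery results on synthetic data therefore demonstrate the
correctness of the inference chain, not robustness to instrumental
artefacts.

## Rate extraction

Two k_obsd estimators:

* `guggenheim-linear` (default, the classical treatment): OLS of
  ln|A∞ − Aₜ| on t; k_obsd = −slope. Points at or beyond A∞ are dropped
  with a warning (their logarithm is undefined); points within 0.5% of the
  endpoint are trimmed silently because the log transform amplifies any A∞
  error exponentially there. A fit needs ≥ 5 usable points; a
  non-negative slope raises "no relaxation detected".
* `exp-nonlinear`: direct least-squares fit of the exponential with
  (A₀, A∞, k_obsd) free — robust when the endpoint is uncertain, since the
  log transform distorts the noise near A∞.

Both agree within 0.5% on clean traces across k_obsd = 10⁻²–10² s⁻¹. A∞ is
taken from the trace's recorded equilibrium value by default (it is
measured directly in the experiment); `estimate_a_inf=True` uses the mean
of the final 5% of points instead, which requires a trace that has truly
plateaued (≳ 10 relaxation times).

The bimolecular slope is fitted with a free intercept; the rate law
predicts zero intercept, so the fitted intercept is kept as a diagnostic
rather than constrained away. Isotope ratios are computed on k₁ values and
paired by (electrophile label, pH) — computing them on k₁ rather than k is
what reproduces the tabulated 0.96–1.14 range.

## LFER conventions

All logarithms are base 10 and all regressions unweighted OLS (no weighting
scheme is defensible for 7–8 points of similar precision). Per-electrophile
log₁₀ k₁ is the mean over the pH 1 and pH 2 determinations: k₁ is
pH-independent by construction, and this convention reproduces the
published fit coefficients to their printed precision where single-pH fits
drift in the last digit. The fluoro electrophile, which has no tabulated E,
is excluded from the Mayr–Patz fit but kept in the Hammett and
Yukawa–Tsuno fits.

Yukawa–Tsuno fitting is genuinely open to two readings and both are
implemented:

* `joint-bilinear` (default): two-regressor OLS on (σ, σ⁺ − σ) with
  ρ = b₁ and r = b₂/b₁ — the global least-squares optimum of the
  three-parameter model (verified against a 200×200 brute-force SSE grid).
* `grid-conditional`: scan r over [−1, 3] in steps of 0.01, one-regressor
  OLS on σ_eff = σ + r(σ⁺ − σ) at each r, keep the SSE-minimising r.

When σ⁺ = σ for every point the resonance term vanishes and r is
unidentifiable: the joint method raises, the grid method returns the plain
Hammett fit flagged `r_identifiable=False`.

The published Yukawa–Tsuno pair (ρ = 2.11, r = 1.54) is **not** recoverable
from the printed rate table: the joint optimum of those data is ρ ≈ 2.92,
r ≈ 0.49. The original fit evidently used unrounded rates and possibly a
different procedure, so this package reports both of its methods and treats
the Yukawa–Tsuno parameters as a qualitative resonance diagnostic, not a
reproducible quantity. The same applies to printed R² values, which refits
of rounded tables cannot match in the last digits; R² is reported to four
decimals but never used as a pass/fail comparison.

## Prediction conventions

`predict_N` evaluates the N–σ⁺ line with its coefficients at their
reporting precision (2 decimals) by default. The published correlation
equation is the deliverable of such an analysis: downstream rate
predictions chain from its printed coefficients, and the tabulated
predicted-N and k_calc values are consistent only under this convention
(the unrounded line gives 8.295 where 8.29 is tabulated).
`coefficient_precision=None` evaluates the unrounded fit. Rate predictions
use log k = s_N(E + N) with the single-rate convention s_N = 1, and the
experiment/prediction comparison applies the reactivity scale's accepted
factor-100 confidence band on max(ratio, 1/ratio).

## Degenerate inputs and tie-breaks

* Missing table cells are `None` end to end; fits drop the record, never
  impute.
* `fit_bimolecular` rejects mixed-pH input, fewer than 3 points, and
  rank-deficient (all-equal-concentration) designs.
* `fit_sigma_plus_model` rejects an all-equal σ⁺ column; coincident points
  among ≥ 3 are allowed.
* `mayr_fit` raises on a non-positive slope (an inverted scale is a sign of
  corrupted input, not a fit result).
* k₂ = 0 (no product channel) and k₋₁ = 0 (irreversible addition) are
  valid mechanism corners; k₋₁ = k₂ = 0 is not (the intermediate would be
  a sink).

## Known data caveats

* One printed speciation pair (the methyl-substituted electrophile at
  pH 1) deviates from k₁ = k·(1 + 10^(pKₐ−pH)) by 1.7% where every other
  pair agrees within 0.5%; no single pKₐ reconciles it, so it is treated
  as a table inconsistency and documented rather than patched.
* The printed experimental/calculated ratio for unsubstituted thiophene
  (11.1) is not the quotient of its printed numerator and denominator
  (10.96); the fixture keeps the printed cells and the consistency test
  allows 2% on that invariant.

## Problem sizes

The default test and acceptance workloads are small by design: campaigns of
7 electrophiles × 5 concentrations × 2 pH × 200-point traces (70 traces,
~0.1 s per campaign), 20-replicate recovery sweeps, and a 200×200
brute-force grid for the Yukawa–Tsuno oracle. These sizes give recovery
standard errors well below the 5% acceptance band while keeping the whole
suite in seconds.
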