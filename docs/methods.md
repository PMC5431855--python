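# Methods

## The comparative scoring model

The package addresses a recurring problem in in vitro biomaterial
assessment: a screen yields a block of donor-paired, non-normal readouts
(viability plus a cytokine panel) for K materials under C test conditions,
and the question "which material is more fibrosis-prone?" needs one
comparable number per material and condition.

The model answers it in three stages.

1. **Pairwise testing.** Within one (condition, readout) cell, every
   unordered material pair is compared with a two-sided Wilcoxon
   signed-rank test on the within-donor differences. The test is paired
   because the dominant variance component is the donor: the same donor's
   macrophages are measured on every material, and differencing removes
   the donor effect entirely.
2. **Ternary scoring.** Each test is collapsed to {−1, 0, +1} for the
   first material of the pair: ±1 when p ≤ α (α = 0.05, two-sided, no
   multiplicity correction by default) with the sign taken from the
   comparison of arithmetic means, 0 otherwise. Direction-from-means with
   significance-from-ranks is kept literally as the model defines it; a
   rank-based direction (`direction="signed_rank"`, sign of W − n(n+1)/4)
   is available for sensitivity analysis. The measure-zero corner case
   "significant but exactly equal means" (reachable when censored
   substitutes make many values identical) scores 0 and is logged.
3. **Aggregation.** A material's significance profile for one readout is
   the sum of its K−1 pairwise scores ∈ [−(K−1), K−1]; the K × R profile
   matrix is the numeric heat map; row sums give the per-condition ∑score
   ∈ [−R(K−1), R(K−1)] and the ranking. Ties in ∑score are reported as
   ties, never broken. Score antisymmetry forces every readout column to
   sum to zero; `build_score_matrix` verifies this and the bounds before
   returning and raises on violation rather than returning silently.

Rankings are validated against the literature consensus ordering of
fibrotic potential, PE < titanium < PTFE < silicone, with glass excluded
as an unranked control. Kendall's τ-b is the primary concordance metric
(4-item rankings with possible tied totals), reported with Spearman's ρ
and the concordant-pair fraction (ties excluded from the denominator).
"Recovery" in the recovery experiment means τ = 1 exactly — the strictest
unambiguous criterion for a short ranking; tied totals therefore count as
non-recovery.

## The exact signed-rank test

With n = 10 donors the normal approximation to W is poor and attainable
significance levels are coarse, so the exact branch is the one that
matters. Implementation details:

- Zero differences are dropped (classic reduction; n_used is the count of
  nonzero differences). All-zero input is not an error: W = 0, p = 1.
- Absolute differences are mid-ranked; ties are therefore half-integers,
  and the null PMF of W is computed on the doubled-rank integer grid by a
  sign-flip convolution (each rank contributes a fair ±). The two-sided
  p-value is min(1, 2·min(P(W ≤ w), P(W ≥ w))).
- The exact branch is used for n_used ≤ 25 (the DP is microseconds there);
  above that a tie-corrected normal approximation without continuity
  correction takes over. PMFs are memoised on the rank multiset, which
  makes the common tie-free n = 10 case a table lookup.
- `exact_signed_rank_null` enumerates all 2^n sign assignments literally
  (guarded at n ≤ 20) and is kept naive on purpose: it is the independent
  oracle the tests compare the convolution against, to full precision,
  for tied and tie-free vectors. The tests additionally cross-check
  tie-free p-values against `scipy.stats.wilcoxon(method="exact")`.
- The attainable size of the two-sided exact test at α = 0.05, n = 10 is
  0.048828125 = 50/1024; Type-I calibration of the scoring is judged
  against this number, not against the nominal α.

Shapiro–Wilk (a documentation screen only — the pipeline never switches
test family on it) and Friedman's ANOVA delegate to `scipy.stats`. The
Friedman omnibus is reported per (material, readout) alongside the
pairwise condition tests but does not gate them by default
(`friedman_gate=True` enables gating); Benjamini–Hochberg per
(condition, readout) family is likewise available behind
`multiple_testing="benjamini_hochberg"` and off by default, so the default
configuration reproduces the flat p ≤ 0.05 rule.

## The synthetic-data generator

No raw per-donor screen data are publicly deposited for this design, so
the generator is the package's test bed and is itself first-class, tested
code. It emulates:

- the reference design — 10 donors × 5 materials (glass, titanium, PTFE,
  silicone, PE) × 5 conditions (untreated, LPS, native plasma,
  heat-inactivated plasma, IL-4) × 7 readouts (CellTiter ATP viability,
  IL-1b, IL-6, TNF-a, IL-8, IL-10, TGF-b1), 1750 rows;
- lognormal measurements: value = exp(baseline + condition effect +
  material effect + donor effect + noise), all effects additive on the
  log scale, hence right-skewed, strictly positive linear-scale values;
- a donor random effect drawn once per (donor, readout) and shared across
  materials and conditions — the component that makes pairing
  informative; donor effects are independent across readouts (no
  cross-readout correlation is quantified anywhere to calibrate against);
- detection-limit censoring: values below a per-readout LOD are flagged
  and substituted (lod/2 by default; 0 and lod available). Flagged values
  participate in tests as ordinary values; the flag is retained so
  sensitivity analyses can re-substitute.

Default parameters are documented modelling assumptions, not estimates:
baselines are typical log pg/ml magnitudes per cytokine (log RLU for
CellTiter); donor SD 0.8 and residual SD 0.5 on the log scale encode the
qualitative observation of high donor-to-donor variation; LODs are
CBA/ELISA-like values chosen so that IL-1b (baseline ~3 pg/ml vs LOD
7.2 pg/ml) is censored for most donor cells while other readouts are
almost never censored, matching the qualitative censoring pattern of such
screens. Default condition effects reproduce the expected directions (LPS
boosts pro-inflammatory cytokines ~e^2.5-fold and depresses ATP; IL-4
raises viability and depresses IL-6/IL-8; TGF-b1 is condition-insensitive
basal medium content). Default *material* effects are zero:
`literature_scenario(config, effect_step)` plants the reference ordering
as an arithmetic progression (PE 0, titanium s, PTFE 2s, silicone 3s,
glass 0) uniformly over readouts and conditions, and `null_scenario`
clears all effects for calibration runs.

What the generator does **not** emulate: technical replicates (the model
operates on one value per donor-cell), cross-readout donor correlation,
condition-specific material interactions beyond what a user plants
explicitly, heavy-tailed or bimodal donor subpopulations, and any
mechanism (polarisation kinetics, protein adsorption). Passing tests on
synthetic data therefore demonstrate the *statistical machinery* —
calibration, conservation, recovery power — not in vivo predictive
accuracy of any particular assay.

## Numerical and design choices

- **Determinism.** All generation flows through
  `numpy.random.default_rng(seed)` with a fixed draw order (donor effects
  first, then residuals in row order); sub-seeds for replicate experiments
  come from `SeedSequence.generate_state` reduced below 2^31. The analysis
  pipeline itself is randomness-free, and identical (data, config) produce
  byte-identical export bundles.
- **Problem sizes.** The recovery and calibration experiments run at the
  design's native n = 10 donors; the conservation sweep uses 1000 random
  single-condition screens (K = 5, R = 7, 4–8 donors, random effect
  draws) and the calibration run 2000 null replicates — sizes at which the
  Monte-Carlo error is far below the decision margins being checked while
  the whole suite stays in the low minutes.
- **Blank medium controls** are accepted as a condition label in input
  but excluded from scoring by default (they are a measurement reference,
  not a scenario); `include_conditions` overrides.
- **Completeness is checked up front**: every (material, condition,
  readout) cell must carry the identical donor set before any statistic
  runs, and violations are reported with the offending cells and donors.
- **CSV round-trips are value-exact** (shortest round-trip float repr);
  the readout-table schema is validated strictly with line-numbered
  errors.
- **All-tied rankings** have undefined rank correlation; τ and ρ are
  reported as NaN rather than an arbitrary 0, and count as non-recovery.

## Known limitations

- The ternary score discards effect sizes; two materials can share a
  ∑score with very different magnitudes of difference. This is inherent
  to the model, not an implementation choice.
- At n = 10 the exact test's attainable two-sided levels are coarse
  (nearest attainable size to 0.05 is 0.0488), so small α changes can
  have no effect.
- Concordance on synthetic data measures recovery of a *planted*
  ordering; it says nothing about the in vivo predictive accuracy of a
  real assay.
- The approximate branch (n_used > 25) omits the continuity correction;
  at those sample sizes the effect on p is negligible relative to α.
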