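# Methods

This note records the statistical model behind `ailmap`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not establish.

## Design and notation

The experiment genotypes nine DNA pools over one marker panel: three
replicate subpools of 30 diploid segregants (60 chromosomes) for each of
two selected tails (growth, survival) and the unselected F6 control.
All statistics are computed on the frequency of the wild-parent
(YE-531) allele; the lab-parent (S288c) frequency is its complement, so
the choice is a convention, not an assumption. Selection is one-tailed
and two-staged: a mass-survival stage keeping 35% of the population
(shared by both traits, applied to the survival phenotype), then
individual phenotyping of a random 300 survivors per trait keeping the
top 90 (30%), for a combined selected proportion of 0.105. In a
two-tail design the same mapping information would correspond to
selecting 21%; this equivalence is reported but not used for effect
estimation (see below).

## Smoothing

Pool-sequencing frequency estimates carry binomial read noise and
subpool-composition noise. Both are attenuated by local regression:

- **Frequency by position**, per chromosome and per subpool column:
  tricube-weighted k-nearest-neighbour local quadratic with a window of
  80 markers (`loess.position_span_points`). Chromosomes with fewer
  than 3 markers pass through unchanged; fitted frequencies are clipped
  to [0, 1].
- **Among-replicate SD by allele frequency**, genome-wide per category:
  the same engine with a window of 10% of markers
  (`loess.sd_span_fraction`). The replicate SD depends on frequency
  (≈ √(pq/n) noise scales), so borrowing strength across markers of
  similar frequency is the natural pooling. Negative fits clip to 0.

The engine is deliberately classical: symmetric k-nearest neighbourhood
by predictor distance with boundary ties included, `dmax` the distance
to the kth neighbour, no robustness iterations, evaluation at observed
sites only. Windows whose predictors coincide fall back to the weighted
mean. Exact reproduction of polynomials up to the fit degree, and
equality with a brute-force per-site weighted-least-squares oracle, are
enforced by tests.

## Association test

For each marker and trait, `D = mean(tail subpools) − mean(control
subpools)` of smoothed frequencies. The standard error is *empirical*:
the sample variance (denominator n−1 = 2) of the three subpool
frequencies within each category estimates the null sampling variance
of one subpool, so `SE²(D) = VarS/3 + VarCtrl/3`. `Z = D/SE` is
referred to the standard normal two-sided (on |Z|; a one-sided reading
would produce P > 1 for negative shifts).

**Small-sample SD bias.** The sample SD of three replicates has
expectation `c4(3)·σ ≈ 0.886σ`. In an ordinary t statistic the heavy
tail of 1/s compensates, but here the SDs are smoothed across thousands
of markers before squaring, which freezes the SE near the biased value
and would inflate the null type-I rate at 0.05 to ≈ 0.08 (and Var(Z) to
≈ 1.27). `associate_trait` therefore divides the smoothed SD by c4(3)
(`unbias_sd=True` by default). With the correction, null simulations
show type-I error within Monte-Carlo noise of the nominal level and
Var(Z) ≈ 1. The worked-example SEs (0.038 and 0.042 from variance
components 0.0034/0.0044 and 0.0010) involve no smoothing step and are
unaffected.

Markers with a missing subpool frequency, or with SE = 0 (all subpools
identical), are masked: excluded from testing and from the multiplicity
count N.

## Multiplicity

True nulls are estimated from the histogram of P-values in bins of
width 0.10: starting from `n2 = N`, find the lowest bin whose count does
not exceed the uniform expectation `n2·binwidth`, set `p*` to its left
edge, and re-estimate `n2 = #{p > p*}/(1 − p*)` until the change is
below half a marker. Uniform inputs return ≈ N; a mixture returns ≈ the
null count; an input that is all signal returns 0.

Thresholding is plain Benjamini–Hochberg step-up at α (default 0.2) with
`m = N`; the adaptive variant `m = n2` is available
(`adaptive_bh: true`). The printed critical-P values of the mapped
experiment are not reproducible from either variant (its two in-text
thresholds also appear swapped relative to its table), so the
conservative standard is the default and critical-P values are never
asserted. Power per FDR level is `R(1 − FDR)/n1`, the expected number
of true discoveries over the estimated non-nulls, undefined when
`n1 = 0`.

Neighbouring markers are correlated by linkage and further by
smoothing; BH remains valid under this positive dependence, but the
`n1` estimate at desk-scale marker counts absorbs correlated drift
ridges and should be read as an upper bound on linked markers.

## QTL intervals

Seeds are local maxima of the smoothed −log₁₀P track whose P passes the
FDR critical value; a plateau of tied values is one seed at its central
marker (ties broken left, an arbitrary but fixed rule). Each seed
extends outward while the score stays strictly above `peak − 1.0`; the
first marker at or below the drop line is outside the interval.
Adjacent significant peaks are separate QTLs iff the valley between
them is at least 1.0 below the lower peak, otherwise they merge into
the higher peak (iterated to a fixed point; with the strict-drop member
rule, surviving intervals cannot overlap). Interval bounds are the
outermost member-marker positions, 1-based inclusive; BED export
converts to 0-based half-open. NaN-scored markers split a chromosome
into independently processed segments.

Inter-QTL distance is end-of-left to start-of-right, exclusive of both.
Gene content (optional GFF3) counts genes overlapping an interval by
≥ 1 bp; absent annotation disables gene summaries.

## Effect estimation

Truncation of a proportion α of a normal phenotype shifts the frequency
of an additive allele by `E[D] ≈ p q (δ/σ_P) i(α)` with
`i(α) = φ(Φ⁻¹(1−α))/α`; the estimator inverts this:
`δ = D σ_P/(p q i)`, with δ the per-allele substitution effect (so
`VarQ = 2 p q δ²`). The intensity uses α = 0.105, the actual combined
one-tail proportion; the "equivalent 21%" figure concerns mapping-power
equivalence with two-tail designs and is exposed
(`selection.intensity_alpha`) but not used by default. The two-stage
selection is collapsed to one effective truncation; because the two
stages rank by independently measured phenotypes, this understates the
achieved intensity somewhat at intermediate heritability (recovery
simulations at h² = 0.5 show ≈ +20–30% inflation of estimated effects
at loci detected near the significance threshold, where the estimate is
also conditioned on exceeding it — winner's curse). Calibration is
therefore assessed on well-powered loci, where recovery is unbiased
within a few percent.

Per QTL, δ averages the |effect| of the top three member markers by
smallest P (ties by |D|, then position), signed by the majority D sign;
p̄, q̄ are the mean control-category frequencies of the same markers.
`favorable_parent` is the wild parent when the signed effect is
positive (its allele enriched in the tail).

## Simulator

`SimConfig` defaults mirror the study design: six generations (five
random-mating rounds after the F1), 35% → 300 → 90 two-stage selection,
3×30 subpools, ~1,000× coverage, 0.38 cM/kb (a yeast-like linear map),
population 10,000. Founders differ at every marker; crossovers are
Poisson on the genetic map with no interference (Haldane); each
generation is a random union of gametes from parents drawn with
replacement. Phenotypes are additive (`genotype value = favourable
allele count × δ` summed over QTLs) plus Gaussian noise scaled to the
target h²; the survival trait is discretised to the 0–14 score scale by
equal-probability thresholds, with random tie-breaking in selection
ranks. Sequencing draws Poisson depth per marker per subpool and
binomial reads at the subpool's true frequency; zero-depth markers are
emitted as missing. The control category is realised as three
independent random subpools of 30 from the whole F6, mirroring the
sequencing design rather than a census frequency. A
`drift_amplification` knob (default off) shrinks the effective parent
pool to emulate extra frequency variance from clonal reproduction and
fitness selection between sexual generations; it is a stand-in, not a
calibrated model of those forces.

What the simulator does **not** model: sequence-level reads and
alignment artefacts, variant-calling error (the QC filters are
exercised on constructed fixtures instead), recombination-rate
heterogeneity and interference, epistasis and dominance, selection
during intercross recuperation beyond the drift knob, and the
cross-trait contamination of stage-1 survival selection on the growth
tail (present in the simulator, ignored by the estimator, as in the
design it emulates). Passing recovery tests therefore demonstrate the
statistical chain is self-consistent under the design's own
assumptions, not that real data meet them.

## Problem sizes

Tests and examples run desk-scale versions of the design: populations
of 1,000–4,000 (default 10,000), genomes of 2–20 chromosomes of
50–300 kb with 1-kb marker spacing, and 20,000 replicate lineages for
the drift calculation. The recovery suite uses ten 250-kb chromosomes
(2,500 markers), population 3,000, h² = 0.5, with ten QTLs of realized
|δ/σ_P| ≈ 0.12/0.25/0.5 under the full selection design. Drift, noise
and selection intensities scale with the configured sizes, and all
closed-form oracles are evaluated at those sizes.

## Numerical choices

- Sample variance over replicates uses ddof = 1 (unbiased at n = 3).
- P-values are clamped to (1e-300, 1]; −log₁₀P plateaus from clamping
  are handled by the plateau seeding rule.
- The dual-reference QC agreement tolerance defaults to |Δf| ≤ 0.01
  (strict equality is fragile in floating point); parent-purity
  requires frequency exactly 1 but only flags (does not remove) markers
  with parental coverage below 10 reads. MAF is computed on the pooled
  control counts; a marker at exactly the 0.05 threshold is kept.
  First-failure accounting order: caller → parent → dual-ref → MAF.
- The local design matrix is centred and scaled per window before the
  least-squares solve; rank-deficient windows fall back to the weighted
  mean.
- `estimate_true_nulls` caps at 100 iterations and clips to [0, N];
  convergence tolerance is 0.5 markers, so the result is deterministic.
- All simulation randomness flows from one `numpy` Generator seeded by
  `SimConfig.seed`; identical configs produce byte-identical outputs.

## Known limitations

The empirical SE treats among-replicate variance as the full null
variance of a subpool mean and ignores any covariance between tail and
control sampling, as the design intends. The n2 estimator is biased
upward when smoothing correlates neighbouring P-values. Log-drop
boundaries on a jittery track can fragment one strong signal into
adjacent intervals (visible in the worked example); the split/merge
rule resolves adjacency but does not re-join intervals separated by a
full log-drop. Effect estimates at marginally significant loci inherit
winner's-curse inflation; interval estimates (standard errors) for δ
are out of scope.
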