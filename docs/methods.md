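# Methods

This note records the statistical model implemented by `dmscan`, the
assumptions behind it, the defaults and why they were chosen, and what the
simulation-based validation does and does not demonstrate.

## Scoring a single selection

A selection is a time series of sequencing libraries: the input (t₀) and one
or more selected timepoints, which may be uniformly spaced rounds or
variably spaced sampling times.  The variant frequency at timepoint *t* is
f_{v,t} = c_{v,t}/N_t, where N_t is the number of accepted reads.  The
change of a variant relative to the input, divided by the wild-type's
change, cancels the library-size terms and absorbs any multiplicative
distortion shared by all variants (e.g. non-linear drift of the wild-type
frequency).  After adding ½ to every count, the per-timepoint response is

    M_{v,t} = ln((c_{v,t} + ½) / (c_{wt,t} + ½))

The input-timepoint term common to all later timepoints only shifts the
intercept, so M is regressed over *all* timepoints, including the input,
against x = t/max(T); the normalized axis makes slopes comparable between
selections whose schedules differ in magnitude (rounds versus hours).  The
score is the slope; the intercept is fitted but never reported.

Under Poisson sampling of counts, Var(ln c) ≈ 1/c, giving

    V_{v,t} = 1/(c_{v,t} + ½) + 1/(c_{wt,t} + ½)

and regression weights 1/V.  Low-coverage timepoints therefore contribute
less, which is the main defense against sampling error concentrated in a
single badly sequenced timepoint.  The slope standard error is the nominal
WLS variance scaled by the weighted residual mean square s² = Σw e²/(n−2):
a perfect fit yields SE = 0 (in particular the wild-type, whose M series is
identically zero under wild-type normalization, scores exactly 0 ± 0), and
variants that remain non-linear after normalization — which the model fits
poorly — are flagged by large SEs rather than silently mis-scored.

With exactly two timepoints there is no residual degree of freedom, so the
score is the two-point slope L_v (the wild-type-adjusted log ratio) and the
standard error is the closed-form Poisson expression
sqrt(Σ 1/(c + ½)) over the four counts involved.

Scoring assumes constant selection pressure; selections with deliberately
modulated pressure are outside the model.  Variants absent from the input
library are reported unscored (the log-ratio series is anchored at the
input), and a selection is only scored against a wild-type row when one
exists — otherwise the filtered library size (the per-timepoint sum of
counts over variants observed at every timepoint) replaces the wild-type
count inside the same formulas, pseudocount included, for uniformity.  The
natural log is used throughout.

## Combining replicates

Replicate scores β̂ᵢ with standard errors σ̂ᵢ are modeled as
β̂ᵢ ~ N(β, σ²ₛ + σ̂ᵢ²) with a single between-replicate variance component
σ²ₛ per variant, each variant combined independently.  σ̂²ₛ is the REML
estimate computed by a multiplicative Fisher-scoring fixed-point update,
initialized at the unweighted sample variance of the replicate scores,
with β̂ recomputed at each iteration as the precision-weighted average
Σβ̂ᵢwᵢ/Σwᵢ, wᵢ = (σ̂²ₛ+σ̂ᵢ²)⁻¹.  The combined SE is sqrt(1/Σwᵢ), which is
never smaller than the fixed-effect SE sqrt(1/Σσ̂ᵢ⁻²) and reduces to it
exactly when σ̂²ₛ = 0; the fixed-effect combination is provided for
comparison only, because it ignores replicate disagreement and can badly
understate uncertainty.

Iteration count is fixed at 50 for all variants in parallel — vectorizing a
fixed number of sweeps is far cheaper than per-variant convergence tests —
and the final-iteration change ε_s is recorded per variant, with |ε_s| >
1e-6 flagged as non-converged.  Two numerical notes:

* The update is provably convergent to the REML stationary point (the test
  suite verifies agreement with a brute-force 1-D restricted-likelihood
  maximizer to 1e-4 relative when the update is run to convergence).  When
  the REML optimum sits at or near the σ²ₛ = 0 boundary the multiplicative
  update approaches it geometrically and 50 sweeps can leave a small
  positive residue; the restricted likelihood is nearly flat there, the
  absolute error in σ̂²ₛ is small, and the effect on the combined SE is
  minor because σ̂ᵢ² dominates.  Variants with genuine heterogeneity — the
  case the model exists for — converge well within 50 sweeps.
* The update cannot go negative from a nonnegative start, but a clamp at 0
  guards against round-off; degenerate rows whose every replicate has
  SE = 0 (the wild-type under wild-type normalization) are combined exactly
  (mean, sample variance, SE = sqrt(σ̂²ₛ/n)).

A variant must be scored in at least two replicates to be combined; no
shrinkage or information sharing across variants is performed.

## Hypothesis tests and filtering

z = β̂/SE is referred to the standard normal for the two-sided test against
the wild-type null, and z = (β̂_A−β̂_B)/sqrt(SE_A²+SE_B²) for the same
variant under two conditions.  Reported p-values are raw; Benjamini–Hochberg
step-up adjustment is offered as a post-step (via
`scipy.stats.false_discovery_control`).  Degenerate SE = 0 cases give p = 1
when the score is 0 and p = 0 otherwise, and are flagged by an infinite z.
Between-condition tests assume the two score distributions are roughly
comparable; no cross-condition normalization is applied, and the caveat is
deliberate — score distributions shift with selection strength.

Filtering ranks variants by combined SE (ascending) or by input/total read
count (descending) and retains the top fraction, ceil(fraction·n), with
ties broken by variant-label order.  SE-based retention is the recommended
criterion; count-based criteria are included as comparators.

## Variant calling

Calling is alignment-free: reads must match the wild-type sequence in
length and start point and are compared position by position, so indels are
not callable and wrong-length reads are counted in a rejection tally
instead.  Reads are accepted only if every base quality meets the threshold
(default 20, configurable — some assays warrant stricter) and no base is N.
Overlapping paired-end reads are merged base-wise: the higher-quality base
wins and the merged quality is the max of the two; a disagreement at equal
quality becomes an N so that ambiguity flows into the existing N filter
rather than a silent call.  (Whether merged qualities should be max, sum,
or recalibrated is an open choice; max is deliberately conservative.)
Barcode reads are resolved through a many-to-one barcode→variant TSV;
unmapped barcodes are tallied and excluded.  Labels are HGVS-like with
1-based nucleotide positions (`c.5A>G`, joined by commas) and per-codon
protein labels (`p.Ile117Ter`) derived with the standard genetic code; the
wild-type sentinel is `_wt`.  N_t is the number of *accepted* reads, not
raw reads.

## The simulator

The simulator emulates the two dominant assay families at a realistic
scale, with every parameter fixed by the study design it reproduces:
10,000 unique variants (including wild-type); true effects drawn from a
normal distribution with sd 0.1 whose mean places the wild-type effect
(p_wt = 0.5 for the per-round selection probability in binding, μ_wt = 1
for the growth rate) at the 75th percentile, matching where wild-type
typically falls empirically; effects bounded to (0.05, 0.99) for p and
(0.05, 5) for μ, with out-of-bounds draws rejected and redrawn to avoid
point masses at the bounds; a population of 10⁷ with wild-type at 1% and
the remainder log-normal (underlying sd 0.4, location set so the mean
input count is 990), independently generated per replicate; 5 rounds of
selection, 5 replicates, and multinomial sequencing of 200 reads/variant
on average (2·10⁶ reads per timepoint).

Binding rounds draw survivors k ~ Binomial(c′, p_v) and regrow by weighted
resampling with replacement back to 10⁷.  Growth rounds draw the grown
population directly as g ~ NegativeBinomial(r = c′, p = e^(−μΔt)) with
Δt = δ·ln2/μ_wt and δ = 2 wild-type doublings per sampled interval — the
numpy parameterization with mean c′(e^(μΔt) − 1), i.e. the offspring of a
linear birth process over the interval — followed by the same resampling.
(The alternative convention that adds the founders, c′ + NB with mean
c′e^(μΔt), differs only in a near-constant offset and a slightly smaller
between-variant signal; the direct draw is the convention this simulator
uses.)  Extinct lineages stay extinct.

Predicted scores under the regression model are β′ = maxT·ln(p_v/p_wt) for
binding and β″ = mδ(μ_v − μ_wt) for growth.  Because the package regresses
natural-log ratios, the realized growth slope is proportional to
mδ·ln2·(μ_v − μ_wt)/μ_wt; both conventions are emitted
(`predicted_score`, `predicted_slope`) and all validation uses the
scale-invariant r², so the choice of units is immaterial there.

Two noise modes emulate real artifacts.  Replicate-effect noise resamples
the true effect of 10% of non-wild-type variants in exactly one replicate
each (2% of variants per replicate across 5 replicates), modeling cloning
errors and replicate-specific biology.  Jackpot noise multiplies or divides
one uniformly chosen (replicate, timepoint) population count — the input
included — by 50 before sequencing, for 5% of variants each way, modeling
PCR jackpotting; the per-timepoint choice is uniform.  All randomness
derives from a single seed through spawned per-replicate streams, so runs
are bit-reproducible and replicates exchangeable.

What the simulator does *not* emulate: sequencing errors and read-level
artifacts (counts are drawn directly, so variant-calling performance is
exercised separately on constructed reads), ligand-concentration/K_d
mechanics linking binding probability to affinity, epistatic or
time-varying effects, and bottlenecks other than the fixed 10⁷ resampling.
Passing the recovery tests therefore demonstrates that the scoring and
combination machinery recovers known effects under the stated stochastic
selection model — not that real libraries are free of the artifacts the
noise modes only approximate.

## Validation results the tests compute

At the full study scale the combined scores recover the analytic
predictions with r² ≈ 0.995 (binding) and ≈ 0.992 (growth); with
replicate-effect noise, noisy variants' combined SEs correlate with the
magnitude of their effect change (r² ≈ 0.87 binding, ≈ 0.93 growth) and
SE-percentile filtering removes noisy variants at better than the chance
rate at every 5% cutoff.  These quantities are recomputed from scratch by
`scripts/acceptance.py` and asserted by `tests/test_acceptance.py`, which
also verifies the WLS core against statsmodels (≤1e-10 relative on 1,000
random instances), the REML fixed point against a brute-force maximizer,
the two-timepoint closed forms on an enumerated count grid, the structural
inequalities of the meta-analysis (random-effects SE ≥ fixed-effect SE ≥
combined precision bound), and the simulator's conservation laws
(population exactly 10⁷ after every resampling, 2·10⁶ reads per timepoint,
bit-identical seeded reruns).  Full-scale runs are used throughout — one
simulated assay takes on the order of a second — so no scaled-down
surrogate conditions are involved.

## Persistence and orchestration

Primary persistence is TSV (counts with a JSON sidecar carrying the
schedule, read totals, and wild-type label; scores and combined tables with
stable column sets), so every artifact is diffable and round-trips exactly.
An optional HDF5 container mirrors the single-file-store design some
pipelines prefer (install the `hdf5` extra).  The config-driven runner
materializes the experiment → condition → selection → library tree, echoes
its config and writes per-stage tallies to a log, and is deterministic
given identical inputs.  When a run contains exactly two conditions the
between-condition comparison report is produced automatically.
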