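# dmscan

Statistical scoring of deep mutational scanning (DMS) selections.

In a deep mutational scan, a library of thousands of protein variants is
subjected to selection — rounds of phage/yeast display panning, or growth in
culture — and the frequency of every variant is tracked by deep sequencing at
successive timepoints.  `dmscan` turns per-timepoint variant counts into
per-variant **enrichment scores with standard errors**, so that noisy variants
can be filtered and hypotheses tested, rather than relying on ad hoc
read-count cutoffs.

## The model

For variant *v* at timepoint *t*, with counts *c*<sub>*v*,*t*</sub> and
wild-type counts *c*<sub>*wt*,*t*</sub>, the wild-type–normalized log ratio is

> *M*<sub>*v*,*t*</sub> = ln[(*c*<sub>*v*,*t*</sub> + ½)/(*c*<sub>*wt*,*t*</sub> + ½)]

with approximate Poisson variance

> *V*<sub>*v*,*t*</sub> = 1/(*c*<sub>*v*,*t*</sub> + ½) + 1/(*c*<sub>*wt*,*t*</sub> + ½).

The **score** β̂<sub>*v*</sub> is the slope of the weighted least-squares
regression of *M*<sub>*v*,*t*</sub> on *t*/max(*T*), with weights
*V*<sub>*v*,*t*</sub><sup>−1</sup> so that low-coverage timepoints are
downweighted; its standard error uses the weighted residual mean square.
With only two timepoints the score is the log-ratio difference *L*<sub>*v*</sub>
with a closed-form Poisson standard error.  Libraries without a wild-type
sequence are normalized by the filtered library size instead.

Replicate selections are combined per variant with a one-random-effect
meta-analysis model: the between-replicate variance σ̂²<sub>*s*</sub> is
estimated by REML (Fisher-scoring fixed-point iterations), and the combined
standard error √[1/Σ(σ̂²<sub>*s*</sub> + σ̂²<sub>*i*</sub>)<sup>−1</sup>]
captures both sampling error and replicate disagreement.  Raw two-sided
*z*-test p-values compare each variant to wild-type or the same variant
between conditions; Benjamini–Hochberg adjustment is available.

A selection **simulator** with known true effects (binomial binding rounds,
negative-binomial growth, multinomial sequencing, replicate-effect and
jackpot noise) is included for end-to-end validation and power exploration.

## Worked example

Simulate a binding-style selection (10,000 variants, 5 rounds, 5 replicates,
200 reads/variant), score it, and combine replicates:

```python
import dmscan
from scipy import stats

config = dmscan.SimulationConfig(assay="binding", seed=7)
dataset = dmscan.simulate_dataset(config)
frames = [dmscan.score_selection(t) for t in dataset.tables]
combined = dmscan.combine_replicates(frames)
print(combined[["score", "SE", "sigma_s2", "p_raw"]].head(6).round(4))

joined = combined.join(dataset.truth.effects).dropna(subset=["score"])
r = stats.pearsonr(joined["score"], joined["predicted_score"]).statistic
print(f"\nrecovery of predicted scores: r^2 = {r**2:.4f} over {len(joined)} variants")
```

This prints:

```
        score      SE  sigma_s2  p_raw
_wt    0.0000  0.0000    0.0000    1.0
v0001 -1.5661  0.0726    0.0000    0.0
v0002  0.7862  0.0355    0.0031    0.0
v0003 -1.4010  0.1169    0.0551    0.0
v0004  1.2618  0.0427    0.0044    0.0
v0005  0.3291  0.0328    0.0019    0.0

recovery of predicted scores: r^2 = 0.9950 over 10000 variants
```

`score` is the regression slope (0 = behaves like wild-type; positive =
enriched relative to wild-type), `SE` its combined standard error across the
five replicates, `sigma_s2` the between-replicate variance, and `p_raw` the
raw z-test p-value against the wild-type null.  The measured scores recover
the analytic predicted scores, max *T* · ln(*p*<sub>*v*</sub>/*p*<sub>*wt*</sub>),
with r² ≈ 0.995.

The same stages are available from the shell:

```sh
dmscan simulate --assay binding --seed 7 --out sim/
dmscan score --counts sim/rep1_counts.tsv --out rep1_scores.tsv
dmscan combine rep*_scores.tsv --out combined.tsv
dmscan test --combined combined.tsv --out tests.tsv
dmscan run --config experiment.json --out results/   # full config-driven run
```

FASTQ inputs (single-end, overlapping paired-end, or barcoded reads plus a
barcode→variant map) are quality-filtered and counted with `dmscan count`;
`dmscan plot` renders a sequence-function map (amino acid × position heatmap
with standard errors drawn as scaled cell diagonals).

## Layout

- `dmscan.refseq` — reads, quality filtering, alignment-free variant calling,
  barcode maps
- `dmscan.counting` — variant × timepoint count tables, frequencies,
  filtered library size, replicate alignment
- `dmscan.scoring` — log ratios, Poisson weights, WLS and ratio scoring
- `dmscan.replicates` — random-effects and fixed-effect combination
- `dmscan.analysis` — SE/count filtering, z-tests, BH adjustment
- `dmscan.simulate` — binding/growth selection simulator with ground truth
- `dmscan.pipeline`, `dmscan.plots`, `dmscan.cli` — orchestration, figures,
  command line

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
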