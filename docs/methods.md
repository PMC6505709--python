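# Methods

## The screen

Input is a genes × samples matrix `T` of log-scale expression with each
sample assigned to one of four stages: control, incipient, moderate,
severe. The screen proceeds in five steps.

1. **Column centering.** For each stage block, `S(i, j) = T(i, j) −
   mean_i T(i, j)`. Samples are profiled on different arrays under different
   conditions, so raw columns are not comparable; subtracting each column's
   across-gene mean removes any per-sample additive offset exactly. Each
   centered column sums to zero (to machine precision).
2. **Overall deviation.** `D_t(i) = (1/n_t) Σ_j S(i, j)` over the `n_t`
   samples of stage `t` — averaging damps sample-level noise by `1/√n_t`.
3. **Signed amplitudes.** `A_t(i) = D_t(i) − D_ctrl(i)` for the three
   disease stages: how far the gene's stage-average deviation has moved from
   its control value. Any per-gene baseline cancels here, so amplitudes
   reflect stage response only.
4. **Absolute amplitudes.** `A′_t(i) = |A_t(i)|`.
5. **Selection.** Per disease stage, `σ_t` and `σ*_t` are the standard
   deviations across genes of the signed and absolute amplitudes
   (`σ = sqrt(E[x²] − E[x]²)`, population convention). The **strict rule**
   calls gene `i` iff `|A_t(i) − Ā_t| > 3σ_t` for all three disease stages
   *and* `D` is strictly monotone across control → incipient → moderate →
   severe (direction = trend sign). The **relaxed rule** calls gene `i` iff
   `A′_t(i) > 3σ*_t` for all three stages and `D` is strictly increasing
   (criterion 1, "up") or strictly decreasing (criterion 2, "down").

On data whose signed amplitudes are roughly symmetric about zero,
`σ* = sqrt(E[A²] − E[|A|]²) ≤ sqrt(E[A²]) ≈ σ`, so the relaxed cutoff is
lower and the relaxed rule's calls form a superset of the strict rule's in
practice; the two lists are nevertheless always reported separately.

The screen is a *gate*, not a trend test: a gene must clear the amplitude
cutoff in every disease stage before the monotonicity condition is even
consulted. Sub-threshold monotone trends are deliberately not called.

## Design choices

- **Absolute-value amplitudes for the relaxed rule.** The relaxed rule's
  motivation — a folded amplitude has positive mean, hence smaller variance
  and a lower 3σ cutoff — only holds when the amplitude is taken as a
  magnitude, so `A′ = |A|` is the default. A `signed` option runs the
  literal alternative (threshold compared against the signed amplitude),
  under which down-trending genes can never pass; it exists for sensitivity
  analysis only.
- **Strict inequalities for monotonicity.** Ties fail the criterion. Exact
  ties are measure-zero on continuous data; strictness is the conservative
  reading.
- **Population variance by default.** `σ` is computed with the raw moment
  identity (divide by N). With thousands of genes the distinction from the
  N−1 convention is negligible; a config flag exposes the sample convention
  for sensitivity analysis.
- **Per-stage thresholds.** `σ_t` is estimated separately for each disease
  stage, since the amplitude spread grows with severity; a single pooled
  threshold would over-call the severe stage and under-call the incipient.
- **Mean-centering in the strict rule.** The signed-amplitude mean `Ā_t` is
  subtracted before comparing against the cutoff. It is typically ≈ 0, but
  subtracting it always keeps the rule correct on shifted data.
- **Probe sets are never deduplicated** by gene symbol: two probe sets for
  the same gene are two analysis units.
- **Missing values are rejected** by default; an opt-in flag drops genes
  with any missing entry (and logs the count) rather than imputing, because
  imputation would distort the σ estimates the cutoffs depend on.
- **Sample-ID normalisation.** Internal whitespace is stripped from sample
  identifiers before matching matrix columns against the stage map, so
  printed forms like "GSM 21215" and the file form "GSM21215" agree.
- **Input is assumed log-transformed.** A `log2` option applies
  `log2(x + 1)` for raw-intensity inputs. No other normalisation is applied.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| multiplier | 3.0 | cutoff in units of σ; 3 captures ~99.7% of normal data |
| variance | population | divide by N (`sample`: N−1) in σ |
| relaxed_amplitude | absolute | amplitude definition for the relaxed rule |
| n_bins (diagnostics) | 60 | histogram granularity for amplitude summaries |

All are surfaced both in `ADAConfig` and as CLI flags.

## Diagnostics

The 3σ cutoff is only as meaningful as the amplitude distribution is
normal. `summarize_amplitudes` reports, per stage and per definition, the
population moments (mean, variance, skewness, excess kurtosis), a 60-bin
histogram, and the observed fraction of genes within 3σ of the mean.
Normality is judged descriptively; an optional D'Agostino omnibus test adds
a p-value. On symmetric signed amplitudes the absolute definition is
right-skewed with positive mean and smaller variance — visible directly in
these summaries.

## The synthetic generator

`SyntheticDesign`/`generate` emulate a four-stage bulk microarray study on
the log scale:

    value(i, j) = baseline_i + stage_shift(i, stage_j) + offset_j + noise_ij

- `samples_per_stage` defaults to (9, 7, 8, 7) — the layout of a small
  brain-tissue cohort with a control group and three severity groups.
- `baseline_mean_range` defaults to [5, 12] log2 units, the span typical of
  log-transformed array intensities.
- `noise_sd` defaults to 0.5 log2 units, a realistic residual scale for
  probe-level array noise; a standardized Student-t option (df
  configurable, variance matched to `noise_sd`) stresses the 3σ rule's
  robustness to heavy tails.
- `sample_offset_sd` (default 0.5) draws one additive constant per sample —
  the array/batch effect that column centering must remove.
- Planted genes: `n_up`/`n_down` (default 10 + 10 of 1,000) receive stage
  shifts `effect_profile` (default (4, 5, 6) log2 units, i.e. 8–12× the
  noise sd), positive and increasing for "up" genes, negated for "down";
  null genes have stage-invariant means. The truth table records each
  gene's status.

What the generator does *not* emulate: probe-level Affymetrix noise
structure, intensity-dependent variance, correlated gene modules, or batch
structure beyond per-sample offsets. Passing recovery tests therefore show
the algorithm's behaviour under its own model assumptions (additive
offsets, i.i.d. noise, clean monotone plants), not performance on real
arrays, where amplitude distributions are heavier-tailed and effects
smaller.

## Numerical notes

- Centering and averaging are vectorized pandas/numpy reductions; the test
  suite pins them against a scalar-loop reimplementation at 1e-12 on small
  matrices, and candidate calls match exactly.
- TSV round trips are bit-exact: floats are written in shortest
  round-tripping form and parsed with correctly rounded conversion (the
  fast pandas parser can be off by one ulp and is avoided).
- A constant amplitude vector has σ = 0; the strict comparison `> 0` then
  calls nothing, and the diagnostics report a single occupied histogram bin
  with 3σ-fraction 1.
- Degenerate inputs are rejected with named errors: stages with fewer than
  two samples, missing stages, duplicate gene or sample IDs, non-numeric
  cells (with row/column coordinates), non-finite values.

## Problem sizes

The packaged experiments use 1,000-gene studies with the (9, 7, 8, 7)
layout: 20 seeds for the null false-call and recovery experiments, one
seed for the worked example. These sizes put the amplitude-σ estimates well
into their asymptotic regime while keeping the full suite and the
reproduction script at a few seconds each; results are insensitive to
raising the gene count.

## Known limitations

- No multiple-testing control: the 3σ conjunction across three stages plus
  strict monotonicity keeps the null call rate low empirically (< 0.1% in
  the packaged null experiments), but no formal error rate is guaranteed.
- σ is estimated on the mixture of null and affected genes; very large or
  very numerous effects inflate it and raise the cutoff (mildly visible in
  the worked example, where planted genes lift σ above its null value).
- The monotonicity test is exact and unordered ties fail it; on data with
  heavy rounding this is stricter than a rank-trend test would be.
- The relaxed rule's superset property over the strict rule is empirical
  (it requires σ* ≤ σ and Ā ≈ 0), not a theorem for arbitrary data.
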