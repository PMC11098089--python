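# Methods

## The model

`tcrdyn` models the fate of template-strand DNA lesions in the interval
between a mutagenic burst and DNA replication. RNA polymerases (RNAP II)
initiate sequentially at a gene's promoter and travel 5'→3'. A fraction
`Pv` of lesions is visible to transcription-coupled repair (TCR); invisible
lesions never interact with the polymerase at all. On reaching a visible,
unrepaired lesion an RNAP

- bypasses it with probability `1 − Pd`,
- repairs it and resumes transcription with probability `Pd·Pr`,
- repairs it and dissociates with probability `Pd·(1 − Pr)`, ending the
  pass and leaving all downstream lesions untouched.

The number of initiations for a gene with nascent expression `e` (nTPM)
under multiplier `m` is the mean-preserving two-point mixture of
`floor(m·e)` and `floor(m·e)+1` with weights `c = 1 − (m·e − floor(m·e))`
and `1 − c`. Under mild assumptions (stable expression, unbiased transcript
sampling) `m` is also the genome-wide number of transcription initiations in
millions, which is what makes census-based plausibility bounds for it
meaningful (`m_bounds_from_census`).

### Analytic expectation

For a focal visible lesion at position `λ` (expected upstream lesions), the
number of visible upstream lesions is Poisson with mean `Pv·λ`, and each
pass acts on the state *(upstream lesions remaining, focal alive)* as a
Markov kernel: the pass reaches the focal site only if no upstream
repair-without-restart occurs, and every upstream repair (with or without
restart) erodes the shield by one. `survival_probability(n, k, pd, pr)`
iterates this kernel exactly; `expected_obs_exp` averages it over the
Poisson shield, truncated when the residual tail mass drops below 1e-9
(raising the tolerance tenfold moves no surface cell by more than 1e-6).
Two exact identities anchor the implementation: survival equals
`(1−Pd)^n` when `k = 0` or `Pr = 1`, and the surface is identically 1 when
`Pd`, `Pv`, `m`, or a stratum's expression is zero (these cases are
short-circuited so they hold to the last bit). Everything else is verified
against brute-force Monte-Carlo and against the forward simulator at 10⁶
genes (cell-wise agreement within three standard errors).

The observed:expected surface evaluates the expectation on 6 expression
strata × 40 position bins of width 0.1 expected lesions. Strata use the
measured mouse-liver values as constants: medians
(0, 0.49, 1.16, 2.07, 3.14, 11.15) nTPM, gene counts
(4649, 1001, 1001, 1001, 1002, 7176), boundaries 0.287 / 3.73 nTPM. Bins are
evaluated at their λ midpoint; a five-point within-bin average is available
(`bin_eval="average5"`) and differs from the midpoint by < 3e-6 at typical
parameters, so the midpoint is the default.

## Simulator

`tcrdyn.simulate` draws cohorts of abstract genes: log-normal lengths
(median 60 kb, log-sd 1.0 — a parametric stand-in for the real annotation's
length list, which can be supplied as a file), strata sampled from the
configured proportions, Poisson lesion counts at 13e-6 per bp, uniform
positions, Bernoulli visibility, and the floor/floor+1 RNAP assignment drawn
Bernoulli per gene. The per-pass semantics are the model's, executed in a
numba kernel (bit-reproducible for a fixed seed and gene order; the
single-gene reference implementation in pure Python is tested against it).

Aggregation maps a surviving lesion at `x` bp to `λ = ρ·x` and bin
`floor(λ/0.1)`. A gene contributes repair-free expectation `0.1 × (number
of genes whose expected-lesion length covers the bin)` — and, for
consistency, its surviving lesions are only counted in bins it fully
covers. This "covered" rule keeps observed and expected commensurate, so
the no-repair ratio is exactly centred on 1; a pro-rated alternative
(partial bin coverage credited on both sides) is available via
`expected_rule="prorated"`. Lesions beyond λ = 4 are dropped from the
surface but not from the repair dynamics.

## Inference

The objective is the Manhattan (L1) distance between 6×40 surfaces over
unmasked cells. A grid search (probabilities step 0.01, `m` in [0.25, 10]
step 0.25; coarse mode 0.05/0.5; bootstrap mode 0.1/1.0) supplies the start
for bounded Nelder–Mead refinement (SciPy, clip-at-bounds, `fatol = xatol =
1e-6`, ≤ 2000 evaluations; the refined distance never exceeds the start's).
Grid ties break by lexicographic scan order (pd, pr, pv, m) — flat regions
are real, e.g. any zero-repair parameter set fits an all-ones surface
exactly. The grid evaluation factorizes: per (pd, pr) the survival stack is
computed once and contracted against precomputed Poisson weight matrices
for every (pv, m), which is what makes dense grids tractable on one CPU.

Bootstrap CIs resample genes (not surface cells) with replacement, rebuild
the surface per replicate from gene-level records, and refit each replicate
from a materialized coarse grid plus refinement; CIs are the 0.025/0.975
quantiles of the replicate estimates. Model comparison assumes Gaussian
cell errors with common variance `v`; the MLE of `v` is the mean squared
residual, so likelihood maximization reduces to least squares, and AIC uses
k = 5 (full) vs k = 4 (no restart, `Pr = 0`). Because the no-restart model
is nested, its optimum seeds a restart of the full-model refinement whenever
it wins, guaranteeing the nesting inequality numerically. The plausibility
map profiles the distance over (pv, m) per (pd, pr) cell and shades it by
the fraction of bootstrap distances at least as large.

`estimate_m_orthogonal` implements the independent check on `m`: per-gene
transcript production `n = rate × active_fraction × minutes` regressed as
`log10 n = log10 e + log10 m`, i.e. `m = 10^mean(log10 n − log10 e)`.

## Mutation pipeline

Coordinates are 0-based half-open throughout. Lesion-strand phasing uses
the asymmetry score `S = (F − R)/(F + R)` of mutations-from-T rates per
tumor per segment (whole chromosomes by default, matching the scale of
lesion segregation); `|S| > 0.33` calls the strand, and gene orientation
then labels lesions template (RP/FM) or nontemplate (FP/RM). Trinucleotide
rates follow the 192-category convention on the lesion strand (mutation
calls and composition reverse-complemented for reverse-strand lesions;
autosomes diploid, X haploid), and `aggregate_rate` is the
composition-weighted mean over the 64 context sums.

Genic position is normalized per tumor to expected upstream lesions: the
context composition between the TSS and the window start (5 kb windows, in
transcription direction) contracted against the tumor's per-context rates.
Those rates are estimated from phaseable intergenic sequence by default
(nontemplate gene bodies optionally); because desk-scale cohorts yield few
intergenic mutations per tumor, the context spectrum is pooled across
tumors and rescaled to each tumor's own burden (`per_tumor_contexts=True`
restores fully per-tumor rates). A fixed 64-vector can be supplied instead
for controlled comparisons — with it, the binning and opportunity structure
of the surface are exactly invariant to the miscoding probability of the
synthetic generator.

Surface cells accumulate composition-weighted mutation counts and
opportunities (a ratio of weighted sums rather than a weighted mean of
per-context ratios; the two coincide when context rates are homogeneous,
and the ratio form is what makes gene-level bootstrap resampling cheap and
exact). Cells with zero nontemplate signal are masked, never zero-filled;
every excluded mutation (unphased segment, intergenic, beyond the λ grid)
is counted in a QC report and the partition provably sums to the input.

## Synthetic cohorts

The generator emulates exactly the data features the pipeline consumes:
random-sequence chromosomes (4 × 5 Mb by default), non-overlapping genes on
both strands with log-normal lengths capped at 320 kb (≈ λ = 4), nascent
expression drawn per stratum so that proportions match the configured
values and the intermediate-stratum medians land near (0.49, 1.16, 2.07,
3.14) nTPM (stratum labels are recomputed through the pipeline's own
stratification, so the annotation round-trips exactly). Each tumor picks a
lesion strand per chromosome (whole-chromosome segregation; a segmental
mode exists for phasing stress tests), places lesions on T bases of that
strand at 52e-6 per T (≈ 13e-6 per bp at uniform composition), runs
template-orientation lesions through the repair kernel with per-gene
`n = m·e` initiations, and miscodes survivors into mutations with
probability `mu` and a fixed T→C/T→A/T→G spectrum (0.8/0.1/0.1 — a
placeholder; no measured spectrum decomposition exists to copy, and the
template/nontemplate ratio is insensitive to it). The default `mu = 1`
keeps the mutation-derived λ normalization on the same scale as the lesion
process, mirroring how the real analysis equates mutation and lesion
burdens; miscoding draws use a dedicated RNG stream so the lesion/repair
history at a fixed seed is invariant to `mu`.

What the generator does *not* emulate: subclonality and VAF structure,
replication timing, selection, context-dependent damage preferences beyond
the T restriction, indels/SVs, or sequencing noise. Passing tests therefore
demonstrate internal consistency of model, simulator, pipeline and
inference — not robustness to those real-data complications.

## Problem sizes and numerical choices

The test suite runs the oracle equivalence at 10⁶ genes per parameter set,
the scaled recovery experiment at 30 datasets × 10⁵ genes (coarse grid +
refinement, Pv fixed at 0.8, truths drawn uniformly from Pd ∈ [0.1, 0.9],
Pr ∈ [0.1, 1], m ∈ [0.5, 8.5] — the lower Pr bound keeps percent errors
well-defined), and the end-to-end loop at 10 experiments × 237 tumors ×
20 Mb with 50 bootstrap replicates each. The acceptance script runs the
recovery experiment at the full 1.94-million-gene scale per dataset, which
the vectorized kernel completes in minutes on one CPU. Agreement tests use
a Poisson-based standard error `sqrt(max(observed, 1))/expected`, which is
conservative (stochastically larger than the exact binomial-style error) at
the relevant counts.

## Known limitations

- `Pr` is weakly identified whenever multi-lesion genes are rare (small
  `m·e` or short genes); its bootstrap intervals are honest about this.
- The ratio estimator in surface cells carries a small positive bias at low
  counts (Jensen's inequality); it shrinks as 1/count and is negligible at
  the 237-tumor scale but visible in tiny fixtures.
- Detection is assumed independent per encounter; a lesion-specific random
  detection effect would be indistinguishable in these data and is not
  modeled.
- The within-stratum spread of per-gene expression (present in real and
  synthetic data) is summarized by the stratum median in the theory
  surface; this is a deliberate approximation shared with the original
  analysis.
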