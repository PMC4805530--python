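# Methods

`l1audit` is a reanalysis toolkit for auditing somatic LINE-1 (L1)
retrotransposition call sets produced from single-cell sequencing. Its
premise: in a single cell, a true somatic insertion is molecularly a
heterozygous variant, so germline *known non-reference* (KNR) L1 insertions
— population-polymorphic insertions absent from the reference genome but
catalogued by prior, independent profiling studies — provide a gold
standard for what true insertion signal looks like in the same experiment.
Candidate somatic calls whose read-count and junction signal deviates
grossly from that standard are, overwhelmingly, amplification or library
chimera artifacts.

## Gold-standard selection

Three method-specific rules define per-individual gold sets, with every
inequality inclusive:

* **RC-seq**: detected with ≥ 40 reads in *both* bulk samples of the
  individual, and reported by a prior independent (non RC-seq) study.
  Calls known only from prior RC-seq work are excluded by default
  (independent-method preference) but can be included via a flag.
* **WGS**: in both bulk samples, ≥ 2 read-anchored-mate reads on each side
  of the breakpoint; ≥ 4 clipped reads; target-site duplication or deletion
  ≤ 50 bp without a poly-A tail or ≤ 250 bp with one; at least half of the
  clipped reads within ± 2 bp of the breakpoint; a prior-study annotation.
* **L1-IP**: confidence score ≥ 0.5 in at least half of the individual's
  bulk samples (ceiling for odd counts), plus a prior-study annotation.

An individual with other than two bulk samples is an error for the RC-seq
rule rather than a silently degraded selection. Selection is a pure
function of the input tables, and the per-locus selection log names the
failed criterion for every exclusion.

## Read-count signal model

Histograms count **per-sample calls**: a KNR insertion detected in three
cells contributes three observations, and dropouts (gold locus absent from
a cell) contribute nothing, because allelic dropout affects germline and
somatic insertions alike.

The single-cell KNR count distribution is bimodal — amplification
non-uniformity at the length scale of retrotransposons pushes roughly two
thirds of calls into a low mode at 1–2 reads, with the rest in an
overdispersed high mode. The model is a two-component zero-truncated
mixture:

* low component: zero-truncated geometric (success probability `p`);
* high component: zero-truncated negative binomial (mean `μ`, shape `r`).

The families are this package's choice; only "finite mixture" bimodality is
inherited from the problem. Fitting is EM on the count histogram with
deterministic initialization (moment split at a count of 3), geometric
M-step in closed form, negative-binomial M-step by Nelder–Mead on the
expected complete-data log-likelihood, and convergence when the relative
log-likelihood change falls below 1e-8 (cap 500 iterations). The
log-likelihood trace is retained and is non-decreasing.

Because a geometric plus a flexible negative binomial can imitate a single
geometric, the fitted mixture is compared by BIC against single-component
zero-truncated geometric and negative-binomial fits; when a single
component wins, the fit collapses to the boundary weight and is flagged.
This keeps the weight estimate identifiable on unimodal data.

**True-candidate fraction.** Somatic candidates are modeled as a mixture of
an artifact component and the *frozen* high component of the gold KNR fit;
EM over the weight and the free artifact component recovers the fraction of
candidates carrying true-insertion signal. The free component is
constrained to the 1–2-read artifact regime (geometric `p ≥ 0.5`) so it
cannot absorb the body of the frozen signal component. A percentile
bootstrap over calls gives the confidence interval.

## Threshold calibration

For each candidate threshold `min_reads` (a threshold printed as "> 2
reads" is stored as `min_reads = 3`), the calibration tabulates: the
retained fraction of gold KNR calls (call sensitivity), the mean per-cell
fraction of the individual's gold loci detected at or above the threshold
(per-cell sensitivity), and the retained fraction of somatic candidate
calls (essentially all false positives). Both retention columns are
non-increasing by construction.

The operating threshold is picked by diminishing returns: a step to the
next threshold is taken while it removes at least a fraction `knee`
(default 0.5) of the remaining false positives *and* removes proportionally
more false positives than the relative sensitivity it costs. Relative
(not percentage-point) reductions are used: the per-step false-positive
counts above a workable threshold are small, and the proportional framing
is scale-free. A table with no false positives keeps `min_reads = 1`. The
knee statistic is a ratio of small counts near the operating point (about
twenty retained candidate calls at ≥ 3 reads even at the 170-cell cohort
scale), so on simulated cohorts the choice occasionally lands one step
higher; the rate estimate is insensitive to that (see below).

## Corrected rate estimation

Per cell: sensitivity = fraction of the individual's gold loci detected in
that cell at or above the threshold; the cell's candidate count above the
threshold, minus candidates a chimera review excluded, is divided by that
sensitivity. Cells with zero surviving candidates contribute a rate of 0
without any division; cells with an empty gold set or zero measured
sensitivity are uncorrectable and skipped. Group summaries are means ± SD
over all estimated cells of the group plus the percentage of candidate-free
cells; groups are compared by classic one-way ANOVA (Kruskal–Wallis is
available as the nonparametric alternative). Reported rates are rounded
half-up to two decimals at the reporting layer only.

The chimera adjustment for cohort-level rates is
`pre_rate × (1 − n_chimeras/n_candidates)` — linear in the rate and
monotone in the chimera count. The stability of the adjusted rate across
thresholds of ≥ 3 reads is what justifies the threshold choice.

**Junction statistics** support three denominators: per call (each
(sample, locus) detection separate), per candidate restricted to
single-cell candidates, and per candidate with junction evidence merged
across cells (5' in one cell plus 3' in another counts as both).

## Chimera rule engine

Candidate contigs are screened against structural hallmarks of genuine
retrotransposition. Definite rules (verdict *chimera*): source element from
an inactive subfamily (R1, activity from a shipped L1Hs/L1PA lookup); 3'
junction without a poly-A tail (R2); 5' and 3' junctions tracing to
distinct source elements (R3). A junction arising inside an L1 body or a
poly-A tract (R4) is *indeterminate* — such breakpoints cannot be rejected
by sequence analysis alone. A TSD above 50 bp (configurable) is a flag that
annotates but never decides a verdict. *Consistent with a true insertion*
requires a poly-A tail, TSD within bound, an active-subfamily single
source; anything else undecided is indeterminate.

## Synthetic cohorts

The generator instantiates the statistical structure the audit assumes, so
every stage is testable without external data. Defaults are calibrated once
to the distribution shape of the audited study type:

| parameter | default | rationale |
|---|---|---|
| individuals × cells | 3 × 57 (171 cells) | cohort scale of the audited study (170 cells) |
| KNR per individual | 120 | order of per-individual gold sets |
| KNR dropout | 0.55 | per-cell detection 45% at ≥ 1 read |
| mixture weights | 2/3 low, 1/3 high | bimodal KNR call split |
| low mode | geometric, mean 2.22 | ~32% of calls at 1 read |
| high mode | ZT-NB μ=55, r=1.5 | ~53% of calls at ≥ 3 reads |
| somatic rate | 0.2 /cell | ~0.19 corrected estimate |
| chimeras | 28 /cell | ~4760 candidates over 170 cells |
| chimera counts | P(1)=0.974, P(2)=0.0235, tail decay 7/12 | 97% at 1 read, 99.6% ≤ 2, 12 vs 7 chimeras at ≥3/≥4 reads |
| both-junction prob | 0.11 true / 0.0004 chimera | junction detection gap |

True somatic insertions are Poisson per cell and are detected with the same
dropout and count law as KNR insertions — the core identifiability
assumption of the audit. Bulk samples carry every germline KNR insertion at
high counts (ZT-NB mean 300, shape 5).

All randomness flows from one global seed through named substreams
(`knr`, `somatic`, `chimera`, `coverage`, `contigs`) so adding a stream
never perturbs another and identical config+seed is byte-identical.

**Coverage tracks.** `flat` is Poisson counting noise around a constant
depth. `mda_like` multiplies depth by a smooth log-field of random
low-frequency sinusoids (periods 50–500 kb) — long-range waviness.
`malbac_like` applies a quasi-periodic ~1 kb peak/trough factor (slow phase
drift) plus per-cell multiplicative white noise. The systematic component
is drawn from a separate `systematic_seed` so simulated cells can share
peak/trough positions while their stochastic noise differs; pooling such
cells cancels white power ≈ 1/K and preserves the periodic peaks.

What the generator does **not** emulate: real sequence content, mappability
and GC structure, locus-specific capture efficiency, correlated dropout
along chromosomes, or inter-individual KNR sharing. Passing tests therefore
demonstrate estimator correctness under the stated model, not performance
on any particular real data set.

## Coverage QC

Equal-read bins are computed on a designated reference sample (per contig,
cut at source-bin edges so each bin holds equal reference reads, expected
span ~500 kb) and then frozen for all compared samples. Log2 ratios use a
pseudocount of one read-equivalent per bin, are depth-normalized, and are
centered to the autosomal median; optional corrections re-center chrX to
the sample's own chrX median (mismatched-sex reference) and set chrY bins
to zero. MAPD is the median |difference| over genomically adjacent
same-contig bin pairs; MDAD the median absolute deviation from the median;
both are shift-invariant. The Lorenz curve sorts bins by depth and the Gini
is one minus twice the trapezoid area; Gini is invariant to uniform depth
rescaling. The PSD is a Welch periodogram (Hann window, 50% overlap,
segment length 2^14 bins by default, mean-detrended per segment) in cycles
per bp; integrated power matches the track variance within 1% (Parseval).
Subsampling is per-bin binomial thinning.

## Detection theory

Closed forms: expected variant reads `(k/n)·D/2`; threshold `T = z·e·D`;
combining gives the depth-independent bound `k/n ≥ 2·z·e` on detectable
mosaicism in bulk sequencing. Variance terms are deliberately omitted from
the closed forms; a binomial Monte-Carlo verifier supplies sampling
variability and shows the detection probability crossing 50% at the bound.
The Hardy–Weinberg carrier heterozygosity `2pq/(p² + 2pq)` quantifies why
most KNR insertions are single-copy, and `single_copy_fraction` is the
companion genotype-count arithmetic.

## Problem sizes and numerical choices

The test suite exercises: cohorts of 171 cells (defaults) and 200 cells
(estimator-recovery runs over 20 seeds per true rate in {0, 0.1, 0.2,
0.5}); mixture fits at n = 4000 over 20 seeds per weight in {0.25, 1/3,
0.5}; 100-seed pure-chimera candidate sets of 4000 calls; 1000-instance
brute-force oracle sweeps for the metrics and selectors; and multi-megabase
coverage tracks at 250–500 bp bins. Ties in rounding use half-up;
thresholds are stored inclusively (`min_reads`); EM tolerance 1e-8;
bootstrap default 200 resamples.

## Known limitations

* The knee policy formalizes a diminishing-returns argument that has no
  canonical objective; the knee ratio is exposed in configuration.
* The true-fraction estimator assumes the gold high component transfers to
  somatic candidates unchanged; capture-efficiency differences between
  loci would violate this.
* The rule engine consumes upstream annotations (subfamily activity,
  poly-A, TSD, source tracing) and cannot rescue mis-annotated contigs;
  R4-class junctions are undecidable by design without full-length
  validation.
* Equal-read bin boundaries are quantized to source-bin edges; with coarse
  source bins the realized bin sizes are correspondingly coarse.
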