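# l1audit

Auditing somatic LINE-1 (L1) retrotransposition call sets from single-cell
sequencing.

Single-cell whole-genome amplification (MDA, MALBAC) creates chimeric DNA
molecules that join unrelated fragments; at an L1 junction such a chimera is
indistinguishable, at a glance, from a genuine retrotransposition event.
Call sets built without a read-count signal model can therefore contain
thousands of artifact "insertions" at 1–2 supporting reads. `l1audit`
implements the audit pipeline that separates signal from artifact:

* **Gold standards** — per-individual sets of germline known non-reference
  (KNR) L1 insertions, selected by method-specific rules (RC-seq ≥ 40 reads
  in both bulks + prior independent study; WGS RAM/clipped-read/TSD
  clauses; L1-IP score ≥ 0.5 in half the bulks). In a single cell a somatic
  insertion is molecularly a heterozygous variant, so KNR insertions define
  the expected true-insertion signal.
* **Read-count signal model** — per-sample count histograms; EM fit of a
  two-component zero-truncated mixture (geometric low mode from
  amplification dropout + negative-binomial high mode), `w_lo·Geom(p) +
  w_hi·NB(μ, r)`; estimation of the true-insertion fraction among somatic
  candidates with the high component frozen to the gold fit.
* **Threshold calibration** — sensitivity vs false-positive retention per
  read-count threshold and a diminishing-returns knee policy that picks the
  operating threshold.
* **Corrected rates** — per-cell sensitivity measured on the individual's
  gold loci, chimera exclusion, division by sensitivity
  (`rate = (n_candidates − n_chimeras)/sensitivity`), group means and
  one-way ANOVA, and the cohort-level chimera adjustment
  `rate × (1 − n_chimeras/n_candidates)`.
* **Chimera rule engine** — explicit rules for inactive source subfamilies,
  missing poly-A tails, split 5'/3' sources, unresolvable in-L1 junctions,
  and oversized target-site duplications.
* **Amplification uniformity QC** — equal-read ~500 kb bins, reference-
  normalized log2 ratios with sex-chromosome corrections, MAPD/MDAD,
  Lorenz/Gini, Welch power spectral density of binned depth, subsampling.
* **Detection theory** — closed forms `(k/n)·D/2`, `T = z·e·D`, the
  depth-independent bound `k/n ≥ 2·z·e`, a Monte-Carlo verifier, and the
  Hardy–Weinberg carrier heterozygosity `2pq/(p² + 2pq)`.
* **Synthetic cohorts** — a first-class generator of call tables, coverage
  tracks, and annotated contigs with ground-truth labels, calibrated to the
  statistical structure the audit assumes, so the whole pipeline runs with
  no external data.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a 171-cell cohort, calibrate the gold standard and threshold, and
estimate corrected somatic insertion rates:

```python
import numpy as np
from l1audit import synthetic, gold_standard, readcount_model, rate_estimation

cfg = synthetic.SimulationConfig(seed=1)
calls, samples, truth = synthetic.simulate_call_tables(cfg)

sets = gold_standard.select_rcseq_gold(calls)
hist = readcount_model.per_sample_histogram(calls, sets, "knr_single_cell")
fit = readcount_model.fit_two_component_mixture(hist)
table = readcount_model.threshold_table(calls, samples, sets)
t = readcount_model.choose_threshold(table)

som = readcount_model.per_sample_histogram(calls, None, "somatic_single_cell")
tf = readcount_model.estimate_true_fraction(som, fit, n_boot=200, seed=1)

chimeras = set(truth.labels.index[truth.labels == "chimera"])
ests = rate_estimation.cohort_rates(calls, samples, sets, chimeras, min_reads=t)
groups = dict(zip(samples["sample_id"], samples["cell_type"]))
summaries, p = rate_estimation.aggregate_rates(ests, groups)
```

Output (printed by the calls above plus a few `print`s):

```
gold set sizes: {'ind1': 105, 'ind2': 107, 'ind3': 104}
mixture: weight_high=0.327 high_mean=54.0
 min_reads  call_sensitivity  mean_per_cell_sensitivity  fp_retained
         1            1.0000                     0.4498       1.0000
         2            0.7018                     0.3157       0.0260
         3            0.5272                     0.2371       0.0033
         4            0.4296                     0.1933       0.0025
chosen min_reads: 3
true fraction among candidates: 0.0023 (95% CI 0.0011-0.0038)
overall corrected rate: 0.13  ANOVA p=0.04
```

Reading this: the EM fit attributes ~1/3 of gold KNR calls to the
high-signal mode; a threshold of `min_reads = 3` ("> 2 reads") keeps 53% of
true KNR calls and a per-cell sensitivity of 24% while discarding 99.7% of
candidate (overwhelmingly chimeric) calls; the mixture model says only
~0.2% of candidates carry true-insertion signal. The corrected rate on this
single cohort is 0.13 insertions per cell against a simulated truth of 0.2
— one cohort of 171 mostly-empty cells carries a sampling SE of ~0.07, and
the zero-inflated rates also make the classic ANOVA p-value approximate
(here nominally 0.04 across identically distributed groups). The
estimator-recovery tests average 20 cohorts per true rate and recover 0.0,
0.1, 0.2, and 0.5 within their Monte-Carlo confidence intervals.

The same pipeline is scriptable from the shell:

```sh
l1audit simulate calls --seed 1 --out sim/
l1audit thresholds --calls sim/calls.tsv --out thresholds.tsv
l1audit rates --calls sim/calls.tsv --min-reads 3 --out rates.tsv
l1audit qc uniformity --sample cell.bedGraph --reference bulk.bedGraph \
    --bin-bp 500000 --out qc.json
l1audit theory hw --p 0.22
```

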