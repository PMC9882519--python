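# genomescape

Genomic-landscape analytics for *TP53*-mutated myeloid malignancies (AML/MDS),
built for whole-genome tumor/normal call sets. *TP53*-mutated AML and MDS are
dominated by complex structural variation — aneuploidy, chromothripsis,
copy-neutral LOH — that standard panel sequencing and cytogenetics
under-resolve. This package implements the downstream analytics of a WGS
characterization of such cohorts as a tested, reusable library:

- **TP53 allele status** — wild-type / monoallelic / multi-hit classification
  from four evidence channels (SNV/indel, allele-specific copy loss,
  CN-LOH detected from B-allele frequency at neutral log2 ratio, SV
  disruption), with biallelic resolution via a cancer-cell-fraction rule.
- **Structural-variant landscape** — class counts (DEL/DUP/INS/INV/BND),
  complex-event clustering by breakend proximity, and the fraction of
  samples with a breakpoint per fixed genome-wide window.
- **Chromothripsis calling** — per chromosome, from interleaved SV
  clustering, copy-number oscillation over 2–3 states, and exact/χ²
  goodness-of-fit tests for random join orientation and exponential
  breakpoint spacing.
- **Cohort copy-number landscapes** — mostly-diploid/WGD sample filters,
  per-unit gain/loss frequencies, cross-cohort contrasts, and
  minimally-deleted regions (MDR).
- **Telomere analytics** — telomeric reads per GC-matched million (TRPM),
  tumor/normal comparisons, singleton telomere-variant-repeat (TVR)
  profiling, and somatic interstitial telomere-insertion detection from
  soft-clipped reads.
- **Exact statistics** — two-sided Fisher 2×2 inference (conditional MLE
  odds ratio and exact conditional CI) implemented from first principles,
  exact Wilcoxon rank-sum, t tests, Benjamini–Hochberg adjustment.
- **Synthetic cohorts** — a ground-truth generator that emulates every
  structure above on a toy genome, so the whole pipeline is verifiable
  without controlled-access patient data.

The exact 2×2 machinery follows the `fisher.test` convention: the
two-sided p sums hypergeometric probabilities of tables no more likely
than the observed one; the odds-ratio estimate ψ̂ solves
E[a | ψ] = a_obs under the noncentral hypergeometric likelihood, and the
95% CI inverts the one-sided exact conditional tests at α/2 per tail.

## Worked example

```python
from genomescape.simulate import SimulationConfig, simulate_cohort
from genomescape.reporting import run_pipeline

profiles, truth = simulate_cohort(SimulationConfig(seed=7, n_samples=8))
report = run_pipeline(profiles)
print(report.aggregates)
```

prints (seed 7, 8 samples):

```
{'n_samples': 8, 'n_failed': 0,
 'tp53_category_counts': {'MULTI_HIT': 8}, 'fraction_multi_hit': 1.0,
 'fraction_biallelic_of_multi_hit': 1.0, 'sv_count_median': 30.0,
 'n_samples_cluster_gt20': 4, 'n_samples_cluster_gt100': 0,
 'fraction_chromothripsis': 0.75, ...}
```

Every sample came back multi-hit at the TP53 locus (reported WGS cohorts
sit at ~94%), six of eight carried a high-confidence chromothripsis chromosome
(planted prevalence 60%), and four had a complex SV cluster of more than
20 members. The `examples/` directory holds one short script per
capability — simulation, TP53 status, chromothripsis, copy-number
landscape + MDR, telomere metrics, exact statistics — each printing the
numbers it computes and what they mean.

A thin CLI wraps the same functions
(`genomescape simulate|validate|tp53|svscan|chromothripsis|cnmap|telomere|stats|run`),
e.g.:

```bash
genomescape stats fisher --table 6,13,4,234
# OR=26 95% CI=(5.44, 142) p=1.26e-05
```

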