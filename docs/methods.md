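# Methods

This note documents the models, rules and numeric choices behind each
analysis stage, what the synthetic-cohort generator does and does not
emulate, and the design decisions taken where the underlying methodology
was genuinely open.

## Data model and conventions

All coordinates are 0-based half-open internally; VCF and SAM positions
are converted at the I/O boundary. Copy-number segments carry
allele-specific values (`major_cn >= minor_cn >= 0`,
`|total - (major+minor)| <= 0.01`) and must be sorted and non-overlapping
per chromosome. Samples below a purity floor of 0.20 (the cohort's
inclusion criterion) are rejected at load time; the floor is a reader
argument. The reference dictionary defaults to GRCh38 chromosome
names/lengths and is fully overridable, which is how the simulator's
four-chromosome toy genome (10–50 Mb chromosomes with named p/q arms)
plugs in.

## TP53 allele status

**CN-LOH detection.** Heterozygous-site BAF is folded
(`max(baf, 1-baf)`) so phasing is never needed. In a tumor of purity ρ, a
copy-neutral LOH region (total CN 2, minor CN 0) shifts the expected
folded BAF of het sites to `(1+ρ)/2`, while the log2 coverage ratio stays
at 0. Detection therefore works over the CN caller's segments: a segment
qualifies when `|log2| <= τ_cn` and its sites' folded-BAF mean reaches
`0.5 + ρ/2 − τ_baf`; adjacent qualifying segments merge into maximal
regions that must span `n_min` sites and still meet the BAF target.
Defaults: `τ_baf = 0.05`, `τ_cn = 0.2`, `n_min = 20`. These are
deliberately loose: at depth 40 the folded-BAF standard error over 20+
sites is well under 0.02, and the nearest confounder (one-copy loss at
ρ ≥ 0.4) sits at `|log2| ≥ 0.32`, outside `τ_cn`. The thresholds degrade
for purity below ~0.4 and are all configurable.

**Classification.** Mechanisms at a locus: SNV/indel calls inside it;
CN_LOSS for an overlapping segment with `minor_cn = 0` *and*
`total_cn < 2` (allele-specific semantics — a subclonal dip does not
count as loss of the wild-type allele); CN_LOH for an overlapping
detected region; SV_DISRUPTION for a breakend strictly inside the locus.
MULTI_HIT requires two small variants, or one small variant plus any
disruptive mechanism, or co-occurring CN_LOSS and SV_DISRUPTION.

**Biallelic resolution.** A small variant combined with physical
loss/disruption of the other allele is BIALLELIC directly. For two small
variants the package uses a documented cancer-cell-fraction proxy:
`CCF = vaf · (ρ·CN + 2(1−ρ)) / (ρ·mult)` at multiplicity 1; if
`CCF₁ + CCF₂ > 1 + τ_ccf` (default `τ_ccf = 0.1`) the variants must
coexist in some tumor cells and the call is BIALLELIC, otherwise
UNRESOLVED. This rule is a proxy, not a proof of trans phase: VAF alone
cannot separate clonal cis from clonal trans pairs in short-read data,
which is exactly why a fraction of real multi-hit cases stay unresolved.
Read-backed phasing, when available, can be injected upstream; it is not
computed here.

## SV landscape

Complex clustering is the transitive closure of breakend proximity: two
SVs link when any breakend of one is within `proximity_bp` of any
breakend of the other on the same chromosome, and both breakends of an SV
always co-cluster (so one interchromosomal junction merges chains). The
default `proximity_bp = 1 Mb` is this package's choice — upstream SV
clustering tools such as LINX do not expose a single fixed distance — and
is computed with a sort-and-link pass that is exactly equivalent to the
pairwise closure in one dimension. Windowed breakpoint frequency counts
breakends (both ends of an SV can hit two windows); a sample contributes
at most once per window regardless of breakpoint count. Cluster-size
summaries use strict thresholds (> 20, > 100 members), the conventional
buckets for complex-SV burden.

## Chromothripsis

The three qualitative hallmarks are operationalized as:

1. **Clustered, interleaved breakpoints** — the largest connected set of
   intrachromosomal SVs under the strict-crossing relation
   (`a₁ < b₁ < a₂ < b₂`; nested or disjoint pairs do not interleave).
   HIGH requires ≥ 6 members.
2. **Copy-number oscillation** — on integer-rounded total CN (half-up for
   determinism), the longest run of adjacent segments that alternate
   within a 2-state alphabet (HIGH: ≥ 7), or within a 3-state alphabet
   (HIGH: ≥ 4, additionally requiring an interchromosomal join into the
   region).
3. **Random join orientation and order** — the four orientation classes
   (DEL-like, DUP-like, head-to-head and tail-to-tail inversion) are
   tested against uniform ¼ each: exact multinomial tail for ≤ 20 joins,
   χ² otherwise; breakpoint spacing is tested by Kolmogorov–Smirnov
   against an exponential with rate n/span. HIGH requires that *neither*
   test rejects at α = 0.05.

These thresholds follow ShatterSeek's published high-confidence scheme;
because cohorts applying that scheme may filter further, every number is
exposed on `CallerThresholds`. LOW confidence marks calls where exactly one
criterion fails within a documented margin (interleaved −2, oscillation
−2, p within α/10). Because the randomness criteria are
*non-rejection* tests, a truly random shattering pattern is missed with
probability ≈ α per test; the measured sensitivity of ~0.92–1.0 on
simulated cohorts reflects that irreducible property of the scheme, not
an implementation artifact.

## Cohort copy number

"Mostly diploid" = no whole-genome doubling and ≥ 50% of covered
autosomal bases at rounded total CN 2 (uncovered bases leave the
denominator). The WGD rule — `major_cn >= 2` over > 50% of covered
autosomal bases — is this package's own PURPLE-style operationalization
of a criterion that is commonly invoked but rarely pinned down. Landscape
units (genes or fixed bins) take a state by majority overlap (> 50% of
unit bases; ties resolve to neutral), so landscapes are invariant to
segment re-splitting. Cross-cohort contrasts run per-unit exact 2×2
tests with Benjamini–Hochberg adjustment at 0.05.

The MDR is computed by iterative intersection: start from the arm and,
per loss-bearing sample, keep the largest piece of the candidate covered
by that sample's losses. When no universal interval exists the largest
interval of maximal support is reported, flagged `universal=False`.

## Telomere analytics

A read is telomeric when a greedy non-overlapping hexamer scan (both
strand orientations, richer one wins) finds ≥ ⌈6·L/100⌉ accepted
hexamers — canonical TTAGGG plus the TVR panel {TCAGGG, TGAGGG, TTGGGG,
TTCGGG, TTTGGG, ATAGGG, CATGGG, CTAGGG, GTAGGG, TAAGGG}. TRPM divides
telomeric reads by reads with GC in [0.48, 0.52] (×10⁶); telomeric reads
count in the numerator regardless of their own GC, and since t-type
repeats are 50% GC they also enter the denominator. The threshold
formula, GC window and TVR panel follow TelomereHunter-style
conventions; all are configurable.

Singleton TVRs require ≥ 3 contiguous t-type hexamers immediately on
each side within one read (contiguity is tracked through the greedy
scan's slot offsets and preserved under strand flipping).

Insertion detection: tumor reads with a soft clip ≥ 12 bp whose clipped
sequence is ≥ 80% telomeric hexamers mark a locus at the clip boundary;
loci cluster within 50 bp, need ≥ 3 supporting reads, must avoid the
outermost 500 kb of each chromosome (real telomere), and are somatic only
when the matched normal has zero qualifying clipped reads at the locus.
Calls carry the distance to the nearest SV breakend and a 10-kb
chromothripsis-region proximity flag. Without a normal read set, calls
are emitted flagged un-subtracted.

## Exact statistics

The 2×2 module builds the conditional likelihood from log-binomial
coefficients (`gammaln`), normalized in log space. Two-sided p uses the
minimum-likelihood rule (sum of tables with probability ≤ observed,
within a 1e−7 relative guard against ties); a doubling rule is available
by flag. The OR estimate solves `E[a | ψ] = a` by Brent root-finding in
log ψ (relative tolerance 1e−8; 0/∞ at the support boundary), and the
95% CI inverts `P(A ≥ a | ψ) = α/2` and `P(A ≤ a | ψ) = α/2`. Degenerate
margins yield one-sided intervals, never errors. Wilcoxon rank-sum is
exact for combined n ≤ 25 via a subset-sum dynamic program over doubled
mid-ranks (ties handled exactly); larger samples use the normal
approximation with tie and continuity corrections. t tests and BH
adjustment delegate to SciPy.

## Synthetic cohorts

The generator's defaults mirror the composition reported for 42-case TP53-mutated AML/MDS WGS cohorts: purity
Uniform(0.4, 0.9) (all above the 0.20 floor, and inside the regime where
default thresholds are stable); arm-loss probabilities 0.80 (5q), 0.56
(7q), 0.45 (12p focal), plus a 0.10 5p gain; TP53 mechanism mix 22/42
SNV+loss, 11/42 SNV+CN-LOH, 3/42 two SNVs, 5/42 SNV+SV, 1/42
monoallelic; chromothripsis probability 0.60 with 15–40 breakpoints;
insertion probability 13/42 with a second locus at 4/13 and 68% of loci
placed within 10 kb of an SV breakend. The 12p losses are focal
expansions of a shared 2.75-Mb core containing the toy ETV6 and CDKN1B
loci, so an MDR exists by construction; the recorded truth MDR is the
intersection of the planted intervals, bookkept independently of the
analysis code. Chromothripsis breakpoints are uniform in their region
(gaps exponential-like, as the spacing test assumes) with copy number
alternating between two states, and joins pair random breakpoints with
uniformly random orientation.

BAF sites are emitted every 100 kb at binomial depth 40 with the major
allele on a random side; log2 ratios carry Gaussian noise (σ = 0.02).
Observed VAFs are binomial at depth 60 around the purity- and
CN-consistent expectation. Telomeric reads are clean hexamer
concatenations (half reverse-complemented); background reads draw GC
from N(0.45, 0.07) so the GC-matched denominator is exercised; planted
content is converted to a Poisson telomeric-read count against the
realized denominator, making the TRPM estimator unbiased with
√λ relative noise. Insertion support reads use a 90M+30S layout so their
clips are fully telomeric while the read as a whole stays below the
telomeric-read threshold.

Determinism: one global seed; every (sample, stage) substream derives
from `(seed, CRC32(sample_id), CRC32(stage))`, so adding a sample never
perturbs existing ones, and cohort writes are byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error, mappability and alignment
artifacts, subclonal copy-number states, germline CNV, replication-timing
or GC-coverage bias beyond the read-level GC draw, realistic SV breakend
homology/insertions, and chromothripsis mixed with other complex
processes (chromoplexy, BFB). Recovery rates on these cohorts are
best-case upper bounds.

## Problem sizes

Test and acceptance runs use a 40-sample cohort on the four-chromosome
toy genome (the package's desk-scale stand-in for a 42-sample
patient cohort), 3,000 background reads per tissue for pipeline runs, and 20,000
background reads when a stable TRPM estimate is the point of the check.
A full simulate-plus-analyze pass over 40 samples takes well under a
minute on one CPU.

## Known limitations

- Biallelic resolution is a CCF proxy; it cannot prove trans phase from
  VAF alone (see above).
- The chromothripsis caller does not separate chromothripsis from
  chromoplexy or BFB cycles, and inherits the α-level miss rate of its
  non-rejection criteria.
- Interstitial-insertion detection requires soft-clip evidence at the
  exact junction; insertions longer than a read or in low-mappability
  context (the reason short-read counts underestimate) are out of reach.
- The exact Wilcoxon path is quadratic in total rank mass and switches to
  the normal approximation above combined n = 25.
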