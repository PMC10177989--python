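# Methods

## Model and procedure

The pipeline treats allele-specific regulation as a per-site binomial
problem. At a heterozygous biallelic SNP, an assay (RNA-seq for expression,
histone-mark ChIP-seq for binding) yields `n` informative reads of which `k`
support the reference allele. Under no allelic effect and no technical bias,
`k ~ Binomial(n, 0.5)`.

Two artifacts break the naive test. First, *reference mapping bias*: reads
carrying the alternative allele mismatch the reference genome and are lost
or mis-placed more often, inflating `k`. The pipeline therefore consumes
counts from two alignments — the reference genome and an individual
*alternative reference* with alternative alleles substituted — on which the
bias acts in opposite directions. The caller runs the exact two-sided
binomial test (doubling the smaller tail, capped at 1) separately on each
target and requires both to be significant *with the same direction of
imbalance*. A genuine allelic effect survives; a bias artifact is pushed in
opposite directions on the two targets and cannot. Second, *multiple
testing*: raw p-values are Benjamini–Hochberg adjusted, with separate
families for RNA-seq and ChIP-seq tests (all histone marks pooled into the
ChIP family; a per-mark family mode is available). BH is applied to each
alignment target's p-values within a family.

An event additionally needs a folded odds ratio `max(r, 1/r)`,
`r = ref/alt`, of at least 1.5 on both targets, so one threshold covers
enrichment and depletion. When one count is zero the Haldane–Anscombe
constant 0.5 is added to both counts and the value flagged extreme; both
counts zero is rejected. Tied counts have no direction and never yield an
event.

A SNP becomes an **rSNP** when it carries ≥ 1 ASE event and ≥ 1 ASB event —
any mark, and by default any individual (a strict same-individual mode
exists; the default reflects that events are recorded per individual on a
shared genomic background and evidence may legitimately come from different
heterozygous carriers). rSNPs are assigned to promoter windows
`[tss − w, tss + w]` (1-based inclusive, floored at 1) with `w = 1000` bp by
default; each TSS of a gene keeps its own window, containment is
strand-agnostic, and the signed distance to the TSS is negative upstream on
the gene's strand.

The annotation cascade is a set of deterministic joins: promoter rSNPs ×
DEG direction lists (a gene may appear in only one direction), × an
epigenetic-regulator catalog with HMW/HMR/HME/CR function categories
(multi-membership allowed, so category counts may sum to more than the gene
total; a catalog entry with no recorded category joins but contributes to no
category count), × a GWAS extract keyed by SNP id. The regulator cascade
emits a link for a peak protein when (a) ≥ 1 of its peaks shares ≥ 1 base
with an AD-related gene's promoter window and (b) the promoter of the gene
encoding the protein contains ≥ 1 rSNP. Protein symbols resolve to gene
symbols through an explicit alias table (identity by default); unresolvable
proteins are logged and skipped, never fuzzy-matched. Links found in the
regulator catalog are reported with their function/complex annotation in a
separate table from plain transcription factors.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `p0` | 0.5 | null ref-allele probability |
| `or_threshold` | 1.5 | folded odds-ratio floor (both targets) |
| `padj_threshold` | 0.1 | BH-adjusted p ceiling (both targets) |
| `min_coverage` | 10 reads | per-target floor below which the exact test has essentially no power; applied before BH so families contain only tested sites |
| `bh_family` | assay class | RNA vs ChIP families; `per_mark` splits ChIP further |
| `w` | 1000 bp | promoter half-width around each TSS |

The thresholds `or_threshold`, `padj_threshold` and `w` are the
conventional operating point for this type of analysis; `min_coverage` and
the BH family layout are this package's explicit choices (marks are pooled
into one ChIP family and all individuals of a run share one family; both
are configurable).

## Synthetic data: what it emulates and what it does not

The generator plants genes every 20 kb on a toy chromosome, places a
configurable fraction of SNPs inside promoter windows and the rest in
intergenic gaps (erroring when the requested SNP count cannot fit), draws
Hardy–Weinberg genotypes from a uniform MAF on [0.1, 0.5], and emits counts
only at heterozygous sites. Coverage is negative binomial per assay (default
mean 30, shape 20 — moderate overdispersion, CV ≈ 0.26 at mean 50, chosen as
a realistic single number rather than fit to any dataset). The ref-allele
probability at a site with true allelic ratio ρ and mapping-bias odds factor
b ≥ 1 is `ρb/(ρb + (1−ρ))` on the reference target and `ρ/(ρ + (1−ρ)b)` on
the alternative target, so the two targets' odds multiply back to the
unbiased `(ρ/(1−ρ))²` — the exact property the concordance requirement
exploits. An optional beta-binomial overdispersion φ (default 0, matching
the pure-binomial test model) draws the success probability from a Beta with
mean p and concentration 1/φ.

Imbalanced SNPs (default 5%) get ρ = 0.8 in RNA plus one or two random
histone marks, so every imbalanced SNP is a ground-truth rSNP. Planted
regulator genes get one designated promoter rSNP, peaks of ±300 bp around
each chosen DEG target's TSS, plus a decoy peak outside any promoter; one
extra decoy protein has peaks in a target promoter but no promoter rSNP and
must never produce a link. Ground-truth SNPs are forced heterozygous in half
the individuals so the planted truth is testable by construction.

A separate site-level panel generator conditions directly on
heterozygosity (default 4 het individuals per site) for calibration and
power studies where the site inventory must be exact. The calibration
scenarios used by the tests and the acceptance script are: 10,000 null
sites at bias b = 1.5, coverage mean 30 (false-call control and the
dual-vs-single-reference comparison); and 500 imbalanced pairs (ρ = 0.8,
coverage mean 50, b = 1; 125 rSNP SNPs with RNA+mark imbalance, 100
ASE-only and 150 ASB-only decoys) among 10,000 null pairs (recall and exact
rSNP-set recovery). These sizes keep each study under a couple of seconds
while leaving Monte-Carlo error well inside the asserted margins.

What the generator does **not** model: read-level artifacts (duplicates,
GC bias, mismatch-dependent mapping), haplotype phase and LD between SNPs,
shared reads between alignment targets (the two targets are drawn
independently, which if anything *understates* their correlation and makes
the concordance requirement harder to satisfy), assay-specific peak
structure, and between-individual effect heterogeneity. Passing tests
therefore demonstrate correctness of the statistics and joins under the
stated model, not end-to-end fidelity to real brain data.

## Numerical choices and degenerate inputs

Exact binomial tails come from `scipy.stats.binom` (`cdf`/`sf`), verified
in the tests against integer pmf enumeration for all n ≤ 50; the two-sided
rule is double-the-smaller-tail, chosen over the minimum-likelihood rule
for exact reproducibility and symmetry at p0 = 0.5. BH adjustment is
`statsmodels` `fdr_bh`, verified against an independent step-up
implementation; input order is preserved. Sites present on only one
alignment target are skipped and counted; empty inputs yield empty outputs
with a warning; duplicate count keys are an error (pooling technical
replicates is the explicit `pool_counts` operation, which refuses to pool
across assays, targets, or — by default — individuals). All randomness
flows from one seeded `numpy` generator; a fixed seed makes every output
file byte-identical, and reports embed the seed and thresholds in their
metadata header.

## Known limitations

- Power at the demo's default coverage (mean 30) is moderate: about
  two-thirds to all of the planted regulator links survive the full
  event-calling chain depending on the seed, because each link needs two
  events (ASE and ASB) to be called. The calibration panels at coverage 50
  show near-complete recovery; low-coverage sites are genuinely untestable
  rather than mis-called.
- The folded odds ratio is reported for both targets and both must pass;
  thresholding one target alone would be less strict, and the AND rule is
  the conservative choice.
- Promoter windows are symmetric and strand-agnostic by design; distal
  regulation (enhancers) is out of scope.
- The regulator cascade counts any-base peak overlap; a summit-containment
  mode would be stricter but peak summits are not part of the BED4 input
  contract.
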