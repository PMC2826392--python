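# Methods

## The problem

Short-oligonucleotide expression arrays measure transcript abundance with
25-mer probes designed against a reference genome. When a sample carries a
single-nucleotide variant inside a probe's target, hybridization is less
efficient and the probe reports a lower intensity regardless of the true
mRNA amount. In a between-population comparison this is dangerous: a SNP
that is common in one panel and absent from the other produces a systematic
intensity difference that mimics differential expression or differential
splicing. `probevar` implements the survey that quantifies this risk: it
maps per-population variant calls onto the probes of an exon-style array,
catalogues the affected exon-level probesets and gene-level transcript
clusters, compares the catalogue against a prior known-SNP-based list, and
re-assesses two-group comparisons with and without the SNP-containing
probes.

## Coordinate model

All annotation I/O is 1-based with inclusive ends, the convention of vendor
annotation files and genome browsers (a 25-mer starting at position *s*
spans *s* .. *s*+24). Internally every interval is stored 0-based
half-open, so there is exactly one conversion boundary; BED export uses the
BED convention. Probe/variant overlap is strand-agnostic — a single-base
variant is *in* a probe iff its position lies in the probe's closed genomic
interval — because the survey is positional. Strand matters only for the
within-probe offset: on the plus strand the offset of position *p* in probe
[*a*, *b*] is *p* − *a* + 1, on the minus strand *b* − *p* + 1, so offsets
always count 1..k from the probe sequence's 5′ end. A `genomic` offset mode
that ignores strand is available as a switch. Offsets are grouped into 5-nt
bins (bin 1 = offsets 1–5 at the 5′ end) and a *middle* flag marks offsets
6..k−4 (6–21 of a 25-mer), the region where a mismatch perturbs
hybridization most.

Probes whose span differs from the configured probe length (control probes
in real annotation files) are skipped with a counted warning rather than
failing the load. A missing reliability column defaults every probeset to
`core` so the reliability breakdown stays computable.

## Allele frequencies and variant classes

Allele frequencies are computed per population from called genotypes only:
missing alleles are excluded from the denominator, all samples are treated
as unrelated, and populations are never pooled. Multi-allelic VCF records
are split into one biallelic variant per alternate allele, sharing the
position and the called-allele denominator; indels and other non-SNV
records are skipped with a count. The minor allele frequency is
MAF = min(f, 1 − f). A variant is **common** when MAF strictly exceeds the
threshold (default 0.05) and **rare** otherwise; the boundary value folds
into rare, and the threshold is configurable.

Known/novel status is a positional match against a dbSNP-style catalogue
keyed by (chromosome, position). An allele disagreement between the call
set and the catalogue is flagged but does not revoke known status, since
matching is purely positional.

## Functional annotation

Known variants take their catalogue function class verbatim. For novel
variants only two families of classes can be inherited from annotated
neighbors, under a deliberately conservative two-sided rule: the nearest
annotated SNP strictly to the left and strictly to the right must agree on
class and on host gene, the class must be `utr-5`/`utr-3` or
`near-gene-5`/`near-gene-3`, and for the near-gene classes both neighbors
must lie within a window (default 2000 bases) of the variant. One-sided
evidence yields `NA`. The window is applied to the variant-to-neighbor
distance; an alternative reading (bounding the distance to the gene) exists
and the window is exposed as configuration for that reason. Coding classes
(missense, nonsense, synonymous, frameshift, splice sites) are never
imputed — they require codon context that a positional rule cannot supply —
and pass through only from the catalogue. Host genes are imputed for
intragenic variants by interval containment; when genes overlap, all
candidates are reported with the smallest-span gene as the deterministic
primary.

## Cataloguing

A probeset is *affected* when ≥1 of its probes contains ≥1 variant passing
the active MAF filter. Counts are distinct SNPs, not hits: a variant lying
in two overlapping probes of one probeset counts once for that probeset
(and contributes both probes to its affected-probe list). Probesets are
classed by SNP count {0, 1, 2, 3+} and by novelty {novel, known, both,
none}; per-cluster and per-reliability breakdowns sum over these. The
prior-catalogue comparison classifies each affected probeset by whether its
SNPs are all absent from the prior list (Novel), all present (Known), or
mixed (Both); the 1-SNP class has Both = 0 by construction.

Chromosomal enrichment uses an exact two-sided binomial test per
chromosome: the number of affected probesets on a chromosome out of all
affected probesets, against that chromosome's share of all probesets.
Bonferroni-adjusted p-values are reported alongside; sidedness and the
correction are implementation choices exposed in the output rather than
prescribed by the method.

## Splicing-impact audit and re-test

The audit takes a list of probesets of interest (e.g. prior
differential-splicing hits) and reports, per population, those containing
≥1 novel SNP at *any* frequency — the worst case, since even a rare
mismatch in one population can bias a between-population contrast. A
`--common-only` path uses the common filter instead. Each record carries
the novel-SNP count, the rare-among-novel count, and whether the probeset
remains measurable after dropping SNP-containing probes.

The re-test summarizes a probeset as the unweighted per-sample mean
(optionally median) of its probe log2 intensities and applies a two-sample
t-test between the two populations, once over all probes and once excluding
probes with ≥1 hit. The default test is pooled-variance; Welch is a flag. A
probeset whose probes are all excluded is reported as not measurable
rather than given a number.

## Synthetic data

The generator's defaults are the study conditions the rest of the package
is validated under: 200 genes on 4 chromosomes, four probesets of four
25-mer probes per gene (3,200 probes), panels of 57 and 56 samples, 2-kb
near-gene flanks, and a variant density of 4 per kb, which yields on the
order of 5,000 variants of which roughly 5–6% fall inside probes. Each gene
is laid out left-to-right as exon/intron alternation with 300-base introns;
the outermost exons are the UTR exons (5′/3′ assigned by strand), inner
exons are coding. Every exon is tiled exactly by one probeset, so the
probeset interval is the exon.

Variant positions are Poisson-placed per chromosome. Each variant draws an
ancestral frequency uniformly on [0.01, 0.5]; the two populations draw
their own frequencies from a Balding–Nichols Beta distribution around it
with divergence F = 0.15 (roughly the CEU–YRI range), and genotypes follow
Hardy–Weinberg proportions. Variants are unlinked: linkage disequilibrium
is irrelevant to interval mapping and is not modeled. A fraction (default
0.7) of variants is entered into the known catalogue with its true class;
the truth table records, for every variant, its geometric class, the class
the annotation stage is expected to assign (catalogue class for known
variants; a bookkeeping twin of the neighbor rule, computed by plain scans,
for novel ones), per-population empirical frequencies, and every planted
probe hit (found by a vectorized containment scan independent of the
interval index). A population's VCF contains exactly the variants with ≥1
alternate allele observed in that panel, mirroring per-population call
sets.

Expression is generated as probeset baseline (uniform 6–9 log2 units) minus
`artifact_delta` (default 0.6 log2 units) per alternate allele at each
variant inside the probe, plus Gaussian noise (`noise_sd`, default 0.3
log2). No population mean effect is planted, so any between-population
signal at a probe is attributable to the artifact. The dose-linear form on
the log2 scale is a modeling choice (the mechanism is only qualitatively
"reduced hybridization") and both parameters are configuration.

The artifact re-test demonstration plants the scenario the audit targets: a
novel SNP at allele frequency 0.45 in one panel and absent from the other,
in one probe of a four-probe probeset (offset 10, middle region). Under the
default effect sizes the with-probes test rejects and the without-probes
test does not in well over 80% of replicates; with the artifact removed
both tests reject at the nominal ~5%.

What the generator does *not* emulate: genotype-calling error (the
real-world motivation for focusing on common variants), linkage
disequilibrium, RMA-style preprocessing artifacts, probe GC/affinity
effects, cross-hybridization, and junction-spanning probes (every probe is
one contiguous genomic interval). Passing the planted-truth tests therefore
demonstrates correctness of the bookkeeping and statistics on clean input,
not robustness to those real-data phenomena.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; fixture bundles and survey outputs are byte-identical
  under a fixed seed, with stable (chrom, pos, probeset id) sort orders.
- The Monte-Carlo calibration of the enrichment test uses 100 affected
  probesets placed multinomially over four equal chromosomes; at n = 100
  and p = 1/4 the exact size of the two-sided binomial test at α = 0.05 is
  0.0487, so the observed rejection rate is compared against that exact
  size (the test is discrete; nominal 5% is not attainable exactly).
- The oracle for overlap mapping is a brute-force double loop over
  (variant, probe) pairs with direct offset arithmetic, kept separate from
  the interval-tree path it checks.
- Problem sizes in the test suite (default bundle ≈3,200 probes / ≈5,300
  variants per panel; 100 re-test replicates; 200 calibration replicates)
  were chosen so the whole suite runs in well under a minute while keeping
  binomial standard errors small enough for the stated tolerances.

## Known limitations

- Function classes for novel variants are imputed only for UTR and
  near-gene classes; everything else is `NA`, so `NA` counts are dominated
  by novel variants — as in any positional-imputation scheme.
- The per-population frequency model treats all samples as unrelated; trio
  or relatedness corrections are out of scope.
- The prior-catalogue comparison keys on probeset id + SNP position; it
  cannot distinguish a prior SNP retired from the catalogue from a novel
  SNP at the same position.
- Absolute genome-scale counts (hundreds of thousands of affected
  probesets) require the real array annotation and population call sets
  and are out of scope; the package validates structure and statistics at
  desk scale.
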