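# Methods

`lncepi` reimplements, as a tested reusable pipeline, an integrative
analysis of plant long noncoding RNAs (lncRNAs) against the epigenome:
positional classification, overlap with inverted repeat regions (IRRs) and
24-nt siRNA loci, cytosine-context DNA methylation, H3K27me3 domains,
metagene profiles, stratified expression statistics, cross-species homology
coverage, and GO enrichment. This note records the models, conventions and
open design choices; nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open. GFF3/GTF, cytosine reports
and BLAST tabular coordinates (1-based inclusive) are converted at the I/O
boundary; BED and bedGraph are consumed as-is. Strand `.` acts as a
wildcard in stranded queries, the usual reading for repeat annotations.
`merge_intervals(gap)` joins runs separated by at most `gap` unshared
bases; tests check it against a per-base bitmap union oracle.

## Transcript classification

Labels are assigned by precedence, mirroring the positional definitions of
the three lncRNA classes:

1. **NAT** — ≥ 1 bp exon-to-exon overlap with a gene on the opposite strand
   (the threshold is configurable; no published value exists).
2. **incRNA** — transcript span fully contained in a single gene intron.
   Either strand qualifies by default since "derived from introns" does not
   fix a strand; a same-strand-only flag is provided. Partial intron
   overlap does not qualify (flag available).
3. Intergenic transcripts: a protein-database hit at e-value ≤ 1e-10 makes
   a **putative mRNA**; otherwise **lincRNA** provided length > 200 nt.

Sense-overlapping non-intronic transcripts, short intergenic transcripts
without hits, and transcripts on chromosomes absent from the gene
annotation are `unclassified`. All three lncRNA labels additionally
require length (sum of exon lengths) > 200 nt. Distance-to-gene bins
default to 0/2 k/5 k/10 k/20 k/∞; only the 2 kb and 20 kb breakpoints are
anchored in the source text, the interior ones are a labeled convention.

## DNA methylation

The per-site level is mC / (mC + umC). Regions aggregate by the
read-weighted level Σ mC / Σ (mC + umC) over covered sites of one context
with both strands pooled — additive across sub-regions, robust at low
coverage, and consistent with the per-site formula (mean-of-sites is a
deliberate non-choice). Zero-coverage sites are undefined and excluded,
never counted as 0. The default minimum per-site coverage is 1 read,
i.e. no filter. Replicates, when present, should be pooled at the count
level before aggregation (a mean-of-replicates alternative can be had by
aggregating per replicate and averaging).

## 24-nt siRNA overlap

Reads are filtered to length 24 and unique mapping. "Perfect sequence
identity to a 24-nt siRNA locus" is implemented as full containment of a
uniquely mapped 24-nt read interval within the transcript's genomic span;
sequence-level identity is implied by unique mapping, so no sequence
comparison is repeated here. Strand is ignored by default (flag provided).
Clusters — used only in cluster overlap mode and for reporting — merge
24-nt read intervals bridging ≤ 100 bp and keep merged intervals with ≥ 3
member reads; both values are explicit conventions because the source
analysis names siRNA clusters without defining them. RPM normalizes by the
full mapped small-RNA library (all lengths), standard practice.

## IRR and H3K27me3 status, stratification

"Overlap" is ≥ 1 bp between the transcript span and an annotated interval,
configurable as a bp minimum or fraction of the transcript, and optionally
exon-restricted. H3K27me3 domains are consumed as precomputed BED; a
labeled convenience (`domains_from_bedgraph`: coverage ≥ c over ≥ w bp,
merged) derives domains from a coverage track but is not a peak caller.
Percentages are printed to one decimal, rounded half away from zero, the
style of the published count pairs (66 of 92 → 71.7). The joint IRR ×
siRNA table exposes the conditional fraction of siRNA-positive transcripts
that harbor IRRs.

## Metagene profiles

Scaled-body + fixed-flank geometry: the body is split into `body_bins`
(default 40) equal-width windows with the remainder spread over the leading
bins, flanks into `flank_bins` (default 20) windows of `flank_bp`/20 bp
(default flank 2 kb — an assumption recorded in output metadata, as the
source figures do not state flank width). Every signal exposes per-base
numerator/denominator arrays: coverage-type signals (siRNA RPM, H3K27me3)
bin to the mean per-base value, methylation bins to Σ mC / Σ reads, so a
single binning rule conserves count totals and weights methylation by
coverage. Minus-strand features are reversed so bin 0 is 5′. Flanks
truncated at chromosome edges and bins without denominator are NaN and drop
out of cross-feature averages; flank overlap with neighboring features is
not masked by default.

## Expression statistics

Stratified comparisons use a two-sided pooled-variance (Student) t-test on
per-transcript mean FPKM between mark-positive and -negative strata within
a class; transcripts, not replicates, are the sampling unit. Raw FPKM is
the default (no transform is stated in the source); log2(FPKM+1) is a
flag. Strata with < 2 members skip the test and report NA. Class-wise
length comparisons use one-way ANOVA; the letter display comes from
pairwise pooled t-tests with Bonferroni correction over all pairs and a
sweep assignment over mean-sorted classes — the post-hoc method is a
package choice, none being published. Constant identical groups return
F = 0, p = 1 rather than NaN.

## Homology coverage and band summaries

HSPs are filtered at e-value ≤ 1e-10, deduplicated, and grouped by
(query, subject, strand). Within a group a maximum-total-bitscore chain is
found by dynamic programming over query-start-sorted HSPs, requiring query
and subject order to advance together and successive subject gaps ≤ 10 kb
(configurable). The best-scoring group is the representative homologous
region; this stands in for genBlastA's internal ranking, which is not
reproduced bit-for-bit — the downstream coverage statistic is the target.
Coverage merges the chain's query intervals first, so overlapping HSPs
count once, and divides by query length. Tests verify the chain score
against exhaustive subset enumeration up to 10 HSPs.

RT-PCR band matrices use symbols `+++`/`+`/`-`. "Expressed" in group
summaries means a strong band only; this is the single reading under which
the published totals (7 of 12 lncRNAs in all six B. rapa lines; 6, 1, 1
and 4 across the three B. oleracea cultivars) match the published matrix,
and the acceptance suite locks that equivalence in.

## GO enrichment

One upper-tail hypergeometric test per term with ≥ 1 study hit, computed
via the survival function in log-space (scipy), with Benjamini–Hochberg
FDR (statsmodels) at a 1% default level. The background population is an
explicit input — the original web-tool background is not reproducible —
and terms are tested as given, with an optional ancestor-propagation
pre-pass that is off by default. Because published figures star tests at
0.05/0.01/0.001 while the stated control is 1% FDR, both a star column and
the FDR-significant flag are emitted; the package does not resolve that
discrepancy, it surfaces it.

## Synthetic data: what it emulates and what it does not

The generator lays out disjoint "units" (a gene, a gene + NAT, a gene with
an enlarged intron hosting an incRNA, a lincRNA, or a putative mRNA)
separated by random intergenic gaps, guaranteeing unambiguous class
identity and exact mark truth: planted IRR/H3K27me3 intervals sit inside
the transcript span, 24-nt source regions (with ≥ 4 uniquely mapped reads)
sit inside the span and nest inside the IRR when both marks are planted,
and background repeats, domains and reads are confined to gaps. Defaults
are the surveyed conditions: class-wise IRR fractions 65.0/55.0/71.7/64.1%,
siRNA fractions 18.7/14.0/17.4/15%, H3K27me3 fractions 10.8/15.7/16.3/
10.8%, a 0.85 conditional probability that a siRNA-positive transcript is
IRR-positive, mean transcript lengths 725/1271/779/1305 nt (log-normal,
σ = 0.45), and single-exon fractions 65.7/72.4/71.0/40%.

Methylation is binomial per site at Poisson(20×) depth over sites spaced
15 bp across feature spans ± 2 kb flanks, with context weights
CG/CHG/CHH = 0.25/0.25/0.50 and base levels 0.45/0.25/0.08 (typical
Brassica leaf ranges); site means are beta-distributed around the regional
mean (concentration 200) and elevated by +0.25 inside IRRs and siRNA
source regions. Expression is log-normal (μ = 1, σ = 1.2) FPKM with two
replicates (σ_rep = 0.1) and a ×2 multiplicative effect for
siRNA-overlapping transcripts. Conservation plants per-genome
(hit-probability × mean-coverage) tiers — B. oleracea highest, B. juncea
lowest — realized as colinear HSP chains with decoy secondary subjects.
The GO map plants one term on 80% of incRNA host genes versus 10% of the
background. One RNG stream per file family derives from the master seed,
so outputs are byte-identical per seed.

Deliberately not modeled: real sequence composition, mapping ambiguity and
multimappers, bisulfite conversion error, assembly artifacts, overlapping
or nested transcription units, and replicate-level biological variance in
the epigenomic tracks. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated definitions, not
robustness to the noise structure of real sequencing data.

## Numerical conventions and problem sizes

Percent rounding is half-away-from-zero at one decimal via exact decimal
arithmetic. Ties in chain selection break deterministically by subject id
and strand. Degenerate inputs (empty classes, empty strata, regions with
no covered sites, all-NaN profiles) warn-and-omit or return NA rather than
silently producing zeros. The test and acceptance runs use a synthetic
genome of six 1.5-Mb chromosomes carrying 1,000 lncRNAs plus 100 putative
mRNAs and 150 standalone genes — large enough that binomial 3-SE recovery
bands are informative while the whole suite runs in well under a minute of
compute for the data-dependent parts.
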