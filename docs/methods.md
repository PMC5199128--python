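# Methods

`apadiv` reimplements, at desk scale, a complete analysis of alternative
polyadenylation (APA) divergence between two inbred mouse strains and their
F1 hybrid: discovery of polyadenylation sites (pAs) from 3'-end sequencing,
construction of a cross-strain reference, allele-specific usage
quantification, attribution of divergent usage to cis- or trans-acting
causes, and sequence/structure characterization of the divergent sites.
Because the original sequencing data are not required, every stage is driven
by a synthetic-data generator with planted ground truth, and every claim the
package makes is checked against that truth.

## The biological design

Two strains ("BL", the reference strain, genome A; "SP", the alternate
strain, genome B) differ by a dense set of sequence variants.  A strain
difference in the usage of a pAs can arise from a *cis*-acting cause (a
sequence variant near the site, inherited with the allele) or a
*trans*-acting cause (a difference in the cellular environment).  In an F1
hybrid both alleles share one trans environment, so an allelic usage
difference inside the F1 isolates the cis component: cis-divergent pAs show
the parental difference between the F1 alleles, trans-divergent pAs do not.

## Synthetic-data generator (`apadiv.simulate`)

The generator is first-class, tested code; its defaults are the package's
standing study conditions.

**Genomes.** Random uniform-composition chromosomes for strain A; strain B
is produced by applying SNPs and short (1–6 bp) indels placed by independent
Bernoulli draws per base.  Defaults `snp_rate=0.013`, `indel_rate=0.002`
mirror the density of the real strain pair (tens of millions of SNPs over
the mouse genome, roughly 1 SNP per 75–100 bp).  Colliding indel placements
are dropped (equivalent to a re-draw).  The variant map is the single source
of truth for coordinate liftover between the genomes.

**Gene models.** Genes are placed on alternating chromosomes, random strand,
with a fixed internal architecture (first exon, intron, long last exon;
plus an alternative last exon transcript when needed) that can host all five
positional pAs categories: terminal (annotated transcript end), tandem
3' UTR, alternative last exon, intronic, internal exonic.  The per-gene pAs
count follows a configurable categorical distribution (default: 45% of
genes with a single pAs).  Each pAs flank receives a canonical AAUAAA
polyadenylation signal at sense offsets −25..−20 with probability 0.9 and a
poly(U) tract (default 6 U) at −52..−47 with probability 0.35.  An internal
A₁₀ tract in exon 1 provides a mispriming anchor.

**Expression and usage.** Gene expression weights are log-normal
(`mu=0, sigma=1`); per-gene pAs usage is Dirichlet (`alpha=2`).  Reads per
gene are multinomial in the gene weights, then multinomial across the
gene's pAs in the condition's usage vector, so per-gene totals always equal
the sum of pAs counts.

**Planted effects.** A configurable fraction of multi-pAs protein-coding
genes receives one effect pAs (at most one per gene, so planted truth stays
identifiable; the fractions are therefore per-gene, defaults 15% cis / 5%
trans, close to the proportions observed in fibroblasts of this strain
pair).  Cis effects are written into exactly one allele's sequence:

* *Signal disruption*: AAUAAA → AAGAAA (the SNP sits at sense offset −23);
  the mutated allele's usage drops by the configured Δ (default 30 points).
* *Poly(U) shortening*: the tract is reduced to 2–5 U by base substitutions
  (keeping coordinates aligned); since the tract represses usage, the
  disrupted allele's usage **rises**, scaled by disruption depth (a tract
  cut to 2 U realizes the full Δ, shallower cuts proportionally less).

Trans effects shift the two parents' usage by Δ with no sequence cause; the
two F1 allele usage vectors are set to the parental mean.  Usage mass is
rebalanced proportionally across the gene's other pAs, so sibling pAs of an
effect pAs genuinely co-diverge (compensation), as they would in a real
transcriptome.

**Read streams.** All reads are emitted at the aligned level (tailmap
records); read alignment itself is out of scope and FASTQ is never written.

* *3' READS*: two replicates per strain, 3'-end positions jittered by a
  rounded Gaussian (sd 2 nt) truncated at ±12 nt so planted sites stay
  within one 24-nt cluster; non-genomic T tail counts follow a categorical
  distribution with P(T≥2) = 0.7 for true-site reads.  BL reads are in
  genome-A coordinates and SP reads in genome-B coordinates, as each parent
  would be aligned to its own genome.  A background fraction (default 5%)
  of reads is placed uniformly *within gene spans* with a mostly-0-T tail
  distribution (5% leak into T≥2).  Uniform-within-transcript placement
  emulates internal-priming artifacts, which dominate the 0-T null in the
  real assay; genome-wide-uniform noise would sit in regions without
  RNA-Seq background coverage, where the enrichment statistic E is
  undefined rather than merely small.
* *3' mRNA-Seq*: two replicates per condition (each parent, F1), emitted in
  reference (A) coordinates; the tailmap `pos` column stores the read
  5'-end anchor used for window counting (for 3' READS it stores the
  3'-end).  Reads are 88 nt (101-nt sequencing minus trimming, as in the
  source protocol).  Every read carries its true allele so assignment
  accuracy is measurable.  A mispriming fraction (2%) starts at the
  internal A-rich anchor and must be rejected by window counting.
* *mock F1*: the two parental streams pooled and relabeled, true strain
  retained, processed exactly like the real F1.
* *Background RNA-Seq*: point coverage placed uniformly within gene spans,
  totals proportional to gene expression, per strain in that strain's
  coordinates.
* *Structure probing*: optional per-base paired/unpaired (V1/S1) count
  tracks, Poisson within genes, with an accessibility dip (elevated S1)
  planted at sense offsets −30..−15 of every pAs.

**Determinism.** All stages draw from named `numpy` Generator streams
derived from the single config seed; a fixed seed reproduces every output
byte-for-byte.

## Site discovery (`apadiv.cluster`)

Reads with ≥2 non-genomic T (PASS reads) define cleavage sites; reads with
exactly one T are discarded; 0-T reads form the pseudo-site null.  Sites
within 24 nt (inclusive) are single-linkage clustered; a component wider
than 24 nt is decomposed greedily: the maximum-coverage position becomes the
representative site (ties break to the smaller coordinate — the source
method does not specify), sites within 24 nt join it, the remainder is
re-clustered.  Clustering is per chromosome and strand.

Each cluster gets `R` (PASS count) and `E` = (R / cluster size) /
((background reads in the strand-aware −500..+50 window + 1) / 550); the
pseudocount of 1 keeps E finite where background coverage is absent.  The
dominance p-value is `P_i = n_i / N` with `n_i` the clusters strictly
greater on both R and E.  The per-cluster FDR is
`Q_i = mean(P_i(0T)) / P_i(2T)` over 100 subsamples of the pseudo-site
cluster set drawn at the real set's size (without replacement when the
pseudo set is large enough), clamped to [0, 1], with `Q = 0` when
`P_i(2T) = 0`.  Replicate reproducibility replaces the published IDR
procedure with a documented criterion behind the same interface: a cluster
survives iff the other replicate has a cluster within 24 nt and both Q
values are below 0.05; matched pairs merge (higher-R site, R summed).
Surviving clusters are re-expressed as fixed windows of offsets −24..+24
(49 positions as literally defined; the off-by-one ambiguity of a "48-nt"
window is resolved in favor of the stated offsets).

## Cross-strain reference (`apadiv.reference`, `apadiv.liftover`)

Liftover is computed from the VCF-derived block chain rather than UCSC
chain files: outside variants the genomes are colinear; positions inside a
strain-specific deletion are unmappable.  A window lifts over only
*colinearly* — both endpoints map, the mapped span keeps its length (no
indel inside), and the round trip restores the original endpoints.  A
cluster survives the mappability filter iff its strand-aware −124..+24
flank lifts over this way; at default indel density this removes roughly a
quarter of clusters, the synthetic analogue of the published reciprocal
LiftOver filter.  Survivors from both strains merge in strain-A coordinates
(24-nt representative distance, matching the clustering scale — the source
does not state its merge rule), keeping strain-specific entries as A-only /
B-only.

Annotation assigns each window a gene by overlap (priority protein_coding >
lincRNA > other ncRNA; ties to the longest overlap) and, for protein-coding
genes only, one of the five categories using the representative site:
Terminal within 50 nt of any annotated transcript 3' end; else tandem
3' UTR if inside the last exon of the transcript ending most downstream;
else alternative last exon if inside another transcript's terminal exon;
else internal exon / intronic against the representative transcript.

## Quantification and filters (`apadiv.quantify`)

A 3' mRNA-Seq read counts toward a pAs iff its 5'-end anchor lies inside
the 48-nt window on the same strand (inclusive at both edges); reads
matching no window (mispriming, filtered pAs) are discarded and reported.
F1 and mock reads are assigned to the parental allele with the strictly
smaller mismatch count over the variants their 88-nt footprint overlaps;
ties — including variant-free footprints — are ambiguous, excluded from
allelic counts but retained in totals.

The mock-F1 filter calibrates allelic recovery: with
`p = Total_mock / Total_parental` estimated genome-wide per allele
(replicates pooled), a pAs is dropped when for either allele the lower-tail
exact binomial probability `P(X ≤ mock | n = parental, p)` is below 0.05, or
mock exceeds parental.  The lower tail is the operative one: too few
assignable reads signals poor allelic resolvability, which is the filter's
stated purpose.

Two expression filters are kept as explicit modes rather than silently
reconciled: *parental* (gene eligible when ≥2 pAs carry ≥10 reads from the
two strains together and per-strain totals over those pAs reach 20) and
*allelic* (pAs eligible when its per-allele replicate-mean count is ≥5 for
both alleles; gene needs ≥2 such pAs and per-allele totals ≥20).  In the
allelic analysis the mock filter is applied **before** the expression
filter, so the ≥2-pAs structure is evaluated on the pAs that actually
remain — otherwise a gene reduced to one surviving pAs would produce a
degenerate usage of 100% in both alleles and masquerade as a trans call.

## Divergence testing and cis/trans calls (`apadiv.divergence`)

Usage is compared per pAs with a two-sided Fisher exact test on the 2×2
table [pAs reads, other-pAs-of-gene reads] × condition, replicates summed.
This is a deliberately fully-specified surrogate for a dispersion-aware
per-bin model (DEXSeq in the source analysis): it has no overdispersion
handling, which on replicate-summed synthetic data (multinomial within
gene) is exact, and it sits behind a plain interface so a beta-binomial
variant could be substituted for real data.  P-values are BH-adjusted
within each family (parental tests together; allelic tests together);
divergence requires adjusted p < 0.01 and |Δusage| > 10 points.

Classification per parental-divergent pAs: *cis* when the allelic
comparison is itself divergent at the same thresholds with the same sign;
*trans* when the allelic comparison is clearly null (adjusted p > 0.05 and
|allelic Δ| < 5 — criteria of this package, as the source states none); the
remainder *ambiguous*; non-divergent pAs are *conserved*.  Same-direction
agreement is required for cis.

The coding/non-coding contrast groups alternative-last-exon, internal-exon
and intronic pAs (coding-affecting) against tandem-3'UTR and terminal pAs,
and applies a two-sided Fisher test to the divergent/non-divergent × group
table.

## Flank features (`apadiv.flank`)

Flanks are transcript-oriented RNA sequences of offsets −100..+100 per
allele (genome A directly; genome B through the chain), with element
windows AUE [−100,−40), CUE [−40,0), CDE (0,40], ADE (40,100].  Controls
are pAs with adjusted allelic p > 0.5 and |Δ| < 5.  Variant density counts
each variant once at its leftmost reference position; the full-flank
density uses the 200-position region [−100,100), which also fixes the
8-nt sliding-window count at 193.  Sliding windows are compared cis vs
control by Mann–Whitney U with Bonferroni correction over all windows.

Hexamer quadrants: within the cis set, group 1 (usage biased toward BL) and
group 2 (toward SP) each contribute summed per-pAs allelic differences
(BL − SP) in hexamer occurrences over the chosen 100-nt side; hexamers more
frequent in the higher-usage allele in both groups are enhancer candidates,
the reverse repressors, ranked by the group-1 − group-2 difference.  Motif
analyses treat a hexamer as *intact* on exact match within the region and
*mutated* when intact in exactly one allele; the presence-effect comparison
orients Δusage to the motif-bearing allele.  The poly(U) analysis groups
pAs by the disrupted allele's maximal U-run length against an
intact-in-both background and orients Δusage to the intact allele.

## Structure (`apadiv.structure`)

The default folding backend is Nussinov base-pair maximization
(Watson–Crick plus G·U wobble, minimum hairpin loop 3, −1 per pair),
chosen because the analysis only compares *relative* stability between two
alleles of the same window; it is exact for its own model and verified
against exhaustive structure enumeration.  An adapter passes sequences to
an external RNAfold binary when thermodynamic energies are wanted; all
group logic is backend-agnostic.  Allelic ΔMFE (BL − SP) per element
window is compared between usage-biased groups and controls by two-sample
Kolmogorov–Smirnov.

PARS scores are `log2((V1 + 5) / (S1 + 5))` per base after scaling both
probe libraries to equal totals (pseudocount and normalization are this
package's constants; the upstream method's exact values are not restated in
the source).  The metagene averages scores per sense offset across pAs,
optionally restricted to each gene's most downstream (distal) pAs.

## Problem sizes and validation

The standing study (`analysis/common.py`) uses 2 × 900 kb chromosomes, 300
genes, 600 k reads per sample — small enough that the full driver sequence
runs in a few minutes while every stage keeps enough events to measure.
The verification suites use focused configurations per question (e.g. 200
genes at per-gene depth 2,000 with Δ = 30 effects for recovery; 500 genes
with no effects for error control; ~500 true pAs with 20% internal noise
for the empirical FDR).  Recovery of planted effects is reported in two
parts: the fraction of *tested* planted events called divergent, and
classification accuracy among events that survive the allelic filters —
filter attrition (variant-free pAs, collapsed gene structures) is a
property of allele-informativeness and is measured separately by the
mock-filter metrics.

## What the generator does not emulate

No sequencing errors, no PCR duplicates, no base-quality information, no
overdispersion between biological replicates beyond multinomial sampling,
no alignment artifacts (alignment is abstracted to tailmap records), no
3' UTR sequence composition bias, and gene architectures are stylized.
Passing tests therefore demonstrate that the pipeline's statistics and
bookkeeping are correct under the stated model — not that the thresholds
would have identical operating characteristics on real libraries, where
overdispersion would make the Fisher surrogate anticonservative.

## Known limitations

* The reproducibility criterion is simpler than a full IDR model; both sit
  behind `reproducibility_filter` so an IDR implementation can be swapped in.
* The Nussinov surrogate's energies are not thermodynamic; only allelic
  contrasts should be interpreted.
* Base-wise flank comparisons (hexamer differences, motif mutation) read
  the two alleles at aligned coordinates; indel-containing flanks shift the
  alignment downstream of the indel, which adds noise to (but does not
  bias) the group-level statistics.
* The cross-strain merge rule and several thresholds (trans criteria,
  pseudocounts) are this package's documented choices where the source
  method is silent; all are configurable.
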