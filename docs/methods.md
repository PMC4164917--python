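# Methods

This note documents the models, rules and numerical choices behind
`sagphage`, and what the synthetic study does and does not show.

## Problem setting

Single-cell amplified genomes (SAGs) of uncultivated bacteria often
co-assemble the genomes of the viruses infecting the sorted cell. The
pipeline (i) recognises viral contigs inside SAG assemblies, (ii)
annotates remnants of *past* infections (CRISPR repeat-spacer arrays,
defective prophages), (iii) uses detected viruses and their hosts as
recruitment platforms to classify presence and estimate abundance across
metagenomes, and (iv) compares viral genomes to each other (genus
clustering, clonality) and statistically tests co-infection patterns.

## Viral-contig detection

Four detectors, combined by precedence (reference-based evidence first):

1. **Hallmark genes.** Case-insensitive substring match of annotation
   text against virion-diagnostic keywords: *virion structure*, *capsid*,
   *portal*, *tail*, *terminase*. A short stop-list ("tailless",
   "capsid-less") guards obvious negations. One matching gene flags the
   whole contig.
2. **Guilt by association.** A contig is viral when at least 50 % of its
   genes have a qualifying protein hit (e-value ≤ 1e-3 **and** bit
   score ≥ 50 — the pipeline-wide qualifying thresholds) to genes of a
   single already-detected viral contig. Newly flagged contigs become
   references and passes repeat to a fixpoint; flagging is monotone in
   the reference set, so the fixpoint is order-independent. A pooled-
   reference mode is available but off by default.
3. **Virome support.** At least three distinct genes each matched at
   ≥ 90 % protein identity by viral-metagenome sequences.
4. **Gene architecture.** All windows of ≥ `min_region_genes`
   (default 8) consecutive genes in which ≥ 50 % of genes are
   uncharacterized and ≥ 80 % of the window's genes lie on one strand
   are enumerated; overlapping qualifying windows are merged, so each
   reported region is a maximal union. Strand coherence is measured over
   *all* genes in the window by default: measuring it over the
   uncharacterized genes alone (also available) barely separates
   operon-structured host contigs from phage-like runs, because the few
   uncharacterized genes in a host window usually share an operon.

A gene is *uncharacterized* when it has no domain hit with
e-value ≤ 1e-3 and score ≥ 30. Contig metrics (average gene size,
strand-change ratio, uncharacterized ratio) use the convention that the
strand-change count is divided by the *total* gene count, not by the
number of adjacent pairs.

**Classification.** Hallmark/association/virome evidence labels a contig
`viral_hallmark`. Architecture regions covering ≥ 90 % of the contig's
genes — on a contig that is itself ≥ 50 % uncharacterized — label it
`viral_putative`; the 90 % (rather than 100 %) absorbs genomes with a
short opposite-strand gene island, which yield two abutting regions
instead of one. Smaller regions leave the contig
`microbial` and are carried forward as prophage candidates.

## Past infections

**CRISPR arrays** are found by exact 8-mer seeds recurring at periods of
39–108 bp (repeat+spacer bounds), chained greedily and extended to
maximal repeats (all copies must agree per column). Accepted arrays need
≥ 3 repeats of 19–48 bp, spacers of 20–60 bp, strict repeat/spacer
alternation and ≥ 85 % repeat-to-consensus identity; overlapping
candidates resolve to the most repeats, then the longer span. These
bounds follow common repeat-recognition defaults and are all keyword
arguments. Spacers are then searched against every contig (both strands,
own-array footprint masked) at ≥ 95 % identity over ≥ 95 % of the spacer.

**Defective prophages.** The architecture scan deliberately over-reaches
(it unions every qualifying window), so each embedded candidate region is
refined before promotion: characterized edge genes are trimmed, exact
20-mer anchors (sampled index, probe step coprime to the index stride)
nominate microbial contigs of *other* SAGs sharing sequence, and 500-bp
chunk alignments locate the longest conserved stretch. The region is
promoted iff that conserved core spans ≥ 2 kb and ≥ 50 % of the refined
region at ≥ 95 % identity, with microbial genes flanking it on both
sides. This automates, with explicit thresholds, a curation step that
was originally manual ("is this viral-like region conserved between
closely related bacterial contigs?"); the 95 %-identity proxy for
"closely related" is recorded in the output.

**Disjointness.** Past-infection sequences (spacers, prophage regions)
are compared with all current-infection viral contigs: spacers at the
spacer-match thresholds, prophage regions at ≥ 80 % identity over
≥ 500 bp (tested by tiling into 500-bp chunks at 250-bp steps; stretches
≥ 1 kb are detected reliably, isolated exactly-500-bp matches can
straddle chunk boundaries). An empty report means no past-infection
sequence matches a current virus.

## Recruitment and abundance

**Protein mode** (viral references): metagenome predicted proteins — or
raw reads, six-frame translated into stop-free peptides ≥ 10 aa — are
aligned to reference gene proteins. Candidate pairs come from shared
exact amino-acid 5-mers; each candidate is scored by Smith-Waterman
(BLOSUM62, gap open 11 / extend 1) and each read is assigned to at most
one gene (best bit score; ties to the lowest gene coordinate), with the
full alignment computed only for that best pair. Qualifying hits need
e-value ≤ 1e-3 and bit ≥ 50; bit scores and e-values use gapped
Karlin-Altschul parameters λ = 0.267, K = 0.041 for this scoring system,
with the search-space size an explicit parameter. Identity is matching
columns over alignment columns; `X` never counts as a match.

**Presence.** With f_high the fraction of reference genes whose best hit
exceeds 80 % identity and f_mid the fraction at ≥ 60 %: *present* iff
f_high > 0.75; else *related* iff f_mid > 0.75; else *absent* — except
that an absent call for an ssDNA reference in a linker-amplified
metagenome is *inconclusive* (that library chemistry selects against
ssDNA templates; positive detection still counts). The 0.75 boundary is
strict ("more than 75 %"), so 15 of 20 genes is absent.

**Nucleotide mode** (host contig sets): a mummer-style mapper — maximal
exact matches ≥ 20 bp, chained co-linearly with gaps ≤ 500 bp, chains
with < 100 anchored bp discarded, per-cluster identity from an
end-to-end (edlib) alignment of the spanned segments. Each read counts
once (best cluster). A gene is covered when ≥ 50 % of its span lies
under accepted clusters; ANI is the length-weighted mean cluster
identity. Host presence requires > 75 % of genes covered at ANI > 95.
Note the anchor arithmetic: at 90 % nucleotide identity a read needs
several hundred bp before ~100 bp of clean 20-mers are expected, so
short-read sets diverge from a reference faster than their true identity
suggests — the identity *of accepted clusters* remains unbiased.

**Abundance.** Relative abundance = recruited bases / reference bp /
(metagenome Mb), with metagenome size the total bases of the read set.
The virus-to-host ratio divides the viral by the host relative abundance
for the same SAG and is *missing* (not 0) when the host abundance is 0.
Identity distributions of qualifying hits (≥ 80 %) are summarised with
type-7 (linear-interpolation) quartiles and the 1.5×IQR outlier rule.
Coverage profiles are per-window means over non-overlapping windows
(≥ 100 bp).

## Comparative analyses

**Genus clustering.** The shared-gene fraction of two genomes is the
mean of the two directed fractions (genes with a qualifying hit in the
other genome over genome size); a min-denominator mode exists. Genera
are single-linkage connected components at fraction ≥ 0.40 (equality
joins: sharing *less than* 40 % is what separates genera).

**Clonality** reports the minimum pairwise global nucleotide identity of
a genome set; circular genomes are compared after rotation/strand
normalisation (infix alignment against the doubled sequence). Clonal
means exactly 100.

**Fisher exact test.** Two-sided p by hypergeometric enumeration with
the probability-mass convention: the sum over tables with the observed
margins whose probability is ≤ that of the observed table, with relative
tolerance 1e-7 on the comparison to absorb floating-point ties. Checked
exhaustively against exact integer-arithmetic enumeration for all tables
with N ≤ 40 (tests) and N ≤ 25 (acceptance script). Calibration uses
1000 null co-occurrence tables of 500 SAGs at infection probability 0.3
for both viruses: at that size the discrete test is near-nominal
(rejection ≈ 4–5 % at α = 0.05); at a few dozen SAGs Fisher is markedly
conservative, which is a property of the test, not of the
implementation.

## Synthetic-data generator

All randomness flows from one `numpy` Generator seeded by the scenario
config; identical configs give byte-identical output, and every planted
feature is recorded in a ground-truth object.

* **Hosts:** 2 contigs × 60 genes per SAG; gene lengths log-normal
  (median 800 bp, σ_log 0.25); 70 % of genes characterized; operon
  blocks of geometric length (mean 5) with alternating strands, so the
  expected strand-change ratio is 1/5.
* **Viruses:** tailed dsDNA phages 15–60 kb, linear, hallmark capsid /
  terminase / portal genes always annotated with their keyword products;
  ssDNA microviruses 4.5–6.5 kb, circular, gene-dense (median gene
  450 bp, ≥ 8 genes). Uncharacterized fraction 0.7; dsDNA phages keep
  the strand with probability 0.95 per gene, while the ssDNA
  microvirus is fully strand-coherent (its real counterparts encode
  essentially everything on one strand).
* **Infections:** current-infection probability per SAG 0.08 / 0.28 /
  0.47 at 100 / 150 / 185 m (an oxygen-minimum-zone-like gradient);
  40 % of deep infections are the microvirus, which carries a linked
  podovirus with probability 0.9 (the co-infection signal); prophage
  probability 0.15 per SAG (blocks of 8–12 viral genes, annotations
  masked, conserved in a second SAG); CRISPR probability 0.2, one spacer
  copied from a *past* virus. Past viruses are distinct genomes from
  every current virus unless the deliberate-overlap scenario is enabled.
  CRISPR arrays and prophages are planted into microbial contigs only.
* **Arrays** are boundary-unambiguous by construction: spacers and
  flanks are rejection-sampled so the columns just outside each repeat
  copy are heterogeneous, making exact-repeat extension stop exactly at
  the planted boundaries. Detection recall on such arrays is a clean
  test of the chaining logic, not of boundary heuristics.
* **Mutation at controlled identity** substitutes a computed number of
  positions (nucleotide level) or whole codons non-synonymously, never
  creating stops (amino-acid level), so realized identity is exact and
  nucleotide/protein identities stay consistent.
* **Metagenomes** are substitution-only reads (default 250 bp, error
  0.5 %), genome drawn ∝ length × copy number, uniform starts, circular
  wrap-around, strands at random. No indels, no platform error profiles,
  no amplification bias: recruitment thresholds are identity-based, so
  substitution-only noise exercises every decision boundary the pipeline
  has.

**What passing tests show — and do not.** The generator reproduces the
*statistical contrasts* the detectors rely on (gene size, strand
coherence, characterization), not real genomes: there are no mosaic
phage genomes, no shared host-virus genes (auxiliary metabolic genes),
no assembly chimeras or MDA coverage bias, and annotation text is drawn
from a tiny vocabulary. Recovery results therefore validate the rules
and their implementation, not real-data performance.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale versions of the study:
30 SAGs (~3.4 Mb of host sequence), an 18-kb reference for presence
recovery (50 replicates × 3 identity targets at 10× gene coverage),
~16 000 nucleotide reads for ratio recovery (≈ 50× per planted copy, so
the rarest virus at ratio 0.01 still recruits ~100 reads and Poisson
noise stays inside the ±25 % recovery band), exhaustive Fisher
enumeration to N = 40, and 20 seeded genus scenarios. Quartiles are
type 7; the window-scan and Fisher implementations are each verified
against independently written brute-force oracles; alignment identity
ties in ORF selection break by descending length, then leftmost
coordinate, then '+' strand.

## Known limitations

* The protein search is seeded by exact k-mers (k = 4–5): sensitivity
  decays below ~50 % amino-acid identity, which is harmless here because
  qualifying thresholds reject such hits anyway, but it is not a full
  Smith-Waterman database search.
* E-values use fixed Karlin-Altschul constants for BLOSUM62 11/1;
  other matrices would need their own constants (bit-score thresholds,
  which the pipeline's rules actually use, are robust to this).
* The CRISPR finder requires exact seed k-mer matches within an array;
  heavily mutated repeats (below ~85 % identity between copies) are out
  of its design envelope.
* `find_crispr_arrays` and the prophage conservation check are quadratic
  in contig count at worst; they are meant for SAG-scale assemblies
  (tens of Mb), not whole metagenome co-assemblies.
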