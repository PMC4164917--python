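# sagphage

Finding viruses inside single-cell amplified genomes (SAGs) of
uncultivated bacteria, and tracking those viruses across metagenomes.

Single-cell genomics co-assembles, alongside a sorted cell's chromosome,
the genomes of whatever viruses were infecting it. That turns a SAG
collection into a direct census of virus-host pairs in nature — if the
viral contigs can be recognised, past infections separated from current
ones, and the resulting references used quantitatively. `sagphage`
implements that pipeline for desk-scale data, together with a fully
seeded synthetic-data generator that plants every feature with ground
truth, so each rule is testable against a known answer.

## What it computes

* **Viral-contig detection** — hallmark virion genes (capsid, portal,
  tail, terminase, virion structure); guilt-by-association (≥ 50 % of
  genes similar to a detected viral contig, e-value ≤ 1e-3 and bit ≥ 50,
  iterated to a fixpoint); virome read support (≥ 3 genes at ≥ 90 %
  protein identity); and a reference-free gene-architecture scan for
  regions of ≥ 8 genes that are ≥ 50 % uncharacterized with ≥ 80 % of
  genes on one strand.
* **Past infections** — CRISPR repeat-spacer arrays (≥ 3 repeats of
  19–48 bp, spacers 20–60 bp), spacer-to-contig matching (≥ 95 %
  identity over ≥ 95 % of the spacer), defective prophages (embedded
  viral-like regions conserved at ≥ 95 % identity in a microbial contig
  of a different SAG), and a disjointness check of past vs current
  infection sequences.
* **Recruitment ecology** — presence classification per reference and
  metagenome (*present*: > 75 % of genes detected at > 80 % amino-acid
  identity; *related*: the same fraction at 60–80 %; *absent*
  otherwise; *inconclusive* for ssDNA references in linker-amplified
  libraries), mummer-style nucleotide recruitment for hosts (ANI > 95
  over > 75 % of genes), relative abundance (recruited bases per
  reference bp per metagenome Mb) and virus-to-host ratios, identity
  distributions with Tukey-style hinges, and coverage profiles.
* **Comparative statistics** — phage genus clustering at ≥ 40 % shared
  genes (single linkage), clonality with circular-rotation
  normalisation, and 2×2 co-infection tables with a two-sided Fisher
  exact test computed by hypergeometric enumeration.

## Worked example

The numbered drivers under `analysis/` run the default synthetic study
(30 SAGs across a 100/150/185 m depth gradient) end to end:

```bash
python analysis/01_simulate_community.py --seed 7
python analysis/02_detect_viruses.py     --seed 7
python analysis/03_past_infections.py    --seed 7
python analysis/04_recruitment_dynamics.py --seed 7
python analysis/05_comparative.py        --seed 7
```

Step 02 prints (seed 7):

```
Hallmark detection: 19/19 planted viral contigs (recall 100%)
Architecture scan on masked annotations: recall 100%, FDR 0%
Metric separation (viral vs microbial means): uncharacterized 0.67 vs 0.31,
strand-change 0.04 vs 0.20, gene size 558 vs 821 bp
```

i.e. every planted virus carries a detectable hallmark gene; with all
annotations masked (a genome absent from every database) the
architecture scan alone still recovers them, and the three contig
metrics separate viral from microbial contigs in the expected
directions — shorter genes, fewer strand changes, more uncharacterized
genes on the viral side.

Step 04 tracks one viral reference across three metagenomes and recovers
a planted virus:host abundance ratio:

```
metagenome   state  frac_genes_gt80  frac_genes_ge60
   mg_2009 present            1.000              1.0
   mg_2010 related            0.107              1.0
   mg_2011  absent            0.000              0.0

Mixed metagenome (9070 reads): host RA 17.51, virus RA 5.67,
virus:host ratio 0.324 (planted 0.30)
```

The metagenome containing the virus itself is *present* (all genes
> 80 % identity), the one containing a 70 %-identity relative is
*related*, and the one without it is *absent*; the recovered
virus-to-host ratio (0.324) sits within ~8 % of the planted 0.30.

Step 05 places each of the four planted viral genomes in its own genus,
finds the Microviridae copies recovered from five different SAGs to be
clonal (minimum pairwise identity 100 % after rotation normalisation),
and rejects independence of ssDNA/dsDNA co-infection (Fisher exact
p ≈ 1e-3 on 20 deep SAGs).

## Layout

```
src/sagphage/     the library: models, io, orfs, align, detection,
                  past, recruitment, comparative, simulate
analysis/         numbered narrative drivers (write tables to results/)
scripts/          acceptance.py
tests/            pytest suite, including end-to-end recovery checks
docs/methods.md   models, thresholds, generator design, limitations
```
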