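# bryostruct

Comparative genome-structure analysis for haploid plant genomes, built
around the questions raised by Marchantiopsida liverworts: why do these
genomes stay small, collinear and slow-changing? The package quantifies
four signals between a pair of genomes such as *Marchantia polymorpha*
and *Lunularia cruciata*:

- **Duplicate genes** — paralog pairs from all-vs-all protein
  comparison, the percent-duplicated statistic (duplicated genes over
  genes whose protein exceeds 150 aa), and tandem vs dispersed
  classification.
- **Collinearity** — single-copy ortholog anchors chained into synteny
  blocks in gene-rank space under the two MCScanX-style knobs *s*
  (minimum anchors per block) and *m* (maximum gap in genes), percent
  collinear, its decay against divergence time, scaffold-to-chromosome
  assignment, and inversion counts from minus-oriented blocks.
- **TE landscapes** — per-copy divergence from family consensus (Kimura
  2-parameter on a global alignment), abundance binned in 1% divergence
  intervals per superfamily, bp-weighted kernel densities per family,
  amplification-burst detection as KDE modes, weighted skewness, and
  full-length vs solo vs truncated LTR retrotransposon calls.
- **U/V gametologs** — Lunularia orthologs of Marchantia gametolog
  pairs classified phylogenetically (U, V, or O when the two Marchantia
  gametologs are mutually closest) from neighbor-joining quartets, and
  genomically (U-linked / V-linked / autosomal) from presence in
  female and male genome assemblies; the two labels combine to call
  U-to-autosome translocations with V-gametolog loss.

Because real analyses of this kind need multi-hundred-Mb assemblies,
the package bundles a seeded genome-evolution **simulator** that
generates two diverged lineages (logged inversions, translocations,
duplications, losses; Jukes–Cantor sequence divergence), TE copy
populations with configured burst ages, and gametolog loci with
optional translocation — all with exact truth tables, so every stage
can be validated end-to-end.

## Worked example

Simulate a dataset and measure collinearity between the two lineages:

```bash
$ bryostruct simulate --seed 42 --outdir demo
$ bryostruct synteny --anchors demo/anchors.tsv \
      --gffa demo/lineageA.gff3 --gffb demo/lineageB.gff3 -s 5 -m 25
n_anchors	391
n_dropped_pairs	0
n_blocks	13
percent_collinear	98.21
n_inverted_blocks	8
```

391 single-copy ortholog pairs survive the simulated rearrangements;
13 blocks of ≥5 anchors absorb 98.21% of them, and 8 blocks run in
reversed orientation — the footprint of the simulated inversions (5 per
lineage by default, some too short or too disrupted to chain).

Classify the simulated gametolog loci and call translocations:

```bash
$ bryostruct uvclass --loci-dir demo \
      --female-genome demo/female_genome.fasta \
      --male-genome demo/male_genome.fasta
locus	phylo	support	genomic	same_gametolog
gam001	U	0.0872	U-linked	0
gam002	U	0.0914	U-linked	0
...
pa010	O	0.1241	autosomal	1
# translocation_candidates	["gam019", "gam030", "gam039", "gam040"]
```

Nonrecombining gametologs come out U/V and sex-linked; pseudoautosomal
loci come out O and autosomal with the same gametolog in both sexes
(`1`); the four loci simulated as translocated from the U to an
autosome — phylogenetically U yet present in both sex genomes, with the
V partner lost — are exactly the four candidates called.

The TE landscape of the same dataset recovers the two configured
Ty3/Gypsy bursts:

```bash
$ bryostruct telandscape --rm-out demo/repeats.out
...
burst_mode	5.05	0.0472	0.0472
burst_mode	24.73	0.0466	0.0235
skewness	0.0094
```

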