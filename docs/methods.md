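# Methods

`bryostruct` quantifies structural genome evolution between haploid
plant genomes — in its motivating use case, Marchantiopsida liverworts
such as *Marchantia polymorpha* and *Lunularia cruciata*. It covers four
analyses (duplicate genes, collinearity, transposable-element
landscapes, U/V gametologs) plus a genome-evolution simulator that
generates every input with exact ground truth. This note records the
models, the defaults, the numerical choices, and what the simulated
validations do and do not establish.

## Sequence evolution model

All simulated sequence change is Jukes–Cantor (JC) substitution: along a
branch of depth *d* (expected substitutions/site) each site mutates with
probability `p = 3/4·(1 − e^(−4d/3))`, uniformly to one of the other
three bases. There are no indels in gene or locus sequences — a
deliberate restriction that keeps every divergence recoverable in closed
form and makes truth tables exact. Two diverged lineages are produced by
mutating each by *d*/2 so that the expected pairwise ortholog distance
equals the configured `speciation_depth` (default 0.10).

Divergence is *estimated* with the Kimura two-parameter (K2P) distance
on a global alignment (transitions and transversions counted separately;
indel columns excluded). K2P applied to JC-generated data recovers the
JC depth, so the estimator and the generator are deliberately not the
same formula — the estimate is a genuine inference, not an echo. An
uncorrected p-distance is selectable. Alignment uses match +2 /
mismatch −3 with affine gaps −7/−2: gap costs are set well above the
mismatch cost because a unit-cost edit distance absorbs substitutions
into spurious indel shifts and biases distances downward by several
points at 20% divergence. Estimates above 50% are refused as saturated
(`SaturationError`): beyond that the correction is unreliable and
homology is doubtful — a sequence compared against its own reverse
complement lands here rather than returning a number.

## Simulator

The ancestor is `n_chromosomes × genes_per_chromosome` genes (default
4×100) of random fully coding sequence (900 bp → 300 aa proteins), laid
on chromosomes with fixed 200 bp spacers. Each lineage then receives a
fixed number of logged events, applied sequentially with uniformly drawn
breakpoints: inversions (reverse a run of 2–20 genes and flip strands),
translocations (move a run of 1–10 genes to another chromosome), tandem
duplications (insert a copy, mutated at depth 0.02, adjacent to its
source), dispersed duplications (insert the copy at a distant position),
and losses. Event counts are integers rather than rates so conservation
(`genes_out = genes_in + duplications − losses`) and per-event truth are
exact. Duplication events prefer sources not yet involved in a
duplication, so a configured count plants an exact coverage fraction.

TE copy populations are generated per burst: each copy's JC depth is
drawn from Normal(mode, sd) truncated at zero (defaults 5%/25% Ty3/Gypsy
bursts and a 15% Ty1/Copia burst, 3 kb copies — modes in the range real
repeat landscapes show). The truth table stores the *realized* JC
divergence (the JC-corrected Hamming fraction actually produced), which
is what the estimator should recover. Burst modes at or beyond 75% are
rejected (JC saturation).

Gametolog loci (1 kb) follow a two-split history: the ancestral gene
splits into U and V copies at `sexchrom_depth` (0.20), each of which
splits into Marchantia- and Lunularia-side copies at `speciation_depth`
(0.10); depths are per-branch, so the U–V pairwise distance is about
2×0.20 and the internal branch of the quartet is 2×(0.20−0.10).
Pseudoautosomal loci split only at the species level, with a shallow
within-species depth (0.002) separating female and male copies — the
closed-form expected identity, 1 − 3/4·(1 − e^(−4·0.004/3)) ≈ 99.6%,
is what makes the ">99% identical opposite-sex scaffold" criterion
meaningful. Outgroup-type loci ("post-speciation duplicates") invert the
splits so the two Marchantia gametologs are mutually closest.
Translocated loci place the Lunularia U copy on an autosomal scaffold
present in both sexes and delete the V copy; autosomal scaffolds share
their spacer sequence between the sexes so that presence/absence, not
assembly artefacts, carries the signal.

## Duplicate genes

A gene is duplicated when its protein pairs with another at ≥30%
identity over ≥50% of the shorter protein (Smith–Waterman, BLOSUM62,
gap open −11 / extend −1), behind a shared 5-mer prefilter (≥2 shared
k-mers); oracle mode disables the prefilter and aligns every pair. The
headline statistic divides duplicated genes by genes whose protein is
*strictly longer than* 150 aa. Pairs are tandem when on one scaffold
with ≤5 intervening genes (rank distance − 1), else dispersed. The
identity/coverage defaults are pragmatic stand-ins for homology-search
criteria that published analyses usually delegate to BLAST-style
E-values; they are exposed in `DuplicationParams` and validation is
against simulator truth, not against any published table.

## Collinearity

Anchors are single-copy ortholog pairs joined onto per-scaffold gene
ranks (ties on start broken by end, then id). A collinear block is a
chain of anchors monotone on both genomes with at most `m` intervening
ranks between consecutive anchors *on each genome* (the symmetric
reading of "maximum gaps allowed") and at least `s` anchors. Chaining
repeatedly extracts the best chain per scaffold pair — most anchors,
ties by smaller total gap, then leftmost start, then plus orientation —
removes its anchors, and repeats; blocks are anchor-disjoint and
mixed-orientation chains are forbidden, so an inversion yields a
separate minus-oriented block. The dynamic program is exact for this
objective; an exhaustive enumerator over all valid chains serves as an
independent oracle on small instances. MCScanX's internal scoring
(match/gap scores, block E-values) is intentionally not reproduced: `s`
and `m` are the operative knobs, and validation is oracle equivalence
plus truth recovery, not bit-parity with another tool. Divergence times
attached to decay points are user-supplied metadata (literature values
such as 220 Ma for the liverwort pair), never computed.

Scaffold-to-chromosome assignment reports, for every scaffold with at
least 10 orthologous hits, the modal chromosome, its hit fraction and
hit count; ties resolve to the lexicographically smallest name and are
flagged.

## TE landscapes

Landscapes accumulate masked bp into half-open divergence bins (default
1%) per superfamily; conservation (Σ bins = Σ hit lengths) is exact by
construction. Family densities are Gaussian KDEs of copy divergence
weighted by copy length — families are ranked by total bp, not copy
number, because the question is genome-size contribution. Burst
detection finds local maxima of the weighted KDE (Silverman bandwidth,
1024-point grid padded with zeros so boundary modes count) with
prominence ≥10% of the global maximum; fewer than 30 copies is refused
rather than over-interpreted. Skewness is the adjusted Fisher–Pearson
third moment, weighted, with the effective sample size `(Σw)²/Σw²` in
the small-sample correction; unweighted it matches
`scipy.stats.skew(bias=False)` exactly. Full-length LTR elements
require both LTRs, each ≥100 bp, at ≥85% global identity (indel columns
as mismatches); one LTR is a solo, anything else truncated.

## Gametologs

Trees are neighbor-joining on pairwise K2P distances (scikit-bio) —
deterministic, which a Bayesian MCMC stand-in would not be; externally
built Newick trees can be supplied instead. Classification reads the
single non-trivial split of the {Lc, MpU, MpV, outgroup} quartet:
{Lc,MpU} → U, {Lc,MpV} → V, {MpU,MpV} → O, with the internal branch
length as support; the split search walks every edge, so the call is
invariant to tip order and rooting. Without an outgroup a closest-pair
fallback compares the three pairwise distances. Genomic labels come
from semi-global (infix) search of the locus against every scaffold of
each sex genome at ≥95% identity over the full query (full-query
alignment subsumes the 80% coverage default); present in both sexes →
autosomal, female-only → U-linked, male-only → V-linked. A
translocation candidate must be phylogenetically U (resolved),
genomically autosomal, and have no V-descended sequence in the male
genome; O loci are excluded by the strict rule, since an outgroup
topology cannot establish U descent.

## Validation scale and limitations

The acceptance experiments run at desk scale, chosen to finish in
minutes on one core while keeping each statistic well-determined:
1,000-gene genomes for decay (11 inversion loads × 10 replicates),
200 random instances × 9 parameter pairs for the chaining oracle, 50
seeds for burst/estimator checks, 100 gametolog loci, 10 translocation
replicates, a 160-gene genome for the duplicate statistic.

What passing shows — and does not. The simulator emulates the
*statistical structure* each stage assumes: JC-divergent single-copy
orthologs, mixture-distributed TE ages, two-split gametolog histories.
It does not emulate indels, assembly fragmentation or chimerism,
annotation error, isoform complexity, GC/CpG mutation bias, nested or
truncated repeat copies, or recombining populations. Recovery rates
near 100% here therefore bound what the algorithms do under their own
model assumptions; on real assemblies the presence thresholds
(0.95/0.80), the tandem gap (5), and the burst prominence rule (10%)
are the knobs most likely to need retuning. Real-scale headline numbers
(e.g. genome-wide percent-duplicated values near 50%, or counts of
full-length LTRs in the thousands) require multi-hundred-Mb assemblies
and are out of this package's validation scope by design.
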