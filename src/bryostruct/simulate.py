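"""Seeded genome-evolution simulator with full ground truth.

Generates two haploid lineages diverged from a common ancestral gene
order through logged inversions, translocations, tandem/dispersed
duplications and gene losses; transposable-element copy populations
whose divergence from consensus reflects configured burst episodes; and
gametolog loci on nonrecombining U/V regions, optionally with a
U-to-autosome translocation accompanied by loss of the V gametolog.

Sequence evolution is Jukes-Cantor substitution only (no indels).  A
"depth" d is an expected number of substitutions per site along a
branch; mutating a sequence to depth d substitutes each site with
probability p = 3/4 * (1 - exp(-4d/3)), choosing uniformly among the
three other bases.  Event counts are fixed integers so that truth tables
are exact.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import (
    GeneRecord,
    RepeatHit,
    write_anchor_table,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TEBurst:
    """One amplification episode of a repeat family.

    ``mode_divergence_pct`` is the burst age expressed as the modal
    Jukes-Cantor distance (in %) of its copies from the family
    consensus; ``sd_pct`` its spread.
    """

    mode_divergence_pct: float
    sd_pct: float
    n_copies: int
    family: str
    superfamily: str = "Ty3/Gypsy"
    copy_length: int = 3000


@dataclass(frozen=True)
class GametologConfig:
    """Gametolog history settings.

    Depths are expected substitutions/site per branch.  Ancestrally
    nonrecombining loci require ``sexchrom_depth > speciation_depth``
    (the U/V split predates the species split).  ``n_outgroup_loci``
    adds loci whose U/V split postdates the Lunularia split, yielding an
    outgroup (O) phylogenetic relationship.  ``pa_within_depth`` is the
    shallow within-species divergence separating female and male copies
    of recombining (pseudoautosomal) loci.
    """

    n_gametolog_pairs: int = 40
    n_pseudoautosomal: int = 10
    n_translocated_U_loci: int = 4
    n_outgroup_loci: int = 10
    speciation_depth: float = 0.10
    sexchrom_depth: float = 0.20
    outgroup_depth: float = 0.40
    pa_within_depth: float = 0.002
    locus_length: int = 1000

    def __post_init__(self) -> None:
        if self.n_translocated_U_loci > self.n_gametolog_pairs:
            raise ValueError(
                "n_translocated_U_loci cannot exceed n_gametolog_pairs"
            )
        if self.sexchrom_depth <= self.speciation_depth:
            raise ValueError(
                "sexchrom_depth must exceed speciation_depth for "
                "ancestrally nonrecombining loci"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration; a fixed seed fixes every output byte."""

    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 100
    n_inversions: int = 5
    n_translocations: int = 1
    n_tandem_dups: int = 5
    n_dispersed_dups: int = 5
    n_losses: int = 5
    inversion_length_distribution: tuple[int, int] = (2, 20)
    translocation_length_distribution: tuple[int, int] = (1, 10)
    speciation_depth: float = 0.10
    dup_divergence: float = 0.02
    seq_length: int = 900
    intergenic_length: int = 200
    te_bursts: tuple[TEBurst, ...] = (
        TEBurst(5.0, 2.0, 300, "Gypsy-1", "Ty3/Gypsy"),
        TEBurst(25.0, 2.0, 300, "Gypsy-1", "Ty3/Gypsy"),
        TEBurst(15.0, 3.0, 200, "Copia-1", "Ty1/Copia"),
    )
    gametolog_cfg: GametologConfig = field(default_factory=GametologConfig)

    def __post_init__(self) -> None:
        for name in (
            "n_inversions", "n_translocations", "n_tandem_dups",
            "n_dispersed_dups", "n_losses",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthTables:
    """Ground truth emitted alongside the simulated data."""

    ortholog_map: list[tuple[str, str]] = field(default_factory=list)
    event_log: list[dict] = field(default_factory=list)
    te_truth: list[dict] = field(default_factory=list)
    gametolog_truth: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence evolution primitives
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def jc_substitution_probability(depth: float) -> float:
    """Per-site substitution probability after a JC branch of given depth."""
    return 0.75 * (1.0 - math.exp(-4.0 * depth / 3.0))


def mutate_jc(rng: np.random.Generator, seq: str, depth: float) -> str:
    """Evolve ``seq`` along a Jukes-Cantor branch of the given depth."""
    if depth <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = jc_substitution_probability(depth)
    hit = rng.random(arr.size) < p
    n = int(hit.sum())
    if n:
        # uniform among the three other bases
        idx = (BASES.searchsorted(arr[hit]) + rng.integers(1, 4, size=n)) % 4
        arr[hit] = BASES[idx]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# genome representation
# ---------------------------------------------------------------------------


@dataclass
class SimGenome:
    """A simulated genome: per-chromosome ordered gene lists + sequences.

    ``chromosomes`` maps chromosome name to an ordered list of
    (gene_id, strand); ``sequences`` maps gene_id to its nucleotide
    sequence (fully coding, length divisible by 3).
    """

    chromosomes: dict[str, list[tuple[str, str]]]
    sequences: dict[str, str]

    def gene_ids(self) -> list[str]:
        return [gid for genes in self.chromosomes.values() for gid, _ in genes]

    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def to_gene_records(self, cfg: SimConfig, prefix: str = "") -> list[GeneRecord]:
        """Lay genes on coordinates with fixed intergenic spacers."""
        records = []
        for chrom, genes in self.chromosomes.items():
            pos = cfg.intergenic_length
            for gid, strand in genes:
                length = len(self.sequences[gid])
                records.append(
                    GeneRecord(
                        gene_id=gid,
                        scaffold=prefix + chrom,
                        start=pos,
                        end=pos + length,
                        strand=strand,
                        exons=((pos, pos + length),),
                        protein_length=length // 3,
                    )
                )
                pos += length + cfg.intergenic_length
        return records

    def scaffold_sequences(self, cfg: SimConfig, rng: np.random.Generator
                           ) -> dict[str, str]:
        out = {}
        for chrom, genes in self.chromosomes.items():
            parts = []
            for gid, _ in genes:
                parts.append(random_sequence(rng, cfg.intergenic_length))
                parts.append(self.sequences[gid])
            parts.append(random_sequence(rng, cfg.intergenic_length))
            out[chrom] = "".join(parts)
        return out


# ---------------------------------------------------------------------------
# ancestor and lineage evolution
# ---------------------------------------------------------------------------


def simulate_ancestor(cfg: SimConfig) -> SimGenome:
    """Generate the ancestral genome: random coding sequences on
    ``n_chromosomes`` chromosomes of ``genes_per_chromosome`` genes each."""
    if cfg.n_chromosomes * cfg.genes_per_chromosome == 0:
        raise ValueError("ancestor must contain at least one gene")
    rng = np.random.default_rng(cfg.seed)
    seq_length = 3 * max(1, cfg.seq_length // 3)
    chromosomes: dict[str, list[tuple[str, str]]] = {}
    sequences: dict[str, str] = {}
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        genes = []
        for g in range(cfg.genes_per_chromosome):
            gid = f"anc_{c + 1}_{g + 1:04d}"
            genes.append((gid, "+" if rng.random() < 0.5 else "-"))
            sequences[gid] = random_sequence(rng, seq_length)
        chromosomes[chrom] = genes
    return SimGenome(chromosomes=chromosomes, sequences=sequences)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def evolve_lineage(
    genome: SimGenome, cfg: SimConfig, lineage_id: str
) -> tuple[SimGenome, list[dict]]:
    """Apply the configured rearrangement/duplication/loss events to a copy
    of ``genome`` and mutate all sequences toward the speciation depth.

    Events are applied sequentially in log order with breakpoints drawn
    uniformly among valid positions.  Inversions reverse a contiguous
    gene run and flip strands; translocations move a run to another
    chromosome; tandem duplications insert a mutated copy adjacent to
    its source; dispersed duplications insert at a random distant
    position; losses delete a gene.  Each lineage is mutated by half the
    speciation depth so the expected pairwise ortholog distance between
    two lineages equals ``speciation_depth``.
    """
    rng = np.random.default_rng((cfg.seed, zlib.crc32(lineage_id.encode())))
    chroms = {c: list(genes) for c, genes in genome.chromosomes.items()}
    seqs = dict(genome.sequences)
    log: list[dict] = []
    names = list(chroms)
    dup_counter = 0
    dup_involved: set[str] = set()

    def pick_segment(min_len: int, max_len: int, kind: str) -> tuple[str, int, int]:
        candidates = [c for c in names if len(chroms[c]) >= min_len]
        if not candidates:
            raise ValueError(f"no chromosome can host a {kind} of {min_len}+ genes")
        chrom = candidates[int(rng.integers(len(candidates)))]
        n = len(chroms[chrom])
        seg_len = int(rng.integers(min_len, min(max_len, n) + 1))
        start = int(rng.integers(0, n - seg_len + 1))
        return chrom, start, seg_len

    events = (
        ["inversion"] * cfg.n_inversions
        + ["translocation"] * cfg.n_translocations
        + ["tandem_dup"] * cfg.n_tandem_dups
        + ["dispersed_dup"] * cfg.n_dispersed_dups
        + ["loss"] * cfg.n_losses
    )
    for etype in events:
        if etype == "inversion":
            lo, hi = cfg.inversion_length_distribution
            chrom, start, seg_len = pick_segment(lo, hi, "inversion")
            seg = chroms[chrom][start:start + seg_len]
            chroms[chrom][start:start + seg_len] = [
                (gid, _flip(st)) for gid, st in reversed(seg)
            ]
            log.append({"lineage": lineage_id, "type": etype, "chrom": chrom,
                        "start": start, "n_genes": seg_len,
                        "genes": [g for g, _ in seg]})
        elif etype == "translocation":
            if len(names) < 2:
                raise ValueError("translocation requires >= 2 chromosomes")
            lo, hi = cfg.translocation_length_distribution
            chrom, start, seg_len = pick_segment(lo, hi, "translocation")
            seg = chroms[chrom][start:start + seg_len]
            del chroms[chrom][start:start + seg_len]
            others = [c for c in names if c != chrom]
            dest = others[int(rng.integers(len(others)))]
            ins = int(rng.integers(0, len(chroms[dest]) + 1))
            chroms[dest][ins:ins] = seg
            log.append({"lineage": lineage_id, "type": etype, "chrom": chrom,
                        "start": start, "n_genes": seg_len, "dest": dest,
                        "dest_pos": ins, "genes": [g for g, _ in seg]})
        elif etype in ("tandem_dup", "dispersed_dup"):
            # prefer sources not yet involved in a duplication, so that
            # configured event counts translate into exact coverage
            fresh = [
                (c, i)
                for c in names
                for i, (g, _) in enumerate(chroms[c])
                if g not in dup_involved
            ]
            if fresh:
                chrom, start = fresh[int(rng.integers(len(fresh)))]
            else:
                chrom, start, _ = pick_segment(1, 1, "duplication")
            gid, strand = chroms[chrom][start]
            dup_counter += 1
            new_id = f"{lineage_id}_dup{dup_counter}"
            seqs[new_id] = mutate_jc(rng, seqs[gid], cfg.dup_divergence)
            dup_involved.update((gid, new_id))
            if etype == "tandem_dup":
                dest, ins = chrom, start + 1
            else:
                dest = names[int(rng.integers(len(names)))]
                ins = int(rng.integers(0, len(chroms[dest]) + 1))
                # keep dispersed copies away from the source position
                if dest == chrom and abs(ins - start) <= 10:
                    ins = (start + len(chroms[dest]) // 2) % (len(chroms[dest]) + 1)
            chroms[dest].insert(ins, (new_id, strand))
            log.append({"lineage": lineage_id, "type": etype, "chrom": chrom,
                        "start": start, "source": gid, "copy": new_id,
                        "dest": dest, "dest_pos": ins})
        elif etype == "loss":
            candidates = [c for c in names if len(chroms[c]) > 1]
            if not candidates:
                raise ValueError("no gene available for loss")
            chrom = candidates[int(rng.integers(len(candidates)))]
            pos = int(rng.integers(len(chroms[chrom])))
            gid, _ = chroms[chrom].pop(pos)
            seqs.pop(gid)
            log.append({"lineage": lineage_id, "type": etype, "chrom": chrom,
                        "start": pos, "gene": gid})

    # rename surviving ancestral genes into this lineage's namespace and
    # push every sequence down half the speciation depth
    branch = cfg.speciation_depth / 2.0

    def rename(gid: str) -> str:
        return f"{lineage_id}_{gid[4:]}" if gid.startswith("anc_") else gid

    seqs = {rename(g): mutate_jc(rng, s, branch) for g, s in seqs.items()}
    chroms = {
        c: [(rename(g), st) for g, st in genes] for c, genes in chroms.items()
    }
    for entry in log:  # event log refers to final (lineage) gene ids
        for key in ("source", "copy", "gene"):
            if key in entry:
                entry[key] = rename(entry[key])
        if "genes" in entry:
            entry["genes"] = [rename(g) for g in entry["genes"]]
    return SimGenome(chromosomes=chroms, sequences=seqs), log


def simulate_divergence_pair(cfg: SimConfig) -> tuple[SimGenome, SimGenome, TruthTables]:
    """Ancestor + two evolved lineages (A and B) with ortholog truth."""
    anc = simulate_ancestor(cfg)
    genome_a, log_a = evolve_lineage(anc, cfg, "A")
    genome_b, log_b = evolve_lineage(anc, cfg, "B")
    truth = TruthTables(event_log=log_a + log_b)
    ids_a = set(genome_a.sequences)
    ids_b = set(genome_b.sequences)
    for gid in anc.sequences:
        suffix = gid[4:]
        a, b = f"A_{suffix}", f"B_{suffix}"
        if a in ids_a and b in ids_b:
            truth.ortholog_map.append((a, b))
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# transposable-element copies
# ---------------------------------------------------------------------------


def simulate_te_copies(
    cfg: SimConfig,
) -> tuple[list[RepeatHit], dict[str, str], dict[str, str], list[dict]]:
    """Generate TE copy populations for each configured burst.

    Each burst mutates the family consensus to a per-copy JC depth drawn
    from Normal(mode, sd) truncated at 0 (in percent).  Returns the
    repeat hits (divergence unset: estimation is downstream's job), the
    copy sequences, the family consensus sequences, and per-copy truth
    rows carrying the realized JC divergence.
    """
    if not cfg.te_bursts:
        raise ValueError("at least one TE burst episode is required")
    for b in cfg.te_bursts:
        if b.mode_divergence_pct >= 75.0:
            raise ValueError(
                f"burst mode {b.mode_divergence_pct}% is beyond Jukes-Cantor "
                "saturation (75%)"
            )
    rng = np.random.default_rng((cfg.seed, 7001))
    hits: list[RepeatHit] = []
    copies: dict[str, str] = {}
    consensus: dict[str, str] = {}
    truth: list[dict] = []
    pos = 0
    for bi, burst in enumerate(cfg.te_bursts):
        if burst.n_copies == 0:
            continue
        if burst.family not in consensus:
            consensus[burst.family] = random_sequence(rng, burst.copy_length)
        cons = consensus[burst.family]
        depths = rng.normal(
            burst.mode_divergence_pct / 100.0,
            burst.sd_pct / 100.0,
            size=burst.n_copies,
        )
        depths = np.clip(depths, 0.0, None)
        for ci, depth in enumerate(depths):
            copy_id = f"te_b{bi}_{ci:05d}"
            seq = mutate_jc(rng, cons, float(depth))
            copies[copy_id] = seq
            # realized divergence: JC correction of the realized mismatch rate
            mism = sum(a != b for a, b in zip(seq, cons)) / len(cons)
            realized = (
                -0.75 * math.log(1.0 - 4.0 * mism / 3.0) if mism < 0.749 else float("nan")
            )
            hits.append(
                RepeatHit(
                    scaffold="repeat_scaffold",
                    start=pos,
                    end=pos + len(seq),
                    family=burst.family,
                    superfamily=burst.superfamily,
                    divergence_pct=None,
                )
            )
            truth.append({
                "copy_id": copy_id, "family": burst.family,
                "superfamily": burst.superfamily, "burst": bi,
                "true_divergence_pct": 100.0 * realized,
                "drawn_depth_pct": 100.0 * float(depth),
            })
            pos += len(seq) + 100
    return hits, copies, consensus, truth


# ---------------------------------------------------------------------------
# gametolog loci
# ---------------------------------------------------------------------------


@dataclass
class SexLoci:
    """Simulated gametolog sequences plus the genome context per sex.

    ``female_seqs``/``male_seqs`` map sequence ids to the Lunularia-side
    sequences present in each sex.  ``mp_u``/``mp_v`` are the Marchantia
    gametologs and ``outgroups`` per-locus outgroup sequences used by the
    quartet classifier.  ``female_genome``/``male_genome`` are scaffold
    sequences (U scaffold female-only, V scaffold male-only, autosomes in
    both).
    """

    female_seqs: dict[str, str]
    male_seqs: dict[str, str]
    mp_u: dict[str, str]
    mp_v: dict[str, str]
    outgroups: dict[str, str]
    female_genome: dict[str, str]
    male_genome: dict[str, str]


def simulate_sex_loci(cfg: SimConfig) -> tuple[SexLoci, list[dict]]:
    """Simulate gametolog, pseudoautosomal, outgroup and translocated loci.

    For gametolog pairs an ancestral sequence splits into U and V copies
    at ``sexchrom_depth``, each of which splits into Marchantia- and
    Lunularia-side copies at ``speciation_depth``.  U-descended
    Lunularia copies are placed only in the female genome and V copies
    only in the male genome, except for ``n_translocated_U_loci`` whose
    U copy moves to an autosome present in both sexes while the V copy
    is lost.  Pseudoautosomal loci split only at the species level and
    are present in both sexes at >99% identity.  Outgroup loci place the
    Lunularia split before the U/V split, so the two Marchantia
    gametologs are each other's closest relatives.
    """
    g = cfg.gametolog_cfg
    rng = np.random.default_rng((cfg.seed, 9001))
    loci = SexLoci({}, {}, {}, {}, {}, {}, {})
    truth: list[dict] = []
    female_auto_parts: list[str] = []
    male_auto_parts: list[str] = []
    u_parts: list[str] = []
    v_parts: list[str] = []

    translocated = set(rng.choice(g.n_gametolog_pairs,
                                  size=g.n_translocated_U_loci, replace=False))
    for i in range(g.n_gametolog_pairs):
        name = f"gam{i + 1:03d}"
        anc = random_sequence(rng, g.locus_length)
        u = mutate_jc(rng, anc, g.sexchrom_depth - g.speciation_depth)
        v = mutate_jc(rng, anc, g.sexchrom_depth - g.speciation_depth)
        loci.mp_u[name] = mutate_jc(rng, u, g.speciation_depth)
        loci.mp_v[name] = mutate_jc(rng, v, g.speciation_depth)
        lc_u = mutate_jc(rng, u, g.speciation_depth)
        lc_v = mutate_jc(rng, v, g.speciation_depth)
        loci.outgroups[name] = mutate_jc(rng, anc, g.outgroup_depth)
        is_trans = i in translocated
        loci.female_seqs[f"{name}_LcU"] = lc_u
        if is_trans:
            # U copy rides an autosome: present in both sexes; V copy lost
            loci.male_seqs[f"{name}_LcU"] = lc_u
            female_auto_parts.append(lc_u)
            male_auto_parts.append(lc_u)
        else:
            loci.male_seqs[f"{name}_LcV"] = lc_v
            u_parts.append(lc_u)
            v_parts.append(lc_v)
        truth.append({
            "locus": name, "kind": "gametolog",
            "lc_u_id": f"{name}_LcU",
            "lc_v_id": None if is_trans else f"{name}_LcV",
            "true_phylo_label_u": "U",
            "true_phylo_label_v": None if is_trans else "V",
            "true_genomic_label": "autosomal" if is_trans else "U-linked",
            "translocated": is_trans,
        })

    for i in range(g.n_pseudoautosomal):
        name = f"pa{i + 1:03d}"
        anc = random_sequence(rng, g.locus_length)
        lc = mutate_jc(rng, anc, g.speciation_depth)
        mp = mutate_jc(rng, anc, g.speciation_depth)
        lc_f = mutate_jc(rng, lc, g.pa_within_depth)
        lc_m = mutate_jc(rng, lc, g.pa_within_depth)
        loci.mp_u[name] = mp
        loci.mp_v[name] = mutate_jc(rng, mp, g.pa_within_depth)
        loci.outgroups[name] = mutate_jc(rng, anc, g.outgroup_depth)
        loci.female_seqs[f"{name}_Lc"] = lc_f
        loci.male_seqs[f"{name}_Lc"] = lc_m
        female_auto_parts.append(lc_f)
        male_auto_parts.append(lc_m)
        truth.append({
            "locus": name, "kind": "pseudoautosomal",
            "lc_u_id": f"{name}_Lc", "lc_v_id": f"{name}_Lc",
            "true_phylo_label_u": "O", "true_phylo_label_v": "O",
            "true_genomic_label": "autosomal", "translocated": False,
        })

    for i in range(g.n_outgroup_loci):
        # post-speciation duplicate: Lc branches before the U/V split
        name = f"out{i + 1:03d}"
        anc = random_sequence(rng, g.locus_length)
        lc = mutate_jc(rng, anc, g.sexchrom_depth)
        mp_anc = mutate_jc(rng, anc, g.sexchrom_depth - g.speciation_depth)
        loci.mp_u[name] = mutate_jc(rng, mp_anc, g.speciation_depth)
        loci.mp_v[name] = mutate_jc(rng, mp_anc, g.speciation_depth)
        loci.outgroups[name] = mutate_jc(rng, anc, g.outgroup_depth)
        loci.female_seqs[f"{name}_Lc"] = lc
        loci.male_seqs[f"{name}_Lc"] = lc
        female_auto_parts.append(lc)
        male_auto_parts.append(lc)
        truth.append({
            "locus": name, "kind": "outgroup_duplicate",
            "lc_u_id": f"{name}_Lc", "lc_v_id": f"{name}_Lc",
            "true_phylo_label_u": "O", "true_phylo_label_v": "O",
            "true_genomic_label": "autosomal", "translocated": False,
        })

    def assemble(parts: list[str], spacers: list[str] | None = None) -> str:
        if spacers is None:
            spacers = [random_sequence(rng, 300) for _ in range(len(parts) + 1)]
        out = []
        for sp, p in zip(spacers, parts):
            out.append(sp)
            out.append(p)
        out.append(spacers[-1])
        return "".join(out)

    if u_parts:
        loci.female_genome["scaffold_U"] = assemble(u_parts)
    if v_parts:
        loci.male_genome["scaffold_V"] = assemble(v_parts)
    # the autosome is homologous between the sexes: shared spacers so the
    # opposite-sex scaffolds stay >99% identical
    shared = [random_sequence(rng, 300)
              for _ in range(len(female_auto_parts) + 1)]
    loci.female_genome["scaffold_auto1"] = assemble(female_auto_parts, shared)
    loci.male_genome["scaffold_auto1"] = assemble(male_auto_parts, shared)
    return loci, truth


# ---------------------------------------------------------------------------
# emit
# ---------------------------------------------------------------------------


def emit(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write every standard-format artefact.

    Writes per-lineage GFF3 + gene FASTA, a single-copy-ortholog anchor
    TSV, a RepeatMasker-style ``.out`` (div column carries the truth),
    TE copy and consensus FASTA, sex-specific genome FASTA and locus
    FASTA, and the truth tables as TSV.  Returns a name -> path map.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome_a, genome_b, truth = simulate_divergence_pair(cfg)
    rng = np.random.default_rng((cfg.seed, 4242))
    for tag, genome in (("A", genome_a), ("B", genome_b)):
        recs = genome.to_gene_records(cfg, prefix=f"{tag}_")
        paths[f"gff_{tag}"] = outdir / f"lineage{tag}.gff3"
        write_gff3(recs, paths[f"gff_{tag}"])
        paths[f"genes_{tag}"] = outdir / f"lineage{tag}_genes.fasta"
        write_fasta(genome.sequences, paths[f"genes_{tag}"])
        paths[f"genome_{tag}"] = outdir / f"lineage{tag}_genome.fasta"
        write_fasta(
            {f"{tag}_{c}": s
             for c, s in genome.scaffold_sequences(cfg, rng).items()},
            paths[f"genome_{tag}"],
        )
    paths["anchors"] = outdir / "anchors.tsv"
    write_anchor_table(
        [(a, b, 1.0) for a, b in truth.ortholog_map], paths["anchors"]
    )
    paths["event_log"] = outdir / "event_log.tsv"
    pd.DataFrame(truth.event_log).to_csv(paths["event_log"], sep="\t", index=False)

    hits, copies, consensus, te_truth = simulate_te_copies(cfg)
    hits_with_truth = [
        replace(h, divergence_pct=t["true_divergence_pct"])
        for h, t in zip(hits, te_truth)
    ]
    paths["repeats_out"] = outdir / "repeats.out"
    write_repeatmasker_out(hits_with_truth, paths["repeats_out"])
    paths["te_copies"] = outdir / "te_copies.fasta"
    write_fasta(copies, paths["te_copies"])
    paths["te_consensus"] = outdir / "te_consensus.fasta"
    write_fasta(consensus, paths["te_consensus"])
    paths["te_truth"] = outdir / "te_truth.tsv"
    pd.DataFrame(te_truth).to_csv(paths["te_truth"], sep="\t", index=False)

    loci, gam_truth = simulate_sex_loci(cfg)
    paths["female_genome"] = outdir / "female_genome.fasta"
    write_fasta(loci.female_genome, paths["female_genome"])
    paths["male_genome"] = outdir / "male_genome.fasta"
    write_fasta(loci.male_genome, paths["male_genome"])
    paths["female_loci"] = outdir / "female_loci.fasta"
    write_fasta(loci.female_seqs, paths["female_loci"])
    paths["male_loci"] = outdir / "male_loci.fasta"
    write_fasta(loci.male_seqs, paths["male_loci"])
    paths["mp_u"] = outdir / "mp_u.fasta"
    write_fasta(loci.mp_u, paths["mp_u"])
    paths["mp_v"] = outdir / "mp_v.fasta"
    write_fasta(loci.mp_v, paths["mp_v"])
    paths["outgroups"] = outdir / "outgroups.fasta"
    write_fasta(loci.outgroups, paths["outgroups"])
    paths["gametolog_truth"] = outdir / "gametolog_truth.tsv"
    pd.DataFrame(gam_truth).to_csv(paths["gametolog_truth"], sep="\t", index=False)

    paths["ortholog_map"] = outdir / "ortholog_map.tsv"
    pd.DataFrame(truth.ortholog_map, columns=["gene_A", "gene_B"]).to_csv(
        paths["ortholog_map"], sep="\t", index=False
    )
    return paths
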