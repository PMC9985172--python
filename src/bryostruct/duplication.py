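"""Duplicate-gene detection and the percent-duplicated statistic.

A gene counts as duplicated when its protein aligns to another protein
above identity and coverage thresholds.  The headline statistic divides
the number of duplicated genes by the number of annotated genes longer
than 150 aa (strictly greater), and duplicate pairs are split into
tandem (few intervening genes on the same scaffold) versus dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import GeneRecord


@dataclass(frozen=True)
class DuplicationParams:
    min_identity: float = 0.30
    min_coverage: float = 0.50
    min_protein_length_aa: int = 150
    tandem_max_intervening: int = 5
    kmer_size: int = 5
    min_shared_kmers: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_protein_length_aa <= 0:
            raise ValueError("min_protein_length_aa must be positive")


@dataclass(frozen=True)
class ParalogPair:
    id_a: str
    id_b: str
    identity: float
    coverage: float


@dataclass(frozen=True)
class DuplicationSummary:
    n_annotated: int
    n_eligible: int
    n_duplicated: int
    percent_duplicated: float
    n_tandem_pairs: int
    n_dispersed_pairs: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aln) -> tuple[float, int]:
    """(identity over aligned columns, aligned length on the query axis)."""
    a, b = aln[0], aln[1]
    matches = cols = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            cols += 1
            continue
        cols += 1
        matches += x == y
    qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0] if len(aln.aligned[0]) else 0
    return (matches / cols if cols else 0.0), qspan


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def find_paralog_pairs(
    proteins: Mapping[str, str],
    params: DuplicationParams = DuplicationParams(),
    use_prefilter: bool = True,
) -> list[ParalogPair]:
    """All unordered protein pairs passing identity and coverage thresholds.

    Pairs are screened with a shared-k-mer prefilter (k amino acids,
    ``min_shared_kmers`` required) and confirmed by Smith-Waterman local
    alignment under BLOSUM62.  Identity is computed over aligned
    columns; coverage is the aligned span of the shorter protein over
    its length.  ``use_prefilter=False`` aligns every pair (oracle
    mode).  Self-pairs are excluded; output is symmetric by
    construction and sorted by (id_a, id_b).
    """
    if not proteins:
        raise ValueError("no protein sequences given")
    ids = sorted(proteins)
    kmer_sets = (
        {i: _kmers(proteins[i], params.kmer_size) for i in ids}
        if use_prefilter else None
    )
    aligner = _make_aligner()
    pairs: list[ParalogPair] = []
    for i, id_a in enumerate(ids):
        seq_a = proteins[id_a]
        for id_b in ids[i + 1:]:
            seq_b = proteins[id_b]
            if kmer_sets is not None:
                shared = kmer_sets[id_a] & kmer_sets[id_b]
                if len(shared) < params.min_shared_kmers:
                    continue
            short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
            if not short:
                continue
            alns = aligner.align(short, long_)
            try:
                aln = alns[0]
            except IndexError:
                continue
            identity, qspan = _alignment_stats(aln)
            coverage = qspan / len(short)
            if identity >= params.min_identity and coverage >= params.min_coverage:
                pairs.append(ParalogPair(id_a, id_b, identity, coverage))
    return pairs


def percent_duplicated(
    genes: Sequence[GeneRecord],
    pairs: Sequence[ParalogPair],
    params: DuplicationParams = DuplicationParams(),
) -> DuplicationSummary:
    """Percent of eligible genes (protein > 150 aa) with a duplicate copy.

    A gene is duplicated iff it participates in at least one paralog
    pair and is itself eligible; the denominator is the eligible-gene
    count.  Tandem/dispersed pair counts come from
    :func:`classify_tandem` when ranks are available, else 0/0.
    """
    by_id = {g.gene_id: g for g in genes}
    for p in pairs:
        for gid in (p.id_a, p.id_b):
            if gid not in by_id:
                raise KeyError(f"pair references unknown gene id {gid!r}")
    thr = params.min_protein_length_aa
    eligible = {g.gene_id for g in genes if g.protein_length > thr}
    in_pair = {gid for p in pairs for gid in (p.id_a, p.id_b)}
    duplicated = eligible & in_pair
    n_tandem = n_dispersed = 0
    if all(g.rank is not None for g in genes):
        labels = classify_tandem(pairs, genes, params)
        n_tandem = sum(v == "tandem" for v in labels.values())
        n_dispersed = sum(v == "dispersed" for v in labels.values())
    pct = 100.0 * len(duplicated) / len(eligible) if eligible else 0.0
    return DuplicationSummary(
        n_annotated=len(genes),
        n_eligible=len(eligible),
        n_duplicated=len(duplicated),
        percent_duplicated=pct,
        n_tandem_pairs=n_tandem,
        n_dispersed_pairs=n_dispersed,
    )


def classify_tandem(
    pairs: Sequence[ParalogPair],
    genes: Sequence[GeneRecord],
    params: DuplicationParams = DuplicationParams(),
) -> dict[tuple[str, str], str]:
    """Label each paralog pair tandem or dispersed.

    Tandem: both genes on one scaffold separated by at most
    ``tandem_max_intervening`` intervening genes (rank distance minus
    one); anything else, including cross-scaffold pairs, is dispersed.
    """
    by_id = {g.gene_id: g for g in genes}
    out: dict[tuple[str, str], str] = {}
    for p in pairs:
        ga, gb = by_id[p.id_a], by_id[p.id_b]
        if ga.rank is None or gb.rank is None:
            raise ValueError(
                f"genes {p.id_a}/{p.id_b} are unranked; run rank_genes first"
            )
        if (ga.scaffold == gb.scaffold
                and abs(ga.rank - gb.rank) - 1 <= params.tandem_max_intervening):
            out[(p.id_a, p.id_b)] = "tandem"
        else:
            out[(p.id_a, p.id_b)] = "dispersed"
    return out


def translate_proteins(gene_seqs: Mapping[str, str]) -> dict[str, str]:
    """Translate coding nucleotide sequences (frame 0, stops stripped)."""
    from Bio.Seq import Seq

    out = {}
    for gid, seq in gene_seqs.items():
        trimmed = seq[: 3 * (len(seq) // 3)]
        out[gid] = str(Seq(trimmed).translate()).replace("*", "")
    return out
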