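"""Readers/writers for the standard formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals; the
GFF3 reader and writer convert at the boundary (GFF3 is 1-based
inclusive).  Gene order is expressed as a per-scaffold ordinal *rank*,
the coordinate system used by the collinearity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger("bryostruct")

SUPERFAMILIES = ("Ty3/Gypsy", "Ty1/Copia", "LINE", "DNA", "unknown", "other")


class ParseError(ValueError):
    """A file could not be parsed; message carries the line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with exon structure and gene-order rank.

    Coordinates are 0-based half-open.  ``exons`` belong to the
    representative (longest) mRNA.  ``rank`` is the 0-based ordinal of
    the gene along its scaffold; ``None`` until :func:`rank_genes`.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_length: int
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.protein_length < 1:
            raise ValueError(f"{self.gene_id}: protein_length must be >= 1")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(
            self.exons[i + 1][0] - self.exons[i][1]
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class RepeatHit:
    """One repeat alignment: a masked interval with family assignment.

    ``divergence_pct`` is the percent divergence of the copy from its
    family consensus; ``None`` when it has not been measured yet.
    """

    scaffold: str
    start: int
    end: int
    family: str
    superfamily: str
    divergence_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("RepeatHit: end must be > start")
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValueError("RepeatHit: divergence_pct must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationStats:
    """Per-annotation gene-feature summary (one representative mRNA per gene)."""

    n_genes: int
    mean_gene_length: float
    mean_cds_length: float
    mean_intron_length: float
    mean_exon_length: float
    exons_per_mrna: float
    has_introns: bool = True


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _validate_gff3_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(line.split(chr(9)))}"
                )


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene models from a GFF3 file into :class:`GeneRecord` objects.

    One record is produced per gene; when a gene has several mRNAs the
    one with the largest summed exon length is taken as representative.
    Genes without any CDS feature are skipped with a warning.
    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene"):
        best_exons: list[tuple[int, int]] | None = None
        best_len = -1
        cds_len = 0
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
            if not exons:  # exonless mRNA: treat whole span as one exon
                exons = [(mrna.start - 1, mrna.end)]
            total = sum(e - s for s, e in exons)
            if total > best_len:
                best_len = total
                best_exons = exons
                cds_len = sum(
                    f.end - f.start + 1
                    for f in db.children(mrna, featuretype="CDS")
                )
        if best_exons is None or cds_len == 0:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            continue
        records.append(
            GeneRecord(
                gene_id=gene.id,
                scaffold=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(best_exons),
                protein_length=max(1, cds_len // 3),
            )
        )
    return records


def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as GFF3 (gene/mRNA/exon/CDS; exons double as CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.start + 1, g.end
            fh.write(
                f"{g.scaffold}\tbryostruct\tgene\t{s1}\t{e1}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.1"
            fh.write(
                f"{g.scaffold}\tbryostruct\tmRNA\t{s1}\t{e1}\t.\t{g.strand}"
                f"\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, start=1):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        f"{g.scaffold}\tbryostruct\t{ftype}\t{xs + 1}\t{xe}"
                        f"\t.\t{g.strand}\t{0 if ftype == 'CDS' else '.'}"
                        f"\tID={mid}.{ftype}{i};Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# gene ranks and annotation statistics
# ---------------------------------------------------------------------------

def rank_genes(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Assign per-scaffold 0-based gene-order ranks.

    Genes are ordered by start position within each scaffold, with a
    deterministic (end, gene_id) tie-break.  Returns new records; input
    order is preserved in the output list.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_id(s): {', '.join(dupes)}")
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    rank_of: dict[str, int] = {}
    for scaffold_genes in by_scaffold.values():
        ordered = sorted(scaffold_genes, key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(ordered):
            rank_of[g.gene_id] = i
    return [replace(g, rank=rank_of[g.gene_id]) for g in genes]


def annotation_stats(genes: Sequence[GeneRecord]) -> AnnotationStats:
    """Compute mean gene/CDS/intron/exon lengths and the exons-per-mRNA ratio.

    Statistics use one representative mRNA per gene.  When no gene has an
    intron the mean intron length is reported as 0 with ``has_introns``
    set to False.
    """
    if not genes:
        raise ValueError("annotation_stats requires at least one gene")
    gene_lengths = [g.length for g in genes]
    cds_lengths = [g.cds_length for g in genes]
    exon_lengths = [e - s for g in genes for s, e in g.exons]
    intron_lengths = [il for g in genes for il in g.intron_lengths]
    n_exons = sum(len(g.exons) for g in genes)
    return AnnotationStats(
        n_genes=len(genes),
        mean_gene_length=sum(gene_lengths) / len(genes),
        mean_cds_length=sum(cds_lengths) / len(genes),
        mean_intron_length=(
            sum(intron_lengths) / len(intron_lengths) if intron_lengths else 0.0
        ),
        mean_exon_length=sum(exon_lengths) / len(exon_lengths),
        exons_per_mrna=n_exons / len(genes),
        has_introns=bool(intron_lengths),
    )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_CLASS_MAP = {
    "gypsy": "Ty3/Gypsy",
    "copia": "Ty1/Copia",
}


def classify_repeat_family(class_string: str) -> str:
    """Map a RepeatMasker class/family string to a repeat superfamily."""
    cs = class_string.lower()
    for key, sf in _CLASS_MAP.items():
        if key in cs:
            return sf
    if cs.startswith("line"):
        return "LINE"
    if cs.startswith("dna"):
        return "DNA"
    if cs.startswith("unknown") or cs.startswith("unspecified"):
        return "unknown"
    logger.warning("unrecognised repeat class %r mapped to 'other'", class_string)
    return "other"


def read_repeatmasker_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` table (3 header lines, aligned columns).

    Columns used: percent divergence (col 2), query scaffold/begin/end
    (cols 5-7), repeat name (col 10) and class/family (col 11).  Query
    coordinates are 1-based inclusive in the file and converted to
    0-based half-open.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ParseError(
                    f"{path}: truncated RepeatMasker line {lineno}: "
                    f"{len(parts)} fields"
                )
            try:
                div = float(parts[1])
                start = int(parts[5]) - 1
                end = int(parts[6])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: unparseable RepeatMasker line {lineno}: {exc}"
                ) from exc
            hits.append(
                RepeatHit(
                    scaffold=parts[4],
                    start=start,
                    end=end,
                    family=parts[9],
                    superfamily=classify_repeat_family(parts[10]),
                    divergence_pct=div,
                )
            )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Write RepeatHits in the RepeatMasker ``.out`` dialect."""
    reverse_class = {
        "Ty3/Gypsy": "LTR/Gypsy", "Ty1/Copia": "LTR/Copia",
        "LINE": "LINE/L1", "DNA": "DNA/hAT", "unknown": "Unknown",
        "other": "Other",
    }
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat         position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat"
            "  class/family   begin end (left) ID\n\n"
        )
        for i, h in enumerate(hits, start=1):
            div = 0.0 if h.divergence_pct is None else h.divergence_pct
            fh.write(
                f"  500  {div:5.1f}  0.0  0.0  {h.scaffold}  {h.start + 1}"
                f"  {h.end}  (0)  +  {h.family}  "
                f"{reverse_class[h.superfamily]}  1  {h.length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# anchor tables
# ---------------------------------------------------------------------------

def read_anchor_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 2- or 3-column TSV of ortholog/anchor gene pairs.

    Rows are preserved in file order; a missing third column defaults the
    similarity to 1.0.
    """
    pairs: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(
                    f"{path}: anchor line {lineno} has fewer than 2 columns"
                )
            sim = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
            pairs.append((parts[0], parts[1], sim))
    return pairs


def write_anchor_table(
    pairs: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a, b, sim in pairs:
            fh.write(f"{a}\t{b}\t{sim:g}\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers around Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
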