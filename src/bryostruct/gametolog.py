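"""U/V gametolog classification and translocation inference.

In dioicous liverworts the female U and male V chromosomes carry
gametolog pairs descended from a single ancestral gene.  For each
Lunularia ortholog of a Marchantia gametolog pair the pipeline asks two
independent questions:

* phylogenetic: is the Lunularia sequence more closely related to the
  Marchantia U gametolog (label U), to the V gametolog (V), or are the
  two Marchantia gametologs each other's closest relatives (O,
  outgroup — the Lunularia copy split before the U/V divergence)?
* genomic: is the sequence found only in the female genome (U-linked),
  only in the male genome (V-linked), in both (autosomal or
  pseudoautosomal), or in neither (unplaced)?

A U-to-autosome translocation with loss of the V partner leaves a
diagnostic combination: phylogenetically U, genomically autosomal, and
no V-descended sequence anywhere in the male genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .te_landscape import SaturationError, count_substitution_types, k2p_distance

PHYLO_LABELS = ("U", "V", "O")
GENOMIC_LABELS = ("U-linked", "V-linked", "autosomal", "unplaced")


@dataclass(frozen=True)
class PresenceParams:
    min_identity: float = 0.95
    min_coverage: float = 0.80
    same_gametolog_identity: float = 0.99
    autosomal_scaffold_identity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage",
                     "same_gametolog_identity", "autosomal_scaffold_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class PhyloLabel:
    label: str           # U, V or O
    support: float       # internal branch length; 0 when unresolved
    resolved: bool = True


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------


def _pairwise_k2p(a: str, b: str) -> float:
    """K2P distance between two equal-length aligned sequences."""
    n, ts, tv = count_substitution_types(a.upper(), b.upper())
    if n == 0:
        raise ValueError("no alignable columns")
    return k2p_distance(ts / n, tv / n)


def build_tree(seqs: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining tree on K2P distances for 4-6 aligned sequences.

    Deterministic for fixed input.  All-identical sequences leave every
    distance at zero; the resulting star-like tree is flagged by giving
    it a ``resolved`` attribute of False (checked by
    :func:`classify_phylo`).
    """
    names = list(seqs)
    if len(names) < 4:
        raise ValueError("build_tree needs at least 4 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must form an equal-length alignment")
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pairwise_k2p(seqs[names[i]], seqs[names[j]])
    tree = nj(DistanceMatrix(mat, ids=names))
    tree.resolved = not np.allclose(mat, 0.0)
    return tree


# ---------------------------------------------------------------------------
# phylogenetic classification
# ---------------------------------------------------------------------------


def _quartet_split(
    tree: TreeNode, tips: Sequence[str]
) -> tuple[frozenset[str], float] | None:
    """The non-trivial bipartition of an unrooted quartet and its length.

    Returns the 2-tip side containing ``tips[0]``'s partner structure as
    a frozenset plus the internal branch length, or None when the tree
    is a star/unresolved for these four tips.
    """
    tipset = frozenset(tips)
    best: tuple[frozenset[str], float] | None = None
    for node in tree.traverse(include_self=False):
        side = frozenset(
            n.name for n in node.traverse(include_self=True)
            if n.name in tipset
        )
        if len(side) == 2:
            length = node.length or 0.0
            if best is None or length > best[1]:
                best = (side, length)
    return best


def classify_phylo(
    tree: TreeNode,
    lc_tip: str = "Lc",
    mp_u_tip: str = "MpU",
    mp_v_tip: str = "MpV",
    outgroup_tip: str = "out",
) -> PhyloLabel:
    """Classify a Lunularia sequence from its quartet topology.

    The unrooted quartet over {Lc, MpU, MpV, outgroup} has one internal
    split: {Lc,MpU}|{MpV,out} labels the sequence U, {Lc,MpV}|{MpU,out}
    labels it V, and {MpU,MpV}|{Lc,out} labels it O (the two Marchantia
    gametologs are more closely related to each other than to the
    Lunularia ortholog).  Support is the internal branch length; an
    unresolved split yields support 0 and ``resolved=False`` with an O
    call by convention.
    """
    tips = (lc_tip, mp_u_tip, mp_v_tip, outgroup_tip)
    names = {n.name for n in tree.traverse(include_self=True)}
    missing = [t for t in tips if t not in names]
    if missing:
        raise ValueError(f"tree is missing tips: {missing}")
    if not getattr(tree, "resolved", True):
        return PhyloLabel("O", 0.0, resolved=False)
    split = _quartet_split(tree, tips)
    if split is None:
        return PhyloLabel("O", 0.0, resolved=False)
    side, length = split
    if side in (frozenset({lc_tip, mp_u_tip}), frozenset({mp_v_tip, outgroup_tip})):
        return PhyloLabel("U", length)
    if side in (frozenset({lc_tip, mp_v_tip}), frozenset({mp_u_tip, outgroup_tip})):
        return PhyloLabel("V", length)
    return PhyloLabel("O", length)


def classify_phylo_distances(
    lc_seq: str, mp_u_seq: str, mp_v_seq: str
) -> PhyloLabel:
    """Outgroup-free fallback: closest-pair rule on K2P distances.

    If the two Marchantia gametologs are mutually closest the Lunularia
    sequence is O; otherwise it takes the label of the nearer gametolog.
    Support is the margin between the two smallest distances.
    """
    d_u = _pairwise_k2p(lc_seq, mp_u_seq)
    d_v = _pairwise_k2p(lc_seq, mp_v_seq)
    d_uv = _pairwise_k2p(mp_u_seq, mp_v_seq)
    ranked = sorted([(d_uv, "O"), (d_u, "U"), (d_v, "V")])
    margin = ranked[1][0] - ranked[0][0]
    return PhyloLabel(ranked[0][1], margin, resolved=margin > 0)


def classify_locus(
    lc_seq: str,
    mp_u_seq: str,
    mp_v_seq: str,
    outgroup_seq: str | None = None,
) -> PhyloLabel:
    """Classify one Lunularia sequence, building the quartet tree when an
    outgroup is available and falling back to the closest-pair rule
    otherwise."""
    if outgroup_seq is None:
        return classify_phylo_distances(lc_seq, mp_u_seq, mp_v_seq)
    tree = build_tree(
        {"Lc": lc_seq, "MpU": mp_u_seq, "MpV": mp_v_seq, "out": outgroup_seq}
    )
    return classify_phylo(tree)


# ---------------------------------------------------------------------------
# genomic classification
# ---------------------------------------------------------------------------


def _present_in_genome(
    query: str, genome: Mapping[str, str], params: PresenceParams
) -> bool:
    """Semi-global search of the query against every scaffold.

    The whole query is aligned within a scaffold (infix alignment);
    identity is 1 - edit_distance / query_length, so indels count
    against identity and full-query alignment satisfies the coverage
    requirement by construction.
    """
    if not genome:
        raise ValueError("empty genome")
    q = query.upper()
    max_ed = int(len(q) * (1.0 - params.min_identity))
    for scaffold in genome.values():
        res = edlib.align(q, scaffold.upper(), mode="HW", task="distance",
                          k=max_ed)
        if res["editDistance"] != -1:
            return True
    return False


def classify_genomic(
    lc_seq: str,
    female_genome: Mapping[str, str],
    male_genome: Mapping[str, str],
    params: PresenceParams = PresenceParams(),
) -> str:
    """Genomic label from presence/absence in the two sex genomes.

    Present in both -> autosomal; female only -> U-linked; male only ->
    V-linked; neither -> unplaced.
    """
    in_f = _present_in_genome(lc_seq, female_genome, params)
    in_m = _present_in_genome(lc_seq, male_genome, params)
    if in_f and in_m:
        return "autosomal"
    if in_f:
        return "U-linked"
    if in_m:
        return "V-linked"
    return "unplaced"


def same_gametolog(
    female_seq: str, male_seq: str,
    params: PresenceParams = PresenceParams(),
) -> bool:
    """True when the female and male sequences are the same gametolog
    (pairwise identity at or above ``same_gametolog_identity``)."""
    res = edlib.align(female_seq.upper(), male_seq.upper(), mode="NW",
                      task="distance")
    identity = 1.0 - res["editDistance"] / max(len(female_seq), len(male_seq))
    return identity >= params.same_gametolog_identity


def scaffold_identity(scaffold_f: str, scaffold_m: str) -> float:
    """Global-alignment percent identity of two scaffolds; indel columns
    count as mismatches.  Autosomal scaffolds in opposite sexes are
    expected above 99%."""
    if not scaffold_f or not scaffold_m:
        raise ValueError("empty scaffold sequence")
    res = edlib.align(scaffold_f.upper(), scaffold_m.upper(), mode="NW",
                      task="distance")
    identity = 1.0 - res["editDistance"] / max(len(scaffold_f), len(scaffold_m))
    if identity <= 0:
        raise SaturationError("scaffolds do not overlap detectably")
    return 100.0 * identity


# ---------------------------------------------------------------------------
# translocation inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusRecord:
    """Per-locus evidence bundle for translocation calling."""

    locus: str
    phylo: PhyloLabel
    genomic_label: str
    v_ortholog_in_male: bool


def infer_translocation(records: Sequence[LocusRecord]) -> list[str]:
    """Call U-to-autosome translocation candidates.

    A locus qualifies iff it is phylogenetically U, genomically
    autosomal (present in both sex genomes), and no V-descended
    sequence is detected in the male genome — the V gametolog having
    been lost, as Muller's ratchet predicts for non-recombining
    regions.  O loci are excluded (strict rule).
    """
    if not records:
        raise ValueError("no locus records")
    return [
        r.locus
        for r in records
        if r.phylo.label == "U"
        and r.phylo.resolved
        and r.genomic_label == "autosomal"
        and not r.v_ortholog_in_male
    ]
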