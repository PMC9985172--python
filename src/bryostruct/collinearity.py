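"""Collinear-block chaining in gene-rank space.

Single-copy ortholog pairs become anchors: points (rankA, rankB) in the
gene orders of two genomes.  A collinear block is a chain of anchors
advancing monotonically on both genomes, with at most ``m`` intervening
gene ranks between consecutive anchors on each genome and at least
``s`` anchors in total.  The orientation of the rankB progression
separates same-strand (+) blocks from inverted (-) blocks, so inverted
segments show up directly as minus-oriented blocks.

Chaining extracts the best chain per scaffold pair (most anchors,
ties by smaller total gap then leftmost start), removes its anchors,
and repeats — a deliberately transparent rule set in place of
MCScanX's scored chaining, keeping s and m as the operative knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .formats_io import GeneRecord

logger = logging.getLogger("bryostruct")


@dataclass(frozen=True)
class ChainParams:
    s: int = 5   # min anchors per block
    m: int = 25  # max intervening gene ranks between consecutive anchors

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("s must be >= 2")
        if self.m < 0:
            raise ValueError("m must be >= 0")


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    scaffold_a: str
    scaffold_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[Anchor, ...]
    orientation: str  # '+' or '-'
    scaffold_a: str
    scaffold_b: str

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class DecayPoint:
    species_pair: str
    divergence_time: float  # Ma, user-supplied metadata
    percent_collinear: float


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def build_anchors(
    orthologs: Sequence[tuple[str, str, float]] | Sequence[tuple[str, str]],
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
) -> tuple[list[Anchor], int]:
    """Join single-copy ortholog pairs onto gene ranks.

    Returns (anchors, n_dropped) where dropped pairs reference genes
    missing from either annotation.  A gene appearing in more than one
    pair violates the single-copy requirement and raises.
    """
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for pair in orthologs:
        a, b = pair[0], pair[1]
        if a in seen_a or b in seen_b:
            raise ValueError(
                f"gene {a if a in seen_a else b!r} occurs in more than one "
                "ortholog pair; anchors must be single-copy"
            )
        seen_a.add(a)
        seen_b.add(b)
    idx_a = {g.gene_id: g for g in genes_a}
    idx_b = {g.gene_id: g for g in genes_b}
    anchors: list[Anchor] = []
    dropped = 0
    for pair in orthologs:
        a, b = pair[0], pair[1]
        ga, gb = idx_a.get(a), idx_b.get(b)
        if ga is None or gb is None:
            dropped += 1
            continue
        if ga.rank is None or gb.rank is None:
            raise ValueError("genes must be ranked before anchor building")
        anchors.append(
            Anchor(a, b, ga.scaffold, gb.scaffold, ga.rank, gb.rank)
        )
    if dropped:
        logger.warning("%d ortholog pairs dropped (gene not annotated)", dropped)
    anchors.sort(key=lambda x: (x.scaffold_a, x.scaffold_b, x.rank_a, x.rank_b))
    return anchors, dropped


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _best_chain_dp(
    anchors: list[Anchor], m: int
) -> tuple[list[int], int, str] | None:
    """Best chain in one scaffold pair by dynamic programming.

    Anchors must be sorted by rank_a.  Returns (indices, total_gap,
    orientation) of the chain maximizing (#anchors, -total_gap,
    -start_rank_a); None when no anchor exists.  The gap bound applies
    per genome: consecutive anchors satisfy 1 <= delta_rank_a <= m+1 and
    1 <= |delta_rank_b| <= m+1 with constant sign.
    """
    n = len(anchors)
    if n == 0:
        return None
    step = m + 1
    # (key3, orient_pref, end_idx, state); key3 = (len, -gap, -start_rank_a)
    best_global: tuple | None = None
    for orient in ("+", "-"):
        sign = 1 if orient == "+" else -1
        # state per anchor: (len, -gap, -start_rank_a, predecessor)
        state: list[tuple[int, int, int, int | None]] = [
            (1, 0, 0, None)
        ] * n
        for i in range(n):
            ai = anchors[i]
            best = (1, 0, -ai.rank_a, None)
            j = i - 1
            while j >= 0 and ai.rank_a - anchors[j].rank_a <= step:
                aj = anchors[j]
                da = ai.rank_a - aj.rank_a
                db = sign * (ai.rank_b - aj.rank_b)
                if 1 <= da and 1 <= db <= step:
                    lj, ngj, nsj, _ = state[j]
                    cand = (lj + 1, ngj - (da - 1) - (db - 1), nsj, j)
                    if cand[:3] > best[:3] or (
                        cand[:3] == best[:3] and cand[3] < best[3]
                    ):
                        best = cand
                j -= 1
            state[i] = best
            # prefer '+' then smaller end index on full ties
            entry = (best[:3], 0 if orient == "+" else 1, i, state)
            if (best_global is None
                    or entry[0] > best_global[0]
                    or (entry[0] == best_global[0]
                        and entry[1:3] < best_global[1:3])):
                best_global = entry
    key3, orient_pref, end_idx, state = best_global
    orient = "+" if (orient_pref == 0 or key3[0] == 1) else "-"
    idx: int | None = end_idx
    chain = []
    while idx is not None:
        chain.append(idx)
        idx = state[idx][3]
    chain.reverse()
    return chain, -key3[1], orient


def _enumerate_best_chain(
    anchors: list[Anchor], m: int
) -> tuple[list[int], int, str] | None:
    """Exhaustive search for the best chain (oracle for small inputs).

    Enumerates every valid chain by depth-first extension and applies
    the same (#anchors, -total_gap, -start) preference as the DP.
    Exponential: intended for <= ~12 anchors per scaffold pair.
    """
    n = len(anchors)
    if n == 0:
        return None
    step = m + 1
    best: list = [None]

    def consider(chain: list[int], gap: int, orient: str) -> None:
        key = (len(chain), -gap, -anchors[chain[0]].rank_a)
        if best[0] is None or key > best[0][0]:
            best[0] = (key, list(chain), gap, orient)

    def extend(chain: list[int], gap: int, sign: int) -> None:
        last = anchors[chain[-1]]
        for j in range(chain[-1] + 1, n):
            aj = anchors[j]
            da = aj.rank_a - last.rank_a
            if da > step:
                break
            db = (aj.rank_b - last.rank_b) * (sign if sign else 1)
            if sign == 0:
                for new_sign in (1, -1):
                    db2 = (aj.rank_b - last.rank_b) * new_sign
                    if 1 <= da and 1 <= db2 <= step:
                        chain.append(j)
                        g2 = gap + (da - 1) + (db2 - 1)
                        consider(chain, g2, "+" if new_sign == 1 else "-")
                        extend(chain, g2, new_sign)
                        chain.pop()
            else:
                if 1 <= da and 1 <= db <= step:
                    chain.append(j)
                    g2 = gap + (da - 1) + (db - 1)
                    consider(chain, g2, "+" if sign == 1 else "-")
                    extend(chain, g2, sign)
                    chain.pop()

    for i in range(n):
        consider([i], 0, "+")
        extend([i], 0, 0)
    _, chain, gap, orient = best[0]
    return chain, gap, orient


def chain_blocks(
    anchors: Sequence[Anchor],
    params: ChainParams = ChainParams(),
    exhaustive: bool = False,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, per scaffold pair.

    Repeatedly extracts the best remaining chain (most anchors, ties by
    smaller total gap then leftmost start), removes its anchors, and
    stops once the best chain falls below ``s`` anchors.  Blocks are
    anchor-disjoint.  ``exhaustive=True`` swaps the DP for brute-force
    chain enumeration (oracle mode, small inputs only).
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.scaffold_a, a.scaffold_b), []).append(a)
    finder = _enumerate_best_chain if exhaustive else _best_chain_dp
    blocks: list[CollinearBlock] = []
    for (sa, sb) in sorted(groups):
        remaining = sorted(groups[(sa, sb)], key=lambda x: (x.rank_a, x.rank_b))
        while remaining:
            found = finder(remaining, params.m)
            if found is None:
                break
            chain_idx, _, orient = found
            if len(chain_idx) < params.s:
                break
            chain_anchors = tuple(remaining[i] for i in chain_idx)
            blocks.append(
                CollinearBlock(chain_anchors, orient, sa, sb)
            )
            used = set(chain_idx)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


def percent_collinear(
    anchors: Sequence[Anchor], blocks: Sequence[CollinearBlock]
) -> float:
    """Percent of anchors lying inside collinear blocks."""
    if not anchors:
        raise ValueError("no anchors")
    in_blocks = sum(len(b) for b in blocks)
    return 100.0 * in_blocks / len(anchors)


# ---------------------------------------------------------------------------
# decay curve, scaffold assignment, inversions
# ---------------------------------------------------------------------------


def decay_curve(points: Sequence[DecayPoint]) -> pd.DataFrame:
    """Average percent-collinear per divergence time, sorted by time."""
    if not points:
        raise ValueError("no decay points")
    df = pd.DataFrame(
        [(p.divergence_time, p.percent_collinear) for p in points],
        columns=["divergence_time", "percent_collinear"],
    )
    return (
        df.groupby("divergence_time", as_index=False)["percent_collinear"]
        .mean()
        .sort_values("divergence_time", ignore_index=True)
    )


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold: str
    chromosome: str
    fraction_modal: float
    n_hits: int
    tie: bool = False


def assign_scaffolds(
    anchors: Sequence[Anchor], min_hits: int = 10
) -> list[ScaffoldAssignment]:
    """Assign each fragmented-genome scaffold to its modal chromosome.

    Scaffolds with fewer than ``min_hits`` orthologous hits are
    excluded.  Ties for the modal chromosome resolve to the
    lexicographically smallest name and are flagged.
    """
    counts: dict[str, dict[str, int]] = {}
    for a in anchors:
        counts.setdefault(a.scaffold_a, {}).setdefault(a.scaffold_b, 0)
        counts[a.scaffold_a][a.scaffold_b] += 1
    out = []
    for scaffold in sorted(counts):
        per_chrom = counts[scaffold]
        n = sum(per_chrom.values())
        if n < min_hits:
            continue
        top = max(per_chrom.values())
        winners = sorted(c for c, k in per_chrom.items() if k == top)
        out.append(
            ScaffoldAssignment(
                scaffold=scaffold,
                chromosome=winners[0],
                fraction_modal=top / n,
                n_hits=n,
                tie=len(winners) > 1,
            )
        )
    return out


def count_inversions(
    blocks: Sequence[CollinearBlock],
) -> dict[tuple[str, str], dict[str, int]]:
    """Per scaffold pair, count minus- and plus-oriented blocks.

    Minus-oriented blocks are the signature of inversions between the
    two genomes.
    """
    out: dict[tuple[str, str], dict[str, int]] = {}
    for b in blocks:
        d = out.setdefault((b.scaffold_a, b.scaffold_b), {"+": 0, "-": 0})
        d[b.orientation] += 1
    return out
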