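"""Transposable-element divergence landscapes and burst detection.

A repeat landscape bins the abundance (bp) of masked repeats by percent
divergence of each copy from its family consensus, a proxy for the age
structure of insertions: modes at low divergence reflect recent
amplification bursts.  Divergence is measured with the Kimura
two-parameter (K2P) distance by default (transitions and transversions
weighted separately); an uncorrected p-distance is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .formats_io import RepeatHit

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distance undefined: sequences are at or beyond K2P/JC saturation."""


# ---------------------------------------------------------------------------
# divergence estimation
# ---------------------------------------------------------------------------


def _make_nt_aligner() -> Align.PairwiseAligner:
    # gap penalties well above the mismatch cost, so substitutions are not
    # absorbed into spurious indel shifts (which biases distances downward)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


_NT_ALIGNER = _make_nt_aligner()


def _aligned_columns(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences and return the aligned strings."""
    aln = _NT_ALIGNER.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def count_substitution_types(aln_a: str, aln_b: str) -> tuple[int, int, int]:
    """Count (matches+mismatches, transitions, transversions), skipping
    indel and ambiguous columns."""
    n = ts = tv = 0
    for x, y in zip(aln_a, aln_b):
        if x == "-" or y == "-" or x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(p_transition: float, q_transversion: float) -> float:
    """Kimura two-parameter distance from transition/transversion fractions."""
    w1 = 1.0 - 2.0 * p_transition - q_transversion
    w2 = 1.0 - 2.0 * q_transversion
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined for P={p_transition:.3f}, Q={q_transversion:.3f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def estimate_divergence(
    copy_seq: str,
    consensus_seq: str,
    metric: str = "k2p",
    max_divergence_pct: float = 50.0,
) -> float:
    """Percent divergence of a repeat copy from its family consensus.

    The sequences are globally aligned; indel columns are excluded from
    the distance.  ``metric`` is ``"k2p"`` (default) or ``"p"`` for the
    uncorrected proportion of mismatching columns.  Raises
    :class:`SaturationError` when the corrected distance is undefined or
    exceeds ``max_divergence_pct`` — beyond that the K2P correction is
    unreliable and the sequences cannot be assumed homologous (a copy
    compared against its reverse complement lands here).
    """
    if not copy_seq or not consensus_seq:
        raise ValueError("empty sequence")
    aln_a, aln_b = _aligned_columns(copy_seq, consensus_seq)
    n, ts, tv = count_substitution_types(aln_a, aln_b)
    if n == 0:
        raise ValueError("no alignable columns")
    if metric == "p":
        return 100.0 * (ts + tv) / n
    if metric != "k2p":
        raise ValueError(f"unknown metric {metric!r}")
    d = 100.0 * k2p_distance(ts / n, tv / n)
    if d > max_divergence_pct:
        raise SaturationError(
            f"estimated divergence {d:.1f}% exceeds the reliability cap "
            f"({max_divergence_pct:g}%)"
        )
    return d


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Landscape:
    """Binned abundance (bp) by percent divergence, per superfamily.

    ``bins[superfamily][i]`` is the total masked bp whose divergence
    falls in the half-open interval [i*w, (i+1)*w).
    """

    bin_width: float
    bins: Mapping[str, Mapping[int, int]]

    def total_bp(self, superfamily: str | None = None) -> int:
        if superfamily is not None:
            return sum(self.bins.get(superfamily, {}).values())
        return sum(sum(b.values()) for b in self.bins.values())


def bin_landscape(
    hits: Sequence[RepeatHit], bin_width: float = 1.0
) -> Landscape:
    """Accumulate hit lengths into divergence bins per superfamily."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins: dict[str, dict[int, int]] = {}
    for h in hits:
        if h.divergence_pct is None:
            raise ValueError(f"hit on {h.scaffold} has no divergence set")
        if h.divergence_pct < 0:
            raise ValueError("negative divergence")
        idx = int(h.divergence_pct // bin_width)
        fam_bins = bins.setdefault(h.superfamily, {})
        fam_bins[idx] = fam_bins.get(idx, 0) + h.length
    return Landscape(bin_width=bin_width, bins=bins)


def family_densities(
    hits: Sequence[RepeatHit], top_k: int = 15
) -> dict[str, gaussian_kde]:
    """Weighted divergence densities for the ``top_k`` largest families.

    Families are ranked by total masked bp; each density is a Gaussian
    KDE of the copy divergences weighted by copy length, so it reflects
    genome-size contribution rather than copy number.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    totals: dict[str, int] = {}
    for h in hits:
        totals[h.family] = totals.get(h.family, 0) + h.length
    if not totals:
        raise ValueError("no hits")
    ranked = sorted(totals, key=lambda f: (-totals[f], f))[:top_k]
    out: dict[str, gaussian_kde] = {}
    for fam in ranked:
        div = np.array([h.divergence_pct for h in hits if h.family == fam],
                       dtype=float)
        w = np.array([h.length for h in hits if h.family == fam], dtype=float)
        if div.size < 2 or np.allclose(div, div[0]):
            continue  # degenerate family: no density estimable
        out[fam] = gaussian_kde(div, bw_method="silverman", weights=w)
    return out


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstCall:
    """Amplification episodes of one family: KDE modes with prominence."""

    family: str
    modes: tuple[tuple[float, float, float], ...]  # (divergence, height, prominence)


def detect_bursts(
    divergences: Sequence[float],
    weights_bp: Sequence[float] | None = None,
    min_copies: int = 30,
    prominence_frac: float = 0.10,
    family: str = "",
) -> BurstCall:
    """Find amplification bursts as modes of the weighted divergence KDE.

    A burst is a local maximum of the Gaussian kernel density (Silverman
    bandwidth) whose prominence is at least ``prominence_frac`` of the
    global maximum.  Requires ``min_copies`` observations: mode-hunting
    on smaller samples is unreliable and refused.
    """
    div = np.asarray(divergences, dtype=float)
    if div.size < min_copies:
        raise ValueError(
            f"{div.size} copies is too few for burst inference "
            f"(need >= {min_copies})"
        )
    w = None if weights_bp is None else np.asarray(weights_bp, dtype=float)
    kde = gaussian_kde(div, bw_method="silverman", weights=w)
    bw = math.sqrt(kde.covariance[0, 0])
    lo = max(0.0, div.min() - 3 * bw)
    hi = div.max() + 3 * bw
    grid = np.linspace(lo, hi, 1024)
    dens = kde(grid)
    # pad so a mode at the domain edge is still a peak
    padded = np.concatenate([[0.0], dens, [0.0]])
    idx, props = find_peaks(padded, prominence=prominence_frac * dens.max())
    modes = tuple(
        (float(grid[i - 1]), float(dens[i - 1]), float(p))
        for i, p in sorted(zip(idx, props["prominences"]))
    )
    return BurstCall(family=family, modes=modes)


# ---------------------------------------------------------------------------
# skewness
# ---------------------------------------------------------------------------


def skewness(
    divergences: Sequence[float], weights_bp: Sequence[float] | None = None
) -> float:
    """Adjusted Fisher-Pearson sample skewness, optionally bp-weighted.

    With weights, moments are weighted and the small-sample adjustment
    uses the effective sample size (sum w)^2 / sum w^2.  Negative values
    mean the distribution leans toward high divergence; a positive skew
    indicates an excess of young (low-divergence) copies.
    """
    x = np.asarray(divergences, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires n >= 3")
    w = (np.ones_like(x) if weights_bp is None
         else np.asarray(weights_bp, dtype=float))
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    m2 = float((w * (x - mean) ** 2).sum() / wsum)
    m3 = float((w * (x - mean) ** 3).sum() / wsum)
    if m2 == 0:
        raise ValueError("skewness undefined for zero variance")
    g1 = m3 / m2 ** 1.5
    n_eff = wsum ** 2 / float((w ** 2).sum())
    if n_eff <= 2:
        raise ValueError("effective sample size too small")
    return g1 * math.sqrt(n_eff * (n_eff - 1)) / (n_eff - 2)


# ---------------------------------------------------------------------------
# full-length LTR elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTRElement:
    """An LTR retrotransposon candidate: its two terminal repeats (either
    may be missing) and the internal-region length."""

    element_id: str
    ltr5_seq: str | None
    ltr3_seq: str | None
    internal_length: int = 0


def ltr_pair_identity(ltr5: str, ltr3: str) -> float:
    """Global-alignment identity of an LTR pair (indel columns count as
    mismatches)."""
    aln_a, aln_b = _aligned_columns(ltr5, ltr3)
    matches = sum(x == y and x != "-" for x, y in zip(aln_a, aln_b))
    return matches / len(aln_a)


def call_full_length(
    elements: Sequence[LTRElement],
    min_ltr_identity: float = 0.85,
    min_ltr_len: int = 100,
) -> dict[str, str]:
    """Classify each element as full_length, solo, or truncated.

    Full length (potentially transposition-competent) requires both LTRs
    present, each at least ``min_ltr_len`` bp, with pairwise identity at
    least ``min_ltr_identity``.  An element with exactly one LTR is a
    solo; anything else failing the rule is truncated.
    """
    calls: dict[str, str] = {}
    for el in elements:
        have5 = bool(el.ltr5_seq)
        have3 = bool(el.ltr3_seq)
        if have5 != have3:
            calls[el.element_id] = "solo"
            continue
        if not (have5 and have3):
            calls[el.element_id] = "truncated"
            continue
        if (len(el.ltr5_seq) >= min_ltr_len and len(el.ltr3_seq) >= min_ltr_len
                and ltr_pair_identity(el.ltr5_seq, el.ltr3_seq)
                >= min_ltr_identity):
            calls[el.element_id] = "full_length"
        else:
            calls[el.element_id] = "truncated"
    return calls
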