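"""End-to-end recovery experiments on simulated genomes.

Each function sets up a simulated study condition, runs the relevant
pipeline stage from scratch, and measures how well the known truth is
recovered.  They back both the validation test suite and the
``scripts/acceptance.py`` summary report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from . import collinearity as col
from . import duplication as dup
from . import gametolog as gam
from . import te_landscape as tel
from .formats_io import rank_genes
from .simulate import (
    GametologConfig,
    SimConfig,
    TEBurst,
    mutate_jc,
    random_sequence,
    simulate_divergence_pair,
    simulate_sex_loci,
)


def _anchor_pipeline(cfg: SimConfig, params: col.ChainParams):
    ga, gb, truth = simulate_divergence_pair(cfg)
    genes_a = rank_genes(ga.to_gene_records(cfg, "A_"))
    genes_b = rank_genes(gb.to_gene_records(cfg, "B_"))
    anchors, _ = col.build_anchors(truth.ortholog_map, genes_a, genes_b)
    blocks = col.chain_blocks(anchors, params)
    return anchors, blocks, truth


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


def chaining_oracle_agreement(
    n_instances: int = 200, max_anchors: int = 12, seed: int = 0
) -> tuple[int, int]:
    """Compare DP chaining against exhaustive enumeration.

    Random anchor instances of <= ``max_anchors`` anchors are chained
    with every (s, m) in {3,4,5} x {1,2,25}; returns (n_checked,
    n_agreeing) on the anchors-in-blocks count.
    """
    rng = np.random.default_rng(seed)
    checked = agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(3, max_anchors + 1))
        ra = rng.permutation(30)[:n]
        rb = rng.permutation(30)[:n]
        anchors = [col.Anchor(f"a{i}", f"b{i}", "sA", "sB",
                              int(ra[i]), int(rb[i])) for i in range(n)]
        for s in (3, 4, 5):
            for m in (1, 2, 25):
                p = col.ChainParams(s=s, m=m)
                fast = sum(len(b) for b in col.chain_blocks(anchors, p))
                slow = sum(len(b) for b in
                           col.chain_blocks(anchors, p, exhaustive=True))
                checked += 1
                agree += fast == slow
    return checked, agree


def identity_limit_percent(seed: int = 0) -> float:
    """Percent collinear for two lineages with zero rearrangements."""
    cfg = SimConfig(seed=seed, n_chromosomes=4, genes_per_chromosome=100,
                    n_inversions=0, n_translocations=0, n_tandem_dups=0,
                    n_dispersed_dups=0, n_losses=0)
    anchors, blocks, _ = _anchor_pipeline(cfg, col.ChainParams(s=5, m=25))
    return col.percent_collinear(anchors, blocks)


def decay_experiment(
    seed: int = 0,
    inversion_counts: tuple[int, ...] = tuple(range(0, 101, 10)),
    replicates: int = 10,
) -> tuple[float, dict[int, float]]:
    """Collinearity decay with increasing inversion load.

    A 1,000-gene genome (10 chromosomes x 100 genes) is rearranged with
    each inversion count per lineage; the mean percent collinear over
    replicates is correlated (Spearman) with the count.  Returns
    (rho, mean percent per count).
    """
    means: dict[int, float] = {}
    for n_inv in inversion_counts:
        vals = []
        for rep in range(replicates):
            cfg = SimConfig(
                seed=seed + 977 * n_inv + rep,
                n_chromosomes=10, genes_per_chromosome=100,
                n_inversions=n_inv, n_translocations=0, n_tandem_dups=0,
                n_dispersed_dups=0, n_losses=0,
            )
            anchors, blocks, _ = _anchor_pipeline(
                cfg, col.ChainParams(s=5, m=25))
            vals.append(col.percent_collinear(anchors, blocks))
        means[n_inv] = float(np.mean(vals))
    rho = float(spearmanr(list(means), [means[k] for k in means]).statistic)
    return rho, means


def inversion_recovery(seed: int = 0, n_inversions: int = 3) -> tuple[int, int]:
    """Planted non-overlapping inversions vs minus-oriented block count.

    Returns (n_planted, n_minus_blocks) for a genome whose only events
    are inversions of at least s genes.
    """
    cfg = SimConfig(seed=seed, n_chromosomes=4, genes_per_chromosome=100,
                    n_inversions=n_inversions, n_translocations=0,
                    n_tandem_dups=0, n_dispersed_dups=0, n_losses=0,
                    inversion_length_distribution=(8, 15))
    anchors, blocks, truth = _anchor_pipeline(cfg, col.ChainParams(s=5, m=25))
    inv = col.count_inversions(blocks)
    n_minus = sum(d["-"] for d in inv.values())
    n_planted = sum(e["type"] == "inversion" for e in truth.event_log)
    return n_planted, n_minus


# ---------------------------------------------------------------------------
# TE landscape
# ---------------------------------------------------------------------------


def burst_recovery(
    n_seeds: int = 50, modes: tuple[float, float] = (5.0, 25.0),
    sd: float = 2.0, n_copies: int = 2000, tol: float = 2.0, seed: int = 0,
) -> tuple[float, list[list[float]]]:
    """Detect two amplification bursts from mixture-distributed divergences.

    For each seed, ``n_copies`` divergences are drawn from an equal
    mixture of Normal(mode_i, sd); success means exactly two KDE modes,
    each within ``tol`` points of its generating mode.  Returns
    (success fraction, per-seed detected modes).
    """
    successes = 0
    all_modes = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        half = n_copies // 2
        x = np.concatenate([rng.normal(modes[0], sd, half),
                            rng.normal(modes[1], sd, n_copies - half)])
        x = np.clip(x, 0.0, None)
        call = tel.detect_bursts(x)
        found = [m[0] for m in call.modes]
        all_modes.append(found)
        if (len(found) == 2
                and abs(found[0] - modes[0]) <= tol
                and abs(found[1] - modes[1]) <= tol):
            successes += 1
    return successes / n_seeds, all_modes


def divergence_estimator_bias(
    n_seeds: int = 50, depth: float = 0.20, length: int = 3000, seed: int = 0
) -> float:
    """Mean K2P estimate (in %) for copies mutated at a known JC depth."""
    estimates = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        cons = random_sequence(rng, length)
        copy = mutate_jc(rng, cons, depth)
        estimates.append(tel.estimate_divergence(copy, cons))
    return float(np.mean(estimates))


def skewness_checks(seed: int = 0, n: int = 10_000) -> tuple[float, float]:
    """(skewness of an exponential(1) sample, skewness of a normal sample)."""
    rng = np.random.default_rng(seed)
    return (float(tel.skewness(rng.exponential(1.0, n))),
            float(tel.skewness(rng.normal(0.0, 1.0, n))))


def ltr_caller_check(seed: int = 0) -> tuple[int, int]:
    """Planted full-length / solo / truncated elements, incl. the 85%
    identity boundary.  Returns (n_elements, n_correct)."""
    rng = np.random.default_rng(seed)

    def mutated(s, k):
        chars = list(s)
        for pos in rng.choice(len(s), size=k, replace=False):
            chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
        return "".join(chars)

    ltr = random_sequence(rng, 1000)
    short = random_sequence(rng, 50)
    elements = [
        (tel.LTRElement("intact", ltr, ltr, 4000), "full_length"),
        (tel.LTRElement("aged", ltr, mutated(ltr, 100), 4000), "full_length"),
        (tel.LTRElement("boundary_at", ltr, mutated(ltr, 150), 4000),
         "full_length"),
        (tel.LTRElement("boundary_below", ltr, mutated(ltr, 151), 4000),
         "truncated"),
        (tel.LTRElement("solo5", ltr, None), "solo"),
        (tel.LTRElement("solo3", None, ltr), "solo"),
        (tel.LTRElement("short_ltrs", short, short, 500), "truncated"),
        (tel.LTRElement("decayed", ltr, mutated(ltr, 400), 100), "truncated"),
    ]
    calls = tel.call_full_length([e for e, _ in elements])
    correct = sum(calls[e.element_id] == want for e, want in elements)
    return len(elements), correct


# ---------------------------------------------------------------------------
# duplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationRecovery:
    percent_detected: float
    percent_truth: float
    n_tandem_planted: int
    n_tandem_recovered: int


def duplication_recovery(seed: int = 0) -> DuplicationRecovery:
    """Plant duplicates over half the eligible genes and re-detect them.

    A 120-gene genome receives 20 tandem and 20 dispersed duplications
    (distinct sources), so exactly 80 of 160 genes are truly duplicated.
    Proteins are translated and screened with the default detector;
    tandem recovery counts planted tandem pairs whose final rank
    distance stays within the gap parameter and which the classifier
    labels tandem.
    """
    from .simulate import evolve_lineage, simulate_ancestor

    cfg = SimConfig(seed=seed, n_chromosomes=2, genes_per_chromosome=60,
                    n_inversions=0, n_translocations=0,
                    n_tandem_dups=20, n_dispersed_dups=20, n_losses=0)
    anc = simulate_ancestor(cfg)
    genome, log = evolve_lineage(anc, cfg, "A")
    genes = rank_genes(genome.to_gene_records(cfg, "A_"))
    proteins = dup.translate_proteins(genome.sequences)
    params = dup.DuplicationParams()
    pairs = dup.find_paralog_pairs(proteins, params)
    summary = dup.percent_duplicated(genes, pairs, params)

    dup_events = [e for e in log if e["type"].endswith("_dup")]
    truth_dup = {e["source"] for e in dup_events} | {e["copy"] for e in dup_events}
    thr = params.min_protein_length_aa
    eligible = {g.gene_id for g in genes if g.protein_length > thr}
    percent_truth = 100.0 * len(truth_dup & eligible) / len(eligible)

    labels = dup.classify_tandem(pairs, genes, params)
    by_pair = {frozenset(k): v for k, v in labels.items()}
    rank_of = {g.gene_id: g.rank for g in genes}
    scaf_of = {g.gene_id: g.scaffold for g in genes}
    planted = recovered = 0
    for e in dup_events:
        if e["type"] != "tandem_dup":
            continue
        src, copy = e["source"], e["copy"]
        if (scaf_of.get(src) == scaf_of.get(copy)
                and abs(rank_of[src] - rank_of[copy]) - 1
                <= params.tandem_max_intervening):
            planted += 1
            recovered += by_pair.get(frozenset((src, copy))) == "tandem"
    return DuplicationRecovery(
        percent_detected=summary.percent_duplicated,
        percent_truth=percent_truth,
        n_tandem_planted=planted,
        n_tandem_recovered=recovered,
    )


# ---------------------------------------------------------------------------
# gametologs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GametologRecovery:
    n_uv: int
    uv_correct: int
    n_o: int
    o_correct: int
    n_genomic: int
    genomic_correct: int

    @property
    def uv_accuracy(self) -> float:
        return self.uv_correct / self.n_uv if self.n_uv else float("nan")

    @property
    def o_accuracy(self) -> float:
        return self.o_correct / self.n_o if self.n_o else float("nan")

    @property
    def genomic_accuracy(self) -> float:
        return self.genomic_correct / self.n_genomic


def gametolog_recovery(
    seed: int = 0,
    cfg: GametologConfig | None = None,
) -> GametologRecovery:
    """Classify every simulated Lunularia sequence and score against truth.

    Default condition: 100 loci (80 ancestrally nonrecombining gametolog
    pairs, 10 pseudoautosomal, 10 post-speciation duplicates) at 1 kb
    with the U/V split twice as deep as the species split.  Both the U-
    and V-descended copies of each gametolog pair are classified.
    """
    if cfg is None:
        cfg = GametologConfig(n_gametolog_pairs=80, n_pseudoautosomal=10,
                              n_outgroup_loci=10, n_translocated_U_loci=0)
    sim_cfg = SimConfig(seed=seed, gametolog_cfg=cfg)
    loci, truth = simulate_sex_loci(sim_cfg)
    res = dict(n_uv=0, uv_correct=0, n_o=0, o_correct=0,
               n_genomic=0, genomic_correct=0)
    for row in truth:
        locus = row["locus"]
        targets = [(row["lc_u_id"], row["true_phylo_label_u"])]
        if row["lc_v_id"] is not None and row["lc_v_id"] != row["lc_u_id"]:
            targets.append((row["lc_v_id"], row["true_phylo_label_v"]))
        for seq_id, true_label in targets:
            lc = loci.female_seqs.get(seq_id) or loci.male_seqs.get(seq_id)
            lab = gam.classify_locus(lc, loci.mp_u[locus], loci.mp_v[locus],
                                     loci.outgroups[locus])
            if true_label in ("U", "V"):
                res["n_uv"] += 1
                res["uv_correct"] += lab.label == true_label
            else:
                res["n_o"] += 1
                res["o_correct"] += lab.label == "O"
        # genomic label is scored on the locus's U-side (or shared) sequence
        lc = (loci.female_seqs.get(row["lc_u_id"])
              or loci.male_seqs.get(row["lc_u_id"]))
        genomic = gam.classify_genomic(lc, loci.female_genome,
                                       loci.male_genome)
        res["n_genomic"] += 1
        res["genomic_correct"] += genomic == row["true_genomic_label"]
    return GametologRecovery(**res)


def translocation_recovery(
    n_seeds: int = 10, seed: int = 0
) -> tuple[int, int, int]:
    """Recover planted U-to-autosome translocations over several seeds.

    Each replicate plants 4 translocated loci among 40 gametolog pairs;
    the full classification pipeline then calls candidates.  Returns
    (n_seeds, n_exact_recoveries, total_false_positives).
    """
    exact = false_pos = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed + i, gametolog_cfg=GametologConfig(
            n_gametolog_pairs=40, n_pseudoautosomal=8, n_outgroup_loci=8,
            n_translocated_U_loci=4))
        loci, truth = simulate_sex_loci(cfg)
        records = []
        for row in truth:
            locus = row["locus"]
            lc = (loci.female_seqs.get(row["lc_u_id"])
                  or loci.male_seqs.get(row["lc_u_id"]))
            lab = gam.classify_locus(lc, loci.mp_u[locus], loci.mp_v[locus],
                                     loci.outgroups[locus])
            genomic = gam.classify_genomic(lc, loci.female_genome,
                                           loci.male_genome)
            v_in_male = (row["lc_v_id"] is not None
                         and row["lc_v_id"] in loci.male_seqs)
            records.append(gam.LocusRecord(locus, lab, genomic, v_in_male))
        called = set(gam.infer_translocation(records))
        planted = {r["locus"] for r in truth if r["translocated"]}
        exact += called == planted
        false_pos += len(called - planted)
    return n_seeds, exact, false_pos
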