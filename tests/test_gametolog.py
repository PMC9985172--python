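"""Quartet trees, U/V/O classification, presence search, translocation calls."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from bryostruct import gametolog as gam
from bryostruct.simulate import (
    GametologConfig,
    SimConfig,
    mutate_jc,
    random_sequence,
    simulate_sex_loci,
)


def tree_from_newick(nwk: str) -> TreeNode:
    t = TreeNode.read(io.StringIO(nwk))
    t.resolved = True
    return t


class TestBuildTree:
    def test_fewer_than_four_rejected(self, rng):
        seqs = {n: random_sequence(rng, 200) for n in "abc"}
        with pytest.raises(ValueError):
            gam.build_tree(seqs)

    def test_identical_pair_forms_cherry(self, rng):
        a = random_sequence(rng, 600)
        twin = a
        b = mutate_jc(rng, a, 0.3)
        c = mutate_jc(rng, b, 0.3)
        tree = gam.build_tree({"t1": a, "t2": twin, "x": b, "y": c})
        # the identical pair must sit on the same side of the internal split
        for node in tree.non_tips():
            names = {t.name for t in node.tips()}
            if len(names) == 2:
                assert names in ({"t1", "t2"}, {"x", "y"})

    def test_recovers_generating_quartet_topology(self, rng):
        anc = random_sequence(rng, 1000)
        left = mutate_jc(rng, anc, 0.15)
        right = mutate_jc(rng, anc, 0.15)
        seqs = {
            "A": mutate_jc(rng, left, 0.05),
            "B": mutate_jc(rng, left, 0.05),
            "C": mutate_jc(rng, right, 0.05),
            "D": mutate_jc(rng, right, 0.05),
        }
        tree = gam.build_tree(seqs)
        sides = [frozenset(t.name for t in n.tips())
                 for n in tree.non_tips()]
        two_tip = {s for s in sides if len(s) == 2}
        assert two_tip <= {frozenset("AB"), frozenset("CD")}
        assert two_tip

    def test_all_identical_flagged_unresolved(self, rng):
        s = random_sequence(rng, 300)
        tree = gam.build_tree({n: s for n in ("a", "b", "c", "d")})
        assert tree.resolved is False


class TestClassifyPhylo:
    def test_u_split(self):
        tree = tree_from_newick("((Lc:1,MpU:1):2,(MpV:1,out:1):2);")
        assert gam.classify_phylo(tree).label == "U"

    def test_v_split(self):
        tree = tree_from_newick("((Lc:1,MpV:1):2,(MpU:1,out:1):2);")
        assert gam.classify_phylo(tree).label == "V"

    def test_o_split_gametologs_are_sisters(self):
        tree = tree_from_newick("((MpU:1,MpV:1):2,(Lc:1,out:1):2);")
        assert gam.classify_phylo(tree).label == "O"

    def test_invariant_to_rotation_and_rerooting(self):
        base = tree_from_newick("((Lc:1,MpU:1):2,(MpV:1,out:1):2);")
        rotated = tree_from_newick("((out:1,MpV:1):2,(MpU:1,Lc:1):2);")
        rerooted = base.root_at(base.find("out"))
        rerooted.resolved = True
        assert gam.classify_phylo(base).label == "U"
        assert gam.classify_phylo(rotated).label == "U"
        assert gam.classify_phylo(rerooted).label == "U"

    def test_missing_tip_rejected(self):
        tree = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="missing"):
            gam.classify_phylo(tree)

    def test_exhaustive_and_exclusive_over_quartets(self):
        # every resolved quartet topology yields exactly one label
        labels = set()
        for nwk in ("((Lc:1,MpU:1):2,(MpV:1,out:1):2);",
                    "((Lc:1,MpV:1):2,(MpU:1,out:1):2);",
                    "((Lc:1,out:1):2,(MpU:1,MpV:1):2);"):
            lab = gam.classify_phylo(tree_from_newick(nwk))
            assert lab.resolved
            labels.add(lab.label)
        assert labels == {"U", "V", "O"}

    def test_distance_fallback_without_outgroup(self, rng):
        anc = random_sequence(rng, 1000)
        u = mutate_jc(rng, anc, 0.15)
        v = mutate_jc(rng, anc, 0.15)
        lc_u = mutate_jc(rng, u, 0.05)
        mp_u = mutate_jc(rng, u, 0.05)
        mp_v = mutate_jc(rng, v, 0.05)
        assert gam.classify_phylo_distances(lc_u, mp_u, mp_v).label == "U"


class TestClassifyGenomic:
    def _genomes(self, rng, planted_f=None, planted_m=None):
        f = {"sf": random_sequence(rng, 3000)}
        m = {"sm": random_sequence(rng, 3000)}
        if planted_f is not None:
            f["sf"] = f["sf"][:1000] + planted_f + f["sf"][1000:]
        if planted_m is not None:
            m["sm"] = m["sm"][:500] + planted_m + m["sm"][500:]
        return f, m

    def test_female_only_is_u_linked(self, rng):
        q = random_sequence(rng, 800)
        f, m = self._genomes(rng, planted_f=q)
        assert gam.classify_genomic(q, f, m) == "U-linked"

    def test_both_is_autosomal(self, rng):
        q = random_sequence(rng, 800)
        f, m = self._genomes(rng, planted_f=q, planted_m=q)
        assert gam.classify_genomic(q, f, m) == "autosomal"

    def test_male_only_is_v_linked(self, rng):
        q = random_sequence(rng, 800)
        f, m = self._genomes(rng, planted_m=q)
        assert gam.classify_genomic(q, f, m) == "V-linked"

    def test_absent_is_unplaced(self, rng):
        q = random_sequence(rng, 800)
        f, m = self._genomes(rng)
        assert gam.classify_genomic(q, f, m) == "unplaced"

    def test_diverged_copy_below_threshold_not_found(self, rng):
        q = random_sequence(rng, 800)
        far = mutate_jc(rng, q, 0.30)  # ~26% sites differ >> 5% allowance
        f, m = self._genomes(rng, planted_f=far)
        assert gam.classify_genomic(q, f, m) == "unplaced"

    def test_empty_genome_rejected(self, rng):
        q = random_sequence(rng, 100)
        with pytest.raises(ValueError):
            gam.classify_genomic(q, {}, {"s": q})


class TestSameGametolog:
    def test_identical_true(self, rng):
        s = random_sequence(rng, 500)
        assert gam.same_gametolog(s, s) is True

    def test_deeply_diverged_false(self, rng):
        u = random_sequence(rng, 500)
        v = mutate_jc(rng, u, 0.4)
        assert gam.same_gametolog(u, v) is False

    def test_boundary_99_percent_inclusive(self, rng):
        s = random_sequence(rng, 100)
        one_sub = ("A" if s[0] != "A" else "C") + s[1:]
        assert gam.same_gametolog(s, one_sub) is True  # identity == 0.99


class TestScaffoldIdentity:
    def test_identical_scaffolds(self, rng):
        s = random_sequence(rng, 10_000)
        assert gam.scaffold_identity(s, s) == 100.0

    def test_one_substitution_in_100(self, rng):
        s = random_sequence(rng, 100)
        mut = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        assert gam.scaffold_identity(s, mut) == pytest.approx(99.0)

    def test_simulated_pseudoautosomal_above_99(self):
        cfg = SimConfig(seed=21)
        loci, truth = simulate_sex_loci(cfg)
        ident = gam.scaffold_identity(
            loci.female_genome["scaffold_auto1"],
            loci.male_genome["scaffold_auto1"],
        )
        assert ident > 99.0


class TestInferTranslocation:
    def _rec(self, locus, label, genomic, v_present, resolved=True):
        return gam.LocusRecord(
            locus, gam.PhyloLabel(label, 1.0, resolved), genomic, v_present)

    def test_rule_table(self):
        records = [
            self._rec("cand", "U", "autosomal", False),
            self._rec("still_u_linked", "U", "U-linked", False),
            self._rec("v_survives", "U", "autosomal", True),
            self._rec("outgroup", "O", "autosomal", False),
            self._rec("v_locus", "V", "V-linked", False),
        ]
        assert gam.infer_translocation(records) == ["cand"]

    def test_unresolved_phylo_excluded(self):
        records = [self._rec("shaky", "U", "autosomal", False, resolved=False)]
        assert gam.infer_translocation(records) == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gam.infer_translocation([])


class TestEndToEndRecovery:
    def test_simulated_loci_classified_correctly(self):
        cfg = SimConfig(seed=33, gametolog_cfg=GametologConfig(
            n_gametolog_pairs=20, n_pseudoautosomal=5, n_outgroup_loci=5,
            n_translocated_U_loci=2))
        loci, truth = simulate_sex_loci(cfg)
        records = []
        n_phylo_ok = n_genomic_ok = 0
        for row in truth:
            locus = row["locus"]
            lc = loci.female_seqs.get(row["lc_u_id"]) \
                or loci.male_seqs.get(row["lc_u_id"])
            lab = gam.classify_locus(lc, loci.mp_u[locus], loci.mp_v[locus],
                                     loci.outgroups[locus])
            genomic = gam.classify_genomic(lc, loci.female_genome,
                                           loci.male_genome)
            n_phylo_ok += lab.label == row["true_phylo_label_u"]
            n_genomic_ok += genomic == row["true_genomic_label"]
            v_in_male = (row["lc_v_id"] is not None
                         and row["lc_v_id"] in loci.male_seqs)
            records.append(gam.LocusRecord(locus, lab, genomic, v_in_male))
        assert n_phylo_ok >= 0.9 * len(truth)
        assert n_genomic_ok == len(truth)
        called = set(gam.infer_translocation(records))
        planted = {r["locus"] for r in truth if r["translocated"]}
        assert called == planted
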