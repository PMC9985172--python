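"""GFF3/RepeatMasker/anchor IO, gene ranking and annotation statistics."""

import pytest

from bryostruct import formats_io as fio


GFF3_THREE_GENES = """##gff-version 3
s1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1
s1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1
s1\tsrc\texon\t1\t300\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
s1\tsrc\tCDS\t1\t300\t.\t+\t0\tID=g1.1.c1;Parent=g1.1
s1\tsrc\tgene\t501\t900\t.\t-\t.\tID=g2
s1\tsrc\tmRNA\t501\t900\t.\t-\t.\tID=g2.1;Parent=g2
s1\tsrc\texon\t501\t700\t.\t-\t.\tID=g2.1.e1;Parent=g2.1
s1\tsrc\texon\t751\t900\t.\t-\t.\tID=g2.1.e2;Parent=g2.1
s1\tsrc\tCDS\t501\t700\t.\t-\t0\tID=g2.1.c1;Parent=g2.1
s1\tsrc\tCDS\t751\t900\t.\t-\t0\tID=g2.1.c2;Parent=g2.1
s2\tsrc\tgene\t11\t310\t.\t+\t.\tID=g3
s2\tsrc\tmRNA\t11\t310\t.\t+\t.\tID=g3.1;Parent=g3
s2\tsrc\texon\t11\t310\t.\t+\t.\tID=g3.1.e1;Parent=g3.1
s2\tsrc\tCDS\t11\t310\t.\t+\t0\tID=g3.1.c1;Parent=g3.1
"""


class TestReadGff3:
    def test_three_gene_fixture_converts_coordinates(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(GFF3_THREE_GENES)
        genes = fio.read_gff3(p)
        assert len(genes) == 3
        by_id = {g.gene_id: g for g in genes}
        # GFF 1..300 becomes internal (0, 300)
        assert (by_id["g1"].start, by_id["g1"].end) == (0, 300)
        assert (by_id["g3"].start, by_id["g3"].end) == (10, 310)
        assert by_id["g2"].strand == "-"
        assert by_id["g2"].exons == ((500, 700), (750, 900))

    def test_longest_mrna_is_representative(self, tmp_path):
        lines = [
            "##gff-version 3",
            "s1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=g1",
            "s1\tsrc\tmRNA\t1\t900\t.\t+\t.\tID=g1.long;Parent=g1",
            "s1\tsrc\texon\t1\t900\t.\t+\t.\tID=e1;Parent=g1.long",
            "s1\tsrc\tCDS\t1\t900\t.\t+\t0\tID=c1;Parent=g1.long",
            "s1\tsrc\tmRNA\t1\t600\t.\t+\t.\tID=g1.short;Parent=g1",
            "s1\tsrc\texon\t1\t600\t.\t+\t.\tID=e2;Parent=g1.short",
            "s1\tsrc\tCDS\t1\t600\t.\t+\t0\tID=c2;Parent=g1.short",
        ]
        p = tmp_path / "iso.gff3"
        p.write_text("\n".join(lines) + "\n")
        (gene,) = fio.read_gff3(p)
        assert gene.exons == ((0, 900),)
        assert gene.protein_length == 300

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\ns1\tsrc\tgene\t1\t300\n")
        with pytest.raises(fio.ParseError, match="line 2"):
            fio.read_gff3(p)

    def test_gene_without_cds_skipped(self, tmp_path):
        lines = [
            "s1\tsrc\tgene\t1\t300\t.\t+\t.\tID=nc1",
            "s1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=nc1.1;Parent=nc1",
            "s1\tsrc\texon\t1\t300\t.\t+\t.\tID=e;Parent=nc1.1",
        ]
        p = tmp_path / "nc.gff3"
        p.write_text("\n".join(lines) + "\n")
        assert fio.read_gff3(p) == []

    def test_roundtrip(self, tmp_path, multi_exon_genes):
        p = tmp_path / "rt.gff3"
        fio.write_gff3(multi_exon_genes, p)
        back = fio.read_gff3(p)
        orig = {(g.gene_id, g.scaffold, g.start, g.end, g.strand, g.exons)
                for g in multi_exon_genes}
        got = {(g.gene_id, g.scaffold, g.start, g.end, g.strand, g.exons)
               for g in back}
        assert got == orig


class TestRankGenes:
    def test_ranks_follow_start_order(self, gene_factory):
        genes = [gene_factory(f"g{i}", "s1", start, start + 50)
                 for i, start in enumerate([900, 10, 500])]
        ranked = {g.gene_id: g.rank for g in fio.rank_genes(genes)}
        assert ranked == {"g1": 0, "g2": 1, "g0": 2}

    def test_tie_break_by_end_then_id(self, gene_factory):
        genes = [
            gene_factory("gz", "s1", 100, 300),
            gene_factory("ga", "s1", 100, 200),
            gene_factory("gb", "s1", 100, 200),
        ]
        ranked = {g.gene_id: g.rank for g in fio.rank_genes(genes)}
        assert ranked == {"ga": 0, "gb": 1, "gz": 2}

    def test_ranks_restart_per_scaffold(self, gene_factory):
        genes = [gene_factory(f"g{i}", f"s{1 + i % 2}", 100 * (i + 1),
                              100 * (i + 1) + 50) for i in range(6)]
        ranked = fio.rank_genes(genes)
        # brute force: independently sort each scaffold
        for scaffold in ("s1", "s2"):
            sub = sorted((g for g in genes if g.scaffold == scaffold),
                         key=lambda g: g.start)
            expected = {g.gene_id: i for i, g in enumerate(sub)}
            for g in ranked:
                if g.scaffold == scaffold:
                    assert g.rank == expected[g.gene_id]

    def test_idempotent_and_permutation_invariant(self, multi_exon_genes):
        once = fio.rank_genes(multi_exon_genes)
        twice = fio.rank_genes(once)
        assert {(g.gene_id, g.rank) for g in once} == \
               {(g.gene_id, g.rank) for g in twice}
        shuffled = fio.rank_genes(list(reversed(multi_exon_genes)))
        assert {(g.gene_id, g.rank) for g in shuffled} == \
               {(g.gene_id, g.rank) for g in once}

    def test_duplicate_id_rejected(self, gene_factory):
        genes = [gene_factory("g1", "s1", 0, 50),
                 gene_factory("g1", "s1", 100, 150)]
        with pytest.raises(ValueError, match="duplicate"):
            fio.rank_genes(genes)


class TestAnnotationStats:
    def test_single_exon_gene(self, gene_factory):
        st = fio.annotation_stats([gene_factory("g", "s", 0, 300)])
        assert st.mean_gene_length == 300
        assert st.exons_per_mrna == 1
        assert st.mean_intron_length == 0
        assert st.has_introns is False

    def test_two_exon_gene_arithmetic(self):
        g = fio.GeneRecord("g", "s", 0, 350, "+",
                           exons=((0, 100), (150, 350)), protein_length=100)
        st = fio.annotation_stats([g])
        assert st.mean_exon_length == 150
        assert st.mean_intron_length == 50

    def test_matches_brute_force_recomputation(self, rng, gene_factory):
        genes = []
        for i in range(10):
            n_ex = int(rng.integers(1, 5))
            start = int(rng.integers(0, 1000))
            exons, pos = [], start
            for _ in range(n_ex):
                ex_len = int(rng.integers(50, 400))
                exons.append((pos, pos + ex_len))
                pos += ex_len + int(rng.integers(30, 200))
            end = exons[-1][1]
            genes.append(fio.GeneRecord(f"g{i}", "s1", start, end, "+",
                                        exons=tuple(exons),
                                        protein_length=max(1, (end - start) // 3)))
        st = fio.annotation_stats(genes)
        # spreadsheet-style: flatten, re-sum
        all_exons = [e - s for g in genes for s, e in g.exons]
        all_introns = [g.exons[i + 1][0] - g.exons[i][1]
                       for g in genes for i in range(len(g.exons) - 1)]
        assert st.mean_gene_length == pytest.approx(
            sum(g.end - g.start for g in genes) / 10)
        assert st.mean_exon_length == pytest.approx(
            sum(all_exons) / len(all_exons))
        assert st.mean_intron_length == pytest.approx(
            sum(all_introns) / len(all_introns))
        assert st.exons_per_mrna == pytest.approx(len(all_exons) / 10)

    def test_copies_leave_means_unchanged(self, gene_factory):
        g = gene_factory("g0", "s", 0, 300)
        single = fio.annotation_stats([g])
        copies = [fio.GeneRecord(f"g{i}", "s", 0, 300, "+", ((0, 300),), 100)
                  for i in range(5)]
        multi = fio.annotation_stats(copies)
        assert multi.mean_gene_length == single.mean_gene_length
        assert multi.exons_per_mrna == single.exons_per_mrna

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fio.annotation_stats([])


RM_OUT = """   SW   perc perc perc  query  position in query  matching repeat ...
score   div. del. ins.  sequence begin end (left) repeat class/family ...

  463   12.5  0.0  0.0  scaf1  101  600  (0)  +  FamA  LTR/Gypsy  1  500  (0)  1
  300    3.2  0.0  0.0  scaf1  700  900  (0)  +  FamB  LTR/Copia  1  200  (0)  2
  211   30.0  0.0  0.0  scaf2  1  150  (0)  C  FamC  DNA/hAT  1  150  (0)  3
"""


class TestRepeatMaskerOut:
    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "h.out"
        p.write_text("\n".join(RM_OUT.splitlines()[:3]) + "\n")
        assert fio.read_repeatmasker_out(p) == []

    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_OUT)
        hits = fio.read_repeatmasker_out(p)
        assert len(hits) == 3
        assert hits[0].scaffold == "scaf1"
        assert (hits[0].start, hits[0].end) == (100, 600)
        assert hits[0].divergence_pct == 12.5
        assert hits[0].family == "FamA"
        assert hits[0].superfamily == "Ty3/Gypsy"
        assert hits[1].superfamily == "Ty1/Copia"
        assert hits[2].superfamily == "DNA"

    def test_truncated_line_rejected(self, tmp_path):
        p = tmp_path / "t.out"
        p.write_text("\n".join(RM_OUT.splitlines()[:3])
                     + "\n  463  12.5  0.0\n")
        with pytest.raises(fio.ParseError, match="line 4"):
            fio.read_repeatmasker_out(p)

    @pytest.mark.parametrize("class_string,expected", [
        ("LTR/Gypsy", "Ty3/Gypsy"),
        ("LTR/Copia", "Ty1/Copia"),
        ("LINE/L1", "LINE"),
        ("DNA/hAT-Ac", "DNA"),
        ("Unknown", "unknown"),
        ("Satellite", "other"),
    ])
    def test_class_mapping(self, class_string, expected):
        assert fio.classify_repeat_family(class_string) == expected

    def test_write_read_roundtrip_counts(self, tmp_path):
        hits = [fio.RepeatHit("s", i * 1000, i * 1000 + 500, "F",
                              "Ty3/Gypsy", 5.0 + i) for i in range(4)]
        p = tmp_path / "w.out"
        fio.write_repeatmasker_out(hits, p)
        back = fio.read_repeatmasker_out(p)
        assert [(h.start, h.end, h.divergence_pct) for h in back] == \
               [(h.start, h.end, h.divergence_pct) for h in hits]


class TestAnchorTable:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert fio.read_anchor_table(p) == []

    def test_five_rows(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("".join(f"a{i}\tb{i}\t0.{i + 1}\n" for i in range(5)))
        pairs = fio.read_anchor_table(p)
        assert len(pairs) == 5
        assert pairs[2] == ("a2", "b2", 0.3)

    def test_two_columns_default_similarity(self, tmp_path):
        p = tmp_path / "a2.tsv"
        p.write_text("x\ty\nu\tv\n")
        pairs = fio.read_anchor_table(p)
        assert all(sim == 1.0 for _, _, sim in pairs)
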