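"""Tandem/segmental classification, clock dating and exon bookkeeping."""

import numpy as np
import pytest

from burpfam.duplication import (
    AnchorSet,
    DuplicationPair,
    GeneModel,
    date_pair,
    exon_count,
    read_anchors_tsv,
    read_gff3,
    segmental_pairs,
    tandem_pairs,
    unique_genes,
    write_gff3,
)


def genes_at_ranks(family_ranks, n=30, chrom="chr1"):
    """A chromosome of n genes at 1000-bp spacing; family genes at the given
    0-based ranks."""
    fam = set(family_ranks)
    out = []
    for k in range(n):
        gid = f"fam{k}" if k in fam else f"bg{k}"
        start = 1000 * (k + 1)
        out.append(
            GeneModel(id=gid, species="sp", chromosome=chrom,
                      start=start, end=start + 500, strand="+",
                      exons=[(start, start + 500)])
        )
    return out, {f"fam{k}" for k in fam}


class TestTandem:
    @pytest.mark.parametrize(
        "ranks,expected_intervening,is_tandem",
        [((5, 7), 1, True), ((5, 16), 10, True), ((5, 17), 11, False)],
    )
    def test_intervening_gene_rule_boundaries(self, ranks, expected_intervening, is_tandem):
        genes, fam = genes_at_ranks(ranks)
        pairs = tandem_pairs(genes, fam)
        if is_tandem:
            assert len(pairs) == 1
            assert pairs[0].intervening_genes == expected_intervening
        else:
            assert pairs == []

    def test_different_chromosomes_never_tandem(self):
        g1, f1 = genes_at_ranks([0], chrom="chr1")
        g2, f2 = genes_at_ranks([1], chrom="chr2")
        # rename to avoid id collisions
        for g in g2:
            g.id += "_c2"
        pairs = tandem_pairs(g1 + g2, {"fam0", "fam1_c2"})
        assert pairs == []

    def test_family_members_counted_as_intervening(self):
        genes, fam = genes_at_ranks([3, 4, 5])
        pairs = tandem_pairs(genes, fam)
        # pair (3,5) has the family gene at rank 4 as its intervening gene
        p = next(p for p in pairs if {p.id_a, p.id_b} == {"fam3", "fam5"})
        assert p.intervening_genes == 1

    def test_invariant_to_record_shuffling(self, rng):
        genes, fam = genes_at_ranks([2, 5, 9, 25])
        ref = tandem_pairs(genes, fam)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert tandem_pairs(shuffled, fam) == ref


class TestSegmental:
    def test_block_kept_with_mean(self):
        block = AnchorSet("b1", [("a", "b", 0.4), ("c", "d", 0.5), ("e", "f", 0.6)])
        pairs = segmental_pairs([block])
        assert len(pairs) == 3
        assert pairs[0].ks_mean == pytest.approx(0.5)

    def test_ks_filter_then_anchor_count_filter(self):
        block = AnchorSet("b1", [("a", "b", 0.4), ("c", "d", 1.2), ("e", "f", 0.5)])
        assert segmental_pairs([block]) == []

    def test_family_restriction(self):
        block = AnchorSet(
            "b1", [("a", "b", 0.4), ("c", "d", 0.5), ("e", "f", 0.6)]
        )
        pairs = segmental_pairs([block], family_ids={"a", "b"})
        assert [(p.id_a, p.id_b) for p in pairs] == [("a", "b")]

    def test_planted_block_recovered(self, family):
        fam_ids = set(family.truth_members.loc[~family.truth_members.is_decoy, "id"])
        pairs = segmental_pairs(family.anchor_sets, fam_ids)
        truth = {
            frozenset((r.id_a, r.id_b))
            for r in family.truth_duplications.itertuples()
            if r.mode == "segmental"
        }
        assert {frozenset((p.id_a, p.id_b)) for p in pairs} == truth

    def test_unique_gene_count_by_set_union(self):
        pairs = [
            DuplicationPair("a", "b", "segmental"),
            DuplicationPair("b", "c", "segmental"),
        ]
        assert unique_genes(pairs) == {"a", "b", "c"}


class TestDating:
    @pytest.mark.parametrize(
        "ks,lam,expected",
        [(0.795, 1.5e-8, 26.5), (0.553, 6.1e-9, 45.3), (0.0, 1e-8, 0.0)],
    )
    def test_published_clock_examples(self, ks, lam, expected):
        rounded, _ = date_pair(ks, lam)
        assert rounded == expected

    def test_linear_in_ks_inverse_in_lambda(self):
        _, base = date_pair(0.4, 1e-8)
        assert date_pair(0.8, 1e-8)[1] == pytest.approx(2 * base)
        assert date_pair(0.4, 2e-8)[1] == pytest.approx(base / 2)

    def test_nonpositive_lambda_is_error(self):
        with pytest.raises(ValueError):
            date_pair(0.5, 0.0)


class TestExons:
    def test_exon_counts(self):
        g = GeneModel("g", "sp", "c", 1, 1000, "+", exons=[(1, 300), (500, 1000)])
        assert exon_count(g) == 2
        g1 = GeneModel("g", "sp", "c", 1, 1000, "+", exons=[(1, 1000)])
        assert exon_count(g1) == 1

    def test_empty_exon_list_is_error(self):
        g = GeneModel("g", "sp", "c", 1, 1000, "+")
        with pytest.raises(ValueError):
            exon_count(g)

    def test_gff_round_trip_many_exons(self, tmp_path):
        exons = [(100 * k + 1, 100 * k + 50) for k in range(18)]
        g = GeneModel("g18", "sp", "chr9", 1, 1800, "+", exons=exons)
        write_gff3([g], tmp_path / "x.gff3")
        back = read_gff3(tmp_path / "x.gff3")
        assert len(back) == 1 and exon_count(back[0]) == 18
        assert back[0].exons == exons


class TestAnchorIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "anchors.tsv"
        path.write_text(
            "block_id\tgene_a\tgene_b\tks\nb1\ta\tb\t0.4\nb1\tc\td\t0.5\n"
        )
        blocks = read_anchors_tsv(path)
        assert len(blocks) == 1 and len(blocks[0].anchors) == 2

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "anchors.tsv"
        path.write_text("b1\ta\tb\tnot_a_number\n")
        with pytest.raises(ValueError, match=":1"):
            read_anchors_tsv(path)
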