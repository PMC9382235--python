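import numpy as np
import pytest

from paleodel import impact_annotation as ia
from paleodel.deletion_scan import DeletionCall
from paleodel.intervals import GenomeIntervalSet
from paleodel.io_formats import GeneModel, IndelVariant, Transcript
from tests.oracles import brute_fisher_two_sided


def gene(gene_id, chrom, start, end, strand="+", exons=None, cds=None):
    exons = exons or [(start, end)]
    cds = cds if cds is not None else exons
    return GeneModel(gene_id, chrom, start, end, strand,
                     [Transcript(f"{gene_id}.t1", exons, cds)])


def simple_indel(chrom, pos, ref, alt):
    return IndelVariant(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,),
        genotypes={}, allele_depths={}, qual=100.0, qd=None, fs=None,
        read_pos_rank_sum=None,
    )


class TestPartition:
    def test_arithmetic_partition(self):
        g = gene("g1", "c", 0, 100, exons=[(0, 30), (70, 100)])
        part = ia.build_partition([g], {"c": 200})
        assert part.exon.total_length() == 60
        assert part.intron.total_length() == 40
        assert part.intergenic.total_length() == 100

    def test_exon_precedence_over_overlapping_gene_intron(self):
        a = gene("a", "c", 0, 100, exons=[(0, 30), (70, 100)])
        b = gene("b", "c", 10, 60, exons=[(10, 50)])  # exon covers a's intron 30..50
        part = ia.build_partition([a, b], {"c": 200})
        cats = part.classify("c", np.array([40]))
        assert cats[0] == 0  # exon wins
        assert part.exon.total_length() + part.intron.total_length() + part.intergenic.total_length() == 200

    def test_no_genes_everything_intergenic(self):
        part = ia.build_partition([], {"c": 500})
        assert part.intergenic.total_length() == 500

    def test_gene_span_smaller_than_exons_rejected(self):
        g = gene("g1", "c", 10, 50, exons=[(0, 30)])
        with pytest.raises(ValueError):
            ia.build_partition([g], {"c": 200})

    def test_partition_conservation_on_simulation(self, small_sim):
        lengths = {c: len(s) for c, s in small_sim.reference.items()}
        part = ia.build_partition(small_sim.gene_models, lengths)
        total = sum(s.total_length() for s in part.category_sets().values())
        assert total == sum(lengths.values())


class TestPositionSampling:
    @pytest.fixture
    def half_exon_partition(self):
        g = gene("g1", "c", 0, 500, exons=[(0, 500)])
        return ia.build_partition([g], {"c": 1000})

    def test_binomial_fraction_and_determinism(self, half_exon_partition):
        regions = GenomeIntervalSet.from_records([("c", 0, 1000)])
        n = 100_000
        counts = ia.sample_random_positions(n, regions, half_exon_partition, seed=5)
        assert sum(counts.values()) == n
        # 50/50 partition: exon fraction within 4 SD of 0.5
        sd = (0.25 / n) ** 0.5
        assert abs(counts["exon"] / n - 0.5) < 4 * sd
        again = ia.sample_random_positions(n, regions, half_exon_partition, seed=5)
        assert counts == again

    def test_single_draw(self, half_exon_partition):
        regions = GenomeIntervalSet.from_records([("c", 0, 1000)])
        counts = ia.sample_random_positions(1, regions, half_exon_partition, seed=1)
        assert sum(counts.values()) == 1

    def test_empty_regions_rejected(self, half_exon_partition):
        with pytest.raises(ValueError):
            ia.sample_random_positions(10, GenomeIntervalSet(), half_exon_partition, seed=1)

    def test_length_weighting_within_variants(self, half_exon_partition):
        # 90 intergenic bases + 10 exonic bases of variant footprint
        variants = [("c", 600, 690), ("c", 100, 110)]
        n = 50_000
        counts = ia.sample_positions_within_variants(variants, n, half_exon_partition, seed=3)
        frac = counts["exon"] / n
        sd = (0.1 * 0.9 / n) ** 0.5
        assert abs(frac - 0.1) < 4 * sd

    def test_deletion_call_weighted_by_length(self, half_exon_partition):
        calls = [DeletionCall("c", 700, 800, 0.0, {})]
        counts = ia.sample_positions_within_variants(calls, 1000, half_exon_partition, seed=3)
        assert counts["intergenic"] == 1000


class TestEnrichment:
    def test_null_table(self):
        res = ia.enrichment_test(
            {"a": 10, "b": 10}, {"a": 10, "b": 10}, "a", "b"
        )
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fold_definition(self):
        res = ia.enrichment_test(
            {"a": 1000, "b": 1000}, {"a": 1900, "b": 1000}, "a", "b"
        )
        assert res.fold == pytest.approx(1.9)

    def test_zero_marginal_fold_undefined(self):
        res = ia.enrichment_test({"a": 10, "b": 10}, {"a": 5, "b": 0}, "a", "b")
        assert res.fold is None
        assert 0 < res.p_value <= 1

    @pytest.mark.parametrize(
        "table", [((8, 2), (1, 5)), ((0, 10), (10, 0)), ((3, 3), (3, 3)), ((12, 0), (0, 0))]
    )
    def test_p_matches_exhaustive_enumeration(self, table):
        res = ia.enrichment_test(
            {"a": table[1][0], "b": table[1][1]},
            {"a": table[0][0], "b": table[0][1]},
            "a", "b",
        )
        assert res.p_value == pytest.approx(brute_fisher_two_sided(table), rel=1e-9)


class TestCodingImpact:
    @pytest.fixture
    def coding_gene(self):
        # + strand, exons (100,200) and (300,400), CDS (130,200)+(300,370)
        return gene("g1", "c", 100, 400, exons=[(100, 200), (300, 400)],
                    cds=[(130, 200), (300, 370)])

    def test_deletion_spanning_exons(self, coding_gene):
        d = DeletionCall("c", 150, 350, 0.0, {})
        impacts = ia.classify_coding_impact([d], [], [coding_gene])
        assert {i.consequence for i in impacts} == {"exon_deleted"}

    def test_intronic_deletion_no_impact(self, coding_gene):
        d = DeletionCall("c", 210, 290, 0.0, {})
        assert ia.classify_coding_impact([d], [], [coding_gene]) == []

    @pytest.mark.parametrize(
        "ref_len,expected", [(5, "frameshift"), (4, "inframe_indel")]
    )
    def test_frameshift_by_size_mod_three(self, coding_gene, ref_len, expected):
        v = simple_indel("c", 150, "A" * ref_len, "A")
        impacts = ia.classify_coding_impact([], [v], [coding_gene])
        assert any(i.consequence == expected for i in impacts)

    def test_start_lost_plus_strand(self, coding_gene):
        v = simple_indel("c", 130, "ACGT", "A")  # overlaps first codon 130..133
        impacts = ia.classify_coding_impact([], [v], [coding_gene])
        assert any(i.consequence == "start_lost" for i in impacts)

    def test_stop_lost_minus_strand_is_lowest_coords(self):
        g = gene("g1", "c", 100, 400, strand="-", exons=[(100, 200), (300, 400)],
                 cds=[(130, 200), (300, 370)])
        v = simple_indel("c", 130, "ACGT", "A")  # lowest CDS codon = stop on minus strand
        impacts = ia.classify_coding_impact([], [v], [g])
        assert any(i.consequence == "stop_lost" for i in impacts)

    def test_variant_on_unannotated_chromosome_ignored(self, coding_gene):
        v = simple_indel("other", 150, "ACGT", "A")
        assert ia.classify_coding_impact([], [v], [coding_gene]) == []


class TestAffectedGenes:
    def test_distinct_gene_count(self):
        impacts = [
            ia.CodingImpact("A", "v1", "exon_deleted"),
            ia.CodingImpact("A", "v2", "frameshift"),
            ia.CodingImpact("B", "v3", "stop_lost"),
        ]
        _, n = ia.affected_gene_summary(impacts)
        assert n == 2

    def test_inframe_only_not_counted(self):
        impacts = [ia.CodingImpact("A", "v1", "inframe_indel")]
        per_gene, n = ia.affected_gene_summary(impacts)
        assert n == 0 and "A" in per_gene

    def test_empty(self):
        assert ia.affected_gene_summary([]) == ({}, 0)
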