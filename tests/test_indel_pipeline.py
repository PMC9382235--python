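import pytest

from paleodel import indel_pipeline as ip
from paleodel.intervals import GenomeIntervalSet
from paleodel.io_formats import IndelVariant
from paleodel.mappability import MappabilityMask


def make_variant(
    tiny_manifest,
    pos=100,
    ref="ACGT",
    alts=("A",),
    qual=500.0,
    qd=20.0,
    fs=5.0,
    rprs=0.0,
    ingroup_gt=(1, 1),
    outgroup_gt=(0, 0),
    alt_reads=10,
    overrides=None,
):
    genotypes, depths = {}, {}
    for s in tiny_manifest.ingroup_samples():
        genotypes[s] = ingroup_gt
        depths[s] = (0, alt_reads) + (0,) * (len(alts) - 1)
    for g in tiny_manifest.outgroup_labels():
        for s in tiny_manifest.group_samples(g):
            genotypes[s] = outgroup_gt
            depths[s] = (30,) + (0,) * len(alts)
    for s, gt in (overrides or {}).items():
        genotypes[s] = gt
    return IndelVariant(
        chrom="c", pos=pos, ref=ref, alts=tuple(alts),
        genotypes=genotypes, allele_depths=depths,
        qual=qual, qd=qd, fs=fs, read_pos_rank_sum=rprs,
    )


def make_mask(unmappable=()):
    return MappabilityMask(
        GenomeIntervalSet.from_records(unmappable), 50, 1, 25, 250, {"c": 100_000}
    )


class TestSiteQuality:
    @pytest.mark.parametrize(
        "field,value,passes",
        [
            ("qd", 1.5, False),
            ("qd", 2.0, True),
            ("qd", 1.99, False),
            ("qual", 30.0, True),
            ("qual", 29.9, False),
            ("fs", 200.0, True),
            ("fs", 200.01, False),
            ("rprs", -20.0, True),
            ("rprs", -20.01, False),
        ],
    )
    def test_literal_boundary_semantics(self, tiny_manifest, field, value, passes):
        v = make_variant(tiny_manifest, **{field: value})
        assert ip.site_quality_filter(v) is passes

    def test_absent_statistics_never_fail(self, tiny_manifest):
        v = make_variant(tiny_manifest, qd=None, fs=None, rprs=None, qual=None)
        assert ip.site_quality_filter(v)


class TestMappability:
    def test_span_rule(self, tiny_manifest):
        mask = make_mask([("c", 102, 200)])
        inside = make_variant(tiny_manifest, pos=300, ref="ACGT")
        assert ip.mappability_filter(inside, mask)
        crossing = make_variant(tiny_manifest, pos=100, ref="ACGT")  # span [100,104)
        assert not ip.mappability_filter(crossing, mask)
        # 1 bp insertion adjacent to the mask boundary: span [101,102) is clear
        adjacent = make_variant(tiny_manifest, pos=101, ref="A", alts=("AT",))
        assert ip.mappability_filter(adjacent, mask)


class TestSupport:
    @pytest.mark.parametrize(
        "alt_counts,passes",
        [((2, 1, 1, 0, 1), True), ((1, 1, 1, 0, 0), False)],
    )
    def test_pooled_ingroup_alt_reads(self, tiny_manifest, alt_counts, passes):
        v = make_variant(tiny_manifest)
        for s, n in zip(tiny_manifest.ingroup_samples(), alt_counts):
            v.allele_depths[s] = (5, n)
        assert ip.support_filter(v, tiny_manifest) is passes

    def test_min_reads_one_any_nonzero(self, tiny_manifest):
        v = make_variant(tiny_manifest)
        for s in tiny_manifest.ingroup_samples():
            v.allele_depths[s] = (5, 0)
        v.allele_depths[tiny_manifest.ingroup_samples()[2]] = (5, 1)
        assert ip.support_filter(v, tiny_manifest, ip.FilterParams(min_support=1))

    def test_missing_allele_depths_count_zero(self, tiny_manifest):
        v = make_variant(tiny_manifest)
        for s in tiny_manifest.ingroup_samples():
            v.allele_depths[s] = None
        assert not ip.support_filter(v, tiny_manifest)


class TestSingleVariant:
    def test_single_alt_passes(self, tiny_manifest):
        assert ip.single_variant_filter(make_variant(tiny_manifest), tiny_manifest)

    def test_two_alts_in_ingroup_fail(self, tiny_manifest):
        v = make_variant(
            tiny_manifest, alts=("A", "AT"),
            overrides={"mam1": (1, 2)},
        )
        assert not ip.single_variant_filter(v, tiny_manifest)

    def test_multiallelic_site_with_single_ingroup_alt_passes(self, tiny_manifest):
        v = make_variant(
            tiny_manifest, alts=("A", "AT"), ingroup_gt=(2, 2),
        )
        assert ip.single_variant_filter(v, tiny_manifest)


class TestFixation:
    def test_fixed_lineage_specific(self, tiny_manifest):
        assert ip.fixed_lineage_specific(make_variant(tiny_manifest), tiny_manifest)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"mam1": (0, 1)},          # het in-group genotype
            {"mam1": (0, 0)},          # hom-ref in-group genotype
            {"afr1": (0, 1)},          # non-ref outgroup
            {"afr1": None},            # missing outgroup genotype
            {"mam3": None},            # missing in-group genotype
        ],
    )
    def test_any_violation_fails(self, tiny_manifest, overrides):
        v = make_variant(tiny_manifest, overrides=overrides)
        assert not ip.fixed_lineage_specific(v, tiny_manifest)

    def test_ingroup_fixed_for_second_alt(self, tiny_manifest):
        v = make_variant(tiny_manifest, alts=("AT", "ATT"), ref="A", ingroup_gt=(2, 2))
        assert ip.fixed_lineage_specific(v, tiny_manifest)


class TestSize:
    @pytest.mark.parametrize(
        "ref,alt,passes",
        [
            ("A" * 25, "A", True),     # 24 bp deletion
            ("A" * 26, "A", False),    # 25 bp deletion
            ("A", "AT", True),         # 1 bp insertion
            ("A" + "C" * 30, "A", False),
        ],
    )
    def test_strict_bound(self, tiny_manifest, ref, alt, passes):
        v = make_variant(tiny_manifest, ref=ref, alts=(alt,))
        assert ip.size_filter(v, tiny_manifest) is passes


class TestTally:
    def test_counts_and_base_totals(self, tiny_manifest):
        vs = [
            make_variant(tiny_manifest, ref="ACG", alts=("A",)),    # 2 bp deletion
            make_variant(tiny_manifest, ref="ACGT", alts=("A",)),   # 3 bp deletion
            make_variant(tiny_manifest, ref="A", alts=("AT",)),     # 1 bp insertion
        ]
        t = ip.tally(vs, tiny_manifest)
        assert (t.n_deletions, t.n_insertions) == (2, 1)
        assert (t.total_deleted_bases, t.total_inserted_bases) == (5, 1)

    def test_empty(self, tiny_manifest):
        t = ip.tally([], tiny_manifest)
        assert (t.n_deletions, t.n_insertions, t.total_deleted_bases, t.total_inserted_bases) == (0, 0, 0, 0)


class TestCascade:
    def test_passing_set_is_intersection_of_filters(self, tiny_manifest):
        """Each filter is a pure predicate, so the cascade equals the
        intersection regardless of evaluation order."""
        mask = make_mask([("c", 5000, 6000)])
        variants = [
            make_variant(tiny_manifest),
            make_variant(tiny_manifest, pos=5500),
            make_variant(tiny_manifest, qd=1.0),
            make_variant(tiny_manifest, overrides={"mam1": (0, 1)}),
            make_variant(tiny_manifest, ref="A" * 30, alts=("A",)),
        ]
        passing, outcomes = ip.apply_cascade(variants, tiny_manifest, mask)
        assert passing == [variants[0]]
        filters = ("site_quality", "mappable", "support", "single_variant", "fixed", "size")
        for v, row in zip(variants, outcomes):
            expected = (
                ip.site_quality_filter(v)
                and ip.mappability_filter(v, mask)
                and ip.support_filter(v, tiny_manifest)
                and ip.single_variant_filter(v, tiny_manifest)
                and ip.fixed_lineage_specific(v, tiny_manifest)
                and ip.size_filter(v, tiny_manifest)
            )
            assert row["pass"] is expected
            assert row["pass"] == all(row[f] for f in filters)
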