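import numpy as np
import pytest

from paleodel import deletion_scan as ds
from paleodel import synthetic_data as sd
from paleodel.intervals import GenomeIntervalSet
from paleodel.io_formats import SampleManifest
from paleodel.mappability import MappabilityMask, build_mappability_mask


def make_mask(lengths, unmappable=()):
    s = GenomeIntervalSet.from_records(unmappable)
    return MappabilityMask(s, 50, 1, 25, 250, dict(lengths))


def make_profile(group, depth, expected):
    return ds.DepthProfile(group, {"c": np.asarray(depth, dtype=np.int64)}, expected)


class TestSumGroupDepth:
    def test_expected_coverage_sums_member_means(self, tiny_manifest):
        depths = {s: {"c": np.zeros(10, dtype=int)} for s in tiny_manifest.samples}
        prof = ds.sum_group_depth(depths, tiny_manifest, "ingroup")
        assert prof.expected_coverage == pytest.approx(59.0)

    def test_elementwise_sum(self, tiny_manifest):
        depths = {s: {"c": np.zeros(3, dtype=int)} for s in tiny_manifest.samples}
        depths["mam1"]["c"] = np.array([1, 2, 3])
        depths["mam2"]["c"] = np.array([0, 1, 0])
        prof = ds.sum_group_depth(depths, tiny_manifest, "ingroup")
        assert prof.depths["c"].tolist() == [1, 3, 3]

    def test_single_sample_group_identity(self, tiny_manifest):
        depths = {s: {"c": np.arange(4)} for s in tiny_manifest.samples}
        prof = ds.sum_group_depth(depths, tiny_manifest, "asian")
        assert prof.depths["c"].tolist() == [0, 1, 2, 3]

    def test_chromosome_mismatch_rejected(self, tiny_manifest):
        depths = {s: {"c": np.zeros(3, dtype=int)} for s in tiny_manifest.samples}
        depths["mam1"] = {"other": np.zeros(3, dtype=int)}
        with pytest.raises(ValueError):
            ds.sum_group_depth(depths, tiny_manifest, "ingroup")


class TestScanCandidates:
    def test_zero_run_with_outgroup_support_found(self):
        depth = np.full(5000, 59)
        depth[1000:3000] = 0
        ing = make_profile("ingroup", depth, 59)
        og = make_profile("african", np.full(5000, 600), 633)
        mask = make_mask({"c": 5000})
        cands = ds.scan_candidate_runs(ing, [og], mask)
        assert cands.intervals("c") == [(1000, 3000)]

    def test_shared_zero_region_discarded(self):
        depth = np.full(5000, 59)
        depth[1000:3000] = 0
        og_depth = np.full(5000, 600)
        og_depth[1000:3000] = 0
        ing = make_profile("ingroup", depth, 59)
        og = make_profile("african", og_depth, 633)
        cands = ds.scan_candidate_runs(ing, [og], make_mask({"c": 5000}))
        assert len(cands) == 0

    def test_every_outgroup_must_support(self):
        depth = np.full(5000, 59)
        depth[1000:3000] = 0
        ing = make_profile("ingroup", depth, 59)
        good = make_profile("african", np.full(5000, 600), 633)
        bad_depth = np.full(5000, 170)
        bad_depth[1000:3000] = 5
        bad = make_profile("asian", bad_depth, 173)
        cands = ds.scan_candidate_runs(ing, [good, bad], make_mask({"c": 5000}))
        assert len(cands) == 0

    def test_zero_run_inside_unmappable_region_ignored(self):
        depth = np.full(5000, 59)
        depth[1000:3000] = 0
        ing = make_profile("ingroup", depth, 59)
        og = make_profile("african", np.full(5000, 600), 633)
        mask = make_mask({"c": 5000}, [("c", 900, 3100)])
        assert len(ds.scan_candidate_runs(ing, [og], mask)) == 0

    def test_unmappable_sites_split_runs(self):
        depth = np.full(5000, 59)
        depth[1000:3000] = 0
        ing = make_profile("ingroup", depth, 59)
        og = make_profile("african", np.full(5000, 600), 633)
        mask = make_mask({"c": 5000}, [("c", 1800, 2000)])
        cands = ds.scan_candidate_runs(ing, [og], mask)
        assert cands.intervals("c") == [(1000, 1800), (2000, 3000)]

    def test_mask_chromosome_mismatch_rejected(self):
        ing = make_profile("ingroup", np.zeros(10), 59)
        with pytest.raises(ValueError):
            ds.scan_candidate_runs(ing, [], make_mask({"other": 10}))


class TestMergeRules:
    def test_merge_adjacent_bookended_and_overlapping(self):
        for pair, expected in [
            ([("c", 0, 500), ("c", 500, 900)], [(0, 900)]),
            ([("c", 0, 500), ("c", 600, 900)], [(0, 500), (600, 900)]),
            ([("c", 0, 500), ("c", 400, 900)], [(0, 900)]),
        ]:
            merged = ds.merge_adjacent(GenomeIntervalSet.from_records(pair))
            assert merged.intervals("c") == expected

    def test_bridge_unmappable_requires_fully_masked_gap(self):
        cands = GenomeIntervalSet.from_records([("c", 0, 800), ("c", 1200, 2000)])
        full = make_mask({"c": 2000}, [("c", 800, 1200)])
        merged = ds.bridge_unmappable(cands, full)
        assert merged.intervals("c") == [(0, 2000)]
        assert "bridged_unmappable" in next(merged.records())[3]
        half = make_mask({"c": 2000}, [("c", 800, 1000)])
        assert ds.bridge_unmappable(cands, half).intervals("c") == [(0, 800), (1200, 2000)]

    def test_bridge_unmappable_chains_transitively(self):
        cands = GenomeIntervalSet.from_records(
            [("c", 0, 800), ("c", 1000, 1800), ("c", 2000, 2800)]
        )
        mask = make_mask({"c": 3000}, [("c", 800, 1000), ("c", 1800, 2000)])
        assert ds.bridge_unmappable(cands, mask).intervals("c") == [(0, 2800)]

    def test_bridge_low_coverage_rule(self):
        depth = np.full(3000, 59)
        depth[0:800] = 0
        depth[1000:1900] = 0
        depth[800:1000] = 4  # mean 4.0 < 5.9
        ing = make_profile("ingroup", depth, 59)
        cands = GenomeIntervalSet.from_records([("c", 0, 800), ("c", 1000, 1900)])
        merged = ds.bridge_low_coverage(cands, ing, max_gap=250, frac=0.10)
        assert merged.intervals("c") == [(0, 1900)]
        assert "bridged_lowcov" in next(merged.records())[3]

    def test_bridge_low_coverage_respects_threshold_and_gap(self):
        depth = np.full(3000, 59)
        cands = GenomeIntervalSet.from_records([("c", 0, 800), ("c", 1000, 1900)])
        depth[800:1000] = 8  # 8.0 >= 5.9: no merge
        ing = make_profile("ingroup", depth, 59)
        assert ds.bridge_low_coverage(cands, ing).intervals("c") == [(0, 800), (1000, 1900)]
        depth[800:1000] = 4
        far = GenomeIntervalSet.from_records([("c", 0, 500), ("c", 800, 1900)])
        ing = make_profile("ingroup", depth, 59)
        # gap 300 > 250: no merge even at low depth
        assert ds.bridge_low_coverage(far, ing).intervals("c") == [(0, 500), (800, 1900)]

    def test_bridging_threshold_is_ten_percent_of_expected(self):
        ing = make_profile("ingroup", np.zeros(10), 59)
        assert 0.10 * ing.expected_coverage == pytest.approx(5.9)


class TestFinalize:
    def test_strictly_longer_than_min_length(self):
        ing = make_profile("ingroup", np.zeros(3000), 59)
        cands = GenomeIntervalSet.from_records(
            [("c", 0, 500), ("c", 600, 1000), ("c", 1200, 1901)]
        )
        calls = ds.finalize_calls(cands, ing, [], min_length=500)
        assert [(c.start, c.end) for c in calls] == [(1200, 1901)]
        assert calls[0].length == 701


def _sim_profiles(seed, n_deletions, lengths=None):
    cfg = sd.SimulationConfig(
        seed=seed,
        chrom_lengths=lengths or {"chr1": 300_000},
        n_deletions=n_deletions,
        genes_per_chrom=4,
        n_indels=0,
        repeats_per_chrom=1,
    )
    sim = sd.simulate(cfg)
    manifest = sim.manifest
    ing = ds.sum_group_depth(sim.depth, manifest, "ingroup")
    ogs = [ds.sum_group_depth(sim.depth, manifest, g) for g in manifest.outgroup_labels()]
    return sim, ing, ogs


class TestEndToEnd:
    def test_planted_deletions_recovered_exactly(self):
        sim, ing, ogs = _sim_profiles(seed=21, n_deletions=4)
        mask = build_mappability_mask(sim.reference)
        calls = ds.call_deletions(ing, ogs, mask)
        got = [(c.chrom, c.start, c.end) for c in calls]
        assert got == [(c, s, e) for c, s, e in sim.truth.deletions]

    def test_no_false_positives_across_replicates(self):
        """Zero-coverage runs never arise by chance at 59X summed depth."""
        cfg = sd.SimulationConfig(
            seed=77, chrom_lengths={"chr1": 120_000}, n_deletions=0,
            genes_per_chrom=2, n_indels=0, repeats_per_chrom=1,
        )
        base = sd.simulate(cfg)
        mask = build_mappability_mask(base.reference)
        manifest = base.manifest
        rng = np.random.default_rng(78)
        for _ in range(100):
            depth = {
                s: {"chr1": rng.poisson(manifest.coverages[s], 120_000).astype(np.int32)}
                for s in manifest.samples
            }
            ing = ds.sum_group_depth(depth, manifest, "ingroup")
            ogs = [ds.sum_group_depth(depth, manifest, g) for g in manifest.outgroup_labels()]
            assert ds.call_deletions(ing, ogs, mask) == []

    def test_call_conservation_invariant(self):
        """Every site of a final call is low-depth, or inside a bridged gap."""
        sim, ing, ogs = _sim_profiles(seed=22, n_deletions=4)
        mask = build_mappability_mask(sim.reference)
        calls = ds.call_deletions(ing, ogs, mask)
        assert calls
        for c in calls:
            depth = ing.depths[c.chrom][c.start:c.end]
            mappable = mask.mappable_bool(c.chrom)[c.start:c.end]
            # with no bridged_lowcov flag, every mappable site is at t_in
            if "bridged_lowcov" not in c.flags:
                assert (depth[mappable] == 0).all()
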