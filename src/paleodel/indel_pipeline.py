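"""Filter a multi-sample indel VCF down to in-group-fixed, lineage-specific indels.

Each filter is a pure predicate on one record; the passing set is the
intersection, so cascade order never changes the result.  Boundary
semantics follow the printed hard-filter expressions literally: a site
fails on ``QD < 2.0``, ``QUAL < 30.0``, ``FS > 200.0`` or
``ReadPosRankSum < -20.0``; a statistic absent from the record cannot
fail it.  "Short" means a REF/ALT length difference strictly below
25 bp; support means pooled ALT-supporting reads across the in-group;
fixation means every in-group genotype homozygous for the one ALT and
every outgroup genotype homozygous reference, with any missing genotype
failing the test.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .intervals import GenomeIntervalSet
from .io_formats import IndelVariant, SampleManifest
from .mappability import MappabilityMask

__all__ = [
    "FilterParams",
    "IndelTally",
    "site_quality_filter",
    "mappability_filter",
    "support_filter",
    "single_variant_filter",
    "fixed_lineage_specific",
    "size_filter",
    "apply_cascade",
    "tally",
    "ingroup_alt_index",
]


@dataclasses.dataclass(frozen=True)
class FilterParams:
    min_qd: float = 2.0
    min_qual: float = 30.0
    max_fs: float = 200.0
    min_read_pos_rank_sum: float = -20.0
    min_support: int = 5
    max_size: int = 25
    support_mode: str = "pooled"  # or "per_sample"


@dataclasses.dataclass
class IndelTally:
    n_deletions: int = 0
    n_insertions: int = 0
    total_deleted_bases: int = 0
    total_inserted_bases: int = 0


def site_quality_filter(v: IndelVariant, params: FilterParams = FilterParams()) -> bool:
    """GATK-style hard filter; fails iff any *present* statistic violates its bound."""
    if v.qd is not None and v.qd < params.min_qd:
        return False
    if v.qual is not None and v.qual < params.min_qual:
        return False
    if v.fs is not None and v.fs > params.max_fs:
        return False
    if v.read_pos_rank_sum is not None and v.read_pos_rank_sum < params.min_read_pos_rank_sum:
        return False
    return True


def mappability_filter(v: IndelVariant, mask: MappabilityMask) -> bool:
    """Pass iff the reference span [pos, pos+len(REF)) is entirely mappable."""
    start, end = v.ref_span
    if v.chrom not in mask.chrom_lengths:
        return False
    return not mask.unmappable.overlaps(v.chrom, start, end)


def support_filter(
    v: IndelVariant,
    manifest: SampleManifest,
    params: FilterParams = FilterParams(),
) -> bool:
    """ALT-read support over the in-group.

    Pooled mode (default): the sum over in-group samples of reads
    supporting any ALT allele must reach ``min_support``.  Per-sample
    mode requires the minimum in every in-group sample instead.  Samples
    without allele-depth data contribute 0.
    """
    per_sample = []
    for s in manifest.ingroup_samples():
        ad = v.allele_depths.get(s)
        per_sample.append(sum(ad[1:]) if ad else 0)
    if params.support_mode == "per_sample":
        return min(per_sample) >= params.min_support
    return sum(per_sample) >= params.min_support


def single_variant_filter(v: IndelVariant, manifest: SampleManifest) -> bool:
    """Pass iff the in-group carries at most one distinct ALT allele at the site."""
    return len(v.alt_carried_by(manifest.ingroup_samples())) <= 1


def fixed_lineage_specific(v: IndelVariant, manifest: SampleManifest) -> bool:
    """In-group homozygous for one ALT everywhere; outgroups homozygous REF.

    A missing genotype anywhere fails: fixation is only asserted on
    observed genotypes in all samples.
    """
    alt: int | None = None
    for s in manifest.ingroup_samples():
        gt = v.genotypes.get(s)
        if gt is None:
            return False
        alleles = set(gt)
        if len(alleles) != 1:
            return False
        a = alleles.pop()
        if a == 0:
            return False
        if alt is None:
            alt = a
        elif a != alt:
            return False
    for g in manifest.outgroup_labels():
        for s in manifest.group_samples(g):
            gt = v.genotypes.get(s)
            if gt is None or set(gt) != {0}:
                return False
    return True


def ingroup_alt_index(v: IndelVariant, manifest: SampleManifest) -> int:
    """Allele index used for size/class: the in-group-carried ALT if unique,
    else the first length-changing ALT."""
    carried = v.alt_carried_by(manifest.ingroup_samples())
    if len(carried) == 1:
        return carried.pop()
    indels = v.indel_alt_indices()
    return indels[0] if indels else 1


def size_filter(
    v: IndelVariant,
    manifest: SampleManifest,
    params: FilterParams = FilterParams(),
) -> bool:
    """Pass iff the indel size is strictly below ``max_size`` (default 25 bp)."""
    return v.size_of_alt(ingroup_alt_index(v, manifest)) < params.max_size


def apply_cascade(
    variants: Iterable[IndelVariant],
    manifest: SampleManifest,
    mask: MappabilityMask,
    params: FilterParams = FilterParams(),
) -> tuple[list[IndelVariant], list[dict]]:
    """Run all filters; return passing variants and a per-record outcome table.

    The outcome table has one row per input record with each filter's
    verdict — the intermediate-size route (>= max_size) is visible there
    rather than silently dropped.
    """
    passing: list[IndelVariant] = []
    outcomes: list[dict] = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "site_quality": site_quality_filter(v, params),
            "mappable": mappability_filter(v, mask),
            "support": support_filter(v, manifest, params),
            "single_variant": single_variant_filter(v, manifest),
            "fixed": fixed_lineage_specific(v, manifest),
            "size": size_filter(v, manifest, params),
        }
        row["pass"] = all(
            row[k] for k in ("site_quality", "mappable", "support", "single_variant", "fixed", "size")
        )
        outcomes.append(row)
        if row["pass"]:
            passing.append(v)
    return passing, outcomes


def tally(
    variants: Sequence[IndelVariant], manifest: SampleManifest
) -> IndelTally:
    """Counts and summed base totals per class for the passing set."""
    t = IndelTally()
    for v in variants:
        idx = ingroup_alt_index(v, manifest)
        size = v.size_of_alt(idx)
        if v.class_of_alt(idx) == "deletion":
            t.n_deletions += 1
            t.total_deleted_bases += size
        else:
            t.n_insertions += 1
            t.total_inserted_bases += size
    return t
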