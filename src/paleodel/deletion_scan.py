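"""Coverage-based calling of deletions fixed in the in-group.

A deletion fixed in the in-group leaves a run of sites with no read
support in every in-group genome while the outgroups retain normal
coverage.  Summing per-site depth across the genomes of a group keeps a
fixed deletion at zero but multiplies the surrounding coverage by the
number of genomes, sharpening the signal: with five in-group genomes at
a summed expectation of 59X, a non-deleted site has probability e^-59 of
showing summed depth zero, so long spurious zero-runs essentially never
occur.

The caller finds maximal runs of consecutive *mappable* sites whose
in-group summed depth is at or below ``t_in`` (default 0), requires mean
outgroup depth support over each run, then applies three rules to
fixpoint:

1. adjacent/overlapping candidate runs are unioned (bedtools merge);
2. candidates separated by an entirely unmappable gap are merged across
   it (the deletion was merely broken apart by the mask);
3. candidates separated by <= ``max_gap`` bp whose gap has mean in-group
   depth below ``frac`` of the expected in-group coverage are merged —
   absorbing small misalignment peaks inside true deletions.

Calls longer than ``min_length`` (strictly) are reported.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomeIntervalSet
from .io_formats import SampleManifest
from .mappability import MappabilityMask

__all__ = [
    "DepthProfile",
    "DeletionCall",
    "sum_group_depth",
    "scan_candidate_runs",
    "merge_adjacent",
    "bridge_unmappable",
    "bridge_low_coverage",
    "finalize_calls",
    "call_deletions",
]

FLAG_MERGED = "merged_adjacent"
FLAG_BRIDGED_UNMAP = "bridged_unmappable"
FLAG_BRIDGED_LOWCOV = "bridged_lowcov"


@dataclasses.dataclass
class DepthProfile:
    """Group-summed per-site depth plus the group's expected coverage E."""

    group: str
    depths: dict[str, np.ndarray]
    expected_coverage: float

    def __post_init__(self) -> None:
        if self.expected_coverage <= 0:
            raise ValueError("expected coverage must be > 0")

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return float(self.depths[chrom][start:end].mean())


@dataclasses.dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    mean_ingroup_depth: float
    outgroup_mean_depth: dict[str, float]
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


def sum_group_depth(
    sample_depths: Mapping[str, Mapping[str, np.ndarray]],
    manifest: SampleManifest,
    group: str,
) -> DepthProfile:
    """Elementwise sum of a group's per-sample depth arrays."""
    members = manifest.group_samples(group)
    if not members:
        raise KeyError(f"no samples in group {group!r}")
    chrom_sets = [frozenset(sample_depths[s]) for s in members]
    if len(set(chrom_sets)) != 1:
        raise ValueError(f"samples of group {group!r} disagree on chromosomes")
    summed: dict[str, np.ndarray] = {}
    for chrom in chrom_sets[0]:
        lengths = {len(sample_depths[s][chrom]) for s in members}
        if len(lengths) != 1:
            raise ValueError(f"chromosome {chrom}: array length mismatch in group {group!r}")
        summed[chrom] = np.sum(
            [np.asarray(sample_depths[s][chrom], dtype=np.int64) for s in members], axis=0
        )
    return DepthProfile(group, summed, manifest.expected_summed_coverage(group))


def scan_candidate_runs(
    ingroup: DepthProfile,
    outgroups: Sequence[DepthProfile],
    mask: MappabilityMask,
    t_in: int = 0,
    outgroup_min_frac: float = 0.20,
) -> GenomeIntervalSet:
    """Maximal mappable runs with in-group summed depth <= t_in.

    Unmappable sites terminate runs; they are neither inside a run nor
    counted against one.  A run is kept only if its mean depth in EVERY
    outgroup group is at least ``outgroup_min_frac`` of that group's
    expected summed coverage — a shared zero-coverage region is missing
    sequence, not a lineage-specific deletion.
    """
    if t_in < 0:
        raise ValueError("t_in must be >= 0")
    if not 0 < outgroup_min_frac <= 1:
        raise ValueError("outgroup_min_frac must be in (0, 1]")
    if set(mask.chrom_lengths) != set(ingroup.depths):
        raise ValueError("mask chromosomes do not match depth chromosomes")
    out = GenomeIntervalSet()
    for chrom, depth in ingroup.depths.items():
        low = (depth <= t_in) & mask.mappable_bool(chrom)
        for c, s, e in GenomeIntervalSet.from_bool(chrom, low):
            if all(
                og.mean_depth(chrom, s, e) >= outgroup_min_frac * og.expected_coverage
                for og in outgroups
            ):
                out.add(c, s, e)
    return out


def merge_adjacent(candidates: GenomeIntervalSet) -> GenomeIntervalSet:
    """Union book-ended (end1 == start2) and overlapping candidates."""
    merged = candidates.merge(0, combine_labels=True)
    out = GenomeIntervalSet()
    for chrom, s, e, lab in merged.records():
        n_in = sum(1 for cs, ce in candidates.intervals(chrom) if cs >= s and ce <= e)
        if n_in > 1:
            lab = _add_flag(lab, FLAG_MERGED)
        out.add(chrom, s, e, lab)
    return out


def _add_flag(label: str | None, flag: str) -> str:
    flags = set(label.split(",")) if label else set()
    flags.add(flag)
    return ",".join(sorted(flags))


def _merge_chain(
    candidates: GenomeIntervalSet,
    should_bridge,
    flag: str,
) -> GenomeIntervalSet:
    """Left-to-right transitive merge of consecutive candidates whose gap
    satisfies ``should_bridge(chrom, gap_start, gap_end)``."""
    out = GenomeIntervalSet()
    for chrom in candidates.chromosomes():
        recs = [[s, e, lab] for s, e, lab in
                ((s, e, lab) for c, s, e, lab in candidates.records() if c == chrom)]
        cur = None
        for s, e, lab in recs:
            if cur is None:
                cur = [s, e, lab]
            elif s > cur[1] and should_bridge(chrom, cur[1], s):
                cur[1] = max(cur[1], e)
                cur[2] = _add_flag(_combine(cur[2], lab), flag)
            else:
                out.add(chrom, cur[0], cur[1], cur[2])
                cur = [s, e, lab]
        if cur is not None:
            out.add(chrom, cur[0], cur[1], cur[2])
    return out


def _combine(a: str | None, b: str | None) -> str | None:
    flags = set()
    for lab in (a, b):
        if lab:
            flags.update(lab.split(","))
    return ",".join(sorted(flags)) if flags else None


def bridge_unmappable(
    candidates: GenomeIntervalSet, mask: MappabilityMask
) -> GenomeIntervalSet:
    """Merge candidates split by a gap consisting entirely of unmappable sites."""
    return _merge_chain(
        candidates,
        lambda chrom, gs, ge: mask.unmappable.covers(chrom, gs, ge),
        FLAG_BRIDGED_UNMAP,
    )


def bridge_low_coverage(
    candidates: GenomeIntervalSet,
    ingroup: DepthProfile,
    max_gap: int = 250,
    frac: float = 0.10,
    gap_statistic: str = "mean",
) -> GenomeIntervalSet:
    """Merge candidates <= max_gap apart whose gap has near-zero in-group depth.

    The gap's depth statistic (mean by default, max optionally) must be
    below ``frac`` of the in-group's expected summed coverage — at
    defaults, below 10% of 59X = 5.9X.
    """
    threshold = frac * ingroup.expected_coverage

    def ok(chrom: str, gs: int, ge: int) -> bool:
        if ge - gs > max_gap:
            return False
        seg = ingroup.depths[chrom][gs:ge]
        stat = float(seg.mean()) if gap_statistic == "mean" else float(seg.max())
        return stat < threshold

    return _merge_chain(candidates, ok, FLAG_BRIDGED_LOWCOV)


def finalize_calls(
    candidates: GenomeIntervalSet,
    ingroup: DepthProfile,
    outgroups: Sequence[DepthProfile],
    min_length: int = 500,
) -> list[DeletionCall]:
    """Keep candidates strictly longer than ``min_length``; attach statistics."""
    calls: list[DeletionCall] = []
    for chrom, s, e, lab in candidates.records():
        if e - s <= min_length:
            continue
        calls.append(
            DeletionCall(
                chrom=chrom,
                start=s,
                end=e,
                mean_ingroup_depth=ingroup.mean_depth(chrom, s, e),
                outgroup_mean_depth={
                    og.group: og.mean_depth(chrom, s, e) for og in outgroups
                },
                flags=tuple(sorted(lab.split(","))) if lab else (),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def call_deletions(
    ingroup: DepthProfile,
    outgroups: Sequence[DepthProfile],
    mask: MappabilityMask,
    t_in: int = 0,
    outgroup_min_frac: float = 0.20,
    max_gap: int = 250,
    bridge_frac: float = 0.10,
    min_length: int = 500,
) -> list[DeletionCall]:
    """Full scan: candidate runs, then merge/bridge rules iterated to fixpoint."""
    cands = scan_candidate_runs(ingroup, outgroups, mask, t_in, outgroup_min_frac)
    while True:
        merged = merge_adjacent(cands)
        merged = bridge_unmappable(merged, mask)
        merged = bridge_low_coverage(merged, ingroup, max_gap, bridge_frac)
        if merged == cands:
            break
        cands = merged
    return finalize_calls(cands, ingroup, outgroups, min_length)
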