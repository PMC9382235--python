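"""Mappability mask from exhaustive overlapping-window self-mapping.

Reads of length k cannot be placed confidently where the reference is
repetitive, so coverage absence there carries no deletion signal.  The
mask is built by fragmenting the reference into every overlapping window
of k bp (step 1), asking whether each window's sequence occurs exactly
once in the genome counting both strands, computing for every site the
number of unique windows covering it, and masking sites whose unique-
window depth falls below a threshold.  Nearby unmappable intervals are
merged across small gaps (bedtools ``merge -d`` semantics).

Uniqueness here is exact-match uniqueness on both strands, a
deterministic, aligner-free criterion: a window is unique iff the count
of occurrences of its sequence plus occurrences of its reverse
complement over all positions of all chromosomes equals exactly 1.  A
palindromic window's self-hit is counted once.  Windows containing any
non-ACGT character are never unique.

Defaults (k=50, step=1, depth threshold 25, merge distance 250 bp) match
a read length of 50 bp: a site is kept only if at least half of the 50
windows overlapping it are unique.  A consequence of the construction is
that the first and last k-1 sites of every chromosome are covered by
fewer than k windows, so at default parameters the terminal 24 bp of
each chromosome are always unmappable.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .intervals import GenomeIntervalSet

__all__ = [
    "MappabilityMask",
    "window_uniqueness",
    "unique_depth",
    "build_mask",
    "build_mappability_mask",
]

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMPLEMENT[_a] = _b

_VALID = np.zeros(256, dtype=bool)
for _a in b"ACGT":
    _VALID[_a] = True


@dataclasses.dataclass
class MappabilityMask:
    """Unmappable regions plus the parameters that produced them."""

    unmappable: GenomeIntervalSet
    window_length: int
    step: int
    depth_threshold: int
    merge_distance: int
    chrom_lengths: dict[str, int]

    def mappable(self) -> GenomeIntervalSet:
        return self.unmappable.complement(self.chrom_lengths)

    def mappable_bool(self, chrom: str) -> np.ndarray:
        return ~self.unmappable.to_bool(chrom, self.chrom_lengths[chrom])

    def header(self) -> str:
        return (
            f"mappability_mask k={self.window_length} step={self.step} "
            f"depth_threshold={self.depth_threshold} merge_distance={self.merge_distance}"
        )


_CODE = np.zeros(256, dtype=np.uint64)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i


def _packed_window_keys(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit packings of every window and its reverse complement.

    Each k-mer maps bijectively to ceil(k/32) uint64 words (base j of the
    window contributes ``code << 2*(j mod 32)`` to word j//32), so equal
    keys mean equal sequences — no hashing collisions.
    """
    n = codes.size - k + 1
    parts = (k + 31) // 32
    fwd = np.zeros((n, parts), dtype=np.uint64)
    rc = np.zeros((n, parts), dtype=np.uint64)
    comp = np.uint64(3) - codes
    for j in range(k):
        p, off = divmod(j, 32)
        shift = np.uint64(2 * off)
        fwd[:, p] += codes[j : j + n] << shift
        rc[:, p] += comp[k - 1 - j : k - 1 - j + n] << shift
    return fwd, rc


def window_uniqueness(reference: Mapping[str, str], k: int) -> dict[str, np.ndarray]:
    """Per-chromosome boolean array over window start positions.

    ``True`` marks a window whose k-mer occurs exactly once genome-wide
    counting both strands (palindromes counted once) and contains only
    A/C/G/T.  A chromosome shorter than k yields a zero-length array.
    Only windows of valid bases enter the occurrence count: a window
    containing an ambiguity code can never share a sequence with one
    that does not.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if k > 512:
        raise ValueError("window length k > 512 not supported")
    chroms = list(reference)
    fwd_parts, rc_parts, valid_parts = [], [], []
    for c in chroms:
        arr = np.frombuffer(reference[c].encode(), dtype=np.uint8)
        if arr.size < k:
            valid_parts.append(np.zeros(0, dtype=bool))
            continue
        bad = np.concatenate([[0], np.cumsum(~_VALID[arr])])
        valid = bad[k:] - bad[:-k] == 0
        valid_parts.append(valid)
        fwd, rc = _packed_window_keys(_CODE[arr], k)
        fwd_parts.append(fwd[valid])
        rc_parts.append(rc[valid])
    out = {c: np.zeros(v.size, dtype=bool) for c, v in zip(chroms, valid_parts)}
    n = sum(f.shape[0] for f in fwd_parts)
    if n == 0:
        return out
    parts = (k + 31) // 32
    void = np.dtype((np.void, 8 * parts))
    keys = np.ascontiguousarray(np.concatenate(fwd_parts + rc_parts)).view(void).ravel()
    uniq, inverse = np.unique(keys, return_inverse=True)
    counts_fwd = np.bincount(inverse[:n], minlength=uniq.size)
    cf = counts_fwd[inverse[:n]]
    cr = counts_fwd[inverse[n:]]
    palindrome = inverse[:n] == inverse[n:]
    total = np.where(palindrome, cf, cf + cr)
    flags_valid = total == 1
    offset = 0
    for c, valid in zip(chroms, valid_parts):
        nv = int(valid.sum())
        if nv:
            out[c][valid] = flags_valid[offset : offset + nv]
        offset += nv
    return out


def unique_depth(
    window_flags: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    k: int,
    s: int = 1,
) -> dict[str, np.ndarray]:
    """Unique-window depth per site: number of unique windows covering it.

    At step 1 the depth at site i is bounded by ``min(i + 1, k, L - i)``
    — the chromosome-end taper.  Steps other than 1 change that ceiling;
    only s=1 is supported.
    """
    if s != 1:
        raise NotImplementedError("only step size 1 is supported")
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        flags = np.asarray(window_flags.get(chrom, np.zeros(0)), dtype=np.int64)
        depth = np.zeros(length, dtype=np.int64)
        if flags.size:
            cum = np.concatenate([[0], np.cumsum(flags)])
            i = np.arange(length)
            lo = np.maximum(0, i - k + 1)
            hi = np.minimum(i, length - k)
            ok = hi >= lo
            depth[ok] = cum[hi[ok] + 1] - cum[lo[ok]]
        out[chrom] = depth
    return out


def build_mask(
    track: Mapping[str, np.ndarray],
    d: int,
    m: int,
    *,
    k: int = 50,
    step: int = 1,
) -> MappabilityMask:
    """Mask sites with unique-window depth < d; merge gaps <= m bp."""
    if d < 1:
        raise ValueError("depth threshold must be >= 1")
    if m < 0:
        raise ValueError("merge distance must be >= 0")
    unmappable = GenomeIntervalSet()
    lengths: dict[str, int] = {}
    for chrom, depth in track.items():
        lengths[chrom] = len(depth)
        for c, s_, e_ in GenomeIntervalSet.from_bool(chrom, depth < d):
            unmappable.add(c, s_, e_)
    return MappabilityMask(
        unmappable=unmappable.merge(m),
        window_length=k,
        step=step,
        depth_threshold=d,
        merge_distance=m,
        chrom_lengths=lengths,
    )


def build_mappability_mask(
    reference: Mapping[str, str],
    k: int = 50,
    step: int = 1,
    depth_threshold: int = 25,
    merge_distance: int = 250,
) -> MappabilityMask:
    """Full pipeline: window uniqueness -> unique depth -> thresholded mask."""
    lengths = {c: len(s) for c, s in reference.items()}
    flags = window_uniqueness(reference, k)
    track = unique_depth(flags, lengths, k, step)
    return build_mask(track, depth_threshold, merge_distance, k=k, step=step)
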