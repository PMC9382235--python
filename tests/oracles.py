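"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: window
uniqueness by substring search on both strands, per-site depth by
explicit window enumeration, Fisher's exact p by full enumeration over
tables with fixed margins, and subset means by literal subset
enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s[::-1].translate(_RC)


def _count_occurrences(pattern: str, sequences: list[str]) -> int:
    """Occurrences of pattern and its reverse complement over all positions
    of all sequences; a palindrome's self-hit is counted once."""
    patterns = {pattern, revcomp(pattern)}
    total = 0
    for seq in sequences:
        for pat in patterns:
            i = seq.find(pat)
            while i != -1:
                total += 1
                i = seq.find(pat, i + 1)
    return total


def brute_window_uniqueness(reference: dict[str, str], k: int) -> dict[str, np.ndarray]:
    seqs = list(reference.values())
    out: dict[str, np.ndarray] = {}
    for chrom, seq in reference.items():
        n = max(0, len(seq) - k + 1)
        flags = np.zeros(n, dtype=bool)
        for w in range(n):
            window = seq[w : w + k]
            if any(c not in "ACGT" for c in window):
                continue
            flags[w] = _count_occurrences(window, seqs) == 1
        out[chrom] = flags
    return out


def brute_unique_depth(flags: dict[str, np.ndarray], lengths: dict[str, int], k: int) -> dict[str, np.ndarray]:
    out = {}
    for chrom, length in lengths.items():
        f = flags.get(chrom, np.zeros(0, dtype=bool))
        depth = np.zeros(length, dtype=int)
        for w in range(f.size):
            if f[w]:
                depth[w : w + k] += 1
        out[chrom] = depth
    return out


def brute_unmappable(reference: dict[str, str], k: int, d: int, m: int) -> list[tuple[str, int, int]]:
    """Full brute-force mask: per-site depth, threshold, gap-merge."""
    lengths = {c: len(s) for c, s in reference.items()}
    flags = brute_window_uniqueness(reference, k)
    depth = brute_unique_depth(flags, lengths, k)
    out: list[tuple[str, int, int]] = []
    for chrom in reference:
        low = depth[chrom] < d
        ivals: list[list[int]] = []
        start = None
        for i, b in enumerate(low):
            if b and start is None:
                start = i
            elif not b and start is not None:
                ivals.append([start, i])
                start = None
        if start is not None:
            ivals.append([start, len(low)])
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s - merged[-1][1] <= m:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def brute_fisher_two_sided(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing probabilities <= the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # hypergeometric probability of table [[x, r1-x], [c1-x, r2-c1+x]]
        return (
            comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def brute_subset_means(codes: np.ndarray, clean: np.ndarray) -> list[tuple[int, float]]:
    """Mean fixed count over all C(n,k) subsets by literal enumeration.

    ``codes``: variants x samples matrix, 2 = homozygous-ALT.
    """
    n = codes.shape[1]
    points = []
    for k in range(1, n + 1):
        vals = []
        for subset in combinations(range(n), k):
            fixed = np.all(codes[:, list(subset)] == 2, axis=1) & clean
            vals.append(int(fixed.sum()))
        points.append((k, float(np.mean(vals))))
    return points


def random_reference(rng: np.random.Generator, length: int,
                     repeat: tuple[int, int] | None = None) -> dict[str, str]:
    """Random ACGT chromosome, optionally with one exact duplicated segment
    (source position, length) copied to the second half."""
    arr = rng.integers(0, 4, size=length)
    seq = "".join("ACGT"[i] for i in arr)
    if repeat is not None:
        src, rlen = repeat
        dst = length // 2 + length // 4
        seq = seq[:dst] + seq[src : src + rlen] + seq[dst + rlen :]
    return {"chr1": seq}
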