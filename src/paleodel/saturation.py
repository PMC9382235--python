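"""Sample-size saturation of in-group-fixed variant counts.

A variant that looks fixed in n sampled genomes may be segregating in
the wider population; the fewer genomes sampled, the more such false
"fixed" calls.  Enumerating every subset of k in-group genomes
(k = 1..n) and counting variants homozygous-ALT in all subset members
(and clean — homozygous-REF — in every outgroup) yields a non-
increasing curve whose decay rate forecasts how many of the n-genome
fixed calls would survive sampling more genomes.  An exponential
trendline y = a*e^(b*k) is fitted log-linearly and the retained
fraction at horizon K is e^(b*(K-n)).

The exact mean over all C(n,k) subsets has the closed form
``mean(k) = sum_v C(m_v, k) / C(n, k)`` with m_v the number of in-group
genomes homozygous-ALT for variant v; the implementation enumerates
subsets explicitly (as the method prescribes) and the closed form is
the test oracle.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Sequence

import numpy as np

from .io_formats import IndelVariant, SampleManifest

__all__ = [
    "GenotypeMatrix",
    "SaturationCurve",
    "build_genotype_matrix",
    "fixed_count",
    "saturation_points",
    "fit_exponential",
    "forecast_retained_fraction",
    "saturation_curve",
]

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
_MAX_EXHAUSTIVE_N = 16


@dataclasses.dataclass
class GenotypeMatrix:
    """variants x in-group samples genotype codes plus outgroup-clean flags.

    Codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Only variants whose
    outgroups are all homozygous reference (``clean``) enter the curve.
    """

    samples: tuple[str, ...]
    codes: np.ndarray          # (V, n) int8
    clean: np.ndarray          # (V,) bool

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.clean = np.asarray(self.clean, dtype=bool)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.samples):
            raise ValueError("codes shape does not match sample count")
        if self.clean.shape != (self.codes.shape[0],):
            raise ValueError("clean flag length does not match variant count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclasses.dataclass
class SaturationCurve:
    points: list[tuple[int, float]]     # (k, mean fixed count over all C(n,k) subsets)
    a: float
    b: float
    horizon: int
    retained_fraction: float


def _code_genotype(gt: tuple[int, ...] | None, alt: int) -> int:
    if gt is None:
        return MISSING
    alleles = set(gt)
    if alleles == {0}:
        return HOM_REF
    if alleles == {alt}:
        return HOM_ALT
    return HET


def build_genotype_matrix(
    variants: Sequence[IndelVariant], manifest: SampleManifest
) -> GenotypeMatrix:
    """Code in-group genotypes against each variant's in-group ALT allele."""
    from .indel_pipeline import ingroup_alt_index

    samples = tuple(manifest.ingroup_samples())
    codes = np.full((len(variants), len(samples)), MISSING, dtype=np.int8)
    clean = np.zeros(len(variants), dtype=bool)
    outgroup_samples = [
        s for g in manifest.outgroup_labels() for s in manifest.group_samples(g)
    ]
    for i, v in enumerate(variants):
        alt = ingroup_alt_index(v, manifest)
        for j, s in enumerate(samples):
            codes[i, j] = _code_genotype(v.genotypes.get(s), alt)
        clean[i] = all(
            v.genotypes.get(s) is not None and set(v.genotypes[s]) == {0}
            for s in outgroup_samples
        )
    return GenotypeMatrix(samples, codes, clean)


def fixed_count(matrix: GenotypeMatrix, subset: Sequence[int]) -> int:
    """Variants hom-alt in every subset member and outgroup-clean.

    A missing genotype in any subset member excludes the variant.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    sub = matrix.codes[:, subset]
    return int(np.sum(np.all(sub == HOM_ALT, axis=1) & matrix.clean))


def saturation_points(matrix: GenotypeMatrix, n: int | None = None) -> list[tuple[int, float]]:
    """Mean fixed count over all C(n,k) subsets, k = 1..n (exhaustive)."""
    if n is None:
        n = matrix.n_samples
    if n != matrix.n_samples:
        raise ValueError("n must equal the matrix's in-group sample count")
    if n > _MAX_EXHAUSTIVE_N:
        raise ValueError(
            f"n={n} too large for exhaustive subset enumeration; "
            "use Monte Carlo subsampling instead"
        )
    points: list[tuple[int, float]] = []
    for k in range(1, n + 1):
        total = 0
        count = 0
        for subset in combinations(range(n), k):
            total += fixed_count(matrix, subset)
            count += 1
        points.append((k, total / count))
    return points


def fit_exponential(points: Sequence[tuple[int, float]]) -> tuple[float, float]:
    """Least-squares fit of ln(y) = ln(a) + b*k (the spreadsheet/R
    'exponential trendline'); returns (a, b)."""
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit")
    k = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(y <= 0):
        raise ValueError("exponential fit undefined for non-positive means")
    b, log_a = np.polyfit(k, np.log(y), 1)
    return float(np.exp(log_a)), float(b)


def forecast_retained_fraction(fit: tuple[float, float], n: int, K: int) -> float:
    """Predicted fraction of n-genome-fixed variants still fixed at K genomes:
    y(K)/y(n) = e^(b*(K-n)), capped at 1 if the fitted curve is non-decreasing."""
    if K <= n:
        raise ValueError("forecast horizon K must exceed n")
    _, b = fit
    frac = float(np.exp(b * (K - n)))
    if b > 0:
        import warnings

        warnings.warn("non-monotone saturation curve (b > 0); fraction capped at 1")
        return 1.0
    return frac


def saturation_curve(
    matrix: GenotypeMatrix, horizon: int
) -> SaturationCurve:
    points = saturation_points(matrix)
    a, b = fit_exponential(points)
    frac = forecast_retained_fraction((a, b), matrix.n_samples, horizon)
    return SaturationCurve(points, a, b, horizon, frac)
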