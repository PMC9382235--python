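"""Genomic distribution and coding impact of the called variants.

The genome is partitioned into exon / intron / intergenic (exon meaning
transcribed exon, UTRs included; precedence exon > intron > intergenic
where genes overlap).  Enrichment of variants away from genes is tested
by comparing two multinomial draws — positions sampled uniformly over
the analyzed genome versus positions sampled uniformly over
variant-covered bases — with a two-sided Fisher exact test on each 2x2
category pair, reporting the relative odds as the fold enrichment.

Coding impact uses simple annotation-geometric rules: a large deletion
removing any exonic base of a gene is ``exon_deleted``; a CDS-
overlapping indel is a ``frameshift`` when its length is not a multiple
of three, ``inframe_indel`` otherwise; variants hitting the annotated
first/last CDS codon are ``start_lost``/``stop_lost`` (strand-aware).
Full translation-based consequence prediction is out of scope.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .deletion_scan import DeletionCall
from .indel_pipeline import ingroup_alt_index
from .intervals import GenomeIntervalSet
from .io_formats import GeneModel, IndelVariant, SampleManifest

__all__ = [
    "AnnotationPartition",
    "ContingencyResult",
    "CodingImpact",
    "build_partition",
    "sample_random_positions",
    "sample_positions_within_variants",
    "enrichment_test",
    "classify_coding_impact",
    "affected_gene_summary",
]

CATEGORIES = ("exon", "intron", "intergenic")
LOSS_CONSEQUENCES = frozenset({"exon_deleted", "frameshift", "start_lost", "stop_lost"})


@dataclasses.dataclass
class AnnotationPartition:
    """Disjoint exon/intron/intergenic interval sets covering the genome."""

    exon: GenomeIntervalSet
    intron: GenomeIntervalSet
    intergenic: GenomeIntervalSet
    chrom_lengths: dict[str, int]

    def category_sets(self) -> dict[str, GenomeIntervalSet]:
        return {"exon": self.exon, "intron": self.intron, "intergenic": self.intergenic}

    def classify(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Category index (0 exon, 1 intron, 2 intergenic) per position."""
        out = np.full(len(positions), 2, dtype=np.int8)
        for idx, ivset in ((0, self.exon), (1, self.intron)):
            ivals = ivset.intervals(chrom)
            if not ivals:
                continue
            starts = np.array([s for s, _ in ivals])
            ends = np.array([e for _, e in ivals])
            j = np.searchsorted(starts, positions, side="right") - 1
            hit = (j >= 0) & (positions < ends[np.clip(j, 0, None)])
            out[hit] = idx
        return out


@dataclasses.dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    fold: float | None
    p_value: float
    categories: tuple[str, str]


@dataclasses.dataclass(frozen=True)
class CodingImpact:
    gene_id: str
    variant_id: str
    consequence: str


def build_partition(
    gene_models: Sequence[GeneModel], chrom_lengths: Mapping[str, int]
) -> AnnotationPartition:
    """exon = union of exons; intron = gene bodies minus exon; rest intergenic."""
    exon = GenomeIntervalSet()
    genic = GenomeIntervalSet()
    for g in gene_models:
        exons = g.exon_union()
        if exons and (exons[0][0] < g.start or exons[-1][1] > g.end):
            raise ValueError(f"gene {g.gene_id}: span smaller than its exons")
        for s, e in exons:
            exon.add(g.chrom, s, e)
        genic.add(g.chrom, g.start, g.end)
    exon = exon.merge(0)
    lengths = dict(chrom_lengths)
    non_exon = exon.complement(lengths)
    intron = genic.merge(0).intersect(non_exon)
    intergenic = GenomeIntervalSet.from_records(
        (c, s, e) for c, s, e in genic.complement(lengths)
    ).intersect(non_exon)
    return AnnotationPartition(exon, intron, intergenic, lengths)


def _interval_sampler(regions: GenomeIntervalSet):
    """Cumulative-length machinery for uniform sampling over a region set."""
    recs = [(c, s, e) for c, s, e in regions]
    if not recs:
        raise ValueError("cannot sample from an empty region set")
    lengths = np.array([e - s for _, s, e in recs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    return recs, cum


def _count_categories(
    partition: AnnotationPartition, chrom_pos: dict[str, np.ndarray]
) -> dict[str, int]:
    counts = np.zeros(3, dtype=np.int64)
    for chrom, positions in chrom_pos.items():
        if chrom not in partition.chrom_lengths:
            continue
        cats = partition.classify(chrom, positions)
        counts += np.bincount(cats, minlength=3)
    return dict(zip(CATEGORIES, (int(x) for x in counts)))


def sample_random_positions(
    n: int,
    regions: GenomeIntervalSet,
    partition: AnnotationPartition,
    seed: int,
) -> dict[str, int]:
    """Draw n positions uniformly (with replacement) over ``regions``;
    count how many fall in each partition category."""
    if n < 1:
        raise ValueError("n must be >= 1")
    recs, cum = _interval_sampler(regions)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right") - 1
    chrom_pos: dict[str, list[np.ndarray]] = {}
    for i in np.unique(idx):
        sel = draws[idx == i] - cum[i] + recs[i][1]
        chrom_pos.setdefault(recs[i][0], []).append(sel)
    merged = {c: np.concatenate(v) for c, v in chrom_pos.items()}
    return _count_categories(partition, merged)


def sample_positions_within_variants(
    variants: Sequence,
    n: int,
    partition: AnnotationPartition,
    seed: int,
    manifest: SampleManifest | None = None,
) -> dict[str, int]:
    """Draw n positions uniformly over the multiset of variant-covered bases.

    Deletions (large calls or indel records) contribute every base of
    their reference footprint, so long deletions are weighted by length;
    insertions contribute their left-anchored insertion point.
    """
    regions = GenomeIntervalSet()
    for v in variants:
        if isinstance(v, DeletionCall):
            regions.add(v.chrom, v.start, v.end)
        elif isinstance(v, IndelVariant):
            start, end = v.ref_span
            regions.add(v.chrom, start, max(end, start + 1))
        else:
            chrom, start, end = v
            regions.add(chrom, start, max(end, start + 1))
    if len(regions) == 0:
        raise ValueError("cannot sample from an empty variant set")
    # no merge: the multiset of covered bases is what is sampled
    recs = [(c, s, e) for c, s, e in regions]
    lengths = np.array([e - s for _, s, e in recs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right") - 1
    chrom_pos: dict[str, list[np.ndarray]] = {}
    for i in np.unique(idx):
        sel = draws[idx == i] - cum[i] + recs[i][1]
        chrom_pos.setdefault(recs[i][0], []).append(sel)
    merged = {c: np.concatenate(v) for c, v in chrom_pos.items()}
    return _count_categories(partition, merged)


def enrichment_test(
    random_counts: Mapping[str, int],
    variant_counts: Mapping[str, int],
    cat_a: str,
    cat_b: str,
) -> ContingencyResult:
    """2x2 Fisher exact test of variant vs random category counts.

    fold = (variant_a / variant_b) / (random_a / random_b): how many
    times more common category-a placement is among variants than under
    the random-position null.  The two-sided p sums hypergeometric table
    probabilities <= the observed table's.
    """
    va, vb = int(variant_counts[cat_a]), int(variant_counts[cat_b])
    ra, rb = int(random_counts[cat_a]), int(random_counts[cat_b])
    table = ((va, vb), (ra, rb))
    if min(va, vb, ra, rb) < 0:
        raise ValueError("negative count")
    fold: float | None
    if vb == 0 or ra == 0 or rb == 0:
        fold = None
    else:
        fold = (va / vb) / (ra / rb)
    _, p = stats.fisher_exact(np.array(table), alternative="two-sided")
    return ContingencyResult(table, fold, float(p), (cat_a, cat_b))


def _first_last_codons(t, strand: str) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Genomic spans of the first and last codon of a transcript's CDS."""
    if not t.cds:
        return None, None
    flat: list[int] = []
    for s, e in t.cds:
        flat.extend(range(s, e))
    if len(flat) < 3:
        return None, None
    if strand == "-":
        first, last = flat[-3:], flat[:3]
    else:
        first, last = flat[:3], flat[-3:]
    return (min(first), max(first) + 1), (min(last), max(last) + 1)


def classify_coding_impact(
    deletions: Sequence[DeletionCall],
    indels: Sequence[IndelVariant],
    gene_models: Sequence[GeneModel],
    manifest: SampleManifest | None = None,
) -> list[CodingImpact]:
    """Consequence records per (gene, variant); one row per consequence."""
    impacts: list[CodingImpact] = []
    for g in gene_models:
        exons = g.exon_union()
        for d in deletions:
            if d.chrom != g.chrom:
                continue
            if any(d.start < ee and d.end > es for es, ee in exons):
                impacts.append(
                    CodingImpact(g.gene_id, f"{d.chrom}:{d.start}-{d.end}", "exon_deleted")
                )
        for v in indels:
            if v.chrom != g.chrom:
                continue
            vs, ve = v.ref_span
            ve = max(ve, vs + 1)
            idx = ingroup_alt_index(v, manifest) if manifest else (v.indel_alt_indices() or [1])[0]
            size = v.size_of_alt(idx)
            vid = f"{v.chrom}:{v.pos}:{v.ref}>{v.alts[idx - 1]}"
            in_cds = any(
                vs < ce and ve > cs for t in g.transcripts for cs, ce in t.cds
            )
            if in_cds:
                impacts.append(
                    CodingImpact(
                        g.gene_id, vid,
                        "frameshift" if size % 3 != 0 else "inframe_indel",
                    )
                )
            for t in g.transcripts:
                first, last = _first_last_codons(t, g.strand)
                if first and vs < first[1] and ve > first[0]:
                    impacts.append(CodingImpact(g.gene_id, vid, "start_lost"))
                if last and vs < last[1] and ve > last[0]:
                    impacts.append(CodingImpact(g.gene_id, vid, "stop_lost"))
    seen: set[tuple[str, str, str]] = set()
    unique: list[CodingImpact] = []
    for imp in impacts:
        key = (imp.gene_id, imp.variant_id, imp.consequence)
        if key not in seen:
            seen.add(key)
            unique.append(imp)
    return unique


def affected_gene_summary(impacts: Sequence[CodingImpact]) -> tuple[dict[str, list[CodingImpact]], int]:
    """Per-gene impact lists plus the count of genes with a coding-sequence-
    altering variant (in-frame indels do not count as loss-causing)."""
    per_gene: dict[str, list[CodingImpact]] = {}
    for imp in impacts:
        per_gene.setdefault(imp.gene_id, []).append(imp)
    per_gene = dict(sorted(per_gene.items()))
    n_affected = sum(
        1 for impl in per_gene.values()
        if any(i.consequence in LOSS_CONSEQUENCES for i in impl)
    )
    return per_gene, n_affected
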