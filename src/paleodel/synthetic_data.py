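"""Synthetic genomes with planted truth for every pipeline stage.

The generator emulates the study conditions the pipeline was designed
for: an in-group of five genomes at 11.8X mean coverage each (59X
summed) against two outgroup groups with summed coverages of 633X and
173X; exact repeats that defeat unique read placement; group-fixed
deletions >= 500 bp visible as zero-coverage runs; a multi-sample indel
VCF mixing fixed, segregating, low-quality, low-support, multi-allelic
and unmappable records; and gene models giving an exon/intron/
intergenic partition with a controllable intergenic enrichment of
variants.

Depth is simulated directly as independent per-site Poisson draws at
each genome's mean coverage (zero inside planted deletions for in-group
genomes) — the analysis consumes depth tracks, so depth is the right
simulation boundary.  Genotypes are drawn under Hardy-Weinberg from a
per-variant in-group ALT frequency; fixation labels are computed from
the realized genotypes, not from the frequency.

Everything is deterministic under the config seed.  ``SimulationTruth``
records every planted event with its expected filter-cascade outcome and
the expected unmappable regions from closed-form geometry (chromosome-
end tapers plus repeat-copy interiors), serving as the recovery oracle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomeIntervalSet
from .io_formats import (
    GeneModel,
    SampleManifest,
    Transcript,
    write_bed,
    write_depth_tsv,
    write_fasta,
    write_manifest,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Simulation",
    "simulate",
    "simulate_reference",
    "simulate_depth",
    "simulate_annotation",
    "simulate_indel_vcf",
    "write_gff3",
    "expected_unmappable",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# margin keeping "clean" placements clear of mask edges (>= repeat halo + merge distance)
_CLEAN_MARGIN = 400
_REPEAT_INTERIOR_MARGIN = 60


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions; defaults are the conditions the pipeline targets."""

    seed: int = 0
    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    # exact repeats: per chromosome, `repeats_per_chrom` segments of
    # `repeat_length` bp duplicated once elsewhere on the same chromosome
    repeats_per_chrom: int = 2
    repeat_length: int = 2_000
    # coverage regime
    n_ingroup: int = 5
    ingroup_coverage: float = 11.8
    outgroup_specs: tuple[tuple[str, int, float], ...] = (
        ("african", 4, 158.25),   # summed 633X
        ("asian", 2, 86.5),       # summed 173X
    )
    # planted fixed large deletions
    n_deletions: int = 12
    deletion_length_range: tuple[int, int] = (600, 5_000)
    misalignment_prob: float = 0.0     # per-deletion chance of a low-level interior peak
    misalignment_epsilon: float = 2.0  # Poisson mean of the peak, summed over the in-group
    misalignment_length: int = 50
    # short indels
    n_indels: int = 20_000
    indel_size_range: tuple[int, int] = (1, 24)
    deletion_bias: float = 0.65        # fraction of indels that are deletions
    fixed_fraction: float = 0.90       # in-group ALT frequency 1.0; rest Beta-segregating
    segregating_beta: tuple[float, float] = (5.0, 1.0)
    frac_outgroup_clean: float = 0.95
    frac_intermediate_size: float = 0.02   # sizes in [25, 40]: routed out by the size filter
    frac_low_support: float = 0.02
    frac_quality_fault: float = 0.04       # one violated site statistic
    frac_stats_absent: float = 0.03
    frac_missing_genotype: float = 0.02
    frac_multiallelic: float = 0.02
    frac_in_repeat: float = 0.03           # placed inside repeat interiors (unmappable)
    frac_snp: float = 0.01                 # same-length records; dropped on read
    # gene models
    genes_per_chrom: int = 20
    exons_per_gene: int = 6
    exon_length: int = 400
    intron_length: int = 2_400
    utr_length: int = 100
    # planted intergenic enrichment: per-base placement odds relative to exon
    weight_exon: float = 1.0
    weight_intron: float = 9.1 / 1.9
    weight_intergenic: float = 9.1
    # mask parameters assumed by the truth geometry
    window_length: int = 50
    mask_depth_threshold: int = 25
    mask_merge_distance: int = 250

    def manifest(self) -> SampleManifest:
        samples, groups, covs = [], {}, {}
        for i in range(self.n_ingroup):
            s = f"mam{i + 1}"
            samples.append(s)
            groups[s] = "ingroup"
            covs[s] = self.ingroup_coverage
        for name, n, cov in self.outgroup_specs:
            for i in range(n):
                s = f"{name}{i + 1}"
                samples.append(s)
                groups[s] = name
                covs[s] = cov
        return SampleManifest(tuple(samples), groups, covs)


@dataclasses.dataclass
class PlantedIndel:
    """One planted VCF record with its expected cascade outcome."""

    chrom: str
    pos: int                  # internal 0-based anchor position
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    qd: float | None
    fs: float | None
    read_pos_rank_sum: float | None
    genotypes: dict[str, tuple[int, ...] | None]
    allele_depths: dict[str, tuple[int, ...]]
    category: str             # exon / intron / intergenic at the anchor
    is_snp: bool
    # expected cascade verdicts, computed from the planted attributes
    expect_mappable: bool = True
    expect_quality: bool = True
    expect_support: bool = True
    expect_single: bool = True
    expect_fixed: bool = True
    expect_size: bool = True

    @property
    def expect_pass(self) -> bool:
        return (not self.is_snp) and all(
            (self.expect_mappable, self.expect_quality, self.expect_support,
             self.expect_single, self.expect_fixed, self.expect_size)
        )

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, ",".join(self.alts))


@dataclasses.dataclass
class SimulationTruth:
    repeats: GenomeIntervalSet
    deletions: GenomeIntervalSet
    expected_unmappable: GenomeIntervalSet
    indels: list[PlantedIndel]

    def expected_passing_keys(self) -> set[tuple]:
        return {p.key() for p in self.indels if p.expect_pass}


@dataclasses.dataclass
class Simulation:
    config: SimulationConfig
    manifest: SampleManifest
    reference: dict[str, str]
    gene_models: list[GeneModel]
    truth: SimulationTruth
    depth: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> per-site depth

    def write_all(self, outdir: str | Path) -> None:
        """Emit FASTA, per-sample depth TSVs, VCF, GFF3, manifest and truth files.

        Depth TSVs are large at full scale; intended for desk-sized configs.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "reference.fasta")
        write_manifest(self.manifest, outdir / "samples.tsv")
        for sample, tracks in self.depth.items():
            write_depth_tsv(tracks, outdir / f"{sample}.depth.tsv")
        write_gff3(self.gene_models, outdir / "genes.gff3")
        write_vcf(self, outdir / "indels.vcf")
        write_bed(self.truth.repeats, outdir / "truth_repeats.bed")
        write_bed(self.truth.deletions, outdir / "truth_deletions.bed")
        write_bed(self.truth.expected_unmappable, outdir / "truth_unmappable.bed")
        with open(outdir / "truth_indels.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talts\tcategory\tis_snp\tmappable\tquality\t"
                     "support\tsingle\tfixed\tsize\tpass\n")
            for p in self.truth.indels:
                fh.write(
                    f"{p.chrom}\t{p.pos}\t{p.ref}\t{','.join(p.alts)}\t{p.category}\t"
                    f"{int(p.is_snp)}\t{int(p.expect_mappable)}\t{int(p.expect_quality)}\t"
                    f"{int(p.expect_support)}\t{int(p.expect_single)}\t"
                    f"{int(p.expect_fixed)}\t{int(p.expect_size)}\t{int(p.expect_pass)}\n"
                )


# ---------------------------------------------------------------------------
# reference and repeats
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], GenomeIntervalSet]:
    """i.i.d. uniform ACGT background with exact duplicated segments.

    Both copies of each repeat are recorded in the truth BED.
    """
    seqs: dict[str, str] = {}
    repeats = GenomeIntervalSet()
    for chrom, length in config.chrom_lengths.items():
        if config.repeats_per_chrom and 2 * config.repeat_length >= length - 10_000:
            raise ValueError(f"repeats exceed chromosome {chrom} length")
        arr = _random_seq(rng, length)
        occupied: list[tuple[int, int]] = []
        for _ in range(config.repeats_per_chrom):
            src = _place(rng, length, config.repeat_length, occupied, margin=5_000)
            dst = _place(rng, length, config.repeat_length, occupied + [src], margin=5_000)
            arr[dst[0]:dst[1]] = arr[src[0]:src[1]]
            # force mismatched flanking bases so the duplicated segment is
            # exactly the recorded interval (no chance extension)
            for a, b in ((src[0] - 1, dst[0] - 1), (src[1], dst[1])):
                if arr[b] == arr[a]:
                    arr[b] = _BASES[(int(np.searchsorted(_BASES, arr[a])) + 1) % 4]
            occupied += [src, dst]
            repeats.add(chrom, *src, label="repeat_src")
            repeats.add(chrom, *dst, label="repeat_copy")
        seqs[chrom] = arr.tobytes().decode()
    return seqs, repeats


def _place(
    rng: np.random.Generator,
    length: int,
    size: int,
    occupied: Sequence[tuple[int, int]],
    margin: int,
    halo: int = 1_000,
) -> tuple[int, int]:
    for _ in range(10_000):
        s = int(rng.integers(margin, length - margin - size))
        e = s + size
        if all(e + halo <= os or s >= oe + halo for os, oe in occupied):
            return s, e
    raise ValueError("could not place segment; chromosome too crowded")


def expected_unmappable(config: SimulationConfig, repeats: GenomeIntervalSet) -> GenomeIntervalSet:
    """Closed-form expected mask for a random background with exact repeats.

    Chromosome ends contribute tapers of k-1-(d-1) = 24 bp at defaults
    (sites covered by fewer than d windows).  A duplicated segment
    [s, e) makes every window fully inside it non-unique, leaving sites
    in [s+d, e-d) at defaults with unique-window depth below d.  Valid
    for repeat length >= 2k and flanks unique, which holds with
    overwhelming probability on an i.i.d. background.
    """
    k, d, m = config.window_length, config.mask_depth_threshold, config.mask_merge_distance
    out = GenomeIntervalSet()
    for chrom, length in config.chrom_lengths.items():
        # boundary depth is min(i+1, k, L-i): below d over the first/last d-1 sites
        out.add(chrom, 0, d - 1)
        out.add(chrom, length - (d - 1), length)
        for s, e in repeats.intervals(chrom):
            # inside [s, e) the unique-window depth is max(0, s+k-1-i) + max(0, i-e+k)
            if e - s >= 2 * k:
                out.add(chrom, s + (k - d), e - (k - d))
    return out.merge(m)


# ---------------------------------------------------------------------------
# gene models / annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneModel]:
    """Non-overlapping genes laid left-to-right with random intergenic gaps.

    Each gene has ``exons_per_gene`` exons; the CDS is the exon chain
    trimmed by a UTR at each end and rounded down to a codon multiple.
    Both strands are represented.
    """
    genes: list[GeneModel] = []
    gene_len = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    for chrom, length in config.chrom_lengths.items():
        usable = length - 6_000
        spare = usable - config.genes_per_chrom * gene_len
        if spare < config.genes_per_chrom * 2_000:
            raise ValueError(f"cannot pack {config.genes_per_chrom} genes into {chrom}")
        mean_gap = spare // (config.genes_per_chrom + 1)
        cursor = 3_000
        for gi in range(config.genes_per_chrom):
            cursor += int(rng.integers(mean_gap // 2, mean_gap + mean_gap // 2))
            start = cursor
            if start + gene_len > length - 3_000:
                break
            exons = [
                (
                    start + i * (config.exon_length + config.intron_length),
                    start + i * (config.exon_length + config.intron_length) + config.exon_length,
                )
                for i in range(config.exons_per_gene)
            ]
            end = exons[-1][1]
            cds_start = exons[0][0] + config.utr_length
            cds_end = exons[-1][1] - config.utr_length
            cds = [(max(s, cds_start), min(e, cds_end)) for s, e in exons]
            cds = [(s, e) for s, e in cds if s < e]
            total = sum(e - s for s, e in cds)
            trim = total % 3
            if trim:
                s, e = cds[-1]
                cds[-1] = (s, e - trim)
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}_g{gi + 1}"
            genes.append(
                GeneModel(gid, chrom, start, end, strand,
                          [Transcript(f"{gid}.t1", exons, cds)])
            )
            cursor = end
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={t.transcript_id}\n")
                for s, e in t.cds:
                    fh.write(f"{g.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={t.transcript_id}\n")


# ---------------------------------------------------------------------------
# deletions and depth
# ---------------------------------------------------------------------------

def _simulate_deletions(
    config: SimulationConfig,
    repeats: GenomeIntervalSet,
    rng: np.random.Generator,
) -> GenomeIntervalSet:
    """Plant disjoint fixed deletions in fully mappable sequence."""
    out = GenomeIntervalSet()
    chroms = list(config.chrom_lengths)
    per_chrom: dict[str, list[tuple[int, int]]] = {
        c: [(s - _CLEAN_MARGIN, e + _CLEAN_MARGIN) for s, e in repeats.intervals(c)]
        for c in chroms
    }
    for i in range(config.n_deletions):
        chrom = chroms[i % len(chroms)]
        size = int(rng.integers(*config.deletion_length_range))
        span = _place(rng, config.chrom_lengths[chrom], size, per_chrom[chrom], margin=_CLEAN_MARGIN)
        per_chrom[chrom].append(span)
        out.add(chrom, *span)
    return out


def simulate_depth(
    config: SimulationConfig,
    deletions: GenomeIntervalSet,
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample per-site Poisson depth; zero inside planted deletions
    for in-group genomes, with optional low-level misalignment peaks."""
    manifest = config.manifest()
    depth: dict[str, dict[str, np.ndarray]] = {}
    for sample in manifest.samples:
        lam = manifest.coverages[sample]
        ingroup = manifest.groups[sample] == "ingroup"
        tracks: dict[str, np.ndarray] = {}
        for chrom, length in config.chrom_lengths.items():
            arr = rng.poisson(lam, size=length).astype(np.int32)
            if ingroup:
                for s, e in deletions.intervals(chrom):
                    arr[s:e] = 0
            tracks[chrom] = arr
        depth[sample] = tracks
    if config.misalignment_prob > 0:
        ing = manifest.ingroup_samples()
        for chrom, s, e in deletions:
            if rng.random() >= config.misalignment_prob:
                continue
            width = min(config.misalignment_length, (e - s) // 3)
            at = int(rng.integers(s + width, e - 2 * width))
            peak = rng.poisson(
                config.misalignment_epsilon / len(ing), size=(len(ing), width)
            ).astype(np.int32)
            for row, sample in enumerate(ing):
                depth[sample][chrom][at:at + width] += peak[row]
    return depth


# ---------------------------------------------------------------------------
# indel VCF
# ---------------------------------------------------------------------------

def _category_intervals(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    repeats: GenomeIntervalSet,
    deletions: GenomeIntervalSet,
) -> dict[str, GenomeIntervalSet]:
    """exon/intron/intergenic intervals restricted to 'clean' zones: away
    from chromosome ends, repeat halos and planted deletions, so an indel
    placed there is unambiguously mappable."""
    lengths = config.chrom_lengths
    exon = GenomeIntervalSet()
    genic = GenomeIntervalSet()
    for g in genes:
        for s, e in g.exon_union():
            exon.add(g.chrom, s, e)
        genic.add(g.chrom, g.start, g.end)
    exon = exon.merge(0)
    genic = genic.merge(0)
    intron = genic.intersect(exon.complement(lengths))
    intergenic = genic.complement(lengths).intersect(exon.complement(lengths))
    dirty = GenomeIntervalSet()
    for chrom, length in lengths.items():
        dirty.add(chrom, 0, _CLEAN_MARGIN)
        dirty.add(chrom, length - _CLEAN_MARGIN, length)
    for chrom, s, e in repeats:
        dirty.add(chrom, max(0, s - _CLEAN_MARGIN), e + _CLEAN_MARGIN)
    for chrom, s, e in deletions:
        dirty.add(chrom, max(0, s - 50), e + 50)
    clean = dirty.merge(0).complement(lengths)
    return {
        "exon": exon.intersect(clean),
        "intron": intron.intersect(clean),
        "intergenic": intergenic.intersect(clean),
    }


def _sample_position(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    cum: np.ndarray,
    span: int,
    used: set[tuple[str, int]],
) -> tuple[str, int] | None:
    for _ in range(200):
        x = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, x, side="right")) - 1
        chrom, s, e = intervals[i]
        if e - s <= span + 2:
            continue
        pos = s + 1 + int(rng.integers(0, e - s - span - 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos
    return None


def simulate_indel_vcf(
    config: SimulationConfig,
    reference: dict[str, str],
    genes: Sequence[GeneModel],
    repeats: GenomeIntervalSet,
    deletions: GenomeIntervalSet,
    rng: np.random.Generator,
) -> list[PlantedIndel]:
    """Plant indel records with known expected cascade outcomes.

    Placement odds per base are weight_cat * |cat|, so the planted
    intergenic:exon and intergenic:intron per-base odds equal the
    configured weight ratios.  Deterministic boundary records (size
    24/25, support 4/5, QD 1.99/2.0, one het in-group genotype, one
    non-reference outgroup genotype, missing genotypes) are appended to
    every simulation.
    """
    manifest = config.manifest()
    cats = _category_intervals(config, genes, repeats, deletions)
    cat_names = ("exon", "intron", "intergenic")
    weights = np.array([config.weight_exon, config.weight_intron, config.weight_intergenic])
    sizes_bp = np.array([cats[c].total_length() for c in cat_names], dtype=float)
    probs = weights * sizes_bp
    probs /= probs.sum()
    cat_ivals = {c: list(cats[c]) for c in cat_names}
    cat_cum = {
        c: np.concatenate([[0], np.cumsum([e - s for _, s, e in cat_ivals[c]])])
        for c in cat_names
    }
    repeat_interiors = [
        (chrom, s + _REPEAT_INTERIOR_MARGIN, e - _REPEAT_INTERIOR_MARGIN)
        for chrom, s, e in repeats
        if e - s > 2 * _REPEAT_INTERIOR_MARGIN + 60
    ]
    rep_cum = np.concatenate([[0], np.cumsum([e - s for _, s, e in repeat_interiors])])
    used: set[tuple[str, int]] = set()
    planted: list[PlantedIndel] = []

    for _ in range(config.n_indels):
        in_repeat = rng.random() < config.frac_in_repeat
        is_snp = (not in_repeat) and rng.random() < config.frac_snp
        intermediate = rng.random() < config.frac_intermediate_size
        if is_snp:
            size = 0
        elif intermediate:
            size = int(rng.integers(25, 41))
        else:
            size = int(rng.integers(config.indel_size_range[0], config.indel_size_range[1] + 1))
        is_del = rng.random() < config.deletion_bias
        span = size + 1 if (is_del and not is_snp) else 1
        if in_repeat:
            where = _sample_position(rng, repeat_interiors, rep_cum, span, used)
            category = "repeat"
        else:
            cat = cat_names[int(rng.choice(3, p=probs))]
            where = _sample_position(rng, cat_ivals[cat], cat_cum[cat], span, used)
            category = cat
        if where is None:
            continue
        chrom, pos = where

        freq = 1.0 if rng.random() < config.fixed_fraction else float(
            rng.beta(*config.segregating_beta)
        )
        clean = rng.random() < config.frac_outgroup_clean
        p = _plant_record(
            config, manifest, reference, rng, chrom, pos, size, is_del, is_snp,
            category, freq, clean,
        )
        planted.append(p)

    planted.extend(_boundary_records(config, manifest, reference, cats, rng, used))
    planted.sort(key=lambda p: (p.chrom, p.pos))
    return planted


def _plant_record(
    config: SimulationConfig,
    manifest: SampleManifest,
    reference: dict[str, str],
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    size: int,
    is_del: bool,
    is_snp: bool,
    category: str,
    ingroup_freq: float,
    outgroup_clean: bool,
    forced: dict | None = None,
) -> PlantedIndel:
    deterministic = forced is not None  # boundary records: no random fault injection
    forced = forced or {}
    seq = reference[chrom]
    anchor = seq[pos]
    if is_snp:
        ref, alt = anchor, {"A": "C", "C": "G", "G": "T", "T": "A"}.get(anchor, "A")
    elif is_del:
        ref, alt = seq[pos : pos + size + 1], anchor
    else:
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
        ref, alt = anchor, anchor + ins
    alts = [alt]

    # multi-allelic: a second ALT carried by one sample
    multi = (not is_snp) and (not deterministic) and rng.random() < config.frac_multiallelic
    multi_in_ingroup = False
    if multi:
        ins2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        alts.append(anchor + ins2 if alt != anchor + ins2 else anchor + ins2 + "A")
        multi_in_ingroup = rng.random() < 0.5

    genotypes: dict[str, tuple[int, ...] | None] = {}
    for s in manifest.ingroup_samples():
        a1 = 1 if rng.random() < ingroup_freq else 0
        a2 = 1 if rng.random() < ingroup_freq else 0
        genotypes[s] = tuple(sorted((a1, a2)))
    outgroup_samples = [
        s for g in manifest.outgroup_labels() for s in manifest.group_samples(g)
    ]
    for s in outgroup_samples:
        genotypes[s] = (0, 0)
    if not outgroup_clean:
        dirty = outgroup_samples[int(rng.integers(0, len(outgroup_samples)))]
        genotypes[dirty] = (0, 1)
    if multi:
        if multi_in_ingroup:
            victim = manifest.ingroup_samples()[int(rng.integers(0, manifest_len_in(manifest)))]
            genotypes[victim] = (1, 2) if genotypes[victim] != (0, 0) else (0, 2)
        else:
            victim = outgroup_samples[int(rng.integers(0, len(outgroup_samples)))]
            genotypes[victim] = (0, 2)

    missing_sample = None
    if (not deterministic) and rng.random() < config.frac_missing_genotype:
        all_samples = list(manifest.samples)
        missing_sample = all_samples[int(rng.integers(0, len(all_samples)))]
        genotypes[missing_sample] = None

    # allele depths: per-sample total ~ Poisson(mean coverage), split by genotype
    low_support = (not is_snp) and (not deterministic) and rng.random() < config.frac_low_support
    allele_depths: dict[str, tuple[int, ...]] = {}
    n_alleles = 1 + len(alts)
    for s in manifest.samples:
        dp = max(1, int(rng.poisson(manifest.coverages[s])))
        ad = [0] * n_alleles
        gt = genotypes[s]
        if gt is None:
            ad[0] = dp
        else:
            counts = {a: gt.count(a) for a in set(gt)}
            for a, c in counts.items():
                ad[a] = int(round(dp * c / 2))
        allele_depths[s] = tuple(ad)
    if low_support:
        target = int(forced.get("support", 4))
        _rescale_ingroup_alt_support(manifest, genotypes, allele_depths, target)
    if "support" in forced and not low_support:
        _rescale_ingroup_alt_support(manifest, genotypes, allele_depths, int(forced["support"]))

    # site statistics
    qual = float(rng.uniform(100, 2000))
    qd: float | None = float(rng.uniform(5, 35))
    fs: float | None = float(rng.uniform(0, 20))
    rprs: float | None = float(np.clip(rng.normal(0, 2), -10, 10))
    quality_ok = True
    if (not deterministic) and rng.random() < config.frac_stats_absent:
        qd = fs = rprs = None
    elif (not is_snp) and (not deterministic) and rng.random() < config.frac_quality_fault:
        which = int(rng.integers(0, 4))
        if which == 0:
            qd = float(rng.uniform(0.1, 1.9))
        elif which == 1:
            qual = float(rng.uniform(1, 29))
        elif which == 2:
            fs = float(rng.uniform(201, 400))
        else:
            rprs = float(rng.uniform(-40, -20.5))
        quality_ok = False
    for key, val in forced.items():
        if key == "qd":
            qd = val
            quality_ok = not (val is not None and val < 2.0)
        elif key == "qual":
            qual = val
            quality_ok = quality_ok and not (val < 30.0)
        elif key == "fs":
            fs = val
            quality_ok = quality_ok and not (val > 200.0)
        elif key == "rprs":
            rprs = val
            quality_ok = quality_ok and not (val < -20.0)

    # expected cascade verdicts from planted attributes
    ing = manifest.ingroup_samples()
    carried = set()
    for s in ing:
        gt = genotypes[s]
        if gt:
            carried.update(a for a in gt if a > 0)
    expect_single = len(carried) <= 1
    expect_fixed = (
        all(genotypes[s] == (1, 1) for s in ing)
        and all(genotypes[s] == (0, 0) for s in outgroup_samples)
    )
    pooled = sum(
        sum(allele_depths[s][1:]) for s in ing
    )
    expect_support = pooled >= 5
    expect_size = (not is_snp) and size < 25

    return PlantedIndel(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        qd=qd,
        fs=fs,
        read_pos_rank_sum=rprs,
        genotypes=genotypes,
        allele_depths=allele_depths,
        category=category,
        is_snp=is_snp,
        expect_mappable=category != "repeat",
        expect_quality=quality_ok,
        expect_support=expect_support,
        expect_single=expect_single,
        expect_fixed=expect_fixed,
        expect_size=expect_size,
    )


def manifest_len_in(manifest: SampleManifest) -> int:
    return len(manifest.ingroup_samples())


def _rescale_ingroup_alt_support(
    manifest: SampleManifest,
    genotypes: dict,
    allele_depths: dict,
    target: int,
) -> None:
    """Force the pooled in-group ALT read count to exactly ``target``."""
    ing = manifest.ingroup_samples()
    budget = target
    for s in ing:
        ad = list(allele_depths[s])
        alt_total = sum(ad[1:])
        keep = min(alt_total, budget)
        if alt_total > 0:
            scaled = [0] * len(ad)
            scaled[0] = ad[0]
            remaining = keep
            for i in range(1, len(ad)):
                take = min(ad[i], remaining)
                scaled[i] = take
                remaining -= take
            scaled[0] += alt_total - keep
            allele_depths[s] = tuple(scaled)
            budget -= keep
    # if the planted genotypes carried fewer ALT reads than target, top up sample 1
    if budget > 0 and ing:
        ad = list(allele_depths[ing[0]])
        ad[1] += budget
        allele_depths[ing[0]] = tuple(ad)


def _boundary_records(
    config: SimulationConfig,
    manifest: SampleManifest,
    reference: dict[str, str],
    cats: dict[str, GenomeIntervalSet],
    rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> list[PlantedIndel]:
    """Deterministic edge cases exercising every filter boundary."""
    ivals = list(cats["intergenic"])
    cum = np.concatenate([[0], np.cumsum([e - s for _, s, e in ivals])])
    out: list[PlantedIndel] = []

    def plant(size=5, forced=None, mutate=None, is_del=True):
        where = _sample_position(rng, ivals, cum, size + 1, used)
        assert where is not None
        chrom, pos = where
        p = _plant_record(
            config, manifest, reference, rng, chrom, pos, size, is_del, False,
            "intergenic", 1.0, True, forced=forced if forced is not None else {},
        )
        if mutate:
            mutate(p)
        out.append(p)

    plant(size=24)                                    # passes the <25 bp bound
    plant(size=25)                                    # fails it
    plant(forced={"support": 4})                      # pooled support 4: fail
    plant(forced={"support": 5})                      # pooled support 5: pass
    plant(forced={"qd": 1.99})
    plant(forced={"qd": 2.0})
    plant(forced={"qual": 30.0})
    plant(forced={"fs": 200.0})
    plant(forced={"rprs": -20.0})

    def make_het(p: PlantedIndel) -> None:
        s = manifest.ingroup_samples()[0]
        p.genotypes[s] = (0, 1)
        p.expect_fixed = False

    def dirty_outgroup(p: PlantedIndel) -> None:
        g = manifest.outgroup_labels()[0]
        s = manifest.group_samples(g)[0]
        p.genotypes[s] = (0, 1)
        p.expect_fixed = False

    def missing_ingroup(p: PlantedIndel) -> None:
        s = manifest.ingroup_samples()[1]
        p.genotypes[s] = None
        p.expect_fixed = False

    def missing_outgroup(p: PlantedIndel) -> None:
        g = manifest.outgroup_labels()[-1]
        s = manifest.group_samples(g)[-1]
        p.genotypes[s] = None
        p.expect_fixed = False

    plant(mutate=make_het)
    plant(mutate=dirty_outgroup)
    plant(mutate=missing_ingroup)
    plant(mutate=missing_outgroup)
    return out


# ---------------------------------------------------------------------------
# VCF writer
# ---------------------------------------------------------------------------

def write_vcf(sim: Simulation, path: str | Path) -> None:
    """Write the planted records as a VCF 4.2 file."""
    manifest = sim.manifest
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sim.config.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(manifest.samples) + "\n")
        for p in sim.truth.indels:
            info_parts = []
            if p.qd is not None:
                info_parts.append(f"QD={p.qd:.2f}")
            if p.fs is not None:
                info_parts.append(f"FS={p.fs:.2f}")
            if p.read_pos_rank_sum is not None:
                info_parts.append(f"ReadPosRankSum={p.read_pos_rank_sum:.2f}")
            info = ";".join(info_parts) if info_parts else "."
            qual = f"{p.qual:.2f}" if p.qual is not None else "."
            fields = [
                p.chrom, str(p.pos + 1), ".", p.ref, ",".join(p.alts), qual, ".", info, "GT:AD",
            ]
            for s in manifest.samples:
                gt = p.genotypes[s]
                gts = "./." if gt is None else "/".join(str(a) for a in gt)
                ad = ",".join(str(x) for x in p.allele_depths[s])
                fields.append(f"{gts}:{ad}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> Simulation:
    """Generate a full dataset (reference, annotation, depth, indels, truth)."""
    rng = np.random.default_rng(config.seed)
    reference, repeats = simulate_reference(config, rng)
    genes = simulate_annotation(config, rng)
    deletions = _simulate_deletions(config, repeats, rng)
    depth = simulate_depth(config, deletions, rng)
    indels = simulate_indel_vcf(config, reference, genes, repeats, deletions, rng)
    truth = SimulationTruth(
        repeats=repeats,
        deletions=deletions,
        expected_unmappable=expected_unmappable(config, repeats),
        indels=indels,
    )
    return Simulation(config, config.manifest(), reference, genes, truth, depth)
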