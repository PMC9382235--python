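"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: everything is converted to 0-based half-open on
read.  VCF ``POS p`` becomes internal ``p - 1``; GFF3 ``start..end``
(1-based inclusive) becomes ``(start - 1, end)``; BED passes through.

Standard formats go through established parsers (Biopython for FASTA,
pysam for VCF, gffutils for GFF3, pandas for tabular files); this module
only enforces the pipeline's validity rules on top of them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .intervals import GenomeIntervalSet

__all__ = [
    "SampleManifest",
    "IndelVariant",
    "Transcript",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_bed",
    "write_bed",
    "read_vcf_indels",
    "read_gff3_genes",
    "read_manifest",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SampleManifest:
    """Assignment of samples to groups, with per-genome mean coverage.

    The in-group is the lineage under study (label ``ingroup``); every
    other label is an outgroup group.  Group-summed expected coverage E
    is the sum of the member genomes' mean coverages — the summation
    units of the deletion scan.
    """

    samples: tuple[str, ...]
    groups: Mapping[str, str]          # sample -> group label
    coverages: Mapping[str, float]     # sample -> mean per-genome coverage (X)

    def __post_init__(self) -> None:
        for s in self.samples:
            if self.coverages[s] <= 0:
                raise ValueError(f"sample {s}: coverage must be > 0")
        if not self.ingroup_samples():
            raise ValueError("manifest has no ingroup samples")
        if not self.outgroup_labels():
            raise ValueError("manifest has no outgroup groups")

    def ingroup_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == "ingroup"]

    def outgroup_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g != "ingroup" and g not in seen:
                seen.append(g)
        return seen

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def expected_summed_coverage(self, group: str) -> float:
        """E for a group: sum of its members' mean coverages (in X)."""
        members = self.group_samples(group)
        if not members:
            raise KeyError(f"no samples in group {group!r}")
        return float(sum(self.coverages[s] for s in members))


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["sample", "group", "coverage"], dtype={"sample": str})
    return SampleManifest(
        samples=tuple(df["sample"]),
        groups=dict(zip(df["sample"], df["group"])),
        coverages=dict(zip(df["sample"], df["coverage"].astype(float))),
    )


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in manifest.samples:
            fh.write(f"{s}\t{manifest.groups[s]}\t{manifest.coverages[s]}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Read a FASTA into ``{name: uppercase sequence}``.

    Returns the sequences and a parallel soft-mask flag track (True where
    the input base was lowercase).  Soft-masking is recorded but nothing
    downstream acts on it.  IUPAC ambiguity codes are retained.
    """
    seqs: dict[str, str] = {}
    softmask: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        raw = str(rec.seq)
        seqs[rec.id] = raw.upper()
        softmask[rec.id] = np.frombuffer(raw.encode(), dtype=np.uint8) >= ord("a")
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs, softmask


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# samtools-depth TSV
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a ``samtools depth``-style TSV (chrom, 1-based pos, depth).

    Sites absent from the file get depth 0 (samtools depth without
    ``-a``).  Every chromosome in ``chrom_lengths`` gets an array of its
    full length.
    """
    arrays = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    try:
        df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"],
                         dtype={"chrom": str, "pos": np.int64, "depth": np.int64})
    except pd.errors.EmptyDataError:
        return arrays
    if (df["depth"] < 0).any():
        raise ValueError(f"negative depth in {path}")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in arrays:
            raise ValueError(f"unknown chromosome {chrom!r} in {path}")
        pos = sub["pos"].to_numpy()
        if (pos < 1).any() or (pos > len(arrays[chrom])).any():
            raise ValueError(f"position outside {chrom} (length {len(arrays[chrom])}) in {path}")
        arrays[chrom][pos - 1] = sub["depth"].to_numpy()
    return arrays


def write_depth_tsv(depths: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-site depths, omitting zero-depth sites (samtools convention)."""
    with open(path, "w") as fh:
        for chrom, arr in depths.items():
            nz = np.flatnonzero(arr)
            for i in nz:
                fh.write(f"{chrom}\t{i + 1}\t{arr[i]}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GenomeIntervalSet:
    """Read BED3/BED4 (0-based half-open); input need not be sorted."""
    out = GenomeIntervalSet()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else None
            out.add(chrom, start, end, label)
    return out


def write_bed(intervals: GenomeIntervalSet, path: str | Path,
              header: str | None = None) -> None:
    """Write sorted BED; a header line (starting '#') records parameters."""
    with open(path, "w") as fh:
        if header:
            fh.write("#" + header.lstrip("#") + "\n")
        for chrom, start, end, label in intervals.records():
            if label is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# VCF indels
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IndelVariant:
    """One VCF indel record with per-sample genotypes and allele depths.

    ``pos`` is internal 0-based (VCF POS - 1).  ``genotypes`` maps sample
    to a tuple of allele indices, or None when the genotype is missing.
    ``allele_depths`` maps sample to the AD tuple (ref first), or None.
    Site statistics that are absent from the record are stored as None,
    never as 0.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int, ...] | None]
    allele_depths: dict[str, tuple[int, ...] | None]
    qual: float | None
    qd: float | None
    fs: float | None
    read_pos_rank_sum: float | None

    def indel_alt_indices(self) -> list[int]:
        """1-based allele indices of ALTs whose length differs from REF."""
        return [i + 1 for i, a in enumerate(self.alts) if len(a) != len(self.ref)]

    def alt_carried_by(self, samples: Sequence[str]) -> set[int]:
        """Distinct non-reference allele indices carried by ``samples``."""
        carried: set[int] = set()
        for s in samples:
            gt = self.genotypes.get(s)
            if gt is None:
                continue
            carried.update(a for a in gt if a is not None and a > 0)
        return carried

    def size_of_alt(self, alt_index: int) -> int:
        return abs(len(self.alts[alt_index - 1]) - len(self.ref))

    def class_of_alt(self, alt_index: int) -> str:
        return "insertion" if len(self.alts[alt_index - 1]) > len(self.ref) else "deletion"

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference footprint [pos, pos + len(REF))."""
        return self.pos, self.pos + len(self.ref)


def _fmt_float(x) -> float | None:
    return None if x is None else float(x)


def read_vcf_indels(path: str | Path, manifest: SampleManifest) -> list[IndelVariant]:
    """Read a multi-sample VCF, keeping only indel records.

    A record is kept iff at least one ALT differs in length from REF
    (pure SNP records are dropped).  Multi-allelic records are retained
    intact: the single-variant filter needs the full allele set.
    """
    vcf = pysam.VariantFile(str(path))
    header_samples = set(vcf.header.samples)
    missing = [s for s in manifest.samples if s not in header_samples]
    if missing:
        raise ValueError(f"manifest samples absent from VCF header: {missing}")
    out: list[IndelVariant] = []
    for rec in vcf:
        alts = tuple(rec.alts or ())
        if not alts or all(len(a) == len(rec.ref) for a in alts):
            continue
        genotypes: dict[str, tuple[int, ...] | None] = {}
        depths: dict[str, tuple[int, ...] | None] = {}
        for s in manifest.samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes[s] = None
            else:
                genotypes[s] = tuple(int(a) for a in gt)
            ad = call.get("AD")
            if ad is None or all(a is None for a in ad):
                depths[s] = None
            else:
                depths[s] = tuple(0 if a is None else int(a) for a in ad)
        info = rec.info
        out.append(
            IndelVariant(
                chrom=rec.chrom,
                pos=rec.pos - 1,
                ref=rec.ref,
                alts=alts,
                genotypes=genotypes,
                allele_depths=depths,
                qual=_fmt_float(rec.qual),
                qd=_fmt_float(info.get("QD")),
                fs=_fmt_float(info.get("FS")),
                read_pos_rank_sum=_fmt_float(info.get("ReadPosRankSum")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]       # 0-based half-open, sorted by start
    cds: list[tuple[int, int]]


@dataclasses.dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript]

    def exon_union(self) -> list[tuple[int, int]]:
        ivals = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features from GFF3 into gene models.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  Each transcript's exons come back sorted; a CDS interval
    falling outside every exon of its transcript is an error, as is an
    exon/mRNA whose Parent is not present.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    gene_ids = {f.id for f in db.features_of_type("gene")}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts: list[Transcript] = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            parents = t.attributes.get("Parent", [])
            if not parents or any(p not in gene_ids for p in parents):
                raise ValueError(f"mRNA {t.id}: Parent missing or unknown")
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="CDS")
            )
            for cs, ce in cds:
                if not any(es <= cs and ce <= ee for es, ee in exons):
                    raise ValueError(
                        f"CDS {cs}-{ce} of transcript {t.id} outside its exons"
                    )
            transcripts.append(Transcript(t.id, exons, cds))
        # orphan exon/CDS check: every exon/CDS child of this gene's mRNAs only
        genes.append(
            GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand, transcripts)
        )
    # any exon/CDS whose Parent is not a known mRNA is malformed
    mrna_ids = {t.transcript_id for gm in genes for t in gm.transcripts}
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents or any(p not in mrna_ids for p in parents):
                raise ValueError(f"{ftype} at {f.seqid}:{f.start} has unknown Parent")
    return genes
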