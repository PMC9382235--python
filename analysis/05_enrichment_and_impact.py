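"""Test the genomic distribution of the fixed indels and classify coding
impact.

Partitions the genome into exon/intron/intergenic, compares positions
sampled within the fixed indels against positions sampled uniformly
over the mappable genome (Fisher's exact test on each category pair),
and lists genes whose coding sequence is altered by a large deletion or
a frameshift/start/stop-affecting indel.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, SEED

from paleodel import deletion_scan as ds
from paleodel import impact_annotation as ia
from paleodel import indel_pipeline as ip
from paleodel import io_formats as io
from paleodel import mappability as mp


def main() -> None:
    manifest = io.read_manifest(SCRATCH / "samples.tsv")
    seqs, _ = io.read_fasta(SCRATCH / "reference.fasta")
    lengths = {c: len(s) for c, s in seqs.items()}
    genes = io.read_gff3_genes(SCRATCH / "genes.gff3")
    mask = mp.MappabilityMask(io.read_bed(SCRATCH / "mask.bed"), 50, 1, 25, 250, lengths)
    variants = io.read_vcf_indels(SCRATCH / "indels.vcf", manifest)
    passing, _ = ip.apply_cascade(variants, manifest, mask)
    calls = _read_calls()

    partition = ia.build_partition(genes, lengths)
    rng = np.random.default_rng(SEED)
    n = 100_000
    random_counts = ia.sample_random_positions(
        n, mask.mappable(), partition, int(rng.integers(2**31))
    )
    variant_counts = ia.sample_positions_within_variants(
        passing, n, partition, int(rng.integers(2**31)), manifest
    )
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "enrichment.tsv", "w") as fh:
        fh.write("cat_a\tcat_b\tvariant_a\tvariant_b\trandom_a\trandom_b\tfold\tp\n")
        for ca, cb in (("intergenic", "intron"), ("intergenic", "exon")):
            r = ia.enrichment_test(random_counts, variant_counts, ca, cb)
            fh.write(f"{ca}\t{cb}\t{r.table[0][0]}\t{r.table[0][1]}\t"
                     f"{r.table[1][0]}\t{r.table[1][1]}\t{r.fold:.4f}\t{r.p_value:.3g}\n")
            print(f"fixed indels are {r.fold:.2f}x more common in {ca} than {cb} "
                  f"(Fisher p = {r.p_value:.2g})")

    impacts = ia.classify_coding_impact(calls, passing, genes, manifest)
    per_gene, n_affected = ia.affected_gene_summary(impacts)
    with open(RESULTS / "gene_impacts.tsv", "w") as fh:
        fh.write("gene\tvariant\tconsequence\n")
        for gene, imps in per_gene.items():
            for i in imps:
                fh.write(f"{gene}\t{i.variant_id}\t{i.consequence}\n")
    print(f"{n_affected} of {len(genes)} genes carry a coding-sequence-altering "
          f"deletion or indel")


def _read_calls():
    calls = []
    with open(RESULTS / "deletions.tsv") as fh:
        next(fh)
        for line in fh:
            chrom, start, end = line.split("\t")[:3]
            calls.append(ds.DeletionCall(chrom, int(start), int(end), 0.0, {}))
    return calls


if __name__ == "__main__":
    main()
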