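"""Filter the multi-sample indel VCF down to in-group-fixed short indels.

Applies the six-predicate cascade (site quality, mappability, pooled
read support, single in-group variant, fixation, <25 bp size), compares
the passing set to the planted expectation, and tallies counts and base
totals by class.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH

from paleodel import indel_pipeline as ip
from paleodel import io_formats as io
from paleodel import mappability as mp


def main() -> None:
    manifest = io.read_manifest(SCRATCH / "samples.tsv")
    seqs, _ = io.read_fasta(SCRATCH / "reference.fasta")
    lengths = {c: len(s) for c, s in seqs.items()}
    mask = mp.MappabilityMask(io.read_bed(SCRATCH / "mask.bed"), 50, 1, 25, 250, lengths)
    variants = io.read_vcf_indels(SCRATCH / "indels.vcf", manifest)
    passing, outcomes = ip.apply_cascade(variants, manifest, mask)
    t = ip.tally(passing, manifest)

    truth = pd.read_csv(SCRATCH / "truth_indels.tsv", sep="\t")
    expected = set(
        map(tuple, truth.loc[truth["pass"] == 1, ["chrom", "pos", "ref", "alts"]].values)
    )
    got = {(v.chrom, v.pos, v.ref, ",".join(v.alts)) for v in passing}

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(outcomes).to_csv(RESULTS / "indel_filter_outcomes.tsv", sep="\t", index=False)
    with open(RESULTS / "indel_tally.tsv", "w") as fh:
        fh.write("n_deletions\tn_insertions\ttotal_deleted_bases\ttotal_inserted_bases\n")
        fh.write(f"{t.n_deletions}\t{t.n_insertions}\t"
                 f"{t.total_deleted_bases}\t{t.total_inserted_bases}\n")
    print(f"{len(passing)}/{len(variants)} indel records pass the cascade")
    print(f"passing set equals planted truth: {got == expected}")
    print(f"tally: {t.n_deletions} deletions ({t.total_deleted_bases} bp), "
          f"{t.n_insertions} insertions ({t.total_inserted_bases} bp)")


if __name__ == "__main__":
    main()
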