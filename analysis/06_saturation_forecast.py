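"""Subsampling saturation: how many fixed indels would survive sampling
more in-group genomes?

Enumerates every subset of the five in-group genomes, counts variants
homozygous-ALT in all subset members (and clean in every outgroup) at
each subset size, fits the exponential trendline y = a*e^(b*k), and
forecasts the retained fraction at a 20-genome horizon.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH

from paleodel import indel_pipeline as ip
from paleodel import io_formats as io
from paleodel import mappability as mp
from paleodel import saturation as sat


def main() -> None:
    manifest = io.read_manifest(SCRATCH / "samples.tsv")
    seqs, _ = io.read_fasta(SCRATCH / "reference.fasta")
    lengths = {c: len(s) for c, s in seqs.items()}
    mask = mp.MappabilityMask(io.read_bed(SCRATCH / "mask.bed"), 50, 1, 25, 250, lengths)
    variants = io.read_vcf_indels(SCRATCH / "indels.vcf", manifest)
    _, outcomes = ip.apply_cascade(variants, manifest, mask)
    # everything surviving the per-site filters enters the curve; fixation is
    # what the subsampling itself probes
    pre_fixation = [
        v for v, o in zip(variants, outcomes)
        if o["site_quality"] and o["mappable"] and o["support"]
        and o["single_variant"] and o["size"]
    ]
    matrix = sat.build_genotype_matrix(pre_fixation, manifest)
    curve = sat.saturation_curve(matrix, horizon=20)

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "saturation.tsv", "w") as fh:
        fh.write("k\tmean_fixed\n")
        for k, y in curve.points:
            fh.write(f"{k}\t{y:.4f}\n")
        fh.write(f"#fit a={curve.a:.6g} b={curve.b:.6g} horizon={curve.horizon} "
                 f"retained_fraction={curve.retained_fraction:.4f}\n")
    print("mean fixed-indel count by in-group sample size:")
    for k, y in curve.points:
        print(f"  k={k}: {y:,.1f}")
    print(f"exponential trendline decay b = {curve.b:.4f}")
    print(f"forecast: {100 * curve.retained_fraction:.1f}% of 5-genome-fixed "
          f"indels still fixed at {curve.horizon} genomes")


if __name__ == "__main__":
    main()
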