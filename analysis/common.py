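"""Shared configuration for the numbered analysis scripts.

The demo dataset is desk-sized (one 400 kb chromosome) so the scripts
run in seconds; the coverage regime matches the full study conditions
(five in-group genomes at 11.8X, outgroups at 633X/173X summed).  Bulky
intermediates (FASTA, depth tracks, VCF) live under scratch/, small
result tables under results/.
"""

from pathlib import Path

from paleodel import synthetic_data as sd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"
SEED = 42


def demo_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(
        seed=SEED,
        chrom_lengths={"chr1": 400_000},
        genes_per_chrom=8,
        n_indels=4_000,
        n_deletions=5,
        repeats_per_chrom=2,
    )
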