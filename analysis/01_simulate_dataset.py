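"""Generate the demo dataset: reference, depth tracks, indel VCF, gene
models and planted truth.

Writes everything a downstream stage consumes to scratch/demo/ so the
later scripts exercise the same file interfaces a real analysis would.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, demo_config

from paleodel import synthetic_data as sd


def main() -> None:
    config = demo_config()
    sim = sd.simulate(config)
    sim.write_all(SCRATCH)
    n_pass = sum(p.expect_pass for p in sim.truth.indels)
    print(f"simulated {sum(config.chrom_lengths.values()):,} bp reference "
          f"with {len(sim.truth.repeats)} repeat copies")
    print(f"planted {len(sim.truth.deletions)} fixed deletions and "
          f"{len(sim.truth.indels)} indel records "
          f"({n_pass} expected to survive the filter cascade)")
    print(f"outputs in {SCRATCH}")


if __name__ == "__main__":
    main()
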