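# paleodel

Coverage-based discovery of lineage-fixed deletions and short indels
from ancient-genome depth tracks.

## The problem

Structural variants are hard to call from ancient DNA: reads are short,
coverage per genome is modest, and repetitive reference sequence
produces coverage holes that mimic deletions.  `paleodel` implements a
conservative pipeline for finding variants *fixed* in an in-group of
genomes (e.g. an extinct lineage such as woolly mammoths) relative to
outgroup genomes (e.g. extant elephants), built around three ideas:

1. **Mappability mask.**  The reference is fragmented into every
   overlapping window of k = 50 bp (step 1).  A window is *unique* iff
   its sequence occurs exactly once genome-wide counting both strands
   (a palindromic self-hit counts once; windows containing non-ACGT
   characters are never unique).  Each site gets a unique-window depth
   `u(i) ≤ min(i+1, k, L−i)`; sites with `u(i) < 25` are unmappable, and
   unmappable intervals within 250 bp of each other are merged.  Reads
   of length ≥ 50 bp cannot be confidently placed in the masked regions,
   so missing coverage there carries no signal.

2. **Group-summed deletion scan.**  Per-site depth is summed across the
   genomes of each group.  With five in-group genomes at mean coverage
   11.8X, the summed expectation is E = 59X, so a non-deleted site has
   probability e^−59 of showing summed depth 0 — but a deletion fixed in
   the in-group stays at exactly 0.  The caller takes maximal runs of
   mappable sites with in-group summed depth ≤ t_in (default 0) that
   have mean depth ≥ 20% of expectation in *every* outgroup group, then
   iterates three merge rules to fixpoint: union adjacent runs; bridge
   runs split by an entirely unmappable gap; bridge runs ≤ 250 bp apart
   whose gap has mean in-group depth < 10% of E (< 5.9X at defaults,
   absorbing misalignment peaks inside true deletions).  Calls longer
   than 500 bp (strictly) are reported.

3. **Fixed-indel cascade.**  A jointly-called multi-sample indel VCF is
   filtered by six pure predicates: GATK-style site quality (fail iff
   QD < 2.0, QUAL < 30.0, FS > 200.0 or ReadPosRankSum < −20.0, with
   absent statistics never failing); reference span entirely mappable;
   pooled in-group ALT-read support ≥ 5; at most one distinct ALT
   carried by the in-group; every in-group genotype homozygous-ALT and
   every outgroup genotype homozygous-REF (missing genotypes fail);
   size strictly below 25 bp.

Downstream, the package tests whether fixed indels avoid genes
(positions sampled within indels vs. uniformly over the mappable
genome, Fisher's exact test per exon/intron/intergenic category pair,
fold = relative odds), classifies coding impact (exon-deleting
deletions; CDS indels are frameshift iff size mod 3 ≠ 0; start/stop
loss by first/last-codon overlap), and runs a subsampling saturation
analysis: over all C(n, k) subsets of the n in-group genomes the mean
fixed count obeys `mean(k) = Σ_v C(m_v, k) / C(n, k)` (m_v = genomes
homozygous-ALT for variant v); an exponential trendline `y = a·e^{bk}`
is fitted log-linearly and the retained fraction at a K-genome horizon
is `e^{b(K−n)}`.

A first-class synthetic-data module generates references with exact
repeats, Poisson depth tracks with planted fixed deletions, indel VCFs
with per-record expected filter outcomes, and gene models with a
controllable intergenic enrichment — so every stage is validated
end-to-end against planted truth without any download.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
demo-scale simulation (one 400 kb chromosome, full-scale coverage):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_build_mask.py
python analysis/03_scan_deletions.py
python analysis/04_filter_indels.py
python analysis/05_enrichment_and_impact.py
python analysis/06_saturation_forecast.py
```

which prints, stage by stage:

```
simulated 400,000 bp reference with 4 repeat copies
planted 5 fixed deletions and 4013 indel records (3074 expected to survive the filter cascade)
7,848 bp unmappable of 400,000 (98.04% mappable)
mask matches the closed-form expectation: True
called 5 deletions >500 bp (summed in-group expectation 59X)
recovered 5/5 planted deletions within 5 bp; 0 unmatched calls
3074/3983 indel records pass the cascade
passing set equals planted truth: True
tally: 2005 deletions (25096 bp), 1069 insertions (13431 bp)
fixed indels are 1.52x more common in intergenic than intron (Fisher p = 0)
fixed indels are 6.32x more common in intergenic than exon (Fisher p = 0)
7 of 8 genes carry a coding-sequence-altering deletion or indel
mean fixed-indel count by in-group sample size:
  k=1: 3,239.0 ... k=5: 3,074.0
exponential trendline decay b = -0.0129
forecast: 82.5% of 5-genome-fixed indels still fixed at 20 genomes
```

Every planted deletion is recovered with exact breakpoints, and the
filter cascade returns exactly the planted passing set.  The enrichment
folds estimate the planted per-base placement odds (1.9 intergenic:
intron, 9.1 intergenic:exon); at this demo scale only a few dozen
indels land in exons, so the estimates carry visible sampling noise —
at the full default scale (three 1 Mb chromosomes, 20,000 indels) they
land much closer (see below).

The same stages are available as a CLI
(`paleodel simulate|mask|scan-deletions|filter-indels|annotate|saturate|run-all`);
bulky intermediates go to `scratch/`, small tables to `results/`.

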