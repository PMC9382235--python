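# Methods

This note documents the models, parameter choices and numerical
conventions behind `paleodel`, and what the synthetic-data validation
does and does not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`, the BED
convention.  VCF `POS p` becomes `p − 1` on read; GFF3 `start..end`
(1-based inclusive) becomes `(start − 1, end)`; both conversions are
self-inverse.  Depth tracks follow the `samtools depth` convention:
a site absent from the TSV has depth 0.  Soft-masked (lowercase)
reference bases are recorded as a flag track but nothing acts on them.
Standard formats are parsed by Biopython (FASTA), pysam (VCF), gffutils
(GFF3) and pandas (tabular); the scientific computations are this
package's own.

## Mappability mask

The mask answers: where can a read of length k be placed uniquely?

* Window generation: every window of k = 50 bp at step 1.  Step sizes
  other than 1 would change the attainable per-site depth ceiling and
  are rejected.
* Uniqueness: exact-match on both strands.  A window is unique iff the
  number of occurrences of its sequence plus occurrences of its reverse
  complement over all positions of all chromosomes equals 1.  A
  palindromic window's self-hit is counted once.  Windows containing
  any non-ACGT character are never unique.  This is a deliberate
  semantic narrowing relative to aligner-based remapping, which also
  multi-maps *near*-identical repeats: exact uniqueness is
  deterministic, aligner-free and exactly testable; the config value
  `uniqueness="exact"` leaves room for near-match modes.  It also
  sidesteps any MAPQ-threshold question entirely.
* Implementation: each k-mer is packed exactly into ceil(k/32) uint64
  words (2 bits per base), so key equality is sequence equality — a
  bijection, not a hash.  Occurrence counting is a single sort over
  forward plus reverse-complement keys of all valid windows.
* Depth and threshold: the unique-window depth at site i is the number
  of unique windows covering i, bounded by `min(i+1, k, L−i)`.  Sites
  with depth < 25 (half the 50 possible covering windows) are
  unmappable.  A direct consequence: the terminal 24 bp of every
  chromosome are always unmappable (taper), which we accept as part of
  the construction.
* Merging: unmappable intervals separated by ≤ 250 bp are merged
  (`bedtools merge -d` semantics: gap = start₂ − end₁).

Test oracle: a brute-force implementation (substring search on both
strands per window, explicit per-site window enumeration) reproduces
the mask exactly on random references with and without planted repeats.
For a planted exact duplicate `[s, e)` on an otherwise-random
background the expected unmappable interior has the closed form
`[s + (k − d), e − (k − d))` with d the depth threshold; the generator
forces mismatched bases flanking each planted copy so this closed form
is exact rather than subject to chance single-base extension.

## Deletion scan

Summing per-site depth across a group's genomes leaves a fixed deletion
at 0 while multiplying flanking coverage by the number of genomes.  At
the default conditions (5 × 11.8X in-group) the summed expectation is
E = 59X and P(summed depth = 0) = e^−59 ≈ 2·10⁻²⁶ per non-deleted site,
so chance zero-runs of any length are effectively impossible — the
recovery and false-positive properties in the tests follow from this
arithmetic, not from tuning.

Design choices where the procedure was genuinely open:

* **Maximal-run formulation.**  An overlapping-window search for
  zero-coverage regions followed by adjacency merging converges to the
  maximal runs of low-coverage sites; we implement the runs directly,
  which is deterministic and parameter-free (no window size/step).
* **t_in = 0 by default** ("no read support"), configurable because
  tolerated misalignment peaks are handled by the low-coverage
  bridging rule instead.
* **Outgroup support** is undefined in prose terms ("good coverage");
  we require mean depth over the candidate ≥ `outgroup_min_frac`
  (default 0.20) of that group's expected summed coverage, for every
  outgroup group separately, and log the per-group means on each call.
* **Gap statistic** for the low-coverage bridge is the mean (10% of E,
  i.e. < 5.9X at defaults), configurable to max.
* **Fixpoint iteration.**  merge-adjacent → bridge-unmappable →
  bridge-low-coverage is repeated until no change; bridging is
  transitive (chains collapse), and the result does not depend on
  within-pass ordering because candidates are kept sorted and disjoint.
* **Strict length bound**: calls must exceed 500 bp; exactly 500 bp is
  dropped.

## Indel filter cascade

Six pure predicates; the passing set is their intersection, so order
cannot matter.  Boundary semantics are taken literally from the
hard-filter expressions: QD = 2.0 passes, QD = 1.99 fails, and so on;
a statistic absent from a record never fails it.  Decisions on
ambiguous points:

* **Support** is pooled ALT-supporting reads across the in-group
  (default ≥ 5), since the allele of interest is the in-group allele;
  a per-sample minimum mode is available.  Samples without AD data
  contribute 0.
* **Fixation** requires every in-group genotype homozygous for the one
  ALT and every outgroup genotype homozygous reference; a missing
  genotype anywhere fails (fixation is asserted only on observed
  genotypes).
* **Multi-allelic records** are kept intact on read: the ≤ 1-variant
  rule inspects the set of ALT alleles actually carried by in-group
  genotypes, so a site where the in-group carries only the second ALT
  passes.
* **Size** is `|len(ALT) − len(REF)|`, strictly < 25 bp; larger records
  are visible in the per-record outcome table rather than silently
  dropped.  Variant calling itself is consumed, not reimplemented.

## Genomic distribution and coding impact

The partition is exon / intron / intergenic with precedence
exon > intron > intergenic at overlapping loci; "exon" means transcribed
exon (UTRs included).  Random positions are sampled over the *mappable*
genome: variants can only be observed in mappable sequence, so the
mappable null is the fair comparison (whole-genome sampling is
available).  Positions "within variants" are sampled uniformly over the
multiset of variant-covered reference bases — deletions weighted by
footprint, insertions anchored at their left insertion point.  The
distribution analysis is run over the fixed short indels, whose
placement the generator controls.

Fold enrichment for categories (a, b) is the relative odds
`(v_a/v_b)/(r_a/r_b)`; the two-sided Fisher exact p sums hypergeometric
probabilities ≤ the observed table's (scipy's implementation, verified
in the tests against full enumeration over all 2×2 tables with
N ≤ 40).  Only the two planned contrasts are tested and p-values are
reported raw.

Coding impact is annotation-geometric: `exon_deleted` for a large
deletion touching ≥ 1 exonic bp of a gene; CDS-overlapping indels are
`frameshift` iff size mod 3 ≠ 0, else `inframe_indel`; `start_lost` /
`stop_lost` by overlap with the strand-aware first/last annotated CDS
codon.  Translation-based consequence prediction is out of scope.  The
affected-gene count includes exon_deleted, frameshift, start_lost and
stop_lost records; in-frame indels are tabulated but not counted as
loss-causing.

## Saturation forecast

All C(n, k) subsets are enumerated exhaustively (guarded at n ≤ 16;
beyond that the error message points to Monte Carlo subsampling, which
is deliberately not silently substituted).  The implementation
enumerates subsets literally; the closed form
`mean(k) = Σ_v C(m_v, k)/C(n, k)` serves as the independent oracle.
The trendline is the spreadsheet/R convention `y = a·e^{bk}` fitted by
OLS on `ln y` — a saturating form `c + a·e^{bk}` would often fit better
(the curve flattens at the truly-fixed count) but the log-linear form
is the stated method and the default.  The forecast horizon K is a
required parameter; the analysis scripts and acceptance report use
K = 20 genomes.  Because the exponential has no asymptote, the forecast
*understates* retention when the curve flattens; treat it as a
conservative lower bound.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions the pipeline targets: three 1 Mb
chromosomes; two exact 2 kb repeats per chromosome; five in-group
genomes at 11.8X (E = 59X); two outgroup groups with summed coverages
633X and 173X (fewer samples than a real cohort — 4 × 158.25X and
2 × 86.5X — so the group sums match at desk scale); twelve fixed
deletions of 600–5000 bp placed in fully mappable sequence; 20,000
indel records of 1–24 bp (plus a 2% intermediate-size fraction and
controlled fractions of quality faults, low support, multi-allelic
sites, missing genotypes, repeat-interior placements and SNP records);
20 genes per Mb with 6 × 400 bp exons (≈ 4.7% exon, 24% intron);
per-base placement odds 9.1 (intergenic) : 9.1/1.9 (intron) : 1
(exon); 90% of indels at in-group frequency 1.0, the rest Beta(5, 1);
95% outgroup-clean.  Genotypes are drawn under Hardy–Weinberg from the
per-variant frequency, and every truth label (fixation, support,
quality, size, mappability) is computed from the *realized* record, so
the expected cascade outcome is exact, not probabilistic.  Deterministic
boundary records (size 24/25, pooled support 4/5, QD 1.99/2.0,
QUAL 30.0, FS 200.0, ReadPosRankSum −20.0, one het in-group genotype,
one non-reference outgroup genotype, missing genotypes) are appended to
every simulation.

Depth is simulated directly as independent per-site Poisson draws —
the pipeline consumes depth tracks, so depth is the right simulation
boundary.  Consequences for interpretation: the simulation has no
fragment-length structure, no correlated coverage (GC, mapping bias),
no ancient-DNA damage (the intended libraries are uracil-treated), no
sequencing error and no near-identical (as opposed to exact) repeats.
Passing the synthetic validation therefore demonstrates the
correctness of the *computations* — masking, run detection, merge
rules, filter semantics, counting — under the stated coverage
arithmetic; it does not certify performance on real alignments, where
misalignment noise and coverage correlation are handled only insofar
as the bridging rules and outgroup-support checks model them.
Misalignment peaks inside deletions can be switched on
(`misalignment_prob`) and are absorbed by the low-coverage bridge; they
are off by default so breakpoint recovery is exact.

## Problem sizes and numerics

Tests and the acceptance script run at the default 3 × 1 Mb scale
(single CPU, minutes): mask oracle equivalence uses ≥ 20 random
references up to 50 kb; deletion recovery uses 20 simulation seeds plus
20 deletion-free depth replicates (and 100 smaller replicates in the
unit suite); enrichment uses 10⁵ sampled positions with tolerances
derived from the realized category counts (4 standard errors of the
log odds ratio); saturation checks are exact.  Means and fits are in
double precision; the exponential fit refuses non-positive means rather
than clamping; interval operations are integer-exact.
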