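# mtspectrum

**PCR-free mitochondrial DNA mutation-spectrum analysis on a doubled
circular reference.**

Mitochondrial DNA (mtDNA) is a small circular genome (~16.3 kb in
mouse) present in hundreds of copies per cell.  Mutations —
single-nucleotide variants (SNVs), deletions, and the very-long-range
deletions (VLRDs) that signal control-region multimers — accumulate
with age and under replication instability (e.g. proof-reading-deficient
*Polg*), and each variant is *heteroplasmic*: present in only a
fraction of the molecules.  Calling such variants from sequencing data
has two structural problems: the circle's arbitrary linearization
origin hides junctions that cross it, and low-fraction calls need
careful support/depth/quality filtering.

`mtspectrum` implements the full analysis chain for this setting:

- **Doubled reference (dMT).** Reads are interpreted against two tandem
  copies of the circle, so any junction is a contiguous alignment; all
  coordinates are normalized mod L and evidence from either copy is
  merged without double-counting fragments.
- **Variant extraction.** CIGAR walking with read-end trimming (5 bp),
  deletion evidence from `D` operations and split/supplementary pairs,
  allele-fraction floor 0.005, published post-filters (SNVs:
  support ≥ 4, depth ≥ 50, quality ≥ 20; deletions: 2/25/10), and the
  DEL/VLRD partition at 15 kb.  Discordant reads are counted with
  `samtools -F 1294` semantics.
- **Direct repeats.** All maximal same-strand repeat pairs ≥ 8 bp with
  ≤ 1 mismatch per 4 nt, guaranteed equal to exhaustive enumeration;
  the shortest average distance from a deletion's 5′/3′ breakpoint pair
  to a repeat pair,

      D(del) = min over repeat pairs r, assignments σ of
               [d(p5, r_σ(1)) + d(p3, r_σ(2))] / 2,

  compared against length-matched randomized deletion libraries with a
  Welch t test.
- **Breakpoint homology.** Needleman–Wunsch–Gotoh identity (match +5,
  mismatch −4, gap open 10, extend 0.5, free end gaps) between the
  ±10 bp windows at the two breakpoints, and its relation to deletion
  length.
- **Spectrum summaries.** 10-bp-bin SNV sharing across regions/animals,
  100-bp binned allele-fraction profiles (highest peak = 1), cumulative
  position curves, the 12-class substitution spectrum, per-gene
  length-normalized loads with their correlation, VLRD–SNV proximity.
- **Cohort statistics.** Welch t with a Shapiro–Wilk gate falling back
  to Wilcoxon, two/three-way type-II ANOVA with Tukey HSD, Bonferroni
  correction, and an exact multi-set intersection test (iterated
  hypergeometric convolution, the k-set generalization of the
  hypergeometric overlap test).
- **Synthetic data.** A first-class generator for circular genomes with
  planted repeats, reads with planted variants at specified
  heteroplasmy fractions (emitted as SAM against the doubled
  reference), and age × genotype × region cohorts with planted effects
  — every downstream stage is testable against ground truth.

## Worked example

Plant one heteroplasmic SNV, two deletions (one spanning the origin),
and a low-fraction VLRD on a random 16.3-kb circle; simulate paired
reads at depth 200; extract, filter, and classify:

```python
from mtspectrum import (SimulationConfig, SnvPlan, DeletionPlan,
                        generate_genome, simulate_alignments,
                        extract_variants, apply_post_filters,
                        classify_deletions)
from mtspectrum.extract import variants_to_frame

cfg = SimulationConfig(
    seed=1, L=16300, depth=200.0,
    snv_plan=(SnvPlan(pos=2000, alt="T", fraction=0.30),),
    deletion_plan=(DeletionPlan(start=5000, length=3500, fraction=0.15),
                   DeletionPlan(start=16200, length=250, fraction=0.40),),
    vlrd_plan=(DeletionPlan(start=900, length=15600, fraction=0.05),),
)
genome, _ = generate_genome(cfg)
records, truth = simulate_alignments(genome, cfg)
calls = classify_deletions(
    apply_post_filters(extract_variants(records, genome)),
    sample_id="demo",
)
print(variants_to_frame(calls).to_string(index=False))
```

Output:

```
sample_id class  pos5_1based pos3_1based length ref alt  support  depth  quality  allele_fraction
     demo   SNV         2001                      G   T       45    165     30.0         0.272727
     demo  VLRD          901         201  15600                7    175     30.0         0.040000
     demo   DEL         5001        8501   3500               27    186     30.0         0.145161
     demo   DEL        16200         150    250               84    201     30.0         0.417910
```

All four planted variants are recovered with the correct class and
coordinates (the last deletion wraps the origin: it starts at 16200 and
ends at position 150 on the circle), and the observed allele fractions
(0.27, 0.04, 0.15, 0.42) estimate the planted heteroplasmy levels
(0.30, 0.05, 0.15, 0.40) to within binomial sampling error at this
depth.

A command-line interface mirrors the library
(`mtspectrum simulate|extract|classify|repeats|identity|spectrum|stats|run-all`);
`run-all` drives the whole pipeline from a YAML config and writes tidy
TSV/JSON outputs plus a manifest of seeds, thresholds, and per-stage
record counts.

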