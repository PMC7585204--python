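# Methods

`mtspectrum` re-implements, as a tested library, a PCR-free analysis of
the mitochondrial DNA (mtDNA) mutation spectrum: single-nucleotide
variants (SNVs), deletions, and very-long-range deletions (VLRDs, the
signature of control-region multimers) called from read alignments
against a *doubled* circular reference, followed by the sequence-context
statistics (direct repeats, breakpoint homology) and cohort statistics
that characterize how those variants accumulate with age, genotype, and
brain region.  Because the raw sequencing data underlying such a study
is not required to exercise any of the algorithms, the package ships a
first-class synthetic-data module that generates circular genomes,
reads, and cohorts with planted ground truth; every guarantee the test
suite makes is a statement about recovery of planted structure.

## Coordinates and the doubled reference

mtDNA is circular (~16.3 kb in mouse) but aligners work on linear
references.  All internal coordinates are 0-based, half-open, on the
forward strand of the circle; tables report 1-based closed positions.
The alignment target is the genome concatenated with itself (`<name>_dMT`,
length 2L), so a junction crossing the linearization origin appears as a
contiguous alignment somewhere on the doubled sequence.  Every reported
position is normalized mod L, and evidence for the same normalized
variant arising in either tandem copy is merged, counting each sequenced
fragment once.  Origin-spanning gene features are encoded as single
records with `start > end`.

## Variant extraction

CIGAR walking produces per-site mismatch pileups (SNVs) and per-junction
deletion evidence from `D` operations and from primary/supplementary
split alignments of the same read.  Evidence within 5 bp of either read
end is ignored (`trim_border`, matching the published caller setting),
and calls with allele fraction < 0.005 are dropped at extraction.
Support and depth are counted per fragment (read-pair name), so a
deletion seen both as a `D` operation and as a split pair of one
fragment contributes a single observation, and depth at a site is the
number of fragments with an aligned base there (at the base preceding
the junction, for deletions).

Deletion breakpoints are left-aligned: the junction is shifted left
while the base entering the gap equals the base leaving it.  The
synthetic generator canonicalizes planted coordinates the same way, so
truth tables and calls agree exactly even for repeat-ambiguous
junctions.

Two published quality proxies replace the upstream caller's
undocumented internal score: an SNV's quality is the mean phred of its
supporting bases; a deletion's is, per supporting fragment, the minimum
of the two flanking aligned-segment mean phreds, averaged over
fragments.  Post-filters are inclusive at the published minimums —
SNVs: support ≥ 4, depth ≥ 50, quality ≥ 20; deletions: support ≥ 2,
depth ≥ 25, quality ≥ 10.  Deletions partition by junction span on the
doubled reference: ≤ 15 kb → DEL, > 15 kb → VLRD (on a circle a VLRD is
indistinguishable from a short duplication, hence "candidate multimer").
Discordant reads are records with none of the flag bits
{proper pair, unmapped, mate unmapped, secondary, duplicate} set — the
complement-of-mask semantics of `samtools -F 1294`.

## Direct repeats

A direct repeat is a pair of same-strand approximate sequence copies.
The search criterion is the published one: length ≥ 8 bp with at most
one mismatch per four nucleotides (Hamming distance ≤ ⌊len/4⌋),
non-overlapping copies, each unordered pair reported once.  Rather than
re-running the original fragment+BLAST heuristic, the package defines
the repeat set directly and guarantees equality with exhaustive
enumeration: on each circular diagonal (offset d between copy starts) a
valid window is reported iff it is not strictly contained in another
valid window on that diagonal.  This "containment maximality" resolves
an ambiguity in one-step-extension definitions (a window whose one-base
extensions are invalid can still sit inside a larger valid window two
steps away).  Every maximal window is either bounded by mismatch
columns on both sides — a *closure*, fully determined by its mismatch
set — or pinned at the non-overlap cap; the implementation enumerates
exactly those two candidate families per diagonal, prunes left bounds
with a sliding-maximum bound on g(t) = m_t − t/rate (m_t the t-th
mismatch position), and reduces by containment.  The test suite checks
equality with an O(L²)-style brute-force oracle on dozens of random
circular genomes and on the degenerate all-A genome.

## Breakpoint-to-repeat distance and the null library

For a deletion with breakpoints (p5, p3), the statistic is the shortest
average distance to a repeat pair: min over repeat pairs and over both
copy-to-breakpoint assignments of (d(p5, copy1) + d(p3, copy2))/2,
where d is circular distance to the nearest base of the copy (zero
inside it).  Nearest-base anchoring was chosen because the published
description does not anchor the distance; it is the only choice
symmetric under rotation and insensitive to copy length, and it is
configurable in principle by filtering the catalogue.  The null model
is a length-matched randomization: n uniform start positions, the
observed length multiset shuffled and assigned, ends computed mod L (a
null deletion may wrap the origin, consistent with the circular
treatment).  Lengths are sorted before shuffling so the library depends
only on the length multiset, not on input order.  Observed and null
distance distributions are compared with a two-sided Welch t test; one
library per observed set by default, with a replicate option for pooled
reporting.

## Breakpoint-window identity

For each deletion the 20-bp windows centred on the two junctions (10 bp
each side; the 5′ window at the last-retained/first-deleted boundary)
are extracted from the circle and aligned with Needleman–Wunsch–Gotoh:
match +5, mismatch −4, affine gaps with open 10 and extend 0.5 (a
length-k gap costs open + k·extend), terminal gap runs free — the
default global mode of the EMBOSS `needle` family, whose published
command line specifies only the gap parameters.  Identity is
100·matches/alignment-columns.  Tie-breaks are deterministic (diagonal
preferred over gaps, then gap in the second sequence).  Windows
containing N are flagged and skipped.  The identity–length relation
reports Pearson r of identity against log10(length) and a two-group
comparison of deletions ≤ 100 bp vs > 100 bp (length exactly 100 goes
to the short group), using the gated location test below.

## Spectrum summaries

SNV sharing counts 10-bp non-overlapping bins: per group (brain region
or animal) a bin is occupied or not — multiple SNVs from one group in
one bin count once — and occupied bins are histogrammed by the number
of groups sharing them (categories 1, 2–3, 4–6 for the six regions; 1,
2–3, ≥4 for animals).  Binned allele-fraction profiles sum fractions in
100-bp bins and scale the highest bin to 1 (an empty input stays an
unnormalized zero vector; a partial final bin is kept and flagged).
Cumulative position curves are step functions reaching 100%.  The
substitution spectrum counts the 12 reference-strand classes plus the
pyrimidine-collapsed 6-class view; transitions are {A>G, G>A, C>T,
T>C}.  Per-gene load divides the count of SNVs inside (deletions
overlapping) each gene by gene length, min-max scales each vector to
[0, 1], and reports the Pearson correlation between them; an
allele-fraction-weighted variant supports chord-style summaries.
VLRD–SNV proximity reports the mean and SD of the circular distance
from each VLRD 5′ breakpoint to its nearest SNV and the fraction at
distance exactly zero.  Cohort counts normalize either to the mean of
the 10-week (optionally WT) reference group or to the smallest sample.

## Statistics layer

Pairwise location tests use Welch's t unless Shapiro–Wilk (α = 0.05)
rejects normality in either group, in which case the two-sided Wilcoxon
rank-sum test is used; groups of n ≥ 30 are exempt (large-sample
normality of the mean), constant groups are treated as non-normal, and
the chosen method is recorded on the result.  Factorial ANOVA uses
type-II sums of squares on a main-effects model (type II is the
standard main-effects choice for the mildly unbalanced n = 4–6 designs
this layer targets), with Tukey HSD post-hoc comparisons and the
main-effects linear-model coefficients.  "Animal" is coded as the
within-group replicate label (a crossed fixed factor); unique animal
IDs would be nested in age and alias it.  Multiplicity correction is
Bonferroni, min(1, p·m), with the family size logged per analysis
rather than guessed.  The multi-set intersection test computes the
exact distribution of the k-way intersection size under independent
uniform draws of the observed set sizes from an N-element background,
by iterated hypergeometric convolution; p is the upper tail
P(X ≥ observed) and the expectation is N·∏(nᵢ/N).  Shapiro–Wilk,
t/F/hypergeometric distributions, and the Tukey studentized range are
delegated to scipy/statsmodels; the gating logic and the intersection
test are implemented here.

## Synthetic data: what it emulates and what it does not

The generator emulates the features the analysis depends on: a circular
genome with planted approximate repeats (exact mismatch counts by
construction); paired 150-bp reads placed uniformly on the circle and
reported against the doubled reference, with each fragment drawn from a
molecule carrying every planted variant independently with probability
equal to its allele fraction; deletions emitted as `D` CIGAR
operations; VLRD-carrying fragments whose mates straddle the junction
emitted as non-proper (discordant) pairs, pair span > 2 kb by default;
a bimodal deletion-length mixture (half uniform on [1, 99] bp, half on
[1, 15] kb) mirroring the observed short/long dichotomy; and cohorts
with expected counts baseline × age × genotype·region × animal effects,
Poisson-sampled.  Cohort defaults plant the observed study pattern as
the test condition: SNV age multiplier 10× at ≥ 50 wk, deletion
multiplier 2.75×, a 3× mutant effect restricted to {COR, NAc, PVT} at
≥ 50 wk, log-normal animal effect (SD 0.15), baselines 20 SNVs / 8
deletions per sample at 10 wk, 5 animals per cell.

Deliberately not emulated: sequencing error and quality variation
(clean Q30 reads; a uniform substitution-error option exists for filter
tests), GC/transposase bias, nuclear mtDNA-like contamination (Numts —
represented only by an upstream contract and a read-exclusion hook),
and mapper behaviour (the pipeline consumes alignments).  Passing tests
therefore demonstrate correctness of the analysis chain on its stated
input contract, not robustness to upstream artefacts.

## Numerical and design choices

- Seeds: every stochastic component takes an explicit seed; outputs are
  pure functions of (configuration, seed).  Sub-seeds are derived with
  `numpy.random.SeedSequence`.
- Problem sizes in the tests are desk-scale by design: recovery runs on
  one 16.3-kb genome at depth 200 (~22k reads); repeat-search oracle
  equivalence on fifty 2-kb circles; the null-library comparison on a
  4-kb circle with 100 planted deletions and 100 replicate libraries;
  ANOVA calibration on 1000 cohort draws.
- Degenerate inputs: empty variant sets return empty/flagged outputs
  rather than NaNs; constant vectors make correlations and normality
  tests report "undefined" instead of raising; single-member sets in
  the null comparison return means with p = None.
- Boundary conventions are inclusive at published thresholds ("minimum"
  is read literally), deletion length 15 000 is DEL, 15 001 is VLRD,
  and identity-group length 100 is "short".

## Known limitations

- The repeat catalogue under the ≥8 bp / ≤1-per-4 criterion is large on
  random sequence (~25k pairs on 4 kb); the distance statistic is
  correspondingly dominated by chance repeats, exactly as it would be on
  real mtDNA, which is why the null library — not the raw distance — is
  the inferential object.
- VLRD "length" is the junction's span on the doubled reference;
  whether it is a deletion or a duplication is deliberately left
  ambiguous.
- The read model gives every fragment the same insert size and places
  read 2 on the reverse strand flag-wise while storing the
  reference-orientation sequence; strand-specific artefacts are out of
  scope.
- `simulate_cohort` returns counts by default; per-sample SAM emission
  (`emit_reads=True`) is available but slow, and the statistics layer
  operates on counts either way.
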