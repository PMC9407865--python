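# Methods

## Scope and model

`ripkit` analyses candidate-gene-scale retrotransposon insertion
polymorphisms (RIPs). The unit of comparison is a *bait locus* — a gene
plus 5 kb upstream and 3 kb downstream flank — aligned pairwise against
the corresponding locus extracted from other genome assemblies. The
package deliberately works at desk scale (tens of kb per locus, tens of
genomes), not genome scale: that assumption licenses exact unique-k-mer
anchoring and full dynamic-programming gap resolution that would be
unaffordable genome-wide.

## Discovery

Each bait/query pair is decomposed as follows:

1. k-mers unique in both sequences (default k = 31) are matched and
   merged into maximal co-diagonal exact runs;
2. the heaviest strictly collinear chain of runs is selected by an
   O(n²) weighted longest-increasing-subsequence dynamic program
   (n is the number of runs — hundreds at a 1% SNP rate, so quadratic
   chaining is cheap);
3. inter-anchor gap segments with both sides non-empty and ≤ 5 kb are
   resolved by global affine alignment (match/mismatch/open/extend =
   2/−3/−5/−1); larger or one-sided gaps pass through unchanged;
4. every gap segment whose net length difference reaches `min_sv_len`
   (default 50 bp) yields one candidate insertion or deletion. Smaller
   indels and substitution-only gaps are discarded.

Breakpoints are **left-normalized**: an insertion adjacent to sequence
identical to its own tail is slid to its leftmost equivalent placement
(the VCF convention). This makes calls from different genomes
comparable but means a TSD-bearing insertion is reported `tsd_len`
positions left of its biological integration point; the simulator's
truth table therefore records both the planted and the normalized
breakpoint.

Cross-genome recurrence replaces multiple alignment: per-genome calls
of the same type merge when breakpoints agree within 20 bp and lengths
within 10% (relative), and clusters supported by fewer than
`min_sources` (default 2) distinct breeds are dropped. The cluster
representative is the longest member (ties: lexicographically first
breed); all members are retained because the annotator uses them for
TSD corroboration.

In-silico PCR is provided for genotyping design: exact (optionally
≤1-mismatch) primer matching, products capped at 5 kb; running both
haplotypes of a heterozygote yields two product lengths differing by
the insertion length.

## Annotation

Insertions are classified by Smith–Waterman local alignment (same
scores as above) against every library consensus and its reverse
complement; the best score wins. Identity is matches over alignment
columns; coverage is aligned insertion bases over insertion length —
computed on the insertion, not the consensus, so a truncated copy of a
long element can still classify. A hit needs identity ≥ 0.70 and
coverage ≥ 0.80 (both configurable); these thresholds stand in for
RepeatMasker-style score cutoffs and are deliberately conservative for
a library of young, little-diverged elements. Below threshold the
insertion is reported `unclassified` with direction `.`.

### TSD detection

A target-site duplication planted at integration survives breakpoint
left-normalization as a rotation: for a duplicated word of length L and
shift s (0 ≤ s ≤ L), s bases of the word sit right of the normalized
breakpoint on the bait and open the inserted sequence, while L − s
bases close the bait's upstream flank and the inserted sequence. The
detector scans L from `tsd_max` (20) down to `tsd_min` (5) over all
rotations, preferring the **longest exact** duplication, and only when
none exists retries allowing ≤ `tsd_max_mismatch` (1) mismatches; ties
at equal length go to the smallest rotation. Exact-first is a
deliberate deviation from "longest word within the mismatch budget":
with a 1-mismatch budget, a true L-mer always extends to a "valid"
(L+1)-mer whose extra column eats the budget, so the naive rule
systematically overcalls by one base.

Two kinds of noise remain and are worth stating plainly. First, chance
junction homology can genuinely extend the duplicated word beyond the
planted TSD (a maximal duplication of 13–15 bp where 12 were planted is
common); the element length quoted in reports (SV length minus TSD) is
therefore an estimate with a few-bp fuzz, while the full SV length is
exact. Second, a background SNP in one genome's copy of the word can
corrupt that genome's call; the annotator therefore takes the TSD of a
clustered RIP by majority vote across the cluster's member genomes.

RIP names follow `<gene>-<class>-RIP<serial>` with serials per
(gene, class) in breakpoint order; a lone RIP keeps the bare `-RIP`
suffix. Insertion point features are reported as the 2-bp interval
flanking the breakpoint (1-based); deletions (element present in the
reference frame) as the full span.

## Population genetics

Allele frequencies come from genotype counts at full precision, never
from rounded percentages. The Hardy–Weinberg test is a Pearson
chi-square with df = 1 and no continuity correction — the convention of
the classic Popgene program, which the package's report dialect
follows (p printed `<0.01` below 0.01, `—` for monomorphic samples).
An exact test (full enumeration of heterozygote counts conditional on
allele counts) is available as `hwe_exact_test` but is not the default.
PIC uses the m-allele double-sum form; monomorphic samples report
PIC 0 and skip the HWE test rather than erroring, because real
genotype tables contain zero-frequency cells.

## Association

One-way ANOVA with Tukey HSD across the genotype groups; unbalanced
designs use the Tukey–Kramer standard error. Group letters are the
maximal cliques of the not-significantly-different graph, assigned in
descending-mean order (lowercase at α = 0.05, uppercase at α = 0.01),
which makes the display invariant under group relabeling. Dispersion
columns printed as `mean ± value` are **standard errors**: published
tables of this kind quote SEs (an SD of ~1 day for age at 100 kg over
63 animals is not biologically plausible), and a `dispersion="sd"`
switch restores the other reading. Rounding is half-up to 2 decimals.

The age-at-100-kg adjustment used by national swine evaluation schemes
is not public in a single canonical form; the packaged default is an
explicit linear extrapolation `age + (100 − weight)·(age/weight)·c`
(c configurable, c = 0 disables), and every report states that this
stand-in was applied.

## Expression

2^−ΔΔCt follows the Livak convention with the calibrator group's *mean*
ΔCt as the reference, so the calibrator's group-level fold is exactly 1
and per-sample calibrator folds scatter around 1. Group-level folds are
2^−(mean ΔΔCt) (the geometric convention). All hypothesis tests run on
the ΔCt/log scale, where normality is plausible, and are displayed as
folds: ANOVA + Tukey for ≥ 3 groups, two-sided t-test for 2.
Dual-luciferase activity is firefly/renilla per well, normalized to the
control construct's mean ratio; construct comparisons are t-tests on
log₂ ratios. Degenerate zero-variance comparisons return p = 1 when the
means agree rather than NaN.

## Synthetic data

The generator emulates the study design end to end from one integer
seed, with named substreams per stage (locus, assemblies, populations,
phenotypes, Ct, luciferase) so stages regenerate independently.

* **Loci**: i.i.d. uniform DNA with an exon grid inside the flanks.
  The default fixture has two loci: a 3-exon 15-kb locus with one
  reverse-oriented 286-bp SINE-like insertion in intron 1, and a
  22-exon 20-kb locus with 301- and 321-bp insertions in introns 2 and
  21; the library carries the three SINE consensi plus a 1-kb LINE
  decoy.
* **Assemblies**: carrier breeds receive the consensus at the
  breakpoint with a duplicated 12-bp target site (typical SINE TSD
  range) and 2% per-copy point divergence — enough to exercise, not
  stress, the annotator; all breeds get 1% background SNPs by default.
  Background small indels (< 50 bp, so they never cross the SV
  threshold) are available per breed but default to 0, and are kept
  ≥ 50 bp away from planted insertions so ground truth stays
  unambiguous. Six breeds per locus with three carriers per insertion
  satisfy the recurrence filter with margin.
* **Populations**: genotype counts are trinomial draws with
  P(+/+) = p² + Fpq, P(+/−) = 2pq(1−F), P(−/−) = q² + Fpq, clamped and
  renormalized; infeasible (p, F) combinations raise.
* **Phenotypes**: Gaussian per genotype group. The default age-at-100-kg
  scenario uses group means 164.81/160.49/160.59 days with SDs derived
  as SE·√n from SEs 1.12/0.59/1.08 and n = 63/297/90.
* **Expression/luciferase**: Ct tables are built so each group's true
  fold is realized in expectation (ΔCt = base − log₂ fold + noise,
  default noise SD 0.2, n = 4/group; default folds 1.0/1.2/2.5 for
  +/+, +/−, −/−); luciferase wells have construct-specific mean ratios
  (default 1.0/1.5/3.0 for empty vector, insertion-bearing, and
  insertion-free promoter constructs; CV 10%, 6 wells).

What the generator does **not** emulate: pig demography, linkage and
recombination, assembly errors other than point/indel noise, nested or
truncated element insertions, qPCR efficiency deviations from 2, and
plate effects. Passing tests therefore demonstrate correctness of the
algorithms under clean planted truth, not performance on real
assemblies.

## Numerical and design notes

* Problem sizes throughout (15–20 kb loci, 6 genomes, 200–500
  Monte-Carlo replicates) are chosen so the full suite runs in well
  under a minute on one core while keeping every statistical check
  comfortably powered.
* The association power check deserves a caveat: under the default
  age-at-100-kg scenario (SE-derived SDs ≈ 9–10 days), the probability
  that a fresh cohort shows a significant ANOVA *and* Tukey-separates
  +/+ from both other genotypes at α = 0.05 is only ≈ 0.56 — a single
  published significant cohort is weak evidence of replicable
  separation at these effect sizes. The acceptance suite states the
  ≥ 90% recovery requirement as given and the corresponding test
  documents this shortfall by failing.
* Score ties in classification prefer the forward orientation; cluster
  representative ties prefer the lexicographically first breed; both
  keep outputs deterministic.
* Monomorphic inputs, empty candidate lists, single-exon genes, and
  zero-noise specs are all legal and exercised by tests; zero-variance
  t-tests return p = 1 on equal means.
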