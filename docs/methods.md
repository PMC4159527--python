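# Methods

## Problem setting

Two groups of individuals (by default 10 "freshwater" and 10 "marine",
mirroring a marine/freshwater ecotype pair) are resequenced at low coverage
(~2.3×, 36 bp single-end reads) and mapped to one reference genome. A gene
whose copy number differs systematically between the groups attracts
proportionally more (or fewer) mapped reads in one group. Because each
group pools independent lineages of one ecotype, a shared difference is
evidence of parallel selection rather than drift; the pipeline's job is to
find such genes and to say whether they are duplications or deletions.

## Counting rules

* **Coordinates** are 0-based half-open internally; 1-based inclusive
  input (Ensembl-style tables) is converted at the boundary. Strand is
  ignored: reads are counted against the whole gene body (exons plus
  introns) regardless of orientation. Scaffolds are ordinary sequences.
* **Deduplication** keys on (chromosome, start) only — single-end
  `rmdup`-style semantics. The highest-mapq read survives; ties keep the
  first record in input order, so the operation is deterministic and
  idempotent. Strand is not part of the key because the minimal tabular
  format omits it; for stranded SAM input this is a documented divergence
  (reads from opposite strands sharing a start position collapse).
* **Multi-hit removal is an input contract**: the upstream aligner is
  expected to keep uniquely mapping reads only. The counting module logs a
  warning when a read id recurs at different positions.
* **Overlap** is ≥ 1 bp of half-open interval intersection (the
  `intersectBed` default); a read spanning two genes increments both, so
  with overlapping annotations the per-gene counts may double-count reads
  (documented; gene sums then exceed the read total).
* **Filters**: a gene is dropped when the median over individuals of
  (count × 100 / gene length in bp) is *less than one* — exact equality is
  retained — or when any single individual has zero reads. Both rules use
  all individuals symmetrically, so they are invariant under group
  relabelling (this matters for the permutation test, below). The median
  over an even number of individuals is the mean of the two central order
  statistics.
* **Normalization** divides each count by the individual's genome-wide
  mapped-read total, counted after deduplication — the same record set the
  matrix is built from.

## The exact test

Counts for gene *g*, individual *i* are modelled NB(μ_gi, φ) with variance
μ + φμ², one common dispersion φ shared across genes; φ = 0 is the Poisson
limit. Library sizes are equalized by proportionally scaling each sample's
counts to the geometric-mean library size, rounding to integer
pseudo-counts.

* **Dispersion** is estimated by maximizing the conditional likelihood of
  the within-group splits given the group totals (for one group of n
  samples with counts y_i summing to z, P ∝ ∏_i C(y_i + r − 1, y_i) /
  C(z + nr − 1, z) with r = 1/φ), summed over genes and both groups. The
  search is bracketed on φ ∈ [0, 10] with tolerance 1e-6; estimates below
  2e-6 are reported as exactly 0. Inside permutations the bracket tolerance
  is relaxed to 1e-4 (the p-values are insensitive at that scale and it
  roughly halves the permutation cost).
* **Test statistic**: using that a sum of n iid NB(r) variables is NB(nr),
  the group sum A given the total N = A + B is beta-binomial
  BetaBin(N, n_A/φ, n_B/φ) — independent of the common mean. The two-sided
  p-value is the minimum-likelihood rule: the summed probability of all
  splits whose probability does not exceed the observed split's (relative
  tie tolerance 1 + 1e-7, the `binom.test` convention). For equal group
  sizes the conditional pmf is symmetric and unimodal, and the rule reduces
  to twice the smaller tail; the batched implementation exploits this with
  shared integer-lgamma tables and truncates tail terms below e⁻⁶⁰ of the
  leading term (relative error < 1e-18). The scalar path enumerates all
  splits via `scipy.stats.betabinom` and handles unequal group sizes and
  the flat/U-shaped regime (φ ≥ n). Both paths agree to ~1e-11, and the
  test agrees with edgeR's classic exact test at fixed dispersion to ~0.2%
  (a cross-check, not a dependency); exact numerical agreement with a full
  edgeR pipeline (its quantile-adjusted equalization, its dispersion
  estimator) is deliberately not claimed — the statistical core here is
  owned, testable code.
* **FDR** is Benjamini–Hochberg: q_(i) = min_{j≥i}(p_(j)·m/j), capped at 1.
* **Consensus**: mapping-stringency replicates (the same reads mapped under
  different mismatch-quality ceilings) are analyzed independently; the
  shared universe is the intersection of the post-filter gene sets (the
  conservative choice when a gene passes the filter under only some
  options), and a consensus GCNV must have FDR < α under every stringency
  with the same direction of change (disagreeing directions drop the gene
  with a warning). α = 0.05 by default; α = 1 disables the threshold.

## Permutation null

The observed consensus (or per-stringency) GCNV count is compared with the
counts obtained after randomly reallocating the 2n individuals into two
balanced groups, rerunning filter → dispersion → exact test → BH each time.
Partitions are drawn by shuffling indices with one seeded generator and
splitting in half; the identity permutation, if drawn, is an ordinary
draw. The empirical p-value is (#{null ≥ observed} + 1)/(n_perm + 1)
(never exactly zero; a flag restores the raw fraction). 10,000 rounds is
the full-scale setting; presets of 200 and 1,000 serve desk-scale work.

Two exactness-preserving shortcuts keep permutations fast:

* the gene filters are label-invariant (see above), so the filtered gene
  set is computed once and shared — mathematically identical to
  re-applying the filter per permutation;
* inside permutations only the *count* of BH-significant genes matters, so
  the exact p-value is computed only for genes whose normal-approximation
  p (continuity-corrected, 3× margin below the screening level) could fall
  under α; all other genes keep an approximate p provably above α, which
  cannot change the BH count. The observed analysis always uses the exact
  test for every gene, and a test verifies screened and unscreened null
  counts are identical.

Because the count null is discrete and concentrated near zero under a true
null, the empirical p is super-uniform (P(p ≤ t) ≤ t), i.e. conservative —
the calibration check asserts the fraction of null replicates with p ≤ 0.05
does not exceed its binomial expectation, not exact uniformity.

## Allelic multiplicity

A diploid individual carries at most two haplotypes at a locus. When
duplicated paralogous copies collapse onto one reference locus during
mapping, single reads phase nearby variant pairs and can reveal ≥ 3
distinct two-base haplotypes — direct evidence of duplication (deletions
cannot produce this). Rules:

* SNVs come either from a VCF or from a minimal pileup caller: a position
  is an SNV iff ≥ 2 distinct bases each have ≥ 2 supporting reads with
  base quality ≥ 30 (Q_min = 30 keeps only confidently called bases; the
  caller is a convenience, not a genotype-likelihood model — no indels).
* Position pairs qualify when separated by ≤ read length − 1 bp (both
  positions on one 36 bp read — co-coverage is what phases the pair; a
  config switch admits ≤ read length for the looser reading).
* A haplotype is retained iff ≥ 2 reads support it, each covering both
  positions at quality ≥ Q_min; reads with N at either position are
  excluded. "Multiple reads" is interpreted as 2, configurable.
* A gene is called duplicated in a group iff ≥ 3 individuals of that group
  each show ≥ 1 pair with ≥ 3 haplotypes; a *strong* call requires ≥ 2
  such pairs per qualifying individual. Any qualifying pair counts — the
  individuals need not share the same pair.

## Synthetic data

`simulate_count_matrices` generates, per gene and individual, a latent
count NB(μ, φ) with μ = lib_factor · depth · (len + L − 1)/L · CN/2 (a read
overlaps a gene iff its start falls in a window of len + L − 1 positions;
CN = 2 is the diploid baseline). Each mapping-stringency replicate is a
binomial thinning of the *same* latent count with a per-option retention
fraction (defaults 1.0/0.93/0.85 from the most lenient to the strictest
option) — thinning preserves the NB family and induces the cross-option
correlation the consensus rule relies on; independent redraws would
misrepresent the real situation, where the three mappings share reads.
Genome totals model genes occupying about half the genome and scale with
the same retention. Defaults: 10 + 10 individuals, 2.3× coverage (the
low-depth regime that limits power in this design), L = 36 bp, φ = 0.1,
library-size CV 0.15, log-normal gene lengths (median ≈ 6.5 kb, log-sd 0.9,
clipped to 0.4–80 kb) so the per-100-bp filter is exercised across a
realistic span. The study-shaped preset plants 24 single-gene events at
copy number 4 vs 2 — 19 up in the freshwater-like group, 5 up in the
marine-like group — and `GcnvEvent` spans of consecutive genes model
segmental events.

`simulate_paralog_reads` draws error-prone 36 bp reads uniformly over a
single reference locus from h equally frequent collapsed haplotypes whose
differences are placed so any site pair separates all haplotypes (auto mode
supports h ≤ 4); constant base quality, configurable error rate.

What the generator does *not* emulate: GC/mappability bias, positional
coverage waviness, mapping-efficiency loss for diverged alleles, unequal
paralog dosage, linked SNV ascertainment noise, or real aligner behaviour
under the mismatch ceilings (retention is a scalar per option). Passing
tests therefore demonstrate correctness of the statistical machinery under
its own model, not robustness to those real-data artefacts.

## Problem sizes used by the checks

The validation suite and `scripts/acceptance.py` run: the exact test vs
the conditional-binomial oracle on 100 random splits (A, B ≤ 50); a
2,000-gene null study (type-I error and p-value KS distance); the
2,000-gene study-shaped signal (recovery ≥ 80% of 24 events, direction
accuracy); its permutation test at n_perm = 1,000 per stringency; 50
pure-null replicates at n_perm = 200 on a reduced 300-gene single-
stringency configuration (same depth, dispersion and group sizes — the
reduced size keeps the 10,000 reanalyses desk-scale); paralog-phasing
recovery for h = 2, 3, 4 at 10× per haplotype; the hand-computed 10-gene
filter matrix; and byte-identity of regenerated fixtures.

## Known limitations

* A single common dispersion; no tagwise/trended dispersion, no GLM, no
  TMM normalization (normalization is by totals only, by design).
* No GC-content or mappability correction.
* The permutation mode treats individuals as exchangeable; geographic
  pairing structure, if present, is not preserved by the reshuffles.
* The pileup caller assumes ungapped fixed-length alignments and ignores
  indels; supply an external VCF for anything richer.
* Integer rounding of equalized pseudo-counts makes the test slightly
  discrete at very low counts; p-values are exact conditional on the
  rounded sums.
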