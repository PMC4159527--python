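# paracnv

Read-depth detection of **gene copy number variants (GCNVs) under parallel
selection** between two groups of low-coverage resequenced genomes — e.g.
marine vs freshwater population pairs, where a variant shared by independent
lineages of one ecotype is evidence of positive selection rather than drift.

## What it does

Given per-individual single-end alignments (or per-gene count matrices) for
two groups of individuals, `paracnv`:

1. **Counts** deduplicated mapped reads overlapping each gene body (exons +
   introns, ≥ 1 bp overlap), removes genes whose median mapped-read count
   per 100 bp of gene length is below one or that have a zero-count
   individual, and normalizes by each individual's genome-wide mapped-read
   total.
2. **Tests** each gene for a two-group difference with a negative-binomial
   exact test. Counts are modelled as NB with a single common dispersion φ
   (variance μ + φμ²) estimated by conditional maximum likelihood on
   library-size-equalized pseudo-counts. Because a sum of n iid NB(1/φ)
   variables is NB(n/φ), the group sum *A* conditional on the total
   *N = A + B* is beta-binomial BetaBin(N, n_A/φ, n_B/φ); the two-sided
   p-value sums the probabilities of all splits no more probable than the
   observed one. The Benjamini–Hochberg step-up procedure controls the FDR at α = 0.05.
3. **Intersects** significant calls across mapping-stringency replicates
   (the same reads mapped under several aligner mismatch ceilings): only
   genes significant under *every* stringency, with a consistent direction,
   are consensus GCNV calls.
4. **Permutes**: reshuffles the individuals into balanced pseudo-groups
   (10,000× at full scale), reruns the whole analysis each time, and
   reports the empirical p-value of the observed GCNV count,
   (#{null ≥ observed} + 1)/(n_perm + 1).
5. **Phases**: for candidate genes, counts distinct read-supported two-base
   haplotypes at SNV position pairs close enough (≤ read length − 1 bp) to
   be covered by one read. Three or more haplotypes cannot come from a
   diploid locus, so a gene showing ≥ 3 haplotypes in ≥ 3 individuals of a
   group is called duplicated/multiplied (not deleted) in that group.

A first-class synthetic-data module generates count matrices and collapsed-
paralog reads with known truth for every stage, emulating a 10 + 10
individual study at ~2.3× coverage with 36 bp reads.

## Worked example

```python
import paracnv as pc

config = pc.parallel_selection_scenario(n_genes=2000, seed=3)
matrices, truth = pc.simulate_count_matrices(config)   # 3 stringencies
result = pc.run_detection(matrices, "freshwater", "marine", alpha=0.05)
print(len(result.consensus_gene_ids), result.dispersions)
```

Running `python examples/01_detect_parallel_gcnvs.py` prints:

```
genes simulated:        2000
genes tested (shared):  2000
estimated dispersions:  e130=0.0995, e100=0.0995, e70=0.0996
consensus GCNV calls:   23
true GCNVs recovered:   23/24
false positives:        0
```

The generator planted 24 genes at copy number 4 vs 2 (ratio 2) among 2,000
genes with dispersion φ = 0.1; the detector recovers 23 of them with the
correct direction and no false calls, and the φ estimates sit on the
generating value. `examples/02_permutation_null.py` then shows the observed
count (23–24) against a permutation null whose maximum is ~7, i.e. an
empirical p at the resolution floor — the group structure, not chance,
drives the detections. The other examples cover allelic multiplicity
(duplication vs deletion), the segmental-duplication ratio report, and
counting from raw alignments.

A thin CLI wraps the same functions:

```bash
paracnv simulate --preset signal --out fixtures/
paracnv run --fixtures fixtures/ --out results/ --n-perm 1000 --seed 1
```

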