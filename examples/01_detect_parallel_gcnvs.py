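"""Detect gene copy number variants shared by two groups of individuals.

Simulates a two-group resequencing study (10 freshwater-like + 10
marine-like individuals, ~2.3x coverage, three correlated mapping-stringency
count matrices, 24 genes truly duplicated in one group), then runs the
filter -> NB exact test -> BH FDR -> stringency-consensus detection and
compares the calls against the planted truth.
"""

import paracnv as pc

config = pc.parallel_selection_scenario(n_genes=2000, seed=3)
matrices, truth = pc.simulate_count_matrices(config)
result = pc.run_detection(matrices, "freshwater", "marine", alpha=0.05)

true_ids = set(truth.loc[truth.is_true_gcnv, "gene_id"])
found = set(result.consensus_gene_ids)

print(f"genes simulated:        {config.n_genes}")
print(f"genes tested (shared):  {len(result.table)}")
print("estimated dispersions:  "
      + ", ".join(f"{k}={v:.4f}" for k, v in result.dispersions.items()))
print(f"consensus GCNV calls:   {len(found)}")
print(f"true GCNVs recovered:   {len(found & true_ids)}/{len(true_ids)}")
print(f"false positives:        {len(found - true_ids)}")

# The dispersion estimates should sit near the generating value (0.1); a
# recovered fraction near 24/24 with no false calls shows that intersecting
# FDR<0.05 calls across the three stringencies keeps the detector both
# sensitive and specific at this coverage.
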