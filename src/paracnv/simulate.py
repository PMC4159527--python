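"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators are provided, with ground truth for every downstream stage:

* :func:`simulate_count_matrices` — per-gene read-count matrices for two
  groups of individuals across several correlated mapping-stringency
  replicates.  Counts are negative binomial with means proportional to
  library size, gene length and copy number; the stringency replicates are
  binomial thinnings of one shared latent count, which induces the
  cross-option correlation that the consensus rule exploits (the real
  mappings share reads, so independent redraws would be wrong).
* :func:`simulate_paralog_reads` — short error-prone reads drawn from
  several divergent paralogous haplotypes that all map onto a single
  reference locus, the situation that produces >= 3 allelic sequences at an
  SNV pair in a duplicated gene.

Defaults emulate a low-coverage two-group resequencing study: 10 + 10
individuals, ~2.3x coverage of 36 bp single-end reads, three mapping
stringencies, diploid baseline copy number 2, and log-normal gene lengths
spanning roughly 0.5-60 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountMatrix
from .io import (
    AlignmentRecord,
    GeneInterval,
    SampleMeta,
    write_gene_models,
    write_group_labels,
)

__all__ = [
    "GcnvEvent",
    "ScenarioConfig",
    "TruthTable",
    "simulate_count_matrices",
    "simulate_paralog_reads",
    "make_fixture_bundle",
    "null_scenario",
    "parallel_selection_scenario",
]

GROUP_A = "freshwater"
GROUP_B = "marine"


@dataclass(frozen=True)
class GcnvEvent:
    """A copy-number event: these gene indices have ``copy_number`` copies
    (instead of the diploid 2) in every individual of ``group``.  A span of
    consecutive indices models a segmental duplication/deletion covering a
    gene cluster."""

    gene_indices: tuple[int, ...]
    group: str
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0 or int(self.copy_number) != self.copy_number:
            raise ValueError("copy_number must be a non-negative integer")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one synthetic study, reproducibly.

    ``stringency_retention`` is ordered from the most lenient to the
    strictest mapping option and must be non-increasing: stricter mapping
    keeps fewer reads.
    """

    n_genes: int = 2000
    n_per_group: int = 10
    mean_depth: float = 2.3  # genome coverage per individual
    read_length: int = 36
    gene_length_log_mean: float = math.log(6500.0)
    gene_length_log_sd: float = 0.9
    gene_length_range: tuple[int, int] = (400, 80_000)
    gcnv_spec: tuple[GcnvEvent, ...] = ()
    phi: float = 0.1  # NB dispersion across individuals
    lib_size_cv: float = 0.15
    stringency_labels: tuple[str, ...] = ("e130", "e100", "e70")
    stringency_retention: tuple[float, ...] = (1.0, 0.93, 0.85)
    group_a: str = GROUP_A
    group_b: str = GROUP_B
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stringency_labels) != len(self.stringency_retention):
            raise ValueError("one retention fraction per stringency label")
        ret = self.stringency_retention
        if any(not (0 < r <= 1) for r in ret):
            raise ValueError("retention fractions must lie in (0, 1]")
        if any(ret[i] < ret[i + 1] for i in range(len(ret) - 1)):
            raise ValueError(
                "retention must be non-increasing from lenient to strict"
            )
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        for ev in self.gcnv_spec:
            if any(not (0 <= i < self.n_genes) for i in ev.gene_indices):
                raise ValueError(f"gene index out of range in {ev}")
            if ev.group not in (self.group_a, self.group_b):
                raise ValueError(f"unknown group {ev.group!r}")


TruthTable = pd.DataFrame  # gene_id, cn_A, cn_B, is_true_gcnv, direction


def _copy_numbers(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    cn_a = np.full(config.n_genes, 2, dtype=int)
    cn_b = np.full(config.n_genes, 2, dtype=int)
    for ev in config.gcnv_spec:
        target = cn_a if ev.group == config.group_a else cn_b
        for i in ev.gene_indices:
            target[i] = ev.copy_number
    return cn_a, cn_b


def _truth_table(config: ScenarioConfig, gene_ids: Sequence[str]) -> TruthTable:
    cn_a, cn_b = _copy_numbers(config)
    direction = np.where(
        cn_a > cn_b, "increased_in_A", np.where(cn_b > cn_a, "increased_in_B", "none")
    )
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "cn_A": cn_a,
            "cn_B": cn_b,
            "is_true_gcnv": cn_a != cn_b,
            "direction": direction,
        }
    )


def simulate_count_matrices(
    config: ScenarioConfig,
) -> tuple[dict[str, CountMatrix], TruthTable]:
    """Generate one count matrix per mapping stringency plus the truth table.

    Per gene g and individual s the latent expected count is
    ``mu = lib_factor_s * depth * (len_g + L - 1) / L * CN(g, group(s)) / 2``
    (a read overlaps the gene body iff its start falls in a window of
    ``len + L - 1`` positions); the latent count is NB(mu, phi) and each
    stringency observes a binomial thinning of it.  Genome-wide totals model
    genes occupying about half the genome and scale with the same retention.
    Fixed seed => bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    lengths = np.exp(
        rng.normal(config.gene_length_log_mean, config.gene_length_log_sd,
                   config.n_genes)
    )
    lengths = np.clip(np.rint(lengths), *config.gene_length_range).astype(int)

    # disjoint genes laid head-to-tail with gene-sized gaps
    gaps = lengths  # intergenic spacer of one gene length each
    starts = np.concatenate([[1000], 1000 + np.cumsum(lengths + gaps)[:-1]])
    genes = [
        GeneInterval(f"gene{i:04d}", "chr_sim", int(s), int(s + l))
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]

    n = config.n_per_group
    sample_ids = [f"fw{i:02d}" for i in range(n)] + [f"mar{i:02d}" for i in range(n)]
    groups = [config.group_a] * n + [config.group_b] * n
    lib_sd = math.sqrt(math.log(1.0 + config.lib_size_cv**2))
    lib_factor = np.exp(rng.normal(-0.5 * lib_sd**2, lib_sd, 2 * n))

    genome_size = 2.0 * lengths.sum()  # genes cover ~half of the genome
    base_totals = np.rint(
        lib_factor * config.mean_depth * genome_size / L
    ).astype(np.int64)

    cn_a, cn_b = _copy_numbers(config)
    cn = np.where(
        np.array(groups)[None, :] == config.group_a,
        cn_a[:, None], cn_b[:, None],
    )
    mu = (
        lib_factor[None, :]
        * config.mean_depth
        * ((lengths + L - 1) / L)[:, None]
        * cn / 2.0
    )
    if config.phi > 0:
        r = 1.0 / config.phi
        latent = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
        latent[mu == 0] = 0
    else:
        latent = rng.poisson(mu)

    matrices: dict[str, CountMatrix] = {}
    for label, retention in zip(config.stringency_labels,
                                config.stringency_retention):
        counts = (
            latent if retention == 1.0 else rng.binomial(latent, retention)
        )
        totals = np.maximum(np.rint(base_totals * retention).astype(np.int64), 1)
        samples = [
            SampleMeta(sid, grp, int(t))
            for sid, grp, t in zip(sample_ids, groups, totals)
        ]
        matrices[label] = CountMatrix(
            genes=genes, samples=samples, counts=counts.copy()
        )
    return matrices, _truth_table(config, [g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def null_scenario(n_genes: int = 2000, seed: int = 0, **overrides) -> ScenarioConfig:
    """No copy-number differences between the groups."""
    return ScenarioConfig(n_genes=n_genes, seed=seed, **overrides)


def parallel_selection_scenario(
    n_genes: int = 2000,
    n_increased_a: int = 19,
    n_increased_b: int = 5,
    copy_number: int = 4,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """A study-shaped scenario: a handful of true GCNVs at copy ratio 2.

    Defaults plant 19 genes duplicated in the freshwater-like group A and 5
    in the marine-like group B (copy number 4 vs the diploid 2), spread
    evenly across the gene list.
    """
    total = n_increased_a + n_increased_b
    if total > n_genes:
        raise ValueError("more GCNVs than genes")
    idx = np.linspace(0, n_genes - 1, total).astype(int)
    events = tuple(
        GcnvEvent((int(i),), GROUP_A if k < n_increased_a else GROUP_B,
                  copy_number)
        for k, i in enumerate(idx)
    )
    return ScenarioConfig(n_genes=n_genes, gcnv_spec=events, seed=seed,
                          **overrides)


# ---------------------------------------------------------------------------
# paralog reads
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _default_divergence_sites(
    n_haplotypes: int, region_length: int, read_length: int
) -> dict[int, tuple[str, ...]]:
    """Three sites spaced to give >= 2 differing positions per read span;
    haplotype j carries base ``"ACGT"[j]`` at every site, so any site pair
    separates all haplotypes (h <= 4)."""
    if n_haplotypes > 4:
        raise ValueError("auto-generated divergence supports at most 4 haplotypes")
    mid = region_length // 2
    step = max(4, (read_length - 1) // 3)
    positions = [mid - step, mid, mid + step]
    return {p: tuple(_BASES[j] for j in range(n_haplotypes)) for p in positions}


def simulate_paralog_reads(
    n_haplotypes: int,
    divergence_sites: Mapping[int, Sequence[str]] | None = None,
    depth_per_haplotype: float = 10.0,
    region_length: int = 300,
    read_length: int = 36,
    error_rate: float = 0.0,
    base_quality: int = 40,
    seed: int = 0,
    chrom: str = "locus",
) -> list[AlignmentRecord]:
    """Reads from h collapsed paralogous haplotypes over one reference locus.

    Each read starts uniformly along the region, comes from a uniformly
    chosen haplotype, and suffers independent per-base substitution errors
    at ``error_rate``; qualities are constant.  All reads carry the single
    reference coordinate system, as after mapping collapsed paralogs.
    """
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    rng = np.random.default_rng(seed)
    ref = rng.integers(0, 4, region_length)
    haplotypes = np.tile(ref, (n_haplotypes, 1))
    sites = divergence_sites or _default_divergence_sites(
        n_haplotypes, region_length, read_length
    )
    for pos, bases in sites.items():
        if len(bases) != n_haplotypes:
            raise ValueError(f"site {pos}: need one base per haplotype")
        for j, b in enumerate(bases):
            haplotypes[j, pos] = _BASES.index(b)

    n_reads = int(round(depth_per_haplotype * n_haplotypes * region_length
                        / read_length))
    reads: list[AlignmentRecord] = []
    quals = (base_quality,) * read_length
    for i in range(n_reads):
        hap = int(rng.integers(n_haplotypes))
        start = int(rng.integers(0, region_length - read_length + 1))
        bases = haplotypes[hap, start:start + read_length].copy()
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            if err.any():
                bases[err] = (bases[err] + rng.integers(1, 4, err.sum())) % 4
        reads.append(
            AlignmentRecord(
                read_id=f"r{i:06d}_h{hap}",
                chrom=chrom,
                start=start,
                read_length=read_length,
                mapq=42,
                sequence="".join(_BASES[b] for b in bases),
                base_qualities=quals,
            )
        )
    reads.sort(key=lambda r: (r.start, r.read_id))
    return reads


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def make_fixture_bundle(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a self-contained fixture directory the CLI can run end-to-end.

    Emits ``genes.bed``, one ``counts_<label>.tsv`` per stringency,
    ``groups.tsv`` and ``truth.tsv``.  Regenerating with the same seed
    reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, truth = simulate_count_matrices(config)
    first = next(iter(matrices.values()))
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.bed"
    write_gene_models(first.genes, paths["genes"], dialect="bed")

    for label, matrix in matrices.items():
        p = outdir / f"counts_{label}.tsv"
        matrix.to_tsv(p)
        paths[f"counts_{label}"] = p

    paths["groups"] = outdir / "groups.tsv"
    write_group_labels(
        {s.sample_id: s.group for s in first.samples}, paths["groups"]
    )

    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
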