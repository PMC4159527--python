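"""Per-gene read counting: deduplication, overlap counting, filtering,
normalization and the group ratio report.

The counting rules mirror a low-coverage read-depth CNV workflow:

* positional deduplication with single-end ``rmdup``-style semantics — at
  most one read survives per (chrom, start) position, the one with the
  highest mapping quality (ties: first in input order);
* a read counts toward a gene iff it overlaps the gene body by >= 1 bp
  (half-open interval intersection, ``intersectBed`` default semantics);
  a read overlapping two genes increments both;
* genes are dropped when the median mapped-read count per 100 bp of gene
  length is below one, or when any single individual has zero reads;
* normalization divides each count by the individual's genome-wide total of
  mapped reads (counted after deduplication).

Multi-hit removal is an input contract (the upstream aligner keeps uniquely
mapping reads only); a warning is logged if a read_id recurs at different
positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AlignmentRecord, GeneInterval, SampleMeta

__all__ = [
    "CountMatrix",
    "deduplicate",
    "count_overlaps",
    "build_count_matrix",
    "filter_genes",
    "normalize",
    "group_ratio_report",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Genes x individuals mapped-read counts plus per-individual totals.

    ``counts[g, s]`` is the number of deduplicated reads overlapping gene
    ``genes[g]`` in sample ``samples[s]``; ``samples[s].total_mapped_reads``
    is that individual's genome-wide mapped-read total.  ``normalized`` is
    counts divided by the per-sample total (fill with :func:`normalize`).
    """

    genes: list[GeneInterval]
    samples: list[SampleMeta]
    counts: np.ndarray
    _normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def gene_lengths(self) -> np.ndarray:
        return np.array([g.length for g in self.genes])

    @property
    def totals(self) -> np.ndarray:
        return np.array([s.total_mapped_reads for s in self.samples])

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.samples]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([s.group == group for s in self.samples])

    @property
    def normalized(self) -> np.ndarray:
        if self._normalized is None:
            raise ValueError("call normalize() first")
        return self._normalized

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        sub = CountMatrix(
            genes=[self.genes[i] for i in keep],
            samples=self.samples,
            counts=self.counts[keep],
        )
        if self._normalized is not None:
            sub._normalized = self._normalized[keep]
        return sub

    # -- TSV round trip ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Counts TSV: ``#totals`` / ``#groups`` header lines, then one row
        per gene (gene_id, chrom, start, end, then one column per sample)."""
        with open(path, "w") as fh:
            ids = "\t".join(s.sample_id for s in self.samples)
            fh.write(f"#totals\t{ids}\n")
            fh.write("#\t" + "\t".join(str(t) for t in self.totals) + "\n")
            fh.write(f"#groups\t" + "\t".join(self.groups) + "\n")
            fh.write("gene_id\tchrom\tstart\tend\t" + ids + "\n")
            for g, row in zip(self.genes, self.counts):
                vals = "\t".join(str(int(v)) for v in row)
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            totals = fh.readline().rstrip("\n").split("\t")
            groups = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#totals" or groups[0] != "#groups":
                raise ValueError(f"{path}: not a paracnv counts TSV")
            sample_ids = header[1:]
            samples = [
                SampleMeta(sid, grp, int(tot))
                for sid, grp, tot in zip(sample_ids, groups[1:], totals[1:])
            ]
            df = pd.read_csv(fh, sep="\t")
        genes = [
            GeneInterval(r.gene_id, str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
        counts = df[sample_ids].to_numpy(dtype=np.int64)
        return cls(genes=genes, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate(alignments: Iterable[AlignmentRecord]) -> Iterator[AlignmentRecord]:
    """Collapse reads sharing a start position, keeping the highest-mapq one.

    Input must be sorted by (chrom, start); the survivor of a mapq tie is
    the first record encountered.  Idempotent.  Raises on unsorted input,
    naming the first out-of-order read.
    """
    prev_key: tuple[str, int] | None = None
    best: AlignmentRecord | None = None
    for rec in alignments:
        key = (rec.chrom, rec.start)
        if prev_key is not None and key < prev_key:
            raise ValueError(
                f"alignments not sorted by (chrom, start): read {rec.read_id} "
                f"at {rec.chrom}:{rec.start} follows {prev_key[0]}:{prev_key[1]}"
            )
        if key == prev_key:
            assert best is not None
            if rec.mapq > best.mapq:
                best = rec
        else:
            if best is not None:
                yield best
            prev_key, best = key, rec
    if best is not None:
        yield best


# ---------------------------------------------------------------------------
# overlap counting
# ---------------------------------------------------------------------------


def _gene_trees(genes: Sequence[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, idx)
    return trees


def count_overlaps(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneInterval],
    warn_repeated_ids: bool = True,
) -> tuple[np.ndarray, int]:
    """Count deduplicated reads overlapping each gene body by >= 1 bp.

    Returns ``(per_gene_counts, total_mapped_reads)`` where the total is the
    number of records consumed (the genome-wide denominator for
    normalization).  A read spanning two genes increments both.
    """
    trees = _gene_trees(genes)
    counts = np.zeros(len(genes), dtype=np.int64)
    total = 0
    seen_ids: set[str] = set()
    repeated = 0
    for rec in alignments:
        total += 1
        if warn_repeated_ids:
            if rec.read_id in seen_ids:
                repeated += 1
            else:
                seen_ids.add(rec.read_id)
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rec.start, rec.end):
            counts[hit.data] += 1
    if repeated:
        logger.warning(
            "%d read ids occurred at more than one position; the input "
            "contract expects uniquely mapping reads only", repeated,
        )
    return counts, total


def build_count_matrix(
    genes: Sequence[GeneInterval],
    alignments_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    groups: Mapping[str, str],
) -> CountMatrix:
    """Deduplicate and count each sample's alignments into a CountMatrix.

    ``total_mapped_reads`` is the per-sample record count after
    deduplication, matching the matrix that is normalized by it.
    """
    samples: list[SampleMeta] = []
    cols = []
    for sample_id, alns in alignments_by_sample.items():
        counts, total = count_overlaps(deduplicate(alns), genes)
        cols.append(counts)
        samples.append(SampleMeta(sample_id, groups[sample_id], total))
    counts = np.stack(cols, axis=1) if cols else np.zeros((len(genes), 0), int)
    return CountMatrix(genes=list(genes), samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_genes(matrix: CountMatrix) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop genes with unreliable coverage; return (subset, removal log).

    A gene is retained iff

    * the median over individuals of ``count * 100 / gene_length`` is >= 1
      ("less than one" removes, so exact equality is retained), and
    * every individual has at least one mapped read.

    The removal log has one row per removed gene with boolean columns
    ``low_median_per_100bp`` and ``zero_count_individual`` saying which
    rule(s) fired.  The median over an even number of individuals is the
    mean of the two central order statistics.
    """
    lengths = matrix.gene_lengths.astype(float)
    per_100bp = matrix.counts * 100.0 / lengths[:, None]
    med = np.median(per_100bp, axis=1)
    low_median = med < 1.0
    has_zero = (matrix.counts == 0).any(axis=1)
    removed = low_median | has_zero
    log = pd.DataFrame(
        {
            "gene_id": np.array(matrix.gene_ids)[removed],
            "low_median_per_100bp": low_median[removed],
            "zero_count_individual": has_zero[removed],
        }
    )
    return matrix.subset_genes(np.flatnonzero(~removed)), log


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(matrix: CountMatrix) -> CountMatrix:
    """Fill ``normalized = counts / total_mapped_reads`` per individual."""
    totals = matrix.totals.astype(float)
    if (totals <= 0).any():
        bad = [s.sample_id for s, t in zip(matrix.samples, totals) if t <= 0]
        raise ValueError(f"non-positive total mapped reads for sample(s) {bad}")
    matrix._normalized = matrix.counts / totals[None, :]
    return matrix


# ---------------------------------------------------------------------------
# group ratio report
# ---------------------------------------------------------------------------


def group_ratio_report(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    region: Sequence[str] | None = None,
    pairing: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-gene ratio of average normalized counts between the two groups.

    ``region`` optionally restricts to a list of gene_ids (e.g. a gene
    cluster plus flanking genes).  If ``pairing`` gives (sample_A, sample_B)
    pairs — e.g. individuals of the two groups from the same geographic
    region — the sample standard deviation of the per-pair ratios is added.
    A zero group-B mean yields ratio NaN with ``undefined=True`` rather than
    an error.
    """
    norm = matrix.normalized
    mask_a = matrix.group_mask(group_a)
    mask_b = matrix.group_mask(group_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be nonempty")

    if region is not None:
        wanted = set(region)
        idx = [i for i, g in enumerate(matrix.genes) if g.gene_id in wanted]
    else:
        idx = list(range(matrix.n_genes))

    mean_a = norm[idx][:, mask_a].mean(axis=1)
    mean_b = norm[idx][:, mask_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "gene_id": [matrix.genes[i].gene_id for i in idx],
            "mean_norm_A": mean_a,
            "mean_norm_B": mean_b,
            "ratio": ratio,
            "undefined": mean_b == 0,
        }
    )
    if pairing:
        ids = [s.sample_id for s in matrix.samples]
        pos = {sid: k for k, sid in enumerate(ids)}
        pair_ratios = []
        for sa, sb in pairing:
            col_a = norm[idx][:, pos[sa]]
            col_b = norm[idx][:, pos[sb]]
            with np.errstate(divide="ignore", invalid="ignore"):
                pair_ratios.append(np.where(col_b > 0, col_a / np.where(col_b > 0, col_b, 1.0), np.nan))
        pr = np.stack(pair_ratios, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["ratio_sd"] = np.nanstd(pr, axis=1, ddof=1)
    return out
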