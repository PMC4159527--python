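"""Read-backed allelic multiplicity: distinguishing duplicated loci from a
diploid background.

When paralogous gene copies collapse onto a single reference locus during
mapping, the reads carry the sequences of every copy.  A diploid individual
can contribute at most two haplotypes at any locus, so observing three or
more distinct read-supported two-base haplotypes across a pair of nearby
SNV positions is direct evidence that the locus is duplicated or
multiplied.  The pair must be coverable by a single read (positions at most
``read_length - 1`` bp apart) so that individual reads phase the two
positions.

Pipeline: call SNVs from pileups of high-quality bases (or ingest VCF
positions), enumerate within-read-length position pairs, tally the
two-base haplotypes supported by at least ``min_support`` reads, and call a
gene duplicated in a group when at least ``min_individuals`` individuals of
that group each show a pair with >= 3 haplotypes.

Alignments are assumed ungapped (fixed-length single-end reads); reads with
``N`` at either position of a pair are excluded from that pair's tally.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import AlignmentRecord, GeneInterval, SnvSite

__all__ = [
    "HaplotypePairTable",
    "MultiplicityCall",
    "call_snvs_minimal",
    "enumerate_pairs",
    "count_haplotypes",
    "classify_gene",
    "analyze_gene_multiplicity",
]

DEFAULT_READ_LENGTH = 36
DEFAULT_Q_MIN = 30


@dataclass
class HaplotypePairTable:
    """Read-supported two-base haplotypes at one SNV position pair."""

    pair: tuple[int, int]  # 0-based positions, pos1 < pos2
    haplotypes: dict[str, int]  # two-base string -> supporting read count

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class MultiplicityCall:
    """Per-gene duplication/multiplication call from allelic multiplicity."""

    gene_id: str
    #: per individual: max distinct haplotypes over all pairs
    max_haplotypes: dict[str, int]
    #: per individual: number of pairs with >= 3 haplotypes
    n_multi_pairs: dict[str, int]
    #: group label -> called duplicated/multiplied in that group
    group_call: dict[str, bool]
    #: group label -> strong call (>= min_pairs_strong qualifying pairs each)
    strong_call: dict[str, bool]


def _pileup_columns(
    reads: Iterable[AlignmentRecord], q_min: int
) -> dict[int, Counter]:
    """High-quality base tallies per reference position (ungapped reads)."""
    columns: dict[int, Counter] = defaultdict(Counter)
    for rec in reads:
        for offset in range(rec.read_length):
            base = rec.sequence[offset]
            if base == "N":
                continue
            if rec.base_qualities[offset] < q_min:
                continue
            columns[rec.start + offset][base] += 1
    return columns


def call_snvs_minimal(
    reads: Sequence[AlignmentRecord],
    region: tuple[int, int] | None = None,
    q_min: int = DEFAULT_Q_MIN,
    min_allele_reads: int = 2,
    chrom: str | None = None,
) -> list[SnvSite]:
    """Call SNVs from a pileup of high-quality bases.

    A position is an SNV iff at least two distinct bases each have
    ``>= min_allele_reads`` supporting reads with base quality >= ``q_min``.
    This is a deliberately minimal caller — a convenience stand-in for a
    full genotype-likelihood pipeline; VCF positions from any external
    caller can be supplied to the downstream steps instead.
    """
    if chrom is None:
        chrom = reads[0].chrom if reads else ""
    columns = _pileup_columns(reads, q_min)
    sites: list[SnvSite] = []
    for pos in sorted(columns):
        if region is not None and not (region[0] <= pos < region[1]):
            continue
        passing = {b: c for b, c in columns[pos].items() if c >= min_allele_reads}
        if len(passing) >= 2:
            sites.append(SnvSite(chrom=chrom, pos=pos, alleles=passing))
    return sites


def enumerate_pairs(
    snvs: Sequence[SnvSite], read_length: int = DEFAULT_READ_LENGTH,
    inclusive: bool = False,
) -> list[tuple[int, int]]:
    """All SNV position pairs coverable by a single read.

    Pair (i, j), i < j, qualifies when ``pos_j - pos_i <= read_length - 1``
    — both positions fit on one read of ``read_length`` bp.  With
    ``inclusive=True`` the looser ``<= read_length`` rule is used instead.
    """
    max_dist = read_length if inclusive else read_length - 1
    positions = [s.pos for s in snvs]
    if positions != sorted(positions):
        raise ValueError("SNV sites must be sorted by position")
    pairs: list[tuple[int, int]] = []
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if positions[j] - positions[i] > max_dist:
                break
            pairs.append((positions[i], positions[j]))
    return pairs


def count_haplotypes(
    pair: tuple[int, int],
    reads: Iterable[AlignmentRecord],
    q_min: int = DEFAULT_Q_MIN,
    min_support: int = 2,
) -> HaplotypePairTable:
    """Tally two-base haplotypes across an SNV pair from co-covering reads.

    A read contributes iff it covers both positions with base quality
    >= ``q_min`` at each and neither base is ``N``; a haplotype is retained
    iff supported by >= ``min_support`` such reads.
    """
    pos1, pos2 = pair
    if pos2 <= pos1:
        raise ValueError("pair positions must satisfy pos1 < pos2")
    tally: Counter = Counter()
    for rec in reads:
        if rec.start > pos1 or rec.end <= pos2:
            continue
        o1, o2 = pos1 - rec.start, pos2 - rec.start
        b1, b2 = rec.sequence[o1], rec.sequence[o2]
        if "N" in (b1, b2):
            continue
        if rec.base_qualities[o1] < q_min or rec.base_qualities[o2] < q_min:
            continue
        tally[b1 + b2] += 1
    kept = {h: c for h, c in tally.items() if c >= min_support}
    return HaplotypePairTable(pair=(pos1, pos2), haplotypes=kept)


def classify_gene(
    gene_id: str,
    tables_by_individual: Mapping[str, Sequence[HaplotypePairTable]],
    groups: Mapping[str, str],
    min_individuals: int = 3,
    min_pairs_strong: int = 2,
) -> MultiplicityCall:
    """Call a gene duplicated/multiplied from per-individual pair tables.

    Three or more distinct haplotypes at a pair cannot originate from one
    diploid locus.  ``group_call[g]`` is true iff >= ``min_individuals``
    individuals of group *g* each have at least one pair with >= 3
    haplotypes; ``strong_call[g]`` additionally requires
    >= ``min_pairs_strong`` such pairs per qualifying individual.
    """
    max_h: dict[str, int] = {}
    n_multi: dict[str, int] = {}
    for sample_id, tables in tables_by_individual.items():
        counts = [t.n_haplotypes for t in tables]
        max_h[sample_id] = max(counts, default=0)
        n_multi[sample_id] = sum(1 for c in counts if c >= 3)

    group_call: dict[str, bool] = {}
    strong_call: dict[str, bool] = {}
    for group in dict.fromkeys(groups.values()):
        members = [s for s in tables_by_individual if groups.get(s) == group]
        qualifying = [s for s in members if n_multi[s] >= 1]
        strong = [s for s in members if n_multi[s] >= min_pairs_strong]
        group_call[group] = len(qualifying) >= min_individuals
        strong_call[group] = len(strong) >= min_individuals
    return MultiplicityCall(
        gene_id=gene_id,
        max_haplotypes=max_h,
        n_multi_pairs=n_multi,
        group_call=group_call,
        strong_call=strong_call,
    )


def analyze_gene_multiplicity(
    gene: GeneInterval,
    reads_by_individual: Mapping[str, Sequence[AlignmentRecord]],
    groups: Mapping[str, str],
    snvs: Sequence[SnvSite] | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    q_min: int = DEFAULT_Q_MIN,
    min_allele_reads: int = 2,
    min_support: int = 2,
    min_individuals: int = 3,
    min_pairs_strong: int = 2,
) -> MultiplicityCall:
    """End-to-end multiplicity analysis of one gene.

    SNVs are called from the pooled reads of all individuals unless a site
    list (e.g. from a VCF) is supplied; pair enumeration and haplotype
    counting then run per individual.
    """
    if snvs is None:
        pooled = [r for reads in reads_by_individual.values() for r in reads]
        snvs = call_snvs_minimal(
            pooled, region=(gene.start, gene.end), q_min=q_min,
            min_allele_reads=min_allele_reads, chrom=gene.chrom,
        )
    else:
        snvs = sorted(
            (s for s in snvs if s.chrom == gene.chrom and gene.start <= s.pos < gene.end),
            key=lambda s: s.pos,
        )
    pairs = enumerate_pairs(snvs, read_length=read_length)
    tables = {
        sample_id: [
            count_haplotypes(pair, reads, q_min=q_min, min_support=min_support)
            for pair in pairs
        ]
        for sample_id, reads in reads_by_individual.items()
    }
    return classify_gene(
        gene.gene_id, tables, groups,
        min_individuals=min_individuals, min_pairs_strong=min_pairs_strong,
    )
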