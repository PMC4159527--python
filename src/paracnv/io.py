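"""Input/output for the formats the pipeline touches.

Internal conventions used by every other module:

* genomic intervals are 0-based, half-open ``[start, end)`` (BED-style);
  1-based inclusive coordinates (Ensembl-style tables) are converted at the
  boundary on input and back on output;
* strand is ignored — reads are counted against the whole gene body (exons
  plus introns) regardless of orientation;
* scaffolds are ordinary reference sequences, treated exactly like
  chromosomes / linkage groups.

Alongside SAM/BAM a minimal tabular alignment format is defined so that
synthetic fixtures need no binary tooling: tab-separated columns
``read_id  chrom  start0  length  mapq  sequence  qualities`` where
``qualities`` is a Phred+33 string of the same length as ``sequence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "GeneInterval",
    "AlignmentRecord",
    "SampleMeta",
    "SnvSite",
    "read_gene_models",
    "write_gene_models",
    "read_alignments",
    "write_alignments_tabular",
    "read_snv_positions",
    "write_results_table",
    "read_results_table",
    "read_group_labels",
    "write_group_labels",
    "ParseError",
]

#: fixed column order of the detection results TSV
RESULT_COLUMNS_FIXED = ["gene_id", "mean_norm_A", "mean_norm_B", "direction"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class GeneInterval:
    """A named genomic span (gene body: exons + introns), 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """A single-end aligned read with its per-base Phred qualities."""

    read_id: str
    chrom: str
    start: int
    read_length: int
    mapq: int
    sequence: str
    base_qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.read_length != len(self.sequence) or self.read_length != len(
            self.base_qualities
        ):
            raise ValueError(
                f"read {self.read_id}: read_length {self.read_length} != "
                f"|sequence| {len(self.sequence)} or |qualities| "
                f"{len(self.base_qualities)}"
            )
        if self.mapq < 0:
            raise ValueError(f"read {self.read_id}: negative mapq")

    @property
    def end(self) -> int:
        return self.start + self.read_length


@dataclass
class SampleMeta:
    """Per-individual metadata: group label and genome-wide mapped-read total."""

    sample_id: str
    group: str
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 0:
            raise ValueError(f"sample {self.sample_id}: negative read total")


@dataclass
class SnvSite:
    """A called single-nucleotide variant: 0-based position and allele support."""

    chrom: str
    pos: int
    alleles: dict[str, int]  # base -> number of supporting high-quality reads


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_DIALECTS = ("bed", "gff", "ensembl")


def read_gene_models(path: str | Path, dialect: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED4, GFF3 or a 1-based Ensembl-style TSV.

    The Ensembl dialect has columns ``gene_id  chrom  start  end`` with
    1-based inclusive coordinates (thousands separators tolerated, header
    line optional); it is converted to the internal 0-based half-open
    convention, so the internal length equals ``end - start + 1`` of the
    input row.  Duplicate gene ids are rejected.
    """
    dialect = dialect.lower()
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if dialect == "bed":
        genes = _read_bed(path)
    elif dialect == "gff":
        genes = _read_gff(path)
    else:
        genes = _read_ensembl_tsv(path)

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_bed(path: Path) -> list[GeneInterval]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED4 needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            try:
                genes.append(GeneInterval(name, chrom, int(start), int(end)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gff(path: Path) -> list[GeneInterval]:
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df = df[df.Feature == "gene"]
    id_col = next((c for c in ("gene_id", "ID", "Name") if c in df.columns), None)
    if id_col is None:
        raise ParseError(f"{path}: no gene identifier attribute in GFF gene rows")
    genes = []
    for row in df.itertuples(index=False):
        # pyranges already converts GFF 1-based inclusive to 0-based half-open
        genes.append(
            GeneInterval(
                str(getattr(row, id_col)), str(row.Chromosome),
                int(row.Start), int(row.End),
            )
        )
    return genes


def _read_ensembl_tsv(path: Path) -> list[GeneInterval]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            gene_id, chrom, start_s, end_s = fields[:4]
            start_s = start_s.replace(",", "")
            end_s = end_s.replace(",", "")
            if lineno == 1 and not (start_s.isdigit() and end_s.isdigit()):
                continue  # header line
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            try:
                genes.append(GeneInterval(gene_id, chrom, start1 - 1, end1))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(
    genes: Sequence[GeneInterval], path: str | Path, dialect: str = "bed"
) -> None:
    """Write gene intervals as BED4 or the 1-based Ensembl-style TSV."""
    dialect = dialect.lower()
    with open(path, "w") as fh:
        for g in genes:
            if dialect == "bed":
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
            elif dialect == "ensembl":
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\n")
            else:
                raise ValueError(f"cannot write dialect {dialect!r}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path, fmt: str | None = None
) -> Iterator[AlignmentRecord]:
    """Yield mapped alignment records in ``(chrom, start)`` order.

    ``fmt`` is ``"sam"`` (SAM or BAM, via pysam) or ``"tabular"``; by default
    it is inferred from the file extension.  Unmapped records are skipped.
    Input that is not coordinate-sorted is sorted in memory before yielding.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() in (".sam", ".bam", ".cram") else "tabular"
    records = list(
        _iter_sam(path) if fmt == "sam" else _iter_tabular(path)
    )
    records.sort(key=lambda r: (r.chrom, r.start))
    yield from records


def _iter_sam(path: Path) -> Iterator[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence or ""
            quals = aln.query_qualities
            quals = tuple(int(q) for q in quals) if quals is not None else (0,) * len(seq)
            if len(seq) != len(quals):
                raise ParseError(
                    f"{path}: read {aln.query_name}: sequence/quality length mismatch"
                )
            yield AlignmentRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                start=int(aln.reference_start),
                read_length=len(seq),
                mapq=int(aln.mapping_quality),
                sequence=seq,
                base_qualities=quals,
            )


def _iter_tabular(path: Path) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            read_id, chrom, start, length, mapq, seq, quals = fields
            qual_ints = tuple(ord(c) - 33 for c in quals)
            try:
                yield AlignmentRecord(
                    read_id=read_id,
                    chrom=chrom,
                    start=int(start),
                    read_length=int(length),
                    mapq=int(mapq),
                    sequence=seq,
                    base_qualities=qual_ints,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: read {read_id}: {exc}") from exc


def write_alignments_tabular(
    records: Iterable[AlignmentRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tstart0\tlength\tmapq\tsequence\tqualities\n")
        for r in records:
            quals = "".join(chr(q + 33) for q in r.base_qualities)
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.read_length}\t"
                f"{r.mapq}\t{r.sequence}\t{quals}\n"
            )


# ---------------------------------------------------------------------------
# SNVs (VCF, read-only)
# ---------------------------------------------------------------------------


def read_snv_positions(path: str | Path) -> list[SnvSite]:
    """Read biallelic-or-more SNV sites from a VCF (v4.x), 0-based positions.

    Per-allele supporting-read counts are taken from the AD FORMAT field when
    present, otherwise every REF/ALT allele is recorded with a count of 0
    (meaning "unknown"); downstream haplotype counting recounts support
    directly from the reads, so VCF input only needs the positions.
    """
    import pysam

    sites: list[SnvSite] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch():
            alleles = [a for a in rec.alleles if a is not None and len(a) == 1]
            if len(alleles) < 2:
                continue  # indels / monomorphic records are out of scope
            counts = dict.fromkeys(alleles, 0)
            for sample in rec.samples.values():
                ad = sample.get("AD")
                if ad is None:
                    continue
                for allele, n in zip(rec.alleles, ad):
                    if allele in counts and n is not None:
                        counts[allele] += int(n)
            sites.append(SnvSite(chrom=rec.chrom, pos=rec.pos - 1, alleles=counts))
    return sites


# ---------------------------------------------------------------------------
# detection results table
# ---------------------------------------------------------------------------


def write_results_table(results: pd.DataFrame, path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    """Write the per-gene detection table as TSV with a fixed column order.

    Columns: gene_id, mean_norm_A, mean_norm_B, direction, then per stringency
    ``p_<label>``, ``fdr_<label>``, ``sig_<label>``, finally consensus_gcnv.
    Extra ``header_lines`` are emitted as ``#``-prefixed comments.
    """
    per_str = [
        c for c in results.columns
        if c.startswith(("p_", "fdr_", "sig_"))
    ]
    cols = [c for c in RESULT_COLUMNS_FIXED if c in results.columns]
    cols += sorted(per_str, key=lambda c: (c.split("_", 1)[1], c.split("_", 1)[0]))
    if "consensus_gcnv" in results.columns:
        cols.append("consensus_gcnv")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        results[cols].to_csv(fh, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for c in df.columns:
        if c.startswith("sig_") or c == "consensus_gcnv":
            df[c] = df[c].astype(bool)
    return df


# ---------------------------------------------------------------------------
# group labels
# ---------------------------------------------------------------------------


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read ``sample_id<TAB>group`` into an ordered mapping."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in labels:
                raise ParseError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
            labels[fields[0]] = fields[1]
    return labels


def write_group_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tgroup\n")
        for sample_id, group in labels.items():
            fh.write(f"{sample_id}\t{group}\n")
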