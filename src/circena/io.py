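"""File formats and core domain records.

Readers and writers for the plain-text formats the pipeline consumes:
FASTA (genome, miRNA), FASTQ (reads), GTF (exon annotation), TSV (count
matrices, result tables) and JSON reports.  Coordinates are 1-based
inclusive everywhere inside the package; BED exports convert to 0-based
half-open at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "ExonAnnotation",
    "ReadRecord",
    "CountMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gtf",
    "write_gtf",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_tsv",
    "write_json",
    "revcomp",
]

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference chromosome: a name and an uppercase DNA sequence."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for chromosome {self.chrom_name!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"chromosome {self.chrom_name!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence in 1-based inclusive coordinates."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise IndexError(
                f"coordinates [{start}, {end}] out of bounds for "
                f"{self.chrom_name} (length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class ExonAnnotation:
    """Exon structure of one transcript.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by start,
    non-overlapping; strand is '+' or '-'.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"exon ({start}, {end}) of {self.transcript_id!r} has start > end"
                )
            if start <= prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id!r} unsorted or overlapping at ({start}, {end})"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    def spliced_sequence(self, genome: Mapping[str, GenomeSequence]) -> str:
        """Mature (intron-free) transcript sequence, 5'->3' on its strand."""
        chrom = genome[self.chrom]
        seq = "".join(chrom.slice1(s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read (FASTQ record)."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def groups_array(self) -> np.ndarray:
        """Group label per sample, in sample order."""
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        return np.array([self.group_labels[s] for s in self.sample_ids])

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in ids]
        return CountMatrix(list(ids), self.sample_ids, self.counts[rows, :],
                           dict(self.group_labels))


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (uppercased)."""
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    # Validate headers ourselves so malformed lines get a line number.
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}:1: FASTA must start with '>' header")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(attr_field: str, path: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed GTF attribute {chunk!r}")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[ExonAnnotation]:
    """Read exon features from a GTF file, grouped per transcript.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  Exons are sorted by coordinate within
    each transcript.
    """
    path = Path(path)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            attrs = _parse_gtf_attributes(attr, str(path), lineno)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise FormatError(f"{path}:{lineno}: exon missing {key} attribute")
            tx = attrs["transcript_id"]
            if tx not in per_tx:
                per_tx[tx] = {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                }
                order.append(tx)
            per_tx[tx]["exons"].append((start, end))
    annotations = []
    for tx in order:
        info = per_tx[tx]
        annotations.append(
            ExonAnnotation(
                gene_id=info["gene_id"],
                transcript_id=tx,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(sorted(info["exons"])),
            )
        )
    return annotations


def write_gtf(annotations: Iterable[ExonAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for i, (start, end) in enumerate(ann.exons, start=1):
                attrs = (
                    f'gene_id "{ann.gene_id}"; transcript_id "{ann.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{ann.chrom}\tcircena\texon\t{start}\t{end}\t.\t{ann.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# TSV / JSON


def read_counts_tsv(path: str | Path, group_row: bool = False) -> CountMatrix:
    """Read a counts TSV: header row of sample names, first column feature ids.

    If ``group_row`` is true, the first data row (feature id ``#group``)
    holds the group label of each sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    groups: dict[str, str] = {}
    if "#group" in df.index:
        groups = dict(zip(df.columns, df.loc["#group"]))
        df = df.drop(index="#group")
    elif group_row:
        raise FormatError(f"{path}: expected a '#group' row with sample group labels")
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at feature "
                    f"{df.index[i]!r}, sample {col!r}"
                )
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at feature "
                    f"{df.index[i]!r}, sample {col!r}"
                )
            counts[i, j] = value
    return CountMatrix(list(df.index), list(df.columns), counts, groups)


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        if matrix.group_labels:
            fh.write(
                "#group\t"
                + "\t".join(matrix.group_labels[s] for s in matrix.sample_ids)
                + "\n"
            )
        for i, fid in enumerate(matrix.feature_ids):
            fh.write(fid + "\t" + "\t".join(str(c) for c in matrix.counts[i]) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
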