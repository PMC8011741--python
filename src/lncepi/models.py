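"""Domain record types shared across the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

from .intervals import GenomicInterval

#: positional/coding classes a transcript can receive
CLASS_LABELS = (
    "lincRNA",
    "NAT",
    "incRNA",
    "putative_mRNA",
    "mRNA",
    "unclassified",
)

#: the three long-noncoding classes, which require length > 200 nt
LNCRNA_CLASSES = ("lincRNA", "NAT", "incRNA")

#: cytosine sequence contexts (H is A, C or T)
CONTEXTS = ("CG", "CHG", "CHH")

#: minimum length (exclusive) for a transcript to count as a lncRNA
MIN_LNCRNA_LENGTH = 200


def _check_exon_chain(exons: Tuple[GenomicInterval, ...], span: GenomicInterval, owner: str):
    if not exons:
        raise ValueError(f"{owner}: at least one exon is required")
    prev_end = None
    for ex in exons:
        if ex.chrom != span.chrom or ex.strand != span.strand:
            raise ValueError(f"{owner}: exon {ex} not on span chrom/strand")
        if ex.start < span.start or ex.end > span.end:
            raise ValueError(f"{owner}: exon {ex} outside span {span}")
        if prev_end is not None and ex.start < prev_end:
            raise ValueError(f"{owner}: exons must be sorted and non-overlapping")
        prev_end = ex.end


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled transcript: exon chain plus a positional class label."""

    id: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...]
    class_label: str = "unclassified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _check_exon_chain(self.exons, self.interval, f"transcript {self.id}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.class_label in LNCRNA_CLASSES and self.length <= MIN_LNCRNA_LENGTH:
            raise ValueError(
                f"transcript {self.id}: class {self.class_label} requires "
                f"length > {MIN_LNCRNA_LENGTH} nt (got {self.length})"
            )

    @property
    def length(self) -> int:
        """Transcript length = sum of exon lengths (nt)."""
        return sum(ex.length for ex in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def with_label(self, label: str) -> "TranscriptModel":
        return replace(self, class_label=label)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene; introns are derived as the exon complement."""

    id: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _check_exon_chain(self.exons, self.interval, f"gene {self.id}")

    @property
    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Complement of the exons within the gene span (may be empty)."""
        out = []
        span = self.interval
        cursor = span.start
        for ex in self.exons:
            if ex.start > cursor:
                out.append(GenomicInterval(span.chrom, cursor, ex.start, span.strand))
            cursor = ex.end
        if cursor < span.end:
            out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
        return tuple(out)


@dataclass(frozen=True)
class CytosineRecord:
    """Methylated/unmethylated read counts at one cytosine position."""

    position: GenomicInterval  # length-1 interval with strand
    context: str
    mc: int
    umc: int

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("cytosine position must be a length-1 interval")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown cytosine context {self.context!r}")
        if self.mc < 0 or self.umc < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.mc + self.umc

    @property
    def zero_coverage(self) -> bool:
        return self.coverage == 0


@dataclass(frozen=True)
class SmallRNAAlignment:
    """A positioned small-RNA read with its length and mapping uniqueness."""

    interval: GenomicInterval
    read_length: int
    unique: bool

    def __post_init__(self) -> None:
        if self.read_length != self.interval.length:
            raise ValueError(
                f"read_length {self.read_length} != interval length {self.interval.length}"
            )
        if not (18 <= self.read_length <= 30):
            raise ValueError(f"read_length {self.read_length} outside the sRNA range 18-30")


@dataclass(frozen=True)
class HSPRecord:
    """One local alignment block from a BLAST-style tabular file.

    Query and subject coordinates follow the BLAST tabular convention
    (1-based, inclusive); on the minus strand ``subject_start`` >
    ``subject_end``. Conversion to the internal convention happens where
    coverage is computed.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    bitscore: float
    evalue: float
    pident: float = 100.0
    align_length: int = 0

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")
        if self.query_start < 1 or min(self.subject_start, self.subject_end) < 1:
            raise ValueError("BLAST tabular coordinates are 1-based")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def strand(self) -> str:
        return "+" if self.subject_start <= self.subject_end else "-"

    @property
    def subject_low(self) -> int:
        return min(self.subject_start, self.subject_end)

    @property
    def subject_high(self) -> int:
        return max(self.subject_start, self.subject_end)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-replicate FPKM values for one transcript."""

    transcript_id: str
    fpkm: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fpkm", tuple(float(v) for v in self.fpkm))
        if not self.fpkm:
            raise ValueError("at least one replicate is required")
        for v in self.fpkm:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"FPKM values must be finite and >= 0, got {v}")

    @property
    def mean(self) -> float:
        return sum(self.fpkm) / len(self.fpkm)


@dataclass(frozen=True)
class CodingHit:
    """Best protein-database homology hit for one transcript."""

    transcript_id: str
    subject_id: str
    best_evalue: float

    def __post_init__(self) -> None:
        if self.best_evalue < 0:
            raise ValueError("evalue must be >= 0")
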