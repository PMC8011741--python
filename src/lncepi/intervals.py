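"""Genomic interval primitives and interval algebra.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
File formats that use 1-based inclusive coordinates (GFF3/GTF, cytosine
reports, BLAST tabular) are converted at the I/O boundary, so no off-by-one
arithmetic leaks into the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with an optional strand.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). An unstranded
    interval is treated as matching either strand in stranded queries, which
    is the usual convention for repeat annotations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty sequence identifier")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def strands_compatible(a: str, b: str) -> bool:
    """Strand match with ``.`` acting as a wildcard."""
    return a == "." or b == "." or a == b


def overlap_length(a: GenomicInterval, b: GenomicInterval, stranded: bool = False) -> int:
    """Number of shared bases between two intervals.

    Returns 0 when the chromosomes differ or, with ``stranded=True``, when
    the strands are incompatible. Symmetric and bounded by
    ``min(a.length, b.length)``.
    """
    if a.chrom != b.chrom:
        return 0
    if stranded and not strands_compatible(a.strand, b.strand):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Merge intervals on one chromosome, bridging gaps of up to ``gap`` bp.

    Successive intervals separated by at most ``gap`` unshared bases are
    merged into one run. The output is sorted and disjoint; strand
    information is dropped (output intervals are unstranded).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(
            f"merge_intervals requires a single chromosome, got {sorted(chroms)}"
        )
    chrom = ivs[0].chrom
    merged: List[GenomicInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def merge_by_chrom(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Convenience wrapper: merge_intervals applied per chromosome."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        out.extend(merge_intervals(by_chrom[chrom], gap=gap))
    return out


class GenomeIndex:
    """Per-chromosome interval index for overlap and containment queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval, data=None) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv if data is None else data
        )
        self._n += 1

    def __len__(self) -> int:
        return self._n

    @property
    def chroms(self) -> Sequence[str]:
        return sorted(self._trees)

    def overlapping(self, query: GenomicInterval, stranded: bool = False) -> list:
        """All stored items overlapping *query* by >= 1 bp."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        if stranded:
            hits = [
                h
                for h in hits
                if strands_compatible(getattr(h, "strand", "."), query.strand)
            ]
        return sorted(hits, key=_sort_key)

    def any_overlap(
        self,
        query: GenomicInterval,
        stranded: bool = False,
        min_overlap: int = 1,
    ) -> bool:
        for hit in self.overlapping(query, stranded=stranded):
            iv = hit if isinstance(hit, GenomicInterval) else getattr(hit, "interval")
            if overlap_length(query, iv, stranded=stranded) >= min_overlap:
                return True
        return False

    def contained_in(self, region: GenomicInterval) -> list:
        """Stored items lying fully within *region* (strand ignored)."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return sorted(
            (h.data for h in tree.envelop(region.start, region.end)), key=_sort_key
        )


def _sort_key(item):
    iv = item if isinstance(item, GenomicInterval) else getattr(item, "interval", None)
    if iv is None:
        return (str(item),)
    return (iv.chrom, iv.start, iv.end, iv.strand)
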