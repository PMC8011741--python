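"""24-nt siRNA extraction, RPM normalization, cluster calling, and
per-transcript overlap status.

The overlap criterion mirrors "perfect sequence identity to genomic regions
encoding 24-nt siRNAs": a transcript is siRNA-positive when at least one
uniquely mapped 24-nt read interval lies fully within its genomic span
(containment mode, the default). Cluster mode instead requires >= 1 bp
overlap with a called cluster. Clusters are a documented convention (merge
gap 100 bp, >= 3 member reads) since the source analysis names clusters
without defining them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, strands_compatible
from .models import SmallRNAAlignment, TranscriptModel

DEFAULT_CLUSTER_GAP = 100
DEFAULT_CLUSTER_MIN_READS = 3


def filter_24nt(
    reads: Iterable[SmallRNAAlignment],
    unique_only: bool = True,
    target_length: int = 24,
) -> List[SmallRNAAlignment]:
    """Reads of the target length (and, by default, uniquely mapped)."""
    return [
        r
        for r in reads
        if r.read_length == target_length and (r.unique or not unique_only)
    ]


def rpm(count: float, library_size: int) -> float:
    """Reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e6 / library_size


@dataclass(frozen=True)
class SiRNACluster:
    interval: GenomicInterval
    read_count: int
    rpm: Optional[float] = None


def call_clusters(
    reads24: Sequence[SmallRNAAlignment],
    gap: int = DEFAULT_CLUSTER_GAP,
    min_reads: int = DEFAULT_CLUSTER_MIN_READS,
    library_size: Optional[int] = None,
) -> List[SiRNACluster]:
    """Merge 24-nt read intervals (bridging <= gap bp) into clusters.

    Clusters with fewer than ``min_reads`` member reads are dropped. The
    cluster interval is exactly the merge of its member read intervals.
    """
    by_chrom: Dict[str, List[SmallRNAAlignment]] = {}
    for read in reads24:
        by_chrom.setdefault(read.interval.chrom, []).append(read)
    clusters: List[SiRNACluster] = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur_start = reads[0].interval.start
        cur_end = reads[0].interval.end
        count = 1
        for read in reads[1:]:
            iv = read.interval
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
                count += 1
            else:
                if count >= min_reads:
                    clusters.append(_make_cluster(chrom, cur_start, cur_end, count, library_size))
                cur_start, cur_end, count = iv.start, iv.end, 1
        if count >= min_reads:
            clusters.append(_make_cluster(chrom, cur_start, cur_end, count, library_size))
    return clusters


def _make_cluster(chrom, start, end, count, library_size):
    value = rpm(count, library_size) if library_size else None
    return SiRNACluster(GenomicInterval(chrom, start, end), count, value)


class _ReadIndex:
    def __init__(self, reads: Iterable[SmallRNAAlignment]):
        self._trees: Dict[str, IntervalTree] = {}
        for read in reads:
            iv = read.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, read)

    def contained_in(self, region: GenomicInterval) -> List[SmallRNAAlignment]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.envelop(region.start, region.end)]

    def overlapping(self, region: GenomicInterval):
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(region.start, region.end)]


def sirna_overlap_status(
    transcript: TranscriptModel,
    reads24: Optional[Sequence[SmallRNAAlignment]] = None,
    clusters: Optional[Sequence[SiRNACluster]] = None,
    mode: str = "containment",
    stranded: bool = False,
    _index: Optional[_ReadIndex] = None,
) -> bool:
    """True when the transcript overlaps the 24-nt siRNA signal.

    ``containment`` mode: >= 1 read interval fully within the transcript
    span. ``cluster`` mode: >= 1 bp overlap with a called cluster.
    """
    span = transcript.interval
    if mode == "containment":
        index = _index if _index is not None else _ReadIndex(reads24 or [])
        for read in index.contained_in(span):
            if not stranded or strands_compatible(read.interval.strand, span.strand):
                return True
        return False
    if mode == "cluster":
        for cluster in clusters or []:
            iv = cluster.interval
            if iv.chrom == span.chrom and iv.start < span.end and span.start < iv.end:
                if not stranded or strands_compatible(iv.strand, span.strand):
                    return True
        return False
    raise ValueError(f"unknown mode {mode!r}")


def sirna_status_table(
    transcripts: Sequence[TranscriptModel],
    reads24: Sequence[SmallRNAAlignment],
    mode: str = "containment",
    stranded: bool = False,
    gap: int = DEFAULT_CLUSTER_GAP,
    min_reads: int = DEFAULT_CLUSTER_MIN_READS,
) -> Dict[str, bool]:
    """Per-transcript siRNA overlap status for a whole transcript set."""
    clusters = call_clusters(reads24, gap=gap, min_reads=min_reads) if mode == "cluster" else None
    index = _ReadIndex(reads24) if mode == "containment" else None
    return {
        tx.id: sirna_overlap_status(
            tx, reads24=reads24, clusters=clusters, mode=mode, stranded=stranded, _index=index
        )
        for tx in transcripts
    }
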