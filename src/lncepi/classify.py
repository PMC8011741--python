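"""Positional classification of assembled transcripts.

A transcript is labeled by precedence:

1. **NAT** — one of its exons overlaps an exon of a gene on the opposite
   strand (natural antisense transcript);
2. **incRNA** — its span lies fully within a single intron of a gene
   (either strand by default);
3. intergenic (no genic overlap) — **putative_mRNA** when it carries a
   protein-database hit at or below the e-value cutoff, otherwise
   **lincRNA** provided its length exceeds 200 nt.

Transcripts failing all rules (sense-overlapping a gene outside introns,
short intergenic transcripts without hits, or on chromosomes absent from
the gene annotation) are labeled ``unclassified``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import CodingHit, GeneModel, MIN_LNCRNA_LENGTH, TranscriptModel

logger = logging.getLogger("lncepi")

DEFAULT_EVALUE_CUTOFF = 1e-10


@dataclass(frozen=True)
class DistanceBinSpec:
    """Breakpoints (bp) for binning transcript-to-gene distances.

    Only the 2 kb and 20 kb breakpoints are anchored in the survey's text;
    the interior breakpoints are a labeled convention.
    """

    breakpoints: Tuple[float, ...] = (0, 2_000, 5_000, 10_000, 20_000, math.inf)

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if bp[0] != 0:
            raise ValueError("first breakpoint must be 0")
        if any(bp[i] >= bp[i + 1] for i in range(len(bp) - 1)):
            raise ValueError("breakpoints must be strictly increasing")

    @property
    def labels(self) -> Tuple[str, ...]:
        def fmt(x: float) -> str:
            if math.isinf(x):
                return "inf"
            return f"{x / 1000:g}kb" if x >= 1000 else f"{x:g}bp"

        bp = self.breakpoints
        return tuple(f"[{fmt(bp[i])},{fmt(bp[i + 1])})" for i in range(len(bp) - 1))

    def bin_index(self, distance: float) -> int:
        bp = self.breakpoints
        for i in range(len(bp) - 1):
            if bp[i] <= distance < bp[i + 1]:
                return i
        return len(bp) - 2  # distance == inf falls in the open last bin


def _exon_tree_by_chrom(genes: Sequence[GeneModel]):
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        for ex in gene.exons:
            trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end, gene)
    return trees


def _intron_tree_by_chrom(genes: Sequence[GeneModel]):
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        for intron in gene.introns:
            trees.setdefault(intron.chrom, IntervalTree()).addi(intron.start, intron.end, (gene, intron))
    return trees


def _span_tree_by_chrom(genes: Sequence[GeneModel]):
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        iv = gene.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gene)
    return trees


def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    hits: Iterable[CodingHit] = (),
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_antisense_overlap: int = 1,
    intron_either_strand: bool = True,
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    """Assign a class label to every transcript.

    Returns the relabeled transcripts plus a ``transcript_id -> gene_id``
    pairing for NATs (antisense-overlapped gene, largest exon overlap) and
    incRNAs (intron host gene).
    """
    best_evalue: Dict[str, float] = {}
    for hit in hits:
        prev = best_evalue.get(hit.transcript_id)
        if prev is None or hit.best_evalue < prev:
            best_evalue[hit.transcript_id] = hit.best_evalue

    exon_trees = _exon_tree_by_chrom(genes)
    intron_trees = _intron_tree_by_chrom(genes)
    span_trees = _span_tree_by_chrom(genes)
    gene_chroms = {g.interval.chrom for g in genes}

    labeled: List[TranscriptModel] = []
    paired_gene: Dict[str, str] = {}
    n_unknown_chrom = 0

    for tx in transcripts:
        span = tx.interval
        if span.chrom not in gene_chroms:
            n_unknown_chrom += 1
            labeled.append(tx.with_label("unclassified"))
            continue

        label = None

        # 1. NAT: transcript exon overlaps a gene exon on the opposite strand
        if span.strand in ("+", "-"):
            best_ov, best_gene = 0, None
            etree = exon_trees.get(span.chrom)
            if etree is not None:
                for ex in tx.exons:
                    for hit_iv in etree.overlap(ex.start, ex.end):
                        gene = hit_iv.data
                        if gene.interval.strand in ("+", "-") and gene.interval.strand != span.strand:
                            ov = max(0, min(ex.end, hit_iv.end) - max(ex.start, hit_iv.begin))
                            if ov > best_ov or (ov == best_ov and best_gene and gene.id < best_gene.id):
                                best_ov, best_gene = ov, gene
            if best_ov >= min_antisense_overlap and best_gene is not None:
                label = "NAT"
                paired_gene[tx.id] = best_gene.id

        # 2. incRNA: span fully inside a single intron
        if label is None:
            itree = intron_trees.get(span.chrom)
            if itree is not None:
                hosts = []
                for hit_iv in itree.overlap(span.start, span.end):
                    gene, intron = hit_iv.data
                    if hit_iv.begin <= span.start and span.end <= hit_iv.end:
                        if intron_either_strand or intron.strand == span.strand:
                            hosts.append(gene)
                if hosts:
                    label = "incRNA"
                    paired_gene[tx.id] = min(h.id for h in hosts)

        # 3. intergenic rules
        if label is None:
            stree = span_trees.get(span.chrom)
            genic = stree is not None and bool(stree.overlap(span.start, span.end))
            if not genic:
                if best_evalue.get(tx.id, math.inf) <= evalue_cutoff:
                    label = "putative_mRNA"
                elif tx.length > MIN_LNCRNA_LENGTH:
                    label = "lincRNA"

        if label in ("NAT", "incRNA") and tx.length <= MIN_LNCRNA_LENGTH:
            label = None
            paired_gene.pop(tx.id, None)

        labeled.append(tx.with_label(label or "unclassified"))

    if n_unknown_chrom:
        logger.warning(
            "classify_transcripts: %d transcripts on chromosomes absent from the "
            "gene annotation were left unclassified",
            n_unknown_chrom,
        )
    return labeled, paired_gene


def exon_count_distribution(
    transcripts: Sequence[TranscriptModel],
    max_exons: int = 4,
) -> pd.DataFrame:
    """Per-class fractions of transcripts with 1, 2, ... >=``max_exons`` exons."""
    by_class: Dict[str, List[int]] = {}
    for tx in transcripts:
        by_class.setdefault(tx.class_label, []).append(tx.n_exons)
    cols = [str(i) for i in range(1, max_exons)] + [f"{max_exons}+"]
    rows = {}
    for cls, counts in sorted(by_class.items()):
        if not counts:
            logger.warning("exon_count_distribution: class %s empty, omitted", cls)
            continue
        arr = np.asarray(counts)
        fracs = [np.mean(arr == i) for i in range(1, max_exons)]
        fracs.append(np.mean(arr >= max_exons))
        rows[cls] = fracs
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "class"
    return df


def length_summary(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Per-class transcript-length summary (nt; length = sum of exon lengths)."""
    by_class: Dict[str, List[int]] = {}
    for tx in transcripts:
        by_class.setdefault(tx.class_label, []).append(tx.length)
    rows = []
    for cls, lengths in sorted(by_class.items()):
        arr = np.asarray(lengths, dtype=float)
        rows.append(
            {
                "class": cls,
                "n": len(arr),
                "mean_nt": float(arr.mean()),
                "median_nt": float(np.median(arr)),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def nearest_gene_distances(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
) -> np.ndarray:
    """Distance (bp) from each transcript span to the nearest gene span.

    0 when overlapping a gene; strand is ignored; ``inf`` when the
    transcript's chromosome carries no gene.
    """
    starts_by_chrom: Dict[str, np.ndarray] = {}
    ends_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in {g.interval.chrom for g in genes}:
        spans = [(g.interval.start, g.interval.end) for g in genes if g.interval.chrom == chrom]
        starts_by_chrom[chrom] = np.sort(np.array([s for s, _ in spans]))
        ends_by_chrom[chrom] = np.sort(np.array([e for _, e in spans]))
    span_trees = _span_tree_by_chrom(list(genes))

    out = np.empty(len(transcripts))
    for i, tx in enumerate(transcripts):
        span = tx.interval
        starts = starts_by_chrom.get(span.chrom)
        if starts is None:
            out[i] = math.inf
            continue
        tree = span_trees[span.chrom]
        if tree.overlap(span.start, span.end):
            out[i] = 0.0
            continue
        ends = ends_by_chrom[span.chrom]
        best = math.inf
        # nearest gene entirely to the right
        j = np.searchsorted(starts, span.end, side="left")
        if j < len(starts):
            best = min(best, float(starts[j] - span.end))
        # nearest gene entirely to the left
        j = np.searchsorted(ends, span.start, side="right")
        if j > 0:
            best = min(best, float(span.start - ends[j - 1]))
        out[i] = best
    return out


def distance_bin_proportions(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    bins: Optional[DistanceBinSpec] = None,
) -> pd.DataFrame:
    """Per-class proportions of transcripts in each distance-to-gene bin."""
    bins = bins or DistanceBinSpec()
    distances = nearest_gene_distances(transcripts, genes)
    rows: Dict[str, np.ndarray] = {}
    by_class: Dict[str, List[int]] = {}
    for i, tx in enumerate(transcripts):
        by_class.setdefault(tx.class_label, []).append(i)
    for cls, idx in sorted(by_class.items()):
        counts = np.zeros(len(bins.labels))
        for i in idx:
            counts[bins.bin_index(distances[i])] += 1
        rows[cls] = counts / counts.sum()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(bins.labels))
    df.index.name = "class"
    return df
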