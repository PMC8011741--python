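"""Per-transcript IRR and H3K27me3 status and class-by-mark stratification.

"Overlap" means >= 1 bp of shared sequence between the transcript span and
an annotated interval (configurable as a bp minimum or a fraction of the
transcript). Percentages are reported to one decimal, rounded half away
from zero, matching the survey's printed style (e.g. 66 of 92 -> 71.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import GenomicInterval, GenomeIndex, merge_by_chrom, overlap_length
from .models import SmallRNAAlignment, TranscriptModel
from .sirna import sirna_status_table

logger = logging.getLogger("lncepi")

MARKS = ("irr", "sirna", "k27")


def percent1(numerator: int, denominator: int) -> float:
    """100 * n / d rounded half-away-from-zero to one decimal."""
    if denominator == 0:
        raise ValueError("denominator must be > 0")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _min_overlap_bp(transcript: TranscriptModel, min_overlap, min_fraction) -> int:
    if min_fraction is not None:
        return max(1, int(min_fraction * transcript.interval.length))
    return min_overlap


def _mark_status(
    transcript: TranscriptModel,
    index: GenomeIndex,
    min_overlap: int = 1,
    min_fraction: Optional[float] = None,
    stranded: bool = False,
    exons_only: bool = False,
) -> bool:
    need = _min_overlap_bp(transcript, min_overlap, min_fraction)
    targets = transcript.exons if exons_only else (transcript.interval,)
    total = 0
    for target in targets:
        for hit in index.overlapping(target, stranded=stranded):
            total += overlap_length(target, hit, stranded=stranded)
            if total >= need:
                return True
    return False


def irr_status(transcript, irrs, **kwargs) -> bool:
    """True iff the transcript overlaps an inverted-repeat annotation."""
    index = irrs if isinstance(irrs, GenomeIndex) else GenomeIndex(irrs)
    return _mark_status(transcript, index, **kwargs)


def k27_status(transcript, domains, **kwargs) -> bool:
    """True iff the transcript overlaps an H3K27me3 domain."""
    index = domains if isinstance(domains, GenomeIndex) else GenomeIndex(domains)
    return _mark_status(transcript, index, **kwargs)


@dataclass(frozen=True)
class MarkStatus:
    transcript_id: str
    irr: bool
    sirna: bool
    k27: bool


def mark_status_table(
    transcripts: Sequence[TranscriptModel],
    irrs: Iterable[GenomicInterval] = (),
    reads24: Sequence[SmallRNAAlignment] = (),
    k27_domains: Iterable[GenomicInterval] = (),
    sirna_mode: str = "containment",
    min_overlap: int = 1,
    min_fraction: Optional[float] = None,
    stranded: bool = False,
    exons_only: bool = False,
) -> pd.DataFrame:
    """Per-transcript class and IRR/siRNA/H3K27me3 booleans."""
    irr_index = GenomeIndex(irrs)
    k27_index = GenomeIndex(k27_domains)
    sirna_map = sirna_status_table(transcripts, reads24, mode=sirna_mode, stranded=stranded)
    rows = []
    for tx in transcripts:
        rows.append(
            {
                "transcript_id": tx.id,
                "class": tx.class_label,
                "irr": _mark_status(tx, irr_index, min_overlap, min_fraction, stranded, exons_only),
                "sirna": sirna_map[tx.id],
                "k27": _mark_status(tx, k27_index, min_overlap, min_fraction, stranded, exons_only),
            }
        )
    return pd.DataFrame(rows)


def stratify(
    status_df: pd.DataFrame,
    classes: Optional[Sequence[str]] = None,
    marks: Sequence[str] = MARKS,
) -> pd.DataFrame:
    """Long-format counts and one-decimal percentages per class x mark x status."""
    if classes is None:
        classes = sorted(status_df["class"].unique())
    rows = []
    for cls in classes:
        sub = status_df[status_df["class"] == cls]
        total = len(sub)
        if total == 0:
            logger.warning("stratify: class %s empty, row omitted", cls)
            continue
        for mark in marks:
            pos = int(sub[mark].sum())
            for status, count in (("+", pos), ("-", total - pos)):
                rows.append(
                    {
                        "class": cls,
                        "mark": mark,
                        "status": status,
                        "count": count,
                        "total": total,
                        "percent": percent1(count, total),
                    }
                )
    return pd.DataFrame(rows)


def joint_irr_sirna(
    status_df: pd.DataFrame, classes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Joint IRR x siRNA counts per class, plus the conditional fraction
    of siRNA-overlapping transcripts that also harbor IRRs."""
    if classes is None:
        classes = sorted(status_df["class"].unique())
    rows = []
    for cls in classes:
        sub = status_df[status_df["class"] == cls]
        if len(sub) == 0:
            continue
        n_pp = int((sub["irr"] & sub["sirna"]).sum())
        n_pm = int((sub["irr"] & ~sub["sirna"]).sum())
        n_mp = int((~sub["irr"] & sub["sirna"]).sum())
        n_mm = int((~sub["irr"] & ~sub["sirna"]).sum())
        n_sirna = n_pp + n_mp
        rows.append(
            {
                "class": cls,
                "irr+sirna+": n_pp,
                "irr+sirna-": n_pm,
                "irr-sirna+": n_mp,
                "irr-sirna-": n_mm,
                "pct_irr_given_sirna": percent1(n_pp, n_sirna) if n_sirna else float("nan"),
                "pct_irr": percent1(n_pp + n_pm, len(sub)),
            }
        )
    return pd.DataFrame(rows)


def domains_from_bedgraph(
    entries: Sequence[Tuple[GenomicInterval, float]],
    min_value: float,
    min_width: int = 200,
    merge_gap: int = 100,
) -> List[GenomicInterval]:
    """Convenience domain caller: threshold a coverage bedGraph.

    Keeps intervals with value >= ``min_value``, merges runs separated by
    <= ``merge_gap`` bp, and drops merged domains shorter than
    ``min_width``. This is a simple threshold deriver, not a peak caller
    with a background model.
    """
    passing = [iv for iv, value in entries if value >= min_value]
    merged = merge_by_chrom(passing, gap=merge_gap)
    return [iv for iv in merged if iv.length >= min_width]
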