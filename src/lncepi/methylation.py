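"""Per-site and per-region DNA methylation levels in CG/CHG/CHH contexts.

The site-level statistic is mC / (mC + umC). Regions aggregate by the
read-weighted level sum(mC) / sum(mC + umC) over covered sites of one
context, pooling both strands; this is additive across sub-regions and
robust at low coverage. Zero-coverage sites are excluded, never counted
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .models import CONTEXTS, CytosineRecord


def site_level(rec: CytosineRecord) -> Optional[float]:
    """Methylation level at one cytosine; None when the site has no reads."""
    total = rec.mc + rec.umc
    if total == 0:
        return None
    return rec.mc / total


@dataclass(frozen=True)
class RegionMethylation:
    """Weighted methylation level of one region in one context."""

    region: GenomicInterval
    context: str
    level: Optional[float]  # None when no covered site falls in the region
    covered_sites: int
    total_reads: int
    methylated_reads: int


class CytosineIndex:
    """Position-sorted per-(chromosome, context) arrays of cytosine counts.

    ``min_coverage`` (default 1) drops sites with fewer total reads from
    all aggregates, implementing the no-filter default while excluding
    zero-coverage sites.
    """

    def __init__(self, records: Iterable[CytosineRecord], min_coverage: int = 1):
        buckets: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = {}
        for rec in records:
            if rec.coverage < min_coverage:
                continue
            key = (rec.position.chrom, rec.context)
            buckets.setdefault(key, []).append((rec.position.start, rec.mc, rec.umc))
        self._data: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, rows in buckets.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            mc = np.array([r[1] for r in rows], dtype=np.int64)
            tot = np.array([r[1] + r[2] for r in rows], dtype=np.int64)
            self._data[key] = (pos, mc, tot)

    def window_counts(
        self, chrom: str, start: int, end: int, context: str
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, mc, total) arrays for sites in [start, end)."""
        data = self._data.get((chrom, context))
        if data is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        pos, mc, tot = data
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], mc[lo:hi], tot[lo:hi]

    def region_level(self, region: GenomicInterval, context: str) -> RegionMethylation:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        _, mc, tot = self.window_counts(region.chrom, region.start, region.end, context)
        n_sites = len(mc)
        mc_sum = int(mc.sum())
        tot_sum = int(tot.sum())
        level = mc_sum / tot_sum if tot_sum > 0 else None
        return RegionMethylation(region, context, level, n_sites, tot_sum, mc_sum)


def region_level(
    records_or_index, region: GenomicInterval, context: str
) -> RegionMethylation:
    """Weighted methylation level of one region (builds an index if needed)."""
    index = (
        records_or_index
        if isinstance(records_or_index, CytosineIndex)
        else CytosineIndex(records_or_index)
    )
    return index.region_level(region, context)


def region_levels_table(
    index: CytosineIndex,
    regions: Sequence[Tuple[str, GenomicInterval]],
    contexts: Sequence[str] = CONTEXTS,
) -> pd.DataFrame:
    """Long-format table of (region_id, context, level, covered_sites, reads)."""
    rows = []
    for region_id, region in regions:
        for context in contexts:
            rm = index.region_level(region, context)
            rows.append(
                {
                    "region_id": region_id,
                    "context": context,
                    "level": np.nan if rm.level is None else rm.level,
                    "covered_sites": rm.covered_sites,
                    "total_reads": rm.total_reads,
                }
            )
    return pd.DataFrame(rows)
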