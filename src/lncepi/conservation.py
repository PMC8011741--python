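"""HSP chaining, query-coverage statistics, and RT-PCR band summaries.

For each (query, target genome) the best colinear chain of HSPs is chosen
by dynamic programming: HSPs are grouped by (subject sequence, strand),
sorted by query start, and a maximum-total-bitscore chain is selected in
which both query and subject coordinates advance monotonically and the
subject-side gap between successive HSPs is at most ``max_gap``. The chain
of the best-scoring group is the representative homologous region, and
coverage is the merged query-aligned length divided by the query length —
overlapping HSPs are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import HSPRecord

DEFAULT_MAX_GAP = 10_000
DEFAULT_EVALUE_CUTOFF = 1e-10

BAND_SYMBOLS = {"+++": "strong", "+": "weak", "-": "absent"}


@dataclass(frozen=True)
class HomologyCall:
    """The representative homologous region for one query in one genome."""

    query_id: str
    target_genome: str
    subject_id: Optional[str]
    strand: Optional[str]
    query_intervals: Tuple[Tuple[int, int], ...]  # merged, 1-based inclusive
    coverage: float
    total_score: float


def hsps_compatible(a: HSPRecord, b: HSPRecord, max_gap: int = DEFAULT_MAX_GAP) -> bool:
    """True when *b* may follow *a* in a colinear chain (same subject/strand)."""
    if a.subject_id != b.subject_id or a.strand != b.strand:
        return False
    if not (a.query_start < b.query_start and a.query_end < b.query_end):
        return False
    if a.strand == "+":
        if not (a.subject_low < b.subject_low and a.subject_high < b.subject_high):
            return False
        gap = b.subject_low - a.subject_high - 1
    else:
        if not (b.subject_low < a.subject_low and b.subject_high < a.subject_high):
            return False
        gap = a.subject_low - b.subject_high - 1
    return gap <= max_gap


def _best_chain(group: List[HSPRecord], max_gap: int) -> Tuple[List[HSPRecord], float]:
    """Maximum-total-bitscore colinear chain within one (subject, strand) group."""
    group = sorted(group, key=lambda h: (h.query_start, h.query_end, h.subject_low))
    n = len(group)
    score = [h.bitscore for h in group]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if hsps_compatible(group[i], group[j], max_gap):
                cand = score[i] + group[j].bitscore
                if cand > score[j]:
                    score[j] = cand
                    prev[j] = i
    best = int(np.argmax(score))
    chain = []
    k = best
    while k != -1:
        chain.append(group[k])
        k = prev[k]
    chain.reverse()
    return chain, score[best]


def _merge_1based(intervals: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    ivs = sorted(intervals)
    merged: List[List[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def chain_hsps(
    hsps: Sequence[HSPRecord],
    query_lengths: Mapping[str, int],
    target_genome: str = "",
    max_gap: int = DEFAULT_MAX_GAP,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> Dict[str, HomologyCall]:
    """One representative HomologyCall per query in ``query_lengths``.

    Duplicate HSP rows are deduplicated; HSPs above the e-value cutoff are
    ignored. Queries with no passing HSP get coverage 0.
    """
    kept = sorted(
        {h for h in hsps if h.evalue <= evalue_cutoff},
        key=lambda h: (h.query_id, h.subject_id, h.query_start, h.query_end, h.subject_low),
    )
    groups: Dict[Tuple[str, str, str], List[HSPRecord]] = {}
    for h in kept:
        if h.query_id not in query_lengths:
            continue
        groups.setdefault((h.query_id, h.subject_id, h.strand), []).append(h)

    best_by_query: Dict[str, Tuple[float, str, str, List[HSPRecord]]] = {}
    for (qid, sid, strand), group in groups.items():
        chain, total = _best_chain(group, max_gap)
        cur = best_by_query.get(qid)
        key = (-total, sid, strand)
        if cur is None or key < (-cur[0], cur[1], cur[2]):
            best_by_query[qid] = (total, sid, strand, chain)

    calls: Dict[str, HomologyCall] = {}
    for qid in sorted(query_lengths):
        qlen = query_lengths[qid]
        if qlen <= 0:
            raise ValueError(f"query {qid}: non-positive length")
        if qid not in best_by_query:
            calls[qid] = HomologyCall(qid, target_genome, None, None, (), 0.0, 0.0)
            continue
        total, sid, strand, chain = best_by_query[qid]
        merged = _merge_1based((h.query_start, h.query_end) for h in chain)
        aligned = sum(e - s + 1 for s, e in merged)
        calls[qid] = HomologyCall(
            qid, target_genome, sid, strand, merged, min(1.0, aligned / qlen), total
        )
    return calls


def coverage_summary(
    calls_by_genome: Mapping[str, Mapping[str, HomologyCall]],
    classes: Mapping[str, str],
    thresholds: Sequence[float] = (0.5, 0.9),
) -> pd.DataFrame:
    """Coverage distribution per class x target genome."""
    rows = []
    for genome in sorted(calls_by_genome):
        calls = calls_by_genome[genome]
        by_class: Dict[str, List[float]] = {}
        for qid, call in calls.items():
            cls = classes.get(qid)
            if cls is None:
                continue
            by_class.setdefault(cls, []).append(call.coverage)
        for cls in sorted(by_class):
            cov = np.asarray(by_class[cls])
            row = {
                "genome": genome,
                "class": cls,
                "n": len(cov),
                "mean": float(cov.mean()),
                "q25": float(np.percentile(cov, 25)),
                "median": float(np.median(cov)),
                "q75": float(np.percentile(cov, 75)),
            }
            for thr in thresholds:
                row[f"frac_ge_{thr:g}"] = float(np.mean(cov >= thr))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BandGroupSummary:
    group: str
    n_lines: int
    n_rows: int
    strong_in_all: int
    strong_in_exactly: Dict[int, int]  # k -> number of rows strong in exactly k lines
    no_strong: int  # rows with no strong band in any line of the group


def band_summary(
    matrix: pd.DataFrame, line_groups: Mapping[str, Sequence[str]]
) -> Dict[str, BandGroupSummary]:
    """Summarize an RT-PCR band matrix per group of lines.

    "Expressed" means a strong band (``+++``); weak bands count as not
    expressed, the only reading under which the survey's printed totals
    match its matrix.
    """
    for value in matrix.to_numpy().ravel():
        if value not in BAND_SYMBOLS:
            raise ValueError(f"unknown band symbol {value!r}")
    out = {}
    for group, lines in line_groups.items():
        missing = [line for line in lines if line not in matrix.columns]
        if missing:
            raise ValueError(f"group {group}: lines absent from matrix: {missing}")
        sub = matrix[list(lines)]
        strong_counts = (sub == "+++").sum(axis=1)
        n = len(lines)
        exactly = {k: int((strong_counts == k).sum()) for k in range(n + 1)}
        out[group] = BandGroupSummary(
            group=group,
            n_lines=n,
            n_rows=len(sub),
            strong_in_all=exactly[n],
            strong_in_exactly=exactly,
            no_strong=exactly[0],
        )
    return out


def band_summary_frame(summaries: Mapping[str, BandGroupSummary]) -> pd.DataFrame:
    rows = []
    for group, s in summaries.items():
        for k in sorted(s.strong_in_exactly):
            rows.append(
                {
                    "group": group,
                    "n_lines": s.n_lines,
                    "strong_in_k_lines": k,
                    "n_lncRNAs": s.strong_in_exactly[k],
                }
            )
    return pd.DataFrame(rows)
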