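"""Stratified expression comparisons and class-wise length ANOVA.

Expression comparisons use a two-sided pooled-variance (Student) t-test on
per-transcript mean FPKM between mark-positive and mark-negative strata
within each class. Transcripts, not replicates, are the sampling unit, so
replicates are averaged per transcript before testing. Raw FPKM is the
default; log2(FPKM + 1) is available by flag.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionRecord

logger = logging.getLogger("lncepi")


def significance_stars(p: Optional[float]) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class StrataTestResult:
    class_label: str
    mark: str
    n_pos: int
    n_neg: int
    mean_pos: float
    mean_neg: float
    t: Optional[float]
    p: Optional[float]
    stars: str


def strata_compare(
    values_pos: Sequence[float], values_neg: Sequence[float]
) -> Tuple[Optional[float], Optional[float]]:
    """Two-sided pooled-variance t-test; (None, None) if a stratum has < 2."""
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None, None
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # identical constant strata: no evidence of difference
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_by_mark(
    expr: Dict[str, float],
    status_df: pd.DataFrame,
    mark: str,
    class_label: str,
    log2: bool = False,
) -> StrataTestResult:
    """Mark-positive vs mark-negative expression within one class."""
    sub = status_df[status_df["class"] == class_label]
    pos, neg = [], []
    for _, row in sub.iterrows():
        value = expr.get(row["transcript_id"])
        if value is None:
            continue
        value = math.log2(value + 1.0) if log2 else value
        (pos if row[mark] else neg).append(value)
    t, p = strata_compare(pos, neg)
    if t is None:
        logger.info(
            "compare_by_mark: %s/%s stratum with < 2 members, test skipped",
            class_label,
            mark,
        )
    return StrataTestResult(
        class_label,
        mark,
        len(pos),
        len(neg),
        float(np.mean(pos)) if pos else math.nan,
        float(np.mean(neg)) if neg else math.nan,
        t,
        p,
        significance_stars(p) if p is not None else "NA",
    )


def expression_table(
    records: Iterable[ExpressionRecord],
    status_df: pd.DataFrame,
    marks: Sequence[str] = ("irr", "sirna", "k27"),
    classes: Optional[Sequence[str]] = None,
    log2: bool = False,
) -> pd.DataFrame:
    """All class x mark strata tests as one table."""
    expr = {rec.transcript_id: rec.mean for rec in records}
    if classes is None:
        classes = sorted(status_df["class"].unique())
    rows = []
    for cls in classes:
        for mark in marks:
            res = compare_by_mark(expr, status_df, mark, cls, log2=log2)
            rows.append(
                {
                    "class": res.class_label,
                    "mark": res.mark,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "mean_pos": res.mean_pos,
                    "mean_neg": res.mean_neg,
                    "t": math.nan if res.t is None else res.t,
                    "p": math.nan if res.p is None else res.p,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    letters: Dict[str, str]  # class -> letter group(s), shared letter = not distinguishable


def anova_lengths(
    lengths_by_class: Dict[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA across classes plus Bonferroni letter grouping.

    Classes with fewer than 2 members are excluded with a warning. Letter
    groups come from pairwise pooled t-tests at ``alpha`` with Bonferroni
    correction over all pairs: classes sharing a letter are not
    significantly different.
    """
    groups = {}
    for cls, values in lengths_by_class.items():
        if len(values) < 2:
            logger.warning("anova_lengths: class %s has < 2 members, excluded", cls)
            continue
        groups[cls] = np.asarray(values, dtype=float)
    if len(groups) < 2:
        raise ValueError("anova_lengths requires >= 2 classes with >= 2 members")

    names = sorted(groups)
    arrays = [groups[name] for name in names]
    grand = np.concatenate(arrays)
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ss_between <= 1e-12 * max(1.0, float(np.abs(grand).max()) ** 2):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
        F, p = float(F), float(p)

    # pairwise tests with Bonferroni correction
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    different = set()
    for a, b in pairs:
        t, pr = strata_compare(groups[a], groups[b])
        if pr is not None and min(1.0, pr * m) < alpha:
            different.add((a, b))
            different.add((b, a))

    # sweep letter assignment over classes sorted by mean
    order = sorted(names, key=lambda n: -groups[n].mean())
    runs: List[Tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            (order[k], order[j + 1]) not in different for k in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters: Dict[str, str] = {name: "" for name in order}
    for letter_idx, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for k in range(lo, hi + 1):
            letters[order[k]] += letter
    return AnovaResult(F, p, letters)
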