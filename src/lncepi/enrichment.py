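"""GO-term over-representation by hypergeometric test with BH-FDR control.

The background population is an explicit input (all annotated genes
supplied), and terms are tested as given — no ancestor propagation unless
the optional pre-pass is applied to the gene->term map first. Both the
FDR-significant set (default 1%) and a star-coded column at 0.05/0.01/0.001
are emitted, since published figures often report stars while the stated
control level is an FDR.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import significance_stars

DEFAULT_ALPHA_FDR = 0.01


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a study set of size ``n`` drawn from a
    population of ``N`` genes of which ``K`` carry the term. Computed in
    log-space via the survival function for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def propagate_terms(
    go_map: Mapping[str, Iterable[str]], parents: Mapping[str, Iterable[str]]
) -> Dict[str, Tuple[str, ...]]:
    """Optional pre-pass: extend each gene's terms with all ancestors."""
    out = {}
    for gene, terms in go_map.items():
        seen = set()
        stack = list(terms)
        while stack:
            term = stack.pop()
            if term in seen:
                continue
            seen.add(term)
            stack.extend(parents.get(term, ()))
        out[gene] = tuple(sorted(seen))
    return out


def enrich(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    go_map: Mapping[str, Iterable[str]],
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
    term_names: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term with a study hit.

    Gene lists are deduplicated; the study set must be a subset of the
    population. Returns a table sorted by q-value with columns term_id,
    term_name, k, n, K, N, p_value, q_value, significant, stars.
    """
    study = sorted(set(study_genes))
    population = sorted(set(population_genes))
    pop_set = set(population)
    offenders = [g for g in study if g not in pop_set]
    if offenders:
        raise ValueError(f"study genes missing from population: {offenders}")

    N = len(population)
    n = len(study)
    study_set = set(study)
    pop_hits: Dict[str, int] = {}
    study_hits: Dict[str, int] = {}
    for gene in population:
        for term in set(go_map.get(gene, ())):
            pop_hits[term] = pop_hits.get(term, 0) + 1
            if gene in study_set:
                study_hits[term] = study_hits.get(term, 0) + 1

    terms = sorted(study_hits)  # only terms with >= 1 study hit are tested
    rows = []
    for term in terms:
        k = study_hits[term]
        K = pop_hits[term]
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_upper(k, n, K, N),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] <= alpha_fdr
        df["stars"] = [significance_stars(p) for p in df["p_value"]]
        df = df.sort_values(["q_value", "p_value", "term_id"]).reset_index(drop=True)
    else:
        df["q_value"] = []
        df["significant"] = []
        df["stars"] = []
    return df
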