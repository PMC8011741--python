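"""Hypergeometric tail vs exact rational enumeration, BH-FDR, enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from lncepi.enrichment import bh_fdr, enrich, hypergeom_upper


def _exact_tail(k, n, K, N) -> Fraction:
    """Exact rational upper-tail hypergeometric probability."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def test_hypergeom_trivial_cases():
    assert hypergeom_upper(0, 5, 5, 20) == 1.0
    assert hypergeom_upper(5, 5, 5, 5) == 1.0  # forced full overlap


def test_hypergeom_worked_example():
    # N=20, K=5, n=5, k=3 -> 1126/15504
    expected = Fraction(1126, 15504)
    assert _exact_tail(3, 5, 5, 20) == expected
    assert hypergeom_upper(3, 5, 5, 20) == pytest.approx(float(expected), rel=1e-12)


def test_hypergeom_matches_rational_enumeration():
    rng = np.random.default_rng(31)
    for _ in range(300):
        N = int(rng.integers(1, 61))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(n, K) + 1))
        assert hypergeom_upper(k, n, K, N) == pytest.approx(
            float(_exact_tail(k, n, K, N)), rel=1e-10, abs=1e-300
        )


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeom_upper(6, 5, 5, 20)
    with pytest.raises(ValueError):
        hypergeom_upper(1, 5, 25, 20)


def test_bh_hand_examples():
    assert bh_fdr([0.03]).tolist() == [0.03]
    # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 then cumulative min from the top
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    assert bh_fdr([]).size == 0
    # monotone non-decreasing in rank order and q >= p
    p = np.array([0.001, 0.2, 0.04, 0.8, 0.011])
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= p - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])


def test_enrich_study_equals_population():
    genes = [f"g{i}" for i in range(20)]
    go = {g: ("GO:1",) for g in genes}
    df = enrich(genes, genes, go)
    assert (df["p_value"] == 1.0).all()


def test_enrich_planted_term_ranks_first():
    """A term covering 80% of a 50-gene study set but 10% of a 1,000-gene
    population tops the table and passes 1% FDR."""
    rng = np.random.default_rng(13)
    population = [f"g{i}" for i in range(1_000)]
    study = population[:50]
    go = {}
    for i, g in enumerate(population):
        terms = []
        if (g in set(study) and rng.random() < 0.8) or (
            g not in set(study) and rng.random() < 0.1
        ):
            terms.append("GO:PLANTED")
        for t in range(5):
            if rng.random() < 0.1:
                terms.append(f"GO:BG{t}")
        go[g] = tuple(terms)
    df = enrich(study, population, go, alpha_fdr=0.01)
    assert df.iloc[0]["term_id"] == "GO:PLANTED"
    assert bool(df.iloc[0]["significant"])


def test_enrich_errors_and_invariances():
    population = ["a", "b", "c", "d"]
    go = {"a": ("GO:1",), "b": ("GO:1",), "c": (), "d": ("GO:2",)}
    with pytest.raises(ValueError, match="missing from population"):
        enrich(["z"], population, go)
    df1 = enrich(["a", "b"], population, go)
    df2 = enrich(["b", "a", "a"], list(reversed(population)) + ["a"], go)
    assert df1.equals(df2)
    # zero-study-hit terms are not tested
    assert "GO:2" not in set(df1["term_id"])


def test_null_fdr_control():
    """Random study sets: the average fraction of terms passing 1% FDR stays
    near the nominal level."""
    rng = np.random.default_rng(99)
    population = [f"g{i}" for i in range(300)]
    go = {g: tuple(f"GO:{t}" for t in range(12) if rng.random() < 0.15) for g in population}
    frac_passing = []
    for _ in range(200):
        study = list(rng.choice(population, size=30, replace=False))
        df = enrich(study, population, go, alpha_fdr=0.01)
        if len(df):
            frac_passing.append(df["significant"].mean())
    assert np.mean(frac_passing) <= 0.02


def test_enriched_term_recovered_from_synthetic_go_map(dataset):
    outdir, manifest = dataset
    from lncepi import io

    go_map = io.read_go_map(outdir / "go_map.tsv")
    genes, _ = io.read_gff(outdir / "genes.gff3")
    population = sorted(g.id for g in genes)
    study = manifest.meta["incRNA_host_genes"]
    df = enrich(study, population, go_map, alpha_fdr=0.01)
    assert df.iloc[0]["term_id"] == manifest.meta["enriched_term"]
    assert bool(df.iloc[0]["significant"])
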