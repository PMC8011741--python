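"""Metagene binning: orientation, conservation of totals, aggregation."""

import numpy as np
import pytest

from lncepi.intervals import GenomicInterval
from lncepi.metaprofile import (
    CoverageSignal,
    MethylationSignal,
    ProfileSpec,
    aggregate_profiles,
    feature_profile,
)
from lncepi.methylation import CytosineIndex
from lncepi.models import CytosineRecord

SIZES = {"A01": 100_000}


def _uniform_signal(value=1.0):
    num = {"A01": np.full(SIZES["A01"], value)}
    den = {"A01": np.ones(SIZES["A01"])}
    from lncepi.metaprofile import DenseSignal

    return DenseSignal(num, den)


def test_uniform_signal_gives_flat_profile():
    spec = ProfileSpec(body_bins=10, flank_bp=500, flank_bins=5)
    prof = feature_profile(GenomicInterval("A01", 10_000, 11_003, "+"), _uniform_signal(), spec)
    assert prof.shape == (20,)
    assert np.allclose(prof, 1.0)


def test_minus_strand_mirrors_plus_strand():
    """An ascending positional signal yields a descending bin vector on the
    minus strand — exactly the reverse of the plus-strand vector, checked
    against a brute-force per-base binning oracle."""
    ramp = {"A01": np.arange(SIZES["A01"], dtype=float)}
    den = {"A01": np.ones(SIZES["A01"])}
    from lncepi.metaprofile import DenseSignal

    signal = DenseSignal(ramp, den)
    spec = ProfileSpec(body_bins=7, flank_bp=300, flank_bins=3)
    plus = feature_profile(GenomicInterval("A01", 20_000, 20_947, "+"), signal, spec)
    minus = feature_profile(GenomicInterval("A01", 20_000, 20_947, "-"), signal, spec)
    assert np.allclose(minus, plus[::-1])
    assert (np.diff(plus) > 0).all()
    # brute-force oracle: split the window positions with np.array_split
    window = np.arange(20_000 - 300, 20_947 + 300, dtype=float)
    chunks = (
        np.array_split(window[:300], 3)
        + np.array_split(window[300:-300], 7)
        + np.array_split(window[-300:], 3)
    )
    oracle = np.array([c.mean() for c in chunks])
    assert np.allclose(plus, oracle)


def test_double_reversal_is_identity():
    spec = ProfileSpec(body_bins=5, flank_bp=100, flank_bins=2)
    iv_minus = GenomicInterval("A01", 5_000, 5_500, "-")
    once = feature_profile(iv_minus, _uniform_signal(2.0), spec)
    assert np.allclose(once[::-1][::-1], once)


def test_binning_conserves_totals_for_count_signals():
    """sum(bin mean x bin width) over the body equals the body read total."""
    rng = np.random.default_rng(5)
    num = {"A01": np.zeros(SIZES["A01"])}
    starts = rng.integers(9_000, 12_000, size=200)
    for s in starts:
        num["A01"][s : s + 24] += 1
    den = {"A01": np.ones(SIZES["A01"])}
    from lncepi.metaprofile import DenseSignal

    signal = DenseSignal(num, den)
    spec = ProfileSpec(body_bins=13, flank_bp=0, flank_bins=1)
    feature = GenomicInterval("A01", 9_000, 12_100, "+")
    prof = feature_profile(feature, signal, spec)
    body = prof[1:-1]
    # reconstruct widths the same way the binner spreads the remainder
    base, rem = divmod(feature.length, 13)
    widths = np.array([base + 1] * rem + [base] * (13 - rem))
    assert np.nansum(body * widths) == pytest.approx(num["A01"][9_000:12_100].sum())


def test_flank_truncation_at_chromosome_edge():
    spec = ProfileSpec(body_bins=4, flank_bp=1_000, flank_bins=4)
    prof = feature_profile(GenomicInterval("A01", 0, 400, "+"), _uniform_signal(), spec)
    assert np.isnan(prof[:4]).all()  # 5' flank entirely off-chromosome
    assert np.allclose(prof[4:], 1.0)


def test_aggregate_means_and_single_feature_identity():
    from lncepi.metaprofile import DenseSignal

    num = {"A01": np.concatenate([np.ones(50_000), np.full(50_000, 3.0)])}
    den = {"A01": np.ones(SIZES["A01"])}
    signal = DenseSignal(num, den)
    spec = ProfileSpec(body_bins=6, flank_bp=100, flank_bins=2)
    f1 = GenomicInterval("A01", 10_000, 10_600, "+")
    f2 = GenomicInterval("A01", 80_000, 80_600, "+")
    agg = aggregate_profiles([f1, f2], signal, spec)
    assert np.allclose(agg.values, 2.0)
    assert agg.n_features == 2
    single = aggregate_profiles([f1], signal, spec)
    assert np.allclose(single.values, feature_profile(f1, signal, spec))


def test_methylation_profile_body_vs_flank_shape():
    """Signal planted only in the flanks yields higher flank bins than body
    bins (the flank-elevated shape seen for intergenic lncRNA methylation)."""
    records = []
    for pos in range(0, 3_000, 10):
        inside_body = 1_000 <= pos < 2_000
        level = 0.05 if inside_body else 0.6
        records.append(
            CytosineRecord(GenomicInterval("A01", pos, pos + 1, "+"), "CHH", int(20 * level), 20 - int(20 * level))
        )
    signal = MethylationSignal(CytosineIndex(records), "CHH")
    spec = ProfileSpec(body_bins=5, flank_bp=1_000, flank_bins=5)
    prof = feature_profile(GenomicInterval("A01", 1_000, 2_000, "+"), signal, spec)
    assert np.nanmax(prof[5:10]) < np.nanmin(prof[:5])
    assert np.nanmax(prof[5:10]) < np.nanmin(prof[10:])


def test_aggregate_requires_signal():
    from lncepi.metaprofile import DenseSignal

    empty = DenseSignal({}, {})
    with pytest.raises(ValueError, match="undefined"):
        aggregate_profiles([GenomicInterval("A01", 0, 100)], empty, ProfileSpec(2, 10, 1))
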