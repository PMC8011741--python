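"""Mark status, stratification counts, and one-decimal percentage style."""

import numpy as np
import pandas as pd
import pytest

from lncepi import io
from lncepi.intervals import GenomicInterval
from lncepi.marks import (
    domains_from_bedgraph,
    irr_status,
    joint_irr_sirna,
    k27_status,
    mark_status_table,
    percent1,
    stratify,
)
from lncepi.models import TranscriptModel
from lncepi.sirna import filter_24nt


def _tx(tid, start, end, chrom="A01", strand="+"):
    return TranscriptModel(
        tid,
        GenomicInterval(chrom, start, end, strand),
        (GenomicInterval(chrom, start, end, strand),),
    )


@pytest.mark.parametrize(
    "n, d, expected",
    [
        (763, 1173, 65.0),
        (291, 529, 55.0),
        (66, 92, 71.7),
        (219, 1173, 18.7),
        (74, 529, 14.0),
        (16, 92, 17.4),
        (127, 1173, 10.8),
        (83, 529, 15.7),
        (15, 92, 16.3),
        (314, 490, 64.1),
        (53, 490, 10.8),
        (1, 3, 33.3),
        (0, 10, 0.0),
    ],
)
def test_percent1_survey_style(n, d, expected):
    assert percent1(n, d) == expected


def test_percent1_zero_denominator():
    with pytest.raises(ValueError):
        percent1(1, 0)


def test_percent1_matches_integer_arithmetic_oracle():
    """Half-away-from-zero to one decimal, checked with exact integers."""
    rng = np.random.default_rng(12)
    for _ in range(1_000):
        d = int(rng.integers(1, 5_000))
        n = int(rng.integers(0, d + 1))
        q, r = divmod(1000 * n, d)
        expected = (q + (1 if 2 * r >= d else 0)) / 10
        assert percent1(n, d) == pytest.approx(expected), (n, d)


def test_irr_and_k27_status_cases():
    tx = _tx("T", 0, 500)
    assert irr_status(tx, [GenomicInterval("A01", 400, 600)]) is True
    assert irr_status(tx, [GenomicInterval("A01", 600, 700)]) is False
    assert k27_status(tx, [GenomicInterval("A01", 100, 200)]) is True
    assert k27_status(tx, [GenomicInterval("B02", 100, 200)]) is False
    # fraction-of-transcript threshold
    assert irr_status(tx, [GenomicInterval("A01", 0, 100)], min_fraction=0.5) is False
    assert irr_status(tx, [GenomicInterval("A01", 0, 400)], min_fraction=0.5) is True


def test_stratify_counts_and_percentages():
    df = pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(10)],
            "class": ["lincRNA"] * 10,
            "irr": [True] * 7 + [False] * 3,
            "sirna": [True] * 2 + [False] * 8,
            "k27": [False] * 10,
        }
    )
    table = stratify(df)
    row = table[(table["mark"] == "irr") & (table["status"] == "+")].iloc[0]
    assert row["count"] == 7 and row["percent"] == 70.0
    # counts over statuses sum to the class total for every mark
    sums = table.groupby("mark")["count"].sum()
    assert (sums == 10).all()
    k27_zero = table[(table["mark"] == "k27") & (table["status"] == "+")].iloc[0]
    assert k27_zero["percent"] == 0.0


def test_conditional_irr_given_sirna_exceeds_marginal(dataset):
    """With nested siRNA-in-IRR planting, the fraction of siRNA+ transcripts
    that harbor IRRs exceeds the marginal IRR fraction."""
    outdir, _ = dataset
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    from lncepi.classify import classify_transcripts

    genes, _ = io.read_gff(outdir / "genes.gff3")
    hits = io.read_coding_hits(outdir / "coding_hits.tsv")
    labeled, _ = classify_transcripts(txs, genes, hits)
    reads24 = filter_24nt(io.read_srna_table(outdir / "srna_reads.tsv"))
    status = mark_status_table(
        labeled,
        irrs=io.read_bed(outdir / "irr.bed"),
        reads24=reads24,
        k27_domains=io.read_bed(outdir / "k27_domains.bed"),
    )
    joint = joint_irr_sirna(status, classes=["lincRNA"])
    row = joint.iloc[0]
    assert row["pct_irr_given_sirna"] > row["pct_irr"]


def test_mark_status_matches_manifest(dataset):
    outdir, manifest = dataset
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    reads24 = filter_24nt(io.read_srna_table(outdir / "srna_reads.tsv"))
    status = mark_status_table(
        txs,
        irrs=io.read_bed(outdir / "irr.bed"),
        reads24=reads24,
        k27_domains=io.read_bed(outdir / "k27_domains.bed"),
    ).set_index("transcript_id")
    truth = manifest.transcripts.set_index("transcript_id").reindex(status.index)
    for mark in ("irr", "sirna", "k27"):
        assert (status[mark].to_numpy() == truth[mark].to_numpy()).all(), mark


def test_domains_from_bedgraph_threshold():
    entries = [
        (GenomicInterval("A01", 0, 100), 5.0),
        (GenomicInterval("A01", 150, 400), 6.0),
        (GenomicInterval("A01", 1_000, 1_050), 9.0),  # too short after merging
        (GenomicInterval("A01", 2_000, 2_400), 1.0),  # below threshold
    ]
    domains = domains_from_bedgraph(entries, min_value=4.0, min_width=200, merge_gap=100)
    assert [(d.start, d.end) for d in domains] == [(0, 400)]
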