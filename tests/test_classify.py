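"""Positional classification rules, distributions, and distance binning."""

import math

import numpy as np
import pytest

from lncepi import io
from lncepi.classify import (
    DistanceBinSpec,
    classify_transcripts,
    distance_bin_proportions,
    exon_count_distribution,
    length_summary,
    nearest_gene_distances,
)
from lncepi.intervals import GenomicInterval
from lncepi.models import CodingHit, GeneModel, TranscriptModel


def _tx(tid, chrom, start, end, strand="+", exons=None):
    exons = exons or [(start, end)]
    return TranscriptModel(
        tid,
        GenomicInterval(chrom, start, end, strand),
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture()
def toy_genes():
    # gene with two exons and one 1 kb intron on '+'
    return [
        GeneModel(
            "G1",
            GenomicInterval("A01", 10_000, 13_000, "+"),
            (
                GenomicInterval("A01", 10_000, 11_000, "+"),
                GenomicInterval("A01", 12_000, 13_000, "+"),
            ),
        )
    ]


def test_definition_cases(toy_genes):
    txs = [
        _tx("intergenic_long", "A01", 20_000, 20_725),          # -> lincRNA
        _tx("antisense", "A01", 10_500, 11_600, strand="-"),    # -> NAT
        _tx("with_hit", "A01", 30_000, 30_900),                 # -> putative_mRNA
        _tx("in_intron", "A01", 11_200, 11_800),                # -> incRNA
        _tx("intergenic_short", "A01", 40_000, 40_180),         # 180 nt -> unclassified
        _tx("sense_exonic", "A01", 10_500, 11_600, strand="+"), # sense overlap -> unclassified
        _tx("alien_chrom", "Z99", 1_000, 2_000),                # unknown chrom -> unclassified
    ]
    hits = [CodingHit("with_hit", "sp|P1", 1e-12)]
    labeled, paired = classify_transcripts(txs, toy_genes, hits)
    got = {t.id: t.class_label for t in labeled}
    assert got == {
        "intergenic_long": "lincRNA",
        "antisense": "NAT",
        "with_hit": "putative_mRNA",
        "in_intron": "incRNA",
        "intergenic_short": "unclassified",
        "sense_exonic": "unclassified",
        "alien_chrom": "unclassified",
    }
    assert paired["antisense"] == "G1" and paired["in_intron"] == "G1"


def test_hit_above_cutoff_stays_lincRNA(toy_genes):
    tx = _tx("weak_hit", "A01", 20_000, 20_725)
    labeled, _ = classify_transcripts([tx], toy_genes, [CodingHit("weak_hit", "s", 1e-5)])
    assert labeled[0].class_label == "lincRNA"


def test_intron_strand_flag(toy_genes):
    tx = _tx("in_intron_rev", "A01", 11_200, 11_800, strand="-")
    either, _ = classify_transcripts([tx], toy_genes)
    assert either[0].class_label == "incRNA"
    same_only, _ = classify_transcripts([tx], toy_genes, intron_either_strand=False)
    assert same_only[0].class_label == "unclassified"


def test_every_transcript_gets_exactly_one_label(dataset):
    outdir, _ = dataset
    genes, _ = io.read_gff(outdir / "genes.gff3")
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    hits = io.read_coding_hits(outdir / "coding_hits.tsv")
    labeled, _ = classify_transcripts(txs, genes, hits)
    assert len(labeled) == len(txs)
    from lncepi.models import CLASS_LABELS

    assert all(t.class_label in CLASS_LABELS for t in labeled)


def test_planted_labels_recovered_fully(dataset):
    outdir, manifest = dataset
    genes, _ = io.read_gff(outdir / "genes.gff3")
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    hits = io.read_coding_hits(outdir / "coding_hits.tsv")
    labeled, _ = classify_transcripts(txs, genes, hits)
    truth = dict(zip(manifest.transcripts["transcript_id"], manifest.transcripts["class"]))
    mismatches = [(t.id, truth[t.id], t.class_label) for t in labeled if t.class_label != truth[t.id]]
    assert mismatches == []


def test_exon_count_distribution_fractions():
    txs = [
        _tx("a", "A", 0, 300),
        _tx("b", "A", 1_000, 1_300),
        _tx("c", "A", 2_000, 2_700, exons=[(2_000, 2_300), (2_400, 2_700)]),
    ]
    txs = [t.with_label("lincRNA") for t in txs]
    df = exon_count_distribution(txs)
    assert df.loc["lincRNA", "1"] == pytest.approx(2 / 3)
    assert df.loc["lincRNA"].sum() == pytest.approx(1.0)


def test_length_summary_mean():
    txs = [_tx("a", "A", 0, 100).with_label("mRNA"), _tx("b", "A", 500, 800).with_label("mRNA")]
    df = length_summary(txs)
    assert df.loc["mRNA", "mean_nt"] == pytest.approx(200.0)


def test_distance_examples(toy_genes):
    near = _tx("near", "A01", 9_000, 9_900)  # gap 100 to gene start 10000
    far = _tx("far", "A01", 38_000, 38_500)  # gap 25000
    overlapping = _tx("ov", "A01", 10_500, 11_500, strand="-")
    d = nearest_gene_distances([near, far, overlapping], toy_genes)
    assert d.tolist() == [100.0, 25_000.0, 0.0]
    spec = DistanceBinSpec()
    assert spec.bin_index(100) == 0     # [0, 2kb)
    assert spec.bin_index(25_000) == 4  # > 20 kb
    assert spec.bin_index(math.inf) == 4


def test_distance_matches_quadratic_oracle_and_mirror():
    rng = np.random.default_rng(9)
    L = 1_000_000
    genes = []
    for i in range(20):
        s = int(rng.integers(0, L - 5_000))
        genes.append(
            GeneModel(f"G{i}", GenomicInterval("A01", s, s + int(rng.integers(500, 3_000))),
                      (GenomicInterval("A01", s, s + 100),))
        )
    txs = []
    for i in range(50):
        s = int(rng.integers(0, L - 2_000))
        txs.append(_tx(f"T{i}", "A01", s, s + int(rng.integers(200, 1_500))))
    d = nearest_gene_distances(txs, genes)
    # quadratic all-pairs oracle
    for i, tx in enumerate(txs):
        best = math.inf
        for g in genes:
            a, b = tx.interval, g.interval
            if a.start < b.end and b.start < a.end:
                best = 0.0
            else:
                best = min(best, float(max(b.start - a.end, a.start - b.end)))
        assert d[i] == best
    # mirror symmetry: reflect every coordinate about L
    mirror = lambda iv: GenomicInterval(iv.chrom, L - iv.end, L - iv.start, iv.strand)
    m_genes = [GeneModel(g.id, mirror(g.interval), (mirror(g.interval),)) for g in genes]
    m_txs = [
        TranscriptModel(t.id, mirror(t.interval), (mirror(t.interval),)) for t in txs
    ]
    assert nearest_gene_distances(m_txs, m_genes).tolist() == d.tolist()


def test_distance_bin_proportions_sum_to_one(dataset):
    outdir, _ = dataset
    genes, _ = io.read_gff(outdir / "genes.gff3")
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    hits = io.read_coding_hits(outdir / "coding_hits.tsv")
    labeled, _ = classify_transcripts(txs, genes, hits)
    df = distance_bin_proportions(labeled, genes)
    assert np.allclose(df.sum(axis=1), 1.0)
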