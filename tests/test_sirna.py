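"""24-nt filtering, RPM, cluster calling vs a transitive-closure oracle,
and the containment overlap criterion."""

import numpy as np
import pytest

from lncepi import io
from lncepi.intervals import GenomicInterval
from lncepi.models import SmallRNAAlignment, TranscriptModel
from lncepi.sirna import (
    call_clusters,
    filter_24nt,
    rpm,
    sirna_overlap_status,
    sirna_status_table,
)


def _read(start, length=24, chrom="A01", strand="+", unique=True):
    return SmallRNAAlignment(
        GenomicInterval(chrom, start, start + length, strand), length, unique
    )


def _tx(tid, start, end, chrom="A01", strand="+"):
    return TranscriptModel(
        tid,
        GenomicInterval(chrom, start, end, strand),
        (GenomicInterval(chrom, start, end, strand),),
    )


def test_filter_by_length_and_uniqueness():
    reads = [_read(0, 21), _read(50, 22), _read(100, 24), _read(200, 24, unique=False)]
    assert len(filter_24nt(reads)) == 1
    assert len(filter_24nt(reads, unique_only=False)) == 2
    assert filter_24nt([]) == []


@pytest.mark.parametrize(
    "count, library, expected",
    [(10, 10**6, 10.0), (0, 10**6, 0.0), (7, int(3.5e6), 2.0)],
)
def test_rpm_values(count, library, expected):
    assert rpm(count, library) == pytest.approx(expected)


def test_rpm_zero_library_errors():
    with pytest.raises(ValueError):
        rpm(5, 0)


def test_rpm_over_partition_sums_to_million():
    """Counting every read exactly once over a genome partition, the RPM
    values sum to 10^6."""
    rng = np.random.default_rng(3)
    starts = rng.integers(0, 10_000, size=400)
    reads = [_read(int(s)) for s in starts]
    edges = [0, 2_500, 5_000, 7_500, 10_100]
    counts = [
        sum(1 for r in reads if lo <= r.interval.start < hi)
        for lo, hi in zip(edges, edges[1:])
    ]
    assert sum(rpm(c, len(reads)) for c in counts) == pytest.approx(1e6)


def test_cluster_examples():
    reads = [_read(0), _read(50), _read(120)]
    (cluster,) = call_clusters(reads, gap=100, min_reads=3)
    assert (cluster.interval.start, cluster.interval.end) == (0, 144)
    assert cluster.read_count == 3
    assert call_clusters(reads[:2], gap=100, min_reads=3) == []


def _closure_oracle(reads, gap):
    """Brute-force transitive closure: two reads group together when any
    chain of pairwise (distance <= gap) links connects them."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            a, b = reads[i].interval, reads[j].interval
            if a.chrom == b.chrom and max(a.start, b.start) - min(a.end, b.end) <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(reads[i])
    return {
        (
            min(r.interval.start for r in g),
            max(r.interval.end for r in g),
            len(g),
        )
        for g in groups.values()
    }


def test_clusters_match_transitive_closure_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        reads = [_read(int(s)) for s in rng.integers(0, 3_000, size=rng.integers(3, 40))]
        gap = int(rng.integers(0, 200))
        got = {
            (c.interval.start, c.interval.end, c.read_count)
            for c in call_clusters(reads, gap=gap, min_reads=1)
        }
        assert got == _closure_oracle(reads, gap)


def test_cluster_monotonicity():
    rng = np.random.default_rng(8)
    reads = [_read(int(s)) for s in rng.integers(0, 5_000, size=60)]
    prev_total = -1
    for gap in (0, 50, 100, 300):
        clusters = call_clusters(reads, gap=gap, min_reads=1)
        total = sum(c.interval.length for c in clusters)
        assert total >= prev_total  # larger gap never shrinks cluster extent
        prev_total = total
    prev_n = len(call_clusters(reads, gap=100, min_reads=1))
    for min_reads in (2, 3, 5):
        n = len(call_clusters(reads, gap=100, min_reads=min_reads))
        assert n <= prev_n
        prev_n = n


def test_containment_criterion():
    tx = _tx("T1", 0, 1_000)
    inside = _read(100)
    straddling = _read(990)  # ends at 1014, crosses the span end
    assert sirna_overlap_status(tx, reads24=[inside]) is True
    assert sirna_overlap_status(tx, reads24=[straddling]) is False
    # cluster mode accepts 1-bp overlap instead
    clusters = call_clusters([_read(980), _read(990), _read(1_000)], gap=100, min_reads=3)
    assert sirna_overlap_status(tx, clusters=clusters, mode="cluster") is True


def test_status_vector_equals_manifest(dataset):
    outdir, manifest = dataset
    reads = io.read_srna_table(outdir / "srna_reads.tsv")
    reads24 = filter_24nt(reads, unique_only=True)
    _, txs = io.read_gff(outdir / "transcripts.gff3")
    status = sirna_status_table(txs, reads24)
    truth = dict(zip(manifest.transcripts["transcript_id"], manifest.transcripts["sirna"]))
    assert status == {tid: bool(v) for tid, v in truth.items()}
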