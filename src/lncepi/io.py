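"""Readers and writers for the external formats the pipeline touches.

Every reader streams line by line, raises on malformed lines with the line
number in the message, logs counts of skipped records, and accepts plain or
gzip-compressed paths. 1-based formats (GFF/GTF, cytosine reports) are
converted to the internal 0-based half-open convention here; BED and
bedGraph are consumed as-is.
"""

from __future__ import annotations

import gzip
import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import GenomicInterval, merge_intervals
from .models import (
    CodingHit,
    CytosineRecord,
    ExpressionRecord,
    GeneModel,
    HSPRecord,
    SmallRNAAlignment,
    TranscriptModel,
)

logger = logging.getLogger("lncepi")

#: context spellings seen in the wild, normalized to the three classes
CONTEXT_ALIASES = {
    "CG": "CG",
    "CPG": "CG",
    "CHG": "CHG",
    "CHH": "CHH",
}


def xopen(path, mode: str = "rt"):
    """Open a plain or gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class ParseError(ValueError):
    pass


def _err(path, line_no: int, msg: str) -> ParseError:
    return ParseError(f"{path}, line {line_no}: {msg}")


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> Dict[str, str]:
    field = field.strip().rstrip(";")
    if not field or field == ".":
        return {}
    if "=" in field.split(";")[0]:
        # GFF3 key=value;key=value
        out = {}
        for part in field.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            out[key.strip()] = value.strip()
        return out
    return {key: value for key, value in _GTF_ATTR.findall(field)}


def read_gff(path) -> Tuple[List[GeneModel], List[TranscriptModel]]:
    """Read gene and transcript models from a GFF3 or GTF file.

    Exons are attached to their parent by ``Parent``/``transcript_id``.
    Transcripts whose parent is a gene contribute their exons to that gene
    model (exon union across isoforms); transcripts without a gene parent
    become standalone :class:`TranscriptModel` records. Coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    genes_raw: Dict[str, GenomicInterval] = {}
    tx_raw: Dict[str, Tuple[GenomicInterval, Optional[str]]] = {}
    exons: Dict[str, List[GenomicInterval]] = defaultdict(list)
    n_lines = n_skipped = 0

    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise _err(path, line_no, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError:
                raise _err(path, line_no, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if start < 0 or end <= start:
                raise _err(path, line_no, f"invalid coordinates {start_s}-{end_s}")
            strand = strand if strand in ("+", "-") else "."
            attrs = _parse_attributes(attr_s)
            iv = GenomicInterval(chrom, start, end, strand)
            ftype_l = ftype.lower()
            if ftype_l == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if not gid:
                    raise _err(path, line_no, "gene feature without ID/gene_id")
                genes_raw[gid] = iv
            elif ftype_l in ("mrna", "transcript"):
                tid = attrs.get("ID") or attrs.get("transcript_id")
                if not tid:
                    raise _err(path, line_no, "transcript feature without ID/transcript_id")
                tx_raw[tid] = (iv, attrs.get("Parent") or attrs.get("gene_id"))
            elif ftype_l == "exon":
                parents = attrs.get("Parent") or attrs.get("transcript_id")
                if not parents:
                    raise _err(path, line_no, "exon feature without Parent/transcript_id")
                for parent in parents.split(","):
                    exons[parent].append(iv)
            else:
                n_skipped += 1

    if n_lines == 0:
        logger.warning("read_gff(%s): empty file", path)
    if n_skipped:
        logger.info("read_gff(%s): skipped %d non-gene/transcript/exon features", path, n_skipped)

    gene_exons: Dict[str, List[GenomicInterval]] = {g: list(exons.get(g, [])) for g in genes_raw}
    standalone: List[Tuple[str, GenomicInterval, List[GenomicInterval]]] = []
    for tid, (iv, parent) in tx_raw.items():
        ex = exons.get(tid, [])
        if parent in genes_raw:
            gene_exons[parent].extend(ex)
        else:
            standalone.append((tid, iv, ex))

    genes = []
    for gid, iv in genes_raw.items():
        ex = gene_exons[gid]
        if not ex:
            ex = [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)]
        for e in ex:
            if e.start < iv.start or e.end > iv.end or e.chrom != iv.chrom:
                raise ParseError(f"{path}: exon {e} outside parent span of gene {gid}")
        merged = merge_intervals(ex)
        ex = tuple(GenomicInterval(iv.chrom, m.start, m.end, iv.strand) for m in merged)
        genes.append(GeneModel(gid, iv, ex))

    transcripts = []
    for tid, iv, ex in standalone:
        if not ex:
            ex = [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)]
        for e in ex:
            if e.start < iv.start or e.end > iv.end or e.chrom != iv.chrom:
                raise ParseError(f"{path}: exon {e} outside parent span of transcript {tid}")
        coords = sorted({(e.start, e.end) for e in ex})
        ex = tuple(GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in coords)
        transcripts.append(TranscriptModel(tid, iv, ex))

    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.id))
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.id))
    return genes, transcripts


def write_gff3(path, genes: Sequence[GeneModel] = (), transcripts: Sequence[TranscriptModel] = (),
               source: str = "lncepi") -> None:
    """Write gene/transcript models as GFF3 (1-based inclusive)."""
    with xopen(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={gene.id}\n"
            )
            for ex in gene.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\tParent={gene.id}\n"
                )
        for tx in transcripts:
            iv = tx.interval
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={tx.id}\n"
            )
            for ex in tx.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\tParent={tx.id}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/4/6 intervals (0-based half-open, consumed as-is)."""
    out = []
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, line_no, "BED line with fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise _err(path, line_no, "non-integer BED coordinates")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise _err(path, line_no, str(exc))
    if not out:
        logger.warning("read_bed(%s): no intervals", path)
    return sorted(out)


def write_bed(path, intervals: Iterable[GenomicInterval], names: Optional[Sequence[str]] = None) -> None:
    intervals = list(intervals)
    with xopen(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path) -> List[Tuple[GenomicInterval, float]]:
    out = []
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise _err(path, line_no, "bedGraph line with fewer than 4 fields")
            try:
                out.append(
                    (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(fields[3]))
                )
            except ValueError as exc:
                raise _err(path, line_no, str(exc))
    return out


def write_bedgraph(path, entries: Iterable[Tuple[GenomicInterval, float]]) -> None:
    with xopen(path, "wt") as fh:
        for iv, value in entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Cytosine report
# ---------------------------------------------------------------------------

def read_cx_report(path) -> List[CytosineRecord]:
    """Read a per-cytosine report: chrom, 1-based pos, strand, mC, umC, context.

    Extra trailing columns (e.g. a trinucleotide column) are ignored.
    Zero-coverage records are retained; aggregation excludes them later.
    """
    out = []
    n_zero = 0
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _err(path, line_no, "cytosine report line with fewer than 6 fields")
            chrom, pos_s, strand, mc_s, umc_s, context = fields[:6]
            try:
                pos = int(pos_s)
                mc = int(mc_s)
                umc = int(umc_s)
            except ValueError:
                raise _err(path, line_no, "non-integer position or counts")
            if mc < 0 or umc < 0:
                raise _err(path, line_no, "negative read count")
            norm = CONTEXT_ALIASES.get(context.upper())
            if norm is None:
                raise _err(path, line_no, f"unknown cytosine context {context!r}")
            if strand not in ("+", "-"):
                strand = "."
            if mc + umc == 0:
                n_zero += 1
            out.append(
                CytosineRecord(GenomicInterval(chrom, pos - 1, pos, strand), norm, mc, umc)
            )
    if n_zero:
        logger.info("read_cx_report(%s): %d zero-coverage sites retained", path, n_zero)
    return out


def write_cx_report(path, records: Iterable[CytosineRecord]) -> None:
    with xopen(path, "wt") as fh:
        for rec in records:
            p = rec.position
            fh.write(f"{p.chrom}\t{p.start + 1}\t{p.strand}\t{rec.mc}\t{rec.umc}\t{rec.context}\n")


# ---------------------------------------------------------------------------
# Small-RNA alignments
# ---------------------------------------------------------------------------

def read_srna_table(path) -> List[SmallRNAAlignment]:
    """Read aligned sRNA reads.

    Two layouts are accepted per line:

    * custom 6 columns: chrom, start, end, strand, read_length, unique(0/1)
    * BED6: chrom, start, end, name, score (unique flag), strand —
      read length inferred from the coordinates
    """
    out = []
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _err(path, line_no, "sRNA line with fewer than 6 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                if fields[3] in ("+", "-", "."):
                    strand = fields[3]
                    length = int(fields[4])
                    unique = fields[5] in ("1", "True", "true")
                else:
                    strand = fields[5] if fields[5] in ("+", "-") else "."
                    length = end - start
                    unique = int(float(fields[4])) > 0
                iv = GenomicInterval(fields[0], start, end, strand)
                out.append(SmallRNAAlignment(iv, length, unique))
            except ValueError as exc:
                raise _err(path, line_no, str(exc))
    if not out:
        logger.warning("read_srna_table(%s): no reads", path)
    return out


def write_srna_table(path, reads: Iterable[SmallRNAAlignment]) -> None:
    with xopen(path, "wt") as fh:
        for read in reads:
            iv = read.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{read.read_length}\t{int(read.unique)}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def read_hsp_table(path) -> List[HSPRecord]:
    """Read a 12-column BLAST tabular file into HSP records."""
    out = []
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise _err(path, line_no, "BLAST tabular line with fewer than 12 fields")
            try:
                out.append(
                    HSPRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        align_length=int(fields[3]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise _err(path, line_no, str(exc))
    return out


def write_hsp_table(path, hsps: Iterable[HSPRecord]) -> None:
    with xopen(path, "wt") as fh:
        for h in hsps:
            mismatch = 0
            gapopen = 0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.align_length}\t{mismatch}\t{gapopen}\t"
                f"{h.query_start}\t{h.query_end}\t{h.subject_start}\t{h.subject_end}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Plain tables
# ---------------------------------------------------------------------------

def read_expression(path) -> List[ExpressionRecord]:
    """Read a TSV of transcript_id plus one column per FPKM replicate."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expression table needs id plus >=1 replicate column")
    out = []
    id_col = df.columns[0]
    for _, row in df.iterrows():
        out.append(ExpressionRecord(str(row[id_col]), tuple(float(v) for v in row.iloc[1:])))
    return out


def write_expression(path, records: Iterable[ExpressionRecord]) -> None:
    records = list(records)
    n_rep = len(records[0].fpkm) if records else 2
    with xopen(path, "wt") as fh:
        fh.write("transcript_id\t" + "\t".join(f"rep{i + 1}" for i in range(n_rep)) + "\n")
        for rec in records:
            fh.write(rec.transcript_id + "\t" + "\t".join(f"{v:.4f}" for v in rec.fpkm) + "\n")


def read_coding_hits(path) -> List[CodingHit]:
    """Read a TSV of transcript_id, subject_id, evalue (header optional)."""
    out = []
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, line_no, "coding-hit line with fewer than 3 fields")
            if line_no == 1 and fields[0].lower() in ("transcript_id", "query"):
                continue
            try:
                out.append(CodingHit(fields[0], fields[1], float(fields[2])))
            except ValueError as exc:
                raise _err(path, line_no, str(exc))
    return out


def write_coding_hits(path, hits: Iterable[CodingHit]) -> None:
    with xopen(path, "wt") as fh:
        fh.write("transcript_id\tsubject_id\tevalue\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.subject_id}\t{h.best_evalue:.2e}\n")


def read_go_map(path) -> Dict[str, Tuple[str, ...]]:
    """Read a gene -> GO-term TSV into a mapping (genes may repeat)."""
    mapping: Dict[str, set] = defaultdict(set)
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise _err(path, line_no, "GO map line with fewer than 2 fields")
            if line_no == 1 and fields[0].lower() in ("gene", "gene_id"):
                continue
            mapping[fields[0]].add(fields[1])
    return {g: tuple(sorted(terms)) for g, terms in mapping.items()}


def read_term_names(path) -> Dict[str, str]:
    out = {}
    with xopen(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2:
                out[fields[0]] = fields[1]
    return out


def read_band_matrix(path) -> pd.DataFrame:
    """Read an RT-PCR band matrix (rows = lncRNAs, columns = lines)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ParseError(f"{path}: empty band matrix")
    return df


def read_chrom_sizes(path) -> Dict[str, int]:
    out = {}
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise _err(path, line_no, "chrom sizes line with fewer than 2 fields")
            out[fields[0]] = int(fields[1])
    return out


def read_class_table(path) -> Dict[str, str]:
    """Read a transcript_id -> class TSV (header optional)."""
    out = {}
    with xopen(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise _err(path, line_no, "class table line with fewer than 2 fields")
            if line_no == 1 and fields[0].lower() == "transcript_id":
                continue
            out[fields[0]] = fields[1]
    return out
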