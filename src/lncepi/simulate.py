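"""Synthetic toy dataset with a ground-truth manifest.

The generator emits every input the pipeline consumes — gene and transcript
annotation, coding hits, inverted-repeat and H3K27me3 BEDs, a per-cytosine
methylation report, aligned small-RNA reads, an FPKM table, per-genome HSP
tables, a GO map — with planted class labels, mark-overlap fractions,
methylation elevations and expression effects, so every stage is testable
without any download.

Placement rules make class identity unambiguous: lincRNAs are intergenic,
NATs overlap a host-gene exon on the opposite strand, incRNAs sit fully
inside a host-gene intron, and putative mRNAs are intergenic transcripts
with a planted protein-database hit. Mark truth is guaranteed by
construction: a planted IRR/H3K27me3 interval lies inside the transcript
span, 24-nt source regions (and their uniquely mapped reads) lie fully
inside the span — nested inside the IRR when both marks are planted — and
background features are confined to inter-unit gaps. Per-site methylated
counts are binomial with beta-distributed per-site means around the
context base level, elevated by ``methylation_boost`` inside IRRs and
24-nt source regions.

One RNG stream per file family, all derived from the master seed, so the
same seed gives byte-identical outputs and adding a file type never
perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io
from .datasets import emit_worked_tables  # noqa: F401  (fixture tables live here)
from .intervals import GenomicInterval, merge_intervals
from .models import (
    CodingHit,
    ExpressionRecord,
    GeneModel,
    HSPRecord,
    SmallRNAAlignment,
    TranscriptModel,
)

CLASSES = ("lincRNA", "NAT", "incRNA", "putative_mRNA")
TARGET_GENOMES = ("B_nigra", "B_oleracea", "B_juncea", "B_napus")

_RNG_STREAMS = (
    "structure",
    "placement",
    "marks",
    "methylation",
    "srna",
    "expression",
    "conservation",
    "go",
)


def _default(d):
    return field(default_factory=lambda: dict(d))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the surveyed conditions
    (class-wise overlap fractions, transcript lengths, exon-count mix) at
    desk scale."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 1_500_000
    n_genes: int = 120
    n_lincRNA: int = 150
    n_NAT: int = 75
    n_incRNA: int = 40
    n_putative_mRNA: int = 70
    irr_overlap_fraction: Dict[str, float] = _default(
        {"lincRNA": 0.650, "NAT": 0.550, "incRNA": 0.717, "putative_mRNA": 0.641}
    )
    sirna_overlap_fraction: Dict[str, float] = _default(
        {"lincRNA": 0.187, "NAT": 0.140, "incRNA": 0.174, "putative_mRNA": 0.150}
    )
    #: fraction of siRNA-overlapping transcripts whose source region nests
    #: inside an IRR (the "> 80%" conditional)
    sirna_in_irr_conditional: float = 0.85
    h3k27_fraction: Dict[str, float] = _default(
        {"lincRNA": 0.108, "NAT": 0.157, "incRNA": 0.163, "putative_mRNA": 0.108}
    )
    mean_length: Dict[str, float] = _default(
        {"lincRNA": 725, "NAT": 1271, "incRNA": 779, "putative_mRNA": 1305}
    )
    length_sigma: float = 0.45
    single_exon_fraction: Dict[str, float] = _default(
        {"lincRNA": 0.657, "NAT": 0.724, "incRNA": 0.710, "putative_mRNA": 0.40}
    )
    gene_mean_length: float = 1305.0
    methylation_base: Dict[str, float] = _default({"CG": 0.45, "CHG": 0.25, "CHH": 0.08})
    methylation_boost: float = 0.25
    methylation_concentration: float = 200.0
    read_depth: float = 20.0
    cx_site_spacing: int = 15
    context_weights: Dict[str, float] = _default({"CG": 0.25, "CHG": 0.25, "CHH": 0.50})
    flank_bp: int = 2_000
    expression_lognormal: Tuple[float, float] = (1.0, 1.2)
    replicate_sigma: float = 0.10
    n_replicates: int = 2
    sirna_expression_effect: float = 2.0
    sirna_reads_mean: float = 8.0
    sirna_source_length: int = 150
    background_irr_prob: float = 0.30
    background_k27_prob: float = 0.15
    gene_k27_prob: float = 0.20
    conservation_mean_coverage: Dict[str, float] = _default(
        {"B_oleracea": 0.85, "B_nigra": 0.55, "B_napus": 0.50, "B_juncea": 0.30}
    )
    conservation_hit_prob: Dict[str, float] = _default(
        {"B_oleracea": 0.95, "B_nigra": 0.80, "B_napus": 0.75, "B_juncea": 0.60}
    )
    coverage_concentration: float = 15.0
    n_go_terms: int = 15
    go_background_prob: float = 0.10
    go_enriched_prob: float = 0.80
    enriched_term: str = "GO:0006355"
    min_unit_gap: int = 800
    max_unit_gap: int = 4_000

    def __post_init__(self) -> None:
        for name in ("irr_overlap_fraction", "sirna_overlap_fraction", "h3k27_fraction"):
            for cls, frac in getattr(self, name).items():
                if not 0 <= frac <= 1:
                    raise ValueError(f"{name}[{cls}] must lie in [0, 1]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        longest = max(max(self.mean_length.values()), self.gene_mean_length)
        if self.chrom_length < 10 * longest:
            raise ValueError("chrom_length must be >= 10x the mean feature length")

    @property
    def n_per_class(self) -> Dict[str, int]:
        return {
            "lincRNA": self.n_lincRNA,
            "NAT": self.n_NAT,
            "incRNA": self.n_incRNA,
            "putative_mRNA": self.n_putative_mRNA,
        }


@dataclass
class GroundTruthManifest:
    """Planted truth for every emitted transcript plus run-level metadata."""

    transcripts: pd.DataFrame
    meta: Dict
    paths: Dict[str, Path] = field(default_factory=dict)

    @classmethod
    def from_dir(cls, outdir) -> "GroundTruthManifest":
        outdir = Path(outdir)
        df = pd.read_csv(outdir / "manifest.tsv", sep="\t")
        for col in ("irr", "sirna", "k27"):
            df[col] = df[col].astype(bool)
        with open(outdir / "manifest.json") as fh:
            meta = json.load(fh)
        return cls(df, meta)


def _split_lengths(rng, total: int, parts: int, min_len: int = 50) -> List[int]:
    if parts == 1:
        return [int(total)]
    extra = total - parts * min_len
    if extra < 0:
        raise ValueError("feature too short to split")
    props = rng.dirichlet(np.full(parts, 2.0))
    alloc = np.floor(props * extra).astype(int)
    alloc[0] += extra - alloc.sum()
    return [int(min_len + a) for a in alloc]


def _draw_length(rng, mean: float, sigma: float, minimum: int = 250) -> int:
    mu = np.log(mean) - sigma**2 / 2.0
    return int(max(minimum, rng.lognormal(mu, sigma)))


@dataclass
class _TxPlan:
    tid: str
    cls: str
    length: int
    exon_lens: List[int]
    intron_lens: List[int]
    irr: bool
    sirna: bool
    k27: bool

    @property
    def span_width(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _assign_marks(rng, n: int, f_irr: float, f_sirna: float, cond: float, f_k27: float):
    irr = rng.random(n) < f_irr
    mass_irr = min(f_irr, f_sirna * cond)
    p_given_irr = mass_irr / f_irr if f_irr > 0 else 0.0
    p_given_not = (f_sirna - mass_irr) / (1 - f_irr) if f_irr < 1 else 0.0
    u = rng.random(n)
    sirna = np.where(irr, u < p_given_irr, u < min(1.0, p_given_not))
    k27 = rng.random(n) < f_k27
    return irr, sirna, k27


def generate_dataset(config: SimulationConfig, outdir) -> GroundTruthManifest:
    """Write the complete synthetic dataset into ``outdir``.

    Raises ``ValueError`` when the configured features cannot be placed on
    the configured chromosomes (the fix is a larger ``chrom_length`` or
    fewer features).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(len(_RNG_STREAMS))
    rng = {name: np.random.default_rng(s) for name, s in zip(_RNG_STREAMS, streams)}

    plans = _plan_transcripts(config, rng["structure"], rng["marks"])
    placed = _place_units(config, plans, rng["placement"])

    chrom_sizes = {f"A{i + 1:02d}": config.chrom_length for i in range(config.n_chroms)}
    paths: Dict[str, Path] = {}

    # annotation
    paths["genes"] = outdir / "genes.gff3"
    io.write_gff3(paths["genes"], genes=placed["genes"])
    paths["transcripts"] = outdir / "transcripts.gff3"
    io.write_gff3(paths["transcripts"], transcripts=placed["transcripts"])
    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    # coding hits for putative mRNAs
    hits = [
        CodingHit(plan.tid, f"sp|Q{i:05d}|SYNT", 10.0 ** -(20 + (i % 10)))
        for i, plan in enumerate(plans)
        if plan.cls == "putative_mRNA"
    ]
    paths["coding_hits"] = outdir / "coding_hits.tsv"
    io.write_coding_hits(paths["coding_hits"], hits)

    # marks
    paths["irr"] = outdir / "irr.bed"
    io.write_bed(paths["irr"], placed["irrs"], names=[f"IRR_{i + 1}" for i in range(len(placed["irrs"]))])
    paths["k27"] = outdir / "k27_domains.bed"
    io.write_bed(paths["k27"], placed["k27"], names=[f"K27_{i + 1}" for i in range(len(placed["k27"]))])

    # small RNA reads (planted 24-nt sources + gap background)
    reads = _emit_background_srna(config, placed, rng["srna"])
    reads.extend(placed["reads"])
    reads.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.read_length))
    paths["srna"] = outdir / "srna_reads.tsv"
    io.write_srna_table(paths["srna"], reads)
    library_size = len(reads)

    # methylation
    paths["cx_report"] = outdir / "cx_report.tsv"
    _emit_cx_report(config, placed, chrom_sizes, rng["methylation"], paths["cx_report"])

    # expression
    expr_records, fpkm_true = _emit_expression(config, placed, rng["expression"])
    paths["fpkm"] = outdir / "fpkm.tsv"
    io.write_expression(paths["fpkm"], expr_records)

    # conservation HSP tables
    for genome in TARGET_GENOMES:
        paths[f"hsp_{genome}"] = outdir / f"hsp_{genome}.tsv"
    _emit_hsps(config, placed, rng["conservation"], outdir)

    # GO map
    paths["go_map"] = outdir / "go_map.tsv"
    paths["term_names"] = outdir / "term_names.tsv"
    _emit_go(config, placed, rng["go"], paths["go_map"], paths["term_names"])

    # manifest
    rows = []
    for entry in placed["truth"]:
        entry = dict(entry)
        entry["fpkm_true"] = fpkm_true[entry["transcript_id"]]
        rows.append(entry)
    manifest_df = pd.DataFrame(rows)
    manifest_df["expr_stratum"] = np.where(manifest_df["sirna"], "sirna+", "sirna-")
    out_df = manifest_df.copy()
    for col in ("irr", "sirna", "k27"):
        out_df[col] = out_df[col].astype(int)
    paths["manifest"] = outdir / "manifest.tsv"
    out_df.to_csv(paths["manifest"], sep="\t", index=False, float_format="%.6g")

    meta = {
        "config": asdict(config),
        "chrom_sizes": chrom_sizes,
        "library_size": library_size,
        "boosted_mean": {
            ctx: min(0.999, config.methylation_base[ctx] + config.methylation_boost)
            for ctx in config.methylation_base
        },
        "base_mean": dict(config.methylation_base),
        "conservation_expected_mean": {
            g: config.conservation_hit_prob[g] * config.conservation_mean_coverage[g]
            for g in TARGET_GENOMES
        },
        "enriched_term": config.enriched_term,
        "incRNA_host_genes": sorted(placed["inc_hosts"]),
        "nat_host_genes": sorted(placed["nat_hosts"]),
        "n_per_class": config.n_per_class,
    }
    paths["manifest_json"] = outdir / "manifest.json"
    with open(paths["manifest_json"], "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    return GroundTruthManifest(manifest_df, meta, paths)


# ---------------------------------------------------------------------------
# planning and placement
# ---------------------------------------------------------------------------

def _plan_transcripts(config, rng_struct, rng_marks) -> List[_TxPlan]:
    plans: List[_TxPlan] = []
    for cls in CLASSES:
        n = config.n_per_class[cls]
        irr, sirna, k27 = _assign_marks(
            rng_marks,
            n,
            config.irr_overlap_fraction[cls],
            config.sirna_overlap_fraction[cls],
            config.sirna_in_irr_conditional,
            config.h3k27_fraction[cls],
        )
        for i in range(n):
            length = _draw_length(rng_struct, config.mean_length[cls], config.length_sigma)
            if rng_struct.random() < config.single_exon_fraction[cls]:
                n_exons = 1
            else:
                n_exons = int(rng_struct.integers(2, 5))
            exon_lens = _split_lengths(rng_struct, length, n_exons)
            intron_lens = [int(rng_struct.integers(100, 501)) for _ in range(n_exons - 1)]
            plans.append(
                _TxPlan(
                    f"{cls[:4].upper()}_{i + 1:04d}",
                    cls,
                    length,
                    exon_lens,
                    intron_lens,
                    bool(irr[i]),
                    bool(sirna[i]),
                    bool(k27[i]),
                )
            )
    return plans


def _exon_chain(chrom, start, strand, exon_lens, intron_lens):
    exons = []
    cursor = start
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
        cursor += elen
        if i < len(intron_lens):
            cursor += intron_lens[i]
    return exons, cursor  # cursor = span end


def _plan_gene(config, rng) -> Tuple[List[int], List[int]]:
    length = _draw_length(rng, config.gene_mean_length, 0.35, minimum=400)
    n_exons = 1 if rng.random() < 0.151 else int(rng.integers(2, 5))
    exon_lens = _split_lengths(rng, length, n_exons, min_len=80)
    intron_lens = [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def _place_units(config, plans: List[_TxPlan], rng) -> Dict:
    chroms = [f"A{i + 1:02d}" for i in range(config.n_chroms)]
    genes: List[GeneModel] = []
    transcripts: List[TranscriptModel] = []
    irrs: List[GenomicInterval] = []
    k27s: List[GenomicInterval] = []
    sources: List[GenomicInterval] = []
    reads: List[SmallRNAAlignment] = []
    truth: List[Dict] = []
    gaps: List[GenomicInterval] = []
    inc_hosts: List[str] = []
    nat_hosts: List[str] = []

    units: List[Tuple[str, object]] = [("tx", plan) for plan in plans]
    units += [("gene", None)] * config.n_genes
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    chrom_idx = 0
    cursor = 3_000
    gene_serial = 0

    def advance(width: int) -> Tuple[str, int]:
        nonlocal chrom_idx, cursor
        gap = int(rng.integers(config.min_unit_gap, config.max_unit_gap + 1))
        start = cursor + gap
        if start + width > config.chrom_length - 3_000:
            if cursor < config.chrom_length:
                gaps.append(GenomicInterval(chroms[chrom_idx], cursor, config.chrom_length))
            chrom_idx += 1
            if chrom_idx >= len(chroms):
                raise ValueError(
                    "cannot place all features: increase chrom_length or n_chroms, "
                    "or reduce feature counts"
                )
            cursor = 3_000
            start = cursor + gap
            if start + width > config.chrom_length - 3_000:
                raise ValueError(
                    "cannot place all features: increase chrom_length or n_chroms, "
                    "or reduce feature counts"
                )
        gaps.append(GenomicInterval(chroms[chrom_idx], cursor, start))
        cursor = start + width
        return chroms[chrom_idx], start

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def place_gene(chrom: str, start: int, strand: str, exon_lens, intron_lens) -> GeneModel:
        nonlocal gene_serial
        gene_serial += 1
        exons, end = _exon_chain(chrom, start, strand, exon_lens, intron_lens)
        gene = GeneModel(
            f"G{gene_serial:05d}", GenomicInterval(chrom, start, end, strand), tuple(exons)
        )
        genes.append(gene)
        return gene

    def plant_marks(plan: _TxPlan, span: GenomicInterval) -> None:
        irr_iv = None
        if plan.irr:
            irr_len = int(rng.integers(200, min(600, span.length - 10) + 1))
            off = int(rng.integers(0, span.length - irr_len + 1))
            irr_iv = GenomicInterval(span.chrom, span.start + off, span.start + off + irr_len)
            irrs.append(irr_iv)
        if plan.sirna:
            host = irr_iv if irr_iv is not None else span
            src_len = min(config.sirna_source_length, host.length - 20)
            src_len = max(30, src_len)
            off = int(rng.integers(0, host.length - src_len + 1))
            src = GenomicInterval(span.chrom, host.start + off, host.start + off + src_len)
            sources.append(src)
            n_reads = 4 + int(rng.poisson(max(0.0, config.sirna_reads_mean - 4)))
            for _ in range(n_reads):
                rstart = int(rng.integers(src.start, src.end - 24 + 1))
                reads.append(
                    SmallRNAAlignment(
                        GenomicInterval(span.chrom, rstart, rstart + 24, rand_strand()), 24, True
                    )
                )
        if plan.k27:
            k_len = min(int(rng.integers(300, 801)), span.length - 4)
            off = int(rng.integers(0, span.length - k_len + 1))
            k27s.append(GenomicInterval(span.chrom, span.start + off, span.start + off + k_len))

    for kind, plan in units:
        if kind == "gene":
            exon_lens, intron_lens = _plan_gene(config, rng)
            width = sum(exon_lens) + sum(intron_lens)
            chrom, start = advance(width)
            gene = place_gene(chrom, start, rand_strand(), exon_lens, intron_lens)
            if rng.random() < config.gene_k27_prob:
                span = gene.interval
                k_len = min(int(rng.integers(300, 801)), span.length - 4)
                off = int(rng.integers(0, span.length - k_len + 1))
                k27s.append(GenomicInterval(chrom, span.start + off, span.start + off + k_len))
            continue

        assert isinstance(plan, _TxPlan)
        host_gene_id = ""
        if plan.cls in ("lincRNA", "putative_mRNA"):
            width = plan.span_width
            chrom, start = advance(width)
            strand = rand_strand()
            exons, end = _exon_chain(chrom, start, strand, plan.exon_lens, plan.intron_lens)
            span = GenomicInterval(chrom, start, end, strand)
        elif plan.cls == "NAT":
            # host gene: two large exons; NAT starts inside exon 1, antisense
            e1 = int(rng.integers(300, 601))
            e2 = int(rng.integers(300, 601))
            g_intron = int(rng.integers(200, 401))
            t_off = e1 // 2
            width = max(e1 + g_intron + e2, t_off + plan.span_width)
            chrom, start = advance(width)
            g_strand = rand_strand()
            gene = place_gene(chrom, start, g_strand, [e1, e2], [g_intron])
            nat_hosts.append(gene.id)
            host_gene_id = gene.id
            strand = "-" if g_strand == "+" else "+"
            exons, end = _exon_chain(chrom, start + t_off, strand, plan.exon_lens, plan.intron_lens)
            span = GenomicInterval(chrom, start + t_off, end, strand)
        else:  # incRNA inside a host-gene intron
            pad = 100
            g_e1 = int(rng.integers(200, 401))
            g_e2 = int(rng.integers(200, 401))
            g_intron = plan.span_width + 2 * pad
            width = g_e1 + g_intron + g_e2
            chrom, start = advance(width)
            g_strand = rand_strand()
            gene = place_gene(chrom, start, g_strand, [g_e1, g_e2], [g_intron])
            inc_hosts.append(gene.id)
            host_gene_id = gene.id
            strand = rand_strand()
            t_start = start + g_e1 + pad
            exons, end = _exon_chain(chrom, t_start, strand, plan.exon_lens, plan.intron_lens)
            span = GenomicInterval(chrom, t_start, end, strand)

        transcripts.append(TranscriptModel(plan.tid, span, tuple(exons)))
        plant_marks(plan, span)
        truth.append(
            {
                "transcript_id": plan.tid,
                "class": plan.cls,
                "chrom": span.chrom,
                "start": span.start,
                "end": span.end,
                "strand": span.strand,
                "length": plan.length,
                "n_exons": len(plan.exon_lens),
                "irr": plan.irr,
                "sirna": plan.sirna,
                "k27": plan.k27,
                "host_gene": host_gene_id,
            }
        )

    if cursor < config.chrom_length:
        gaps.append(GenomicInterval(chroms[chrom_idx], cursor, config.chrom_length))

    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.id))
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.id))
    truth.sort(key=lambda r: r["transcript_id"])
    return {
        "genes": genes,
        "transcripts": transcripts,
        "irrs": sorted(irrs),
        "k27": sorted(k27s),
        "sources": sorted(sources),
        "reads": reads,
        "truth": truth,
        "gaps": gaps,
        "inc_hosts": inc_hosts,
        "nat_hosts": nat_hosts,
    }


def _emit_background_srna(config, placed, rng) -> List[SmallRNAAlignment]:
    """Off-length background everywhere in gaps plus sparse 24-nt noise
    kept out of every transcript span."""
    reads: List[SmallRNAAlignment] = []
    margin = 60
    for gap in placed["gaps"]:
        usable = gap.length - 2 * margin
        if usable < 100:
            continue
        n_off = rng.poisson(gap.length / 1500.0)
        for _ in range(int(n_off)):
            length = int(rng.choice([21, 22]))
            start = int(rng.integers(gap.start + margin, gap.end - margin - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                SmallRNAAlignment(
                    GenomicInterval(gap.chrom, start, start + length, strand),
                    length,
                    bool(rng.random() < 0.8),
                )
            )
        if usable >= 200 and rng.random() < 0.25:
            # a background 24-nt cluster in intergenic space
            n24 = int(rng.integers(3, 7))
            w_start = int(rng.integers(gap.start + margin, gap.end - margin - 150 + 1))
            for _ in range(n24):
                start = int(rng.integers(w_start, w_start + 150 - 24 + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(
                    SmallRNAAlignment(
                        GenomicInterval(gap.chrom, start, start + 24, strand),
                        24,
                        bool(rng.random() < 0.7),
                    )
                )
    # background IRR / K27 annotation in gaps
    for gap in placed["gaps"]:
        if gap.length < 800:
            continue
        if rng.random() < config.background_irr_prob:
            length = int(rng.integers(200, min(600, gap.length - 2 * margin) + 1))
            start = int(rng.integers(gap.start + margin, gap.end - margin - length + 1))
            placed["irrs"].append(GenomicInterval(gap.chrom, start, start + length))
        if rng.random() < config.background_k27_prob:
            length = int(rng.integers(300, min(800, gap.length - 2 * margin) + 1))
            start = int(rng.integers(gap.start + margin, gap.end - margin - length + 1))
            placed["k27"].append(GenomicInterval(gap.chrom, start, start + length))
    placed["irrs"].sort()
    placed["k27"].sort()
    return reads


def _emit_cx_report(config, placed, chrom_sizes, rng, path) -> None:
    """Cytosine records over feature spans plus flanks, binomial counts with
    beta-distributed per-site means; boosted inside IRRs and 24-nt sources."""
    flank = config.flank_bp
    windows_by_chrom: Dict[str, List[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for feats in (placed["transcripts"], placed["genes"]):
        for feat in feats:
            iv = feat.interval
            windows_by_chrom[iv.chrom].append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - flank),
                    min(chrom_sizes[iv.chrom], iv.end + flank),
                )
            )
    for iv in placed["irrs"]:
        windows_by_chrom[iv.chrom].append(iv)

    boosted_by_chrom: Dict[str, List[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in placed["irrs"] + placed["sources"]:
        boosted_by_chrom[iv.chrom].append(iv)

    contexts = np.array(["CG", "CHG", "CHH"])
    weights = np.array([config.context_weights[c] for c in contexts], dtype=float)
    weights /= weights.sum()
    base = np.array([config.methylation_base[c] for c in contexts])
    conc = config.methylation_concentration

    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            wins = merge_intervals(windows_by_chrom[chrom]) if windows_by_chrom[chrom] else []
            if not wins:
                continue
            pos = np.concatenate(
                [np.arange(w.start, w.end, config.cx_site_spacing) for w in wins]
            )
            ctx_idx = rng.choice(len(contexts), size=len(pos), p=weights)
            mean = base[ctx_idx].copy()
            boosted = merge_intervals(boosted_by_chrom[chrom]) if boosted_by_chrom[chrom] else []
            if boosted:
                bs = np.array([b.start for b in boosted])
                be = np.array([b.end for b in boosted])
                j = np.searchsorted(bs, pos, side="right") - 1
                inside = (j >= 0) & (pos < be[np.clip(j, 0, None)])
                mean[inside] += config.methylation_boost
            mean = np.clip(mean, 1e-3, 0.999)
            site_mean = rng.beta(mean * conc, (1 - mean) * conc)
            depth = rng.poisson(config.read_depth, size=len(pos))
            mc = rng.binomial(depth, site_mean)
            umc = depth - mc
            strands = np.where(pos % 2 == 0, "+", "-")
            for p, s, m, u, ci in zip(pos, strands, mc, umc, ctx_idx):
                fh.write(f"{chrom}\t{p + 1}\t{s}\t{m}\t{u}\t{contexts[ci]}\n")


def _emit_expression(config, placed, rng):
    mu, sigma = config.expression_lognormal
    records: List[ExpressionRecord] = []
    fpkm_true: Dict[str, float] = {}
    truth_by_id = {t["transcript_id"]: t for t in placed["truth"]}
    for tx in placed["transcripts"]:
        entry = truth_by_id[tx.id]
        base = float(rng.lognormal(mu, sigma))
        if entry["sirna"]:
            base *= config.sirna_expression_effect
        reps = base * np.exp(rng.normal(0.0, config.replicate_sigma, config.n_replicates))
        records.append(ExpressionRecord(tx.id, tuple(float(v) for v in reps)))
        fpkm_true[tx.id] = base
    return records, fpkm_true


def _emit_hsps(config, placed, rng, outdir: Path) -> None:
    queries = placed["transcripts"]
    for genome in TARGET_GENOMES:
        mean_cov = config.conservation_mean_coverage[genome]
        hit_prob = config.conservation_hit_prob[genome]
        conc = config.coverage_concentration
        hsps: List[HSPRecord] = []
        for tx in queries:
            if rng.random() >= hit_prob:
                continue
            qlen = tx.length
            cov = float(rng.beta(mean_cov * conc, (1 - mean_cov) * conc))
            aligned = max(60, min(qlen, int(round(cov * qlen))))
            n_hsp = 1 if aligned < 200 else int(rng.integers(1, 4))
            pieces = _split_lengths(rng, aligned, n_hsp, min_len=40)
            slack = qlen - aligned
            gap_alloc = rng.multinomial(slack, np.full(n_hsp + 1, 1.0 / (n_hsp + 1)))
            sid = f"{genome}_scaffold{int(rng.integers(1, 9))}"
            minus = rng.random() < 0.5
            scursor = int(rng.integers(50_000, 2_000_000))
            qcursor = 1 + int(gap_alloc[0])
            placed_pieces = []
            for i, plen in enumerate(pieces):
                qs, qe = qcursor, qcursor + plen - 1
                placed_pieces.append((qs, qe, plen))
                qcursor = qe + 1 + int(gap_alloc[i + 1])
            for qs, qe, plen in placed_pieces:
                ss = scursor
                se = scursor + plen - 1
                scursor = se + 1 + int(rng.integers(0, 500))
                if minus:
                    ss, se = 4_000_000 - ss, 4_000_000 - se
                hsps.append(
                    HSPRecord(
                        query_id=tx.id,
                        subject_id=sid,
                        query_start=qs,
                        query_end=qe,
                        subject_start=ss,
                        subject_end=se,
                        bitscore=round(1.8 * plen, 1),
                        evalue=1e-30,
                        pident=95.0,
                        align_length=plen,
                    )
                )
            if rng.random() < 0.3:
                # weaker decoy hit on another subject
                dlen = max(40, aligned // 3)
                ds = int(rng.integers(1, max(2, qlen - dlen)))
                hsps.append(
                    HSPRecord(
                        query_id=tx.id,
                        subject_id=f"{genome}_scaffold_decoy",
                        query_start=ds,
                        query_end=ds + dlen - 1,
                        subject_start=1_000,
                        subject_end=1_000 + dlen - 1,
                        bitscore=round(0.9 * dlen, 1),
                        evalue=1e-12,
                        pident=80.0,
                        align_length=dlen,
                    )
                )
        io.write_hsp_table(outdir / f"hsp_{genome}.tsv", hsps)


def _emit_go(config, placed, rng, map_path, names_path) -> None:
    genes = sorted(g.id for g in placed["genes"])
    inc_hosts = set(placed["inc_hosts"])
    terms = [f"GO:{7000000 + i}" for i in range(config.n_go_terms - 1)]
    enriched = config.enriched_term
    rows = []
    for gid in genes:
        p_enriched = config.go_enriched_prob if gid in inc_hosts else config.go_background_prob
        if rng.random() < p_enriched:
            rows.append((gid, enriched))
        for term in terms:
            if rng.random() < config.go_background_prob:
                rows.append((gid, term))
    with open(map_path, "w") as fh:
        fh.write("gene\tterm\n")
        for gid, term in rows:
            fh.write(f"{gid}\t{term}\n")
    with open(names_path, "w") as fh:
        fh.write(f"{enriched}\ttranscription, DNA-templated\n")
        for i, term in enumerate(terms):
            fh.write(f"{term}\tsynthetic process {i + 1}\n")
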