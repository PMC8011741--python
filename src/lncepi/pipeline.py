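"""End-to-end pipeline: wire the analysis stages over a flat config.

The config is a flat ``key = value`` text file (or an equivalent dict)
naming input files and overriding defaults. Missing inputs for the
requested stages are reported before any computation starts, and each
stage is a pure function of its declared inputs plus the config, so a
rerun with the same config produces byte-identical summary tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from . import __version__, io
from .classify import (
    DistanceBinSpec,
    classify_transcripts,
    distance_bin_proportions,
    exon_count_distribution,
    length_summary,
)
from .conservation import band_summary, band_summary_frame, chain_hsps, coverage_summary
from .enrichment import enrich
from .expression import anova_lengths, expression_table
from .intervals import GenomicInterval
from .marks import joint_irr_sirna, mark_status_table, stratify
from .metaprofile import (
    CoverageSignal,
    MethylationSignal,
    ProfileSpec,
    aggregate_profiles,
)
from .methylation import CytosineIndex, region_levels_table
from .models import CONTEXTS
from .sirna import filter_24nt

logger = logging.getLogger("lncepi")

ALL_STAGES = (
    "classify",
    "marks",
    "methylation",
    "profile",
    "stats",
    "conserve",
    "enrich",
)

#: config keys naming input files needed by each stage
STAGE_INPUTS: Dict[str, Sequence[str]] = {
    "classify": ("transcripts", "genes", "coding_hits"),
    "marks": ("transcripts", "genes", "coding_hits", "irr", "srna", "k27"),
    "methylation": ("transcripts", "cx_report"),
    "profile": ("transcripts", "genes", "coding_hits", "irr", "srna", "cx_report", "k27", "chrom_sizes"),
    "stats": ("transcripts", "genes", "coding_hits", "irr", "srna", "k27", "fpkm"),
    "conserve": ("transcripts",),  # plus >=1 hsp_* key
    "enrich": ("transcripts", "genes", "coding_hits", "irr", "srna", "k27", "go_map"),
}

DEFAULT_PARAMS = {
    "evalue_cutoff": 1e-10,
    "cluster_gap": 100,
    "cluster_min_reads": 3,
    "sirna_mode": "containment",
    "body_bins": 40,
    "flank_bp": 2000,
    "flank_bins": 20,
    "alpha_fdr": 0.01,
    "log2_expression": False,
    "max_chain_gap": 10000,
}


def read_config(path) -> Dict[str, str]:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {line_no}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def config_for_dataset(dataset_dir) -> Dict[str, str]:
    """Config dict pointing at the file layout written by generate_dataset."""
    d = Path(dataset_dir)
    cfg = {
        "transcripts": str(d / "transcripts.gff3"),
        "genes": str(d / "genes.gff3"),
        "coding_hits": str(d / "coding_hits.tsv"),
        "irr": str(d / "irr.bed"),
        "srna": str(d / "srna_reads.tsv"),
        "k27": str(d / "k27_domains.bed"),
        "cx_report": str(d / "cx_report.tsv"),
        "fpkm": str(d / "fpkm.tsv"),
        "go_map": str(d / "go_map.tsv"),
        "term_names": str(d / "term_names.tsv"),
        "chrom_sizes": str(d / "chrom_sizes.tsv"),
    }
    for hsp in sorted(d.glob("hsp_*.tsv")):
        cfg[f"hsp_{hsp.stem[4:]}"] = str(hsp)
    return cfg


def _validate_inputs(config: Dict[str, str], stages: Sequence[str]) -> None:
    missing: List[str] = []
    for stage in stages:
        for key in STAGE_INPUTS.get(stage, ()):
            path = config.get(key)
            if path is None:
                missing.append(f"{stage}: config key '{key}' not set")
            elif not Path(path).exists():
                missing.append(f"{stage}: {key} file not found: {path}")
        if stage == "conserve" and not any(k.startswith("hsp_") for k in config):
            missing.append("conserve: no hsp_<genome> inputs configured")
    if missing:
        raise FileNotFoundError("pipeline input validation failed:\n  " + "\n  ".join(missing))


def _param(config, key, cast):
    raw = config.get(key)
    if raw is None:
        return DEFAULT_PARAMS[key]
    if cast is bool:
        return str(raw).lower() in ("1", "true", "yes")
    return cast(raw)


def run_pipeline(
    config,
    outdir,
    stages: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> Path:
    """Run the requested stages (default: all) and write TSV outputs.

    ``config`` is a path to a flat key=value file or a dict. Returns the
    output directory; a ``run_manifest.json`` records inputs, parameters
    and the package version.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    stages = list(stages) if stages else list(ALL_STAGES)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    _validate_inputs(config, stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    evalue_cutoff = _param(config, "evalue_cutoff", float)
    sirna_mode = _param(config, "sirna_mode", str)
    log2 = _param(config, "log2_expression", bool)

    genes = transcripts = labeled = None
    paired: Dict[str, str] = {}
    status_df = None
    reads24 = None

    def ensure_classified():
        nonlocal genes, transcripts, labeled, paired
        if labeled is None:
            genes, _ = io.read_gff(config["genes"])
            _, transcripts = io.read_gff(config["transcripts"])
            hits = io.read_coding_hits(config["coding_hits"]) if config.get("coding_hits") else []
            labeled, paired = classify_transcripts(
                transcripts, genes, hits, evalue_cutoff=evalue_cutoff
            )
        return labeled

    def ensure_status():
        nonlocal status_df, reads24
        if status_df is None:
            txs = ensure_classified()
            irrs = io.read_bed(config["irr"])
            k27 = io.read_bed(config["k27"])
            reads = io.read_srna_table(config["srna"])
            reads24 = filter_24nt(reads, unique_only=True)
            status_df = mark_status_table(
                txs, irrs=irrs, reads24=reads24, k27_domains=k27, sirna_mode=sirna_mode
            )
        return status_df

    if "classify" in stages:
        txs = ensure_classified()
        pd.DataFrame(
            {
                "transcript_id": [t.id for t in txs],
                "class": [t.class_label for t in txs],
                "paired_gene": [paired.get(t.id, "") for t in txs],
            }
        ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
        exon_count_distribution(txs).to_csv(outdir / "exon_counts.tsv", sep="\t", float_format="%.6g")
        length_summary(txs).to_csv(outdir / "length_summary.tsv", sep="\t", float_format="%.6g")
        distance_bin_proportions(txs, genes, DistanceBinSpec()).to_csv(
            outdir / "distance_bins.tsv", sep="\t", float_format="%.6g"
        )

    if "marks" in stages:
        sdf = ensure_status()
        out = sdf.copy()
        for col in ("irr", "sirna", "k27"):
            out[col] = out[col].astype(int)
        out.to_csv(outdir / "status.tsv", sep="\t", index=False)
        stratify(sdf).to_csv(outdir / "stratification.tsv", sep="\t", index=False, float_format="%.6g")
        joint_irr_sirna(sdf).to_csv(
            outdir / "stratification_joint.tsv", sep="\t", index=False, float_format="%.6g"
        )

    if "methylation" in stages:
        txs = ensure_classified()
        records = io.read_cx_report(config["cx_report"])
        index = CytosineIndex(records)
        regions = [(t.id, t.interval) for t in txs]
        region_levels_table(index, regions).to_csv(
            outdir / "methylation.tsv", sep="\t", index=False, float_format="%.6g"
        )

    if "profile" in stages:
        txs = ensure_classified()
        chrom_sizes = io.read_chrom_sizes(config["chrom_sizes"])
        spec = ProfileSpec(
            body_bins=_param(config, "body_bins", int),
            flank_bp=_param(config, "flank_bp", int),
            flank_bins=_param(config, "flank_bins", int),
        )
        reads = io.read_srna_table(config["srna"])
        r24 = filter_24nt(reads, unique_only=True)
        sirna_signal = CoverageSignal.from_reads(r24, chrom_sizes, rpm_library=len(reads))
        k27_signal = CoverageSignal.from_intervals(io.read_bed(config["k27"]), chrom_sizes)
        meth_index = CytosineIndex(io.read_cx_report(config["cx_report"]))
        feature_sets = {
            "genes": [g.interval for g in genes],
            "IRR": io.read_bed(config["irr"]),
        }
        for cls in ("lincRNA", "NAT", "incRNA", "putative_mRNA"):
            ivs = [t.interval for t in txs if t.class_label == cls]
            if ivs:
                feature_sets[cls] = ivs
        rows = []
        for set_name, features in feature_sets.items():
            signals = {"sirna_rpm": sirna_signal, "k27_coverage": k27_signal}
            for ctx in CONTEXTS:
                signals[f"methylation_{ctx}"] = MethylationSignal(meth_index, ctx)
            for sig_name, signal in signals.items():
                try:
                    profile = aggregate_profiles(features, signal, spec)
                except ValueError:
                    continue
                frame = profile.to_frame()
                frame.insert(0, "signal", sig_name)
                frame.insert(0, "feature_set", set_name)
                rows.append(frame)
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )

    if "stats" in stages:
        sdf = ensure_status()
        records = io.read_expression(config["fpkm"])
        expression_table(records, sdf, log2=log2).to_csv(
            outdir / "expression_tests.tsv", sep="\t", index=False, float_format="%.6g"
        )
        lengths = {}
        for tx in ensure_classified():
            lengths.setdefault(tx.class_label, []).append(tx.length)
        lengths.pop("unclassified", None)
        result = anova_lengths(lengths)
        with open(outdir / "length_anova.tsv", "w") as fh:
            fh.write("class\tletters\tF\tp\n")
            for cls in sorted(result.letters):
                fh.write(f"{cls}\t{result.letters[cls]}\t{result.F:.6g}\t{result.p:.6g}\n")

    if "conserve" in stages:
        txs = ensure_classified()
        qlens = {t.id: t.length for t in txs}
        classes = {t.id: t.class_label for t in txs}
        calls_by_genome = {}
        rows = []
        for key in sorted(config):
            if not key.startswith("hsp_"):
                continue
            genome = key[4:]
            hsps = io.read_hsp_table(config[key])
            calls = chain_hsps(
                hsps,
                qlens,
                target_genome=genome,
                max_gap=_param(config, "max_chain_gap", int),
                evalue_cutoff=evalue_cutoff,
            )
            calls_by_genome[genome] = calls
            for qid in sorted(calls):
                call = calls[qid]
                rows.append(
                    {
                        "query_id": qid,
                        "genome": genome,
                        "class": classes.get(qid, ""),
                        "subject_id": call.subject_id or "",
                        "coverage": call.coverage,
                        "total_score": call.total_score,
                    }
                )
        pd.DataFrame(rows).to_csv(
            outdir / "conservation_coverage.tsv", sep="\t", index=False, float_format="%.6g"
        )
        coverage_summary(calls_by_genome, classes).to_csv(
            outdir / "conservation_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if config.get("band_matrix"):
            matrix = io.read_band_matrix(config["band_matrix"])
            groups = {}
            if config.get("line_groups"):
                for part in config["line_groups"].split(";"):
                    name, _, cols = part.partition(":")
                    groups[name.strip()] = [c.strip() for c in cols.split(",")]
            else:
                groups["all"] = list(matrix.columns)
            band_summary_frame(band_summary(matrix, groups)).to_csv(
                outdir / "band_summary.tsv", sep="\t", index=False
            )

    if "enrich" in stages:
        ensure_classified()
        sdf = ensure_status()
        go_map = io.read_go_map(config["go_map"])
        term_names = io.read_term_names(config["term_names"]) if config.get("term_names") else None
        population = sorted({g.id for g in genes})
        marked = sdf[sdf[["irr", "sirna", "k27"]].any(axis=1)]["transcript_id"]
        marked = set(marked)
        study_sets = {}
        for cls in ("incRNA", "NAT"):
            ids = [t for t, c in zip(sdf["transcript_id"], sdf["class"]) if c == cls]
            study_sets[cls] = sorted(
                {paired[t] for t in ids if t in paired and paired[t] in set(population)}
            )
            study_sets[f"{cls}_marked"] = sorted(
                {
                    paired[t]
                    for t in ids
                    if t in marked and t in paired and paired[t] in set(population)
                }
            )
        alpha = _param(config, "alpha_fdr", float)
        for name, study in study_sets.items():
            if not study:
                continue
            enrich(study, population, go_map, alpha_fdr=alpha, term_names=term_names).to_csv(
                outdir / f"enrichment_{name}.tsv", sep="\t", index=False, float_format="%.6g"
            )

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "inputs": {k: v for k, v in config.items()},
        "parameters": {k: _param(config, k, type(v) if not isinstance(v, bool) else bool)
                       for k, v in DEFAULT_PARAMS.items()},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished: %s", outdir)
    return outdir
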