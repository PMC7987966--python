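"""Configuration-driven orchestration of the full G4-landscape analysis.

Stages run in a fixed order — predict, annotate, enrich, compare, link —
each logged, and the results are assembled into a JSON-serializable report
whose every number comes from one of the library operations. Conditions are
labelled generically (condition_a / condition_b) so the pipeline is reusable
beyond any one disease contrast; classes of peaks are reported relative to
condition_a ("gained" = specific to A, "lost" = specific to B).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .expression_link import (
    PeakClass,
    assign_peaks_to_genes,
    read_de_table,
    read_splicing_calls,
    summarize_peak_splicing,
    upregulated_fraction,
)
from .feature_annotation import (
    GenomicContext,
    LadMap,
    compare_peaksets,
    genome_repartition,
    genomic_context_profile,
    lad_colocalization,
    peak_repeat_profile,
    read_rmsk,
    repeats_as_interval_sets,
)
from .genome_io import IntervalSet, OverlapIndex, coverage_fraction, read_bed, read_fasta
from .g4_predict import PRESETS, genome_g4_track, peaks_with_g4_fraction
from .region_enrichment import multi_feature_enrichment

logger = logging.getLogger("g4scape.pipeline")


@dataclass
class AnalysisConfig:
    """File paths and knobs for one full analysis run."""

    genome_fasta: str
    peaks_a: str
    peaks_b: str | None = None
    rmsk: str | None = None
    clad: str | None = None
    flad: str | None = None
    genes: str | None = None
    enhancers: str | None = None
    cpg_islands: str | None = None
    de_table: str | None = None
    splicing_calls: str | None = None
    preset: str = "canonical"
    flank: int = 50
    n_perm: int = 1000
    seed: int = 0
    outdir: str = "g4scape_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output directory
        is excluded so reruns into different directories compare equal)."""
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    logger.info("stage: %s", name)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and return the report dict (also written to
    ``<outdir>/report.json`` together with per-table TSVs)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "g4scape_version": __version__,
            "preset": config.preset,
        }
    }

    try:
        _stage("predict")
        seqs, genome = read_fasta(config.genome_fasta)
        params = PRESETS[config.preset]
        g4 = genome_g4_track(seqs, genome, params, "both")
        report["g4_track"] = {
            "n_motifs": len(g4),
            "genome_coverage": coverage_fraction(g4, genome),
        }

        peaks = {"condition_a": read_bed(config.peaks_a, genome)}
        if config.peaks_b:
            peaks["condition_b"] = read_bed(config.peaks_b, genome)
        report["peak_g4"] = {}
        for cond, pk in peaks.items():
            frac, _ = peaks_with_g4_fraction(pk, g4, flank=config.flank)
            report["peak_g4"][cond] = {"n_peaks": len(pk), "fraction_with_g4": frac}
    except Exception as e:
        raise RuntimeError(f"stage 'predict' failed: {e}") from e

    try:
        _stage("annotate")
        pa = peaks["condition_a"]
        if config.rmsk:
            repeats = read_rmsk(config.rmsk, genome)
            report["repeat_profile"] = {
                level: peak_repeat_profile(pa, repeats, level).to_dict()
                for level in ("class", "family")
            }
        if config.clad and config.flad:
            lads = LadMap(read_bed(config.clad, genome), read_bed(config.flad, genome))
            report["lad"] = {
                "peak_colocalization": lad_colocalization(pa, lads),
                "genome_repartition": genome_repartition(
                    {"cLAD": lads.clad, "fLAD": lads.flad}, genome
                ),
            }
        if config.genes and config.enhancers and config.cpg_islands:
            context = GenomicContext(
                read_bed(config.genes, genome),
                read_bed(config.enhancers, genome),
                read_bed(config.cpg_islands, genome),
            )
            report["genomic_context"] = genomic_context_profile(pa, context)
    except Exception as e:
        raise RuntimeError(f"stage 'annotate' failed: {e}") from e

    try:
        _stage("enrich")
        features: dict[str, IntervalSet] = {"predicted_g4": g4}
        if config.rmsk:
            features.update(repeats_as_interval_sets(repeats, genome, "family"))
        table = multi_feature_enrichment(
            pa, features, n_perm=config.n_perm, flank=0, rng_seed=config.seed
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        report["enrichment"] = table.to_dict(orient="index")
    except Exception as e:
        raise RuntimeError(f"stage 'enrich' failed: {e}") from e

    try:
        _stage("compare")
        if "condition_b" in peaks:
            pb = peaks["condition_b"]
            report["peakset_comparison"] = compare_peaksets(pa, pb)
    except Exception as e:
        raise RuntimeError(f"stage 'compare' failed: {e}") from e

    try:
        _stage("link")
        if config.genes and config.de_table:
            genes = read_bed(config.genes, genome)
            de = read_de_table(config.de_table)
            report["expression"] = {
                "upregulated_fraction": upregulated_fraction(de)
            }
            classes = []
            if "condition_b" in peaks:
                pb = peaks["condition_b"]
                b_idx, a_idx = OverlapIndex(pb), OverlapIndex(pa)
                gained = IntervalSet([p for p in pa if b_idx.count(p) == 0], genome)
                lost = IntervalSet([p for p in pb if a_idx.count(p) == 0], genome)
                common = IntervalSet([p for p in pa if b_idx.count(p) > 0], genome)
                for label, pset in (("lost", lost), ("common", common), ("gained", gained)):
                    gene_ids: set[str] = set()
                    if len(pset):
                        for gs in assign_peaks_to_genes(pset, genes):
                            gene_ids.update(gs)
                    classes.append(PeakClass(label, frozenset(gene_ids)))
            else:
                gene_ids = set()
                for gs in assign_peaks_to_genes(pa, genes):
                    gene_ids.update(gs)
                classes.append(PeakClass("condition_a", frozenset(gene_ids)))
            calls = (
                read_splicing_calls(config.splicing_calls)
                if config.splicing_calls else []
            )
            summary = summarize_peak_splicing(classes, calls, de)
            summary.to_csv(outdir / "peak_splicing_summary.tsv", sep="\t")
            report["peak_classes"] = {
                c.label: {"n_genes": len(c.genes)} for c in classes
            }
            report["splicing_summary"] = summary.reset_index().to_dict(orient="records")
        else:
            report["expression"] = {"skipped": True}
            logger.info("link stage skipped: no DE table / gene BED configured")
    except Exception as e:
        raise RuntimeError(f"stage 'link' failed: {e}") from e

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    logger.info("report written to %s", outdir / "report.json")
    return report
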