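"""End-to-end discovery pipeline: genotypes → ROH → triage → retention →
consequence → RT-PCR/qPCR, from a single JSON config.

``make_demo`` writes a complete synthetic cohort bundle (genotypes, marker
map, VCF, gene models, junction reads, fragment areas, Ct values and a
truth sidecar); ``run_pipeline`` executes every stage in dependency order
and serialises a machine-readable discovery report.  Failures are surfaced
as :class:`StageError` naming the stage, so a broken input does not corrupt
the outputs of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consequence import retained_intron_orf
from .models import (
    GeneModel,
    GenomicInterval,
    RegionSequence,
    load_gene_model,
    write_gene_model_bed12,
    write_gene_model_gff_lite,
)
from .retention import (
    JunctionCounts,
    allelic_association,
    compare_groups,
    count_junctions,
    retention_table,
)
from .roh import detect_roh_all, lod_profile, minimal_overlap_roh
from .rtpcr import ddct_relative, group_summary
from .simulate import (
    CohortSpec,
    ReadSimConfig,
    SpliceQuantSimConfig,
    demo_gene,
    demo_gene_plus,
    gen_genotypes,
    gen_junction_reads,
    gen_splice_quant,
    gen_variant_fixture,
    read_genotypes_tsv,
    read_reads_tsv,
    read_vcf,
    write_genotypes_tsv,
    write_reads_tsv,
    write_splice_quant_tsv,
    write_vcf,
)
from .triage import triage_summary


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (JSON-serialisable)."""

    genotypes: str
    marker_map: str
    vcf: str
    gene_model: str
    gene_region_json: str          # {"chrom":..,"start":..,"seq":..}
    reads: str
    areas: str
    ct: str
    anchor: dict = field(
        default_factory=lambda: {"chrom": "21", "start": 33_344_469, "end": 34_196_070}
    )
    variant: dict = field(
        default_factory=lambda: {"pos": 33_582_064, "ref": "T", "alt": "C"}
    )
    focal_intron: int = 6
    af_threshold: float = 0.01
    min_anchor: int = 6
    roh_min_markers: int = 25
    roh_min_length_kb: int = 500
    roh_max_missing_run: int = 2
    lod_error_rate: float = 0.01
    lod_window: int = 11
    nmd_rule_nt: int = 50
    reference_group: str = "control"
    seed: int = 0
    outdir: str = "retmap_out"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _anchor_interval(cfg: PipelineConfig) -> GenomicInterval:
    a = cfg.anchor
    return GenomicInterval(str(a["chrom"]), int(a["start"]), int(a["end"]))


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> dict:
    """Execute all stages; return (and optionally write) the discovery report."""
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(cfg), sort_keys=True).encode()
            ).hexdigest()[:16],
        }
    }
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- homozygosity mapping -------------------------------------------
    stage = "roh"
    try:
        genotypes, marker_map = read_genotypes_tsv(cfg.genotypes, cfg.marker_map)
        affected = genotypes[genotypes["role"] == "affected"]
        segs = detect_roh_all(
            affected,
            marker_map,
            min_markers=cfg.roh_min_markers,
            min_length_kb=cfg.roh_min_length_kb,
            max_missing_run=cfg.roh_max_missing_run,
        )
        candidate = minimal_overlap_roh(segs, _anchor_interval(cfg))
        prof = lod_profile(
            genotypes, marker_map, eps=cfg.lod_error_rate, window=cfg.lod_window
        )
        peak = prof.loc[prof["lod"].idxmax()]
        report["candidate_interval"] = {
            "chrom": candidate.interval.chrom,
            "start": candidate.interval.start,
            "end": candidate.interval.end,
            "n_inconsistent_markers": len(candidate.inconsistent_markers),
            "lod_peak_marker": str(peak["marker_id"]),
            "lod_peak_pos": int(peak["pos"]),
            "lod_peak": float(peak["lod"]),
        }
        if write:
            prof.to_csv(outdir / "lod_profile.tsv", sep="\t", index=False)
    except (OSError, ValueError, KeyError) as e:
        raise StageError(stage, str(e)) from e

    # --- variant triage -------------------------------------------------
    stage = "triage"
    try:
        variants = read_vcf(cfg.vcf)
        gene = load_gene_model(cfg.gene_model)
        with open(cfg.gene_region_json) as fh:
            region = RegionSequence(**json.load(fh))
        models: list[tuple[GeneModel, RegionSequence | None]] = [(gene, region)]
        interval = GenomicInterval(
            candidate.interval.chrom, candidate.interval.start, candidate.interval.end
        )
        summary = triage_summary(variants, models, interval, cfg.af_threshold)
        table = summary.pop("table")
        report["triage"] = summary
        if write:
            table.to_csv(outdir / "triage.tsv", sep="\t", index=False)
    except (OSError, ValueError, KeyError) as e:
        raise StageError(stage, str(e)) from e

    # --- retention ------------------------------------------------------
    stage = "retention"
    try:
        reads = read_reads_tsv(cfg.reads)
        per_sample, per_group = count_junctions(
            reads, gene, min_anchor=cfg.min_anchor
        )
        rtable = retention_table(per_group)
        focal = per_group[per_group["intron"] == cfg.focal_intron]
        counts_by_group = {
            str(r["group"]): JunctionCounts(
                cfg.focal_intron, int(r["spanning"]), int(r["spliced"]), str(r["group"])
            )
            for _, r in focal.iterrows()
        }
        comparisons = compare_groups(counts_by_group)
        het = reads[reads["group"] == "parent"]
        assoc = allelic_association(het, cfg.variant["alt"], cfg.variant["ref"])
        report["retention"] = {
            "focal_intron": cfg.focal_intron,
            "by_group": {
                str(r["group"]): {
                    "spanning": int(r["spanning"]),
                    "spliced": int(r["spliced"]),
                    "retention": float(r["retention"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                }
                for _, r in rtable[rtable["intron"] == cfg.focal_intron].iterrows()
            },
            "comparisons": [
                {
                    "groups": [c.group_a, c.group_b],
                    "p_raw": c.p_raw,
                    "p_holm": c.p_adjusted,
                }
                for c in comparisons
            ],
            "allelic_association": {
                "mutant_reads": assoc.mutant_reads,
                "reference_reads": assoc.reference_reads,
                "mutant_fraction": assoc.mutant_fraction,
                "p_value": assoc.p_value,
            },
            "top_retained_intron_affected": int(
                rtable[rtable["group"] == "affected"]
                .sort_values("retention", ascending=False)
                .iloc[0]["intron"]
            ),
        }
        if write:
            rtable.to_csv(outdir / "retention.tsv", sep="\t", index=False)
            per_sample.to_csv(outdir / "retention_per_sample.tsv", sep="\t", index=False)
    except (OSError, ValueError, KeyError) as e:
        raise StageError(stage, str(e)) from e

    # --- consequence ----------------------------------------------------
    stage = "consequence"
    try:
        cons = retained_intron_orf(gene, region, cfg.focal_intron, cfg.nmd_rule_nt)
        report["consequence"] = asdict(cons)
    except (OSError, ValueError, KeyError) as e:
        raise StageError(stage, str(e)) from e

    # --- RT-PCR / qPCR --------------------------------------------------
    stage = "rtpcr"
    try:
        areas = pd.read_csv(cfg.areas, sep="\t")
        ct = pd.read_csv(cfg.ct, sep="\t")
        summaries, tests = group_summary(areas)
        rel = ddct_relative(ct, cfg.reference_group)
        report["splice_quant"] = {
            "groups": [asdict(s) for s in summaries],
            "pairwise_t": [
                {"groups": [t.group_a, t.group_b], "t": t.t_statistic,
                 "p_raw": t.p_raw, "p_holm": t.p_adjusted}
                for t in tests
            ],
            "relative_expression": [asdict(r) for r in rel],
        }
    except (OSError, ValueError, KeyError) as e:
        raise StageError(stage, str(e)) from e

    if write:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def make_demo(outdir, seed: int = 7) -> PipelineConfig:
    """Write the full synthetic cohort bundle and return a ready config.

    The bundle emulates the study at desk scale: SNP genotypes with a
    shared autozygous segment, a variant fixture with 38 rare noncoding
    variants in the candidate interval, allele-tagged junction reads over
    the demonstration gene, and RT-PCR/qPCR quantification tables.  A
    ``truth.json`` sidecar documents every latent parameter.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    model, region, variant = demo_gene(0)
    genotypes, marker_map, geno_truth = gen_genotypes(
        CohortSpec(seed=seed, error_rate=0.0, missing_rate=0.01)
    )
    write_genotypes_tsv(
        genotypes, marker_map, out / "genotypes.tsv", out / "marker_map.tsv"
    )
    variants, var_truth = gen_variant_fixture(seed)
    write_vcf(variants, out / "variants.vcf")
    var_truth.to_csv(out / "variants_truth.tsv", sep="\t", index=False)

    write_gene_model_bed12(model, out / "gene_model.bed")
    write_gene_model_gff_lite(model, out / "gene_model.gff")
    with open(out / "gene_region.json", "w") as fh:
        json.dump({"chrom": region.chrom, "start": region.start, "seq": region.seq}, fh)

    reads, read_truth = gen_junction_reads(
        ReadSimConfig(gene=model, seed=seed, fragments_per_sample_per_intron=120)
    )
    write_reads_tsv(reads, out / "reads.tsv")

    quant, quant_truth = gen_splice_quant(SpliceQuantSimConfig(seed=seed))
    write_splice_quant_tsv(quant, out / "areas.tsv", out / "ct.tsv")

    truth = {
        "seed": seed,
        "autozygous_segment": {
            "chrom": geno_truth["segment"].chrom,
            "start": geno_truth["segment"].start,
            "end": geno_truth["segment"].end,
        },
        "variant": variant,
        "retention": read_truth,
        "splice_quant": {
            "fraction_unspliced": {
                g: list(v) for g, v in quant_truth["fraction_unspliced"].items()
            },
            "relative_expression": quant_truth["relative_expression"],
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    cfg = PipelineConfig(
        genotypes=str(out / "genotypes.tsv"),
        marker_map=str(out / "marker_map.tsv"),
        vcf=str(out / "variants.vcf"),
        gene_model=str(out / "gene_model.bed"),
        gene_region_json=str(out / "gene_region.json"),
        reads=str(out / "reads.tsv"),
        areas=str(out / "areas.tsv"),
        ct=str(out / "ct.tsv"),
        seed=seed,
        outdir=str(out / "results"),
    )
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, sort_keys=True)
    return cfg
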