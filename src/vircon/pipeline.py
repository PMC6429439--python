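"""End-to-end pipeline: ingest -> annotate -> contrast -> scan -> stats
-> pfam -> candidates, with one machine-readable summary."""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import candidates as candidates_mod
from . import contrast as contrast_mod
from . import effects as effects_mod
from . import genomic_io as io
from . import pfam as pfam_mod
from . import scan as scan_mod
from . import stats as stats_mod
from .errors import ConfigError
from .models import SV, ScanParams, SVFilterParams

log = logging.getLogger(__name__)

STAGES = ("annotate", "contrast", "scan", "stats", "pfam", "candidates")


@dataclass
class PipelineConfig:
    fasta: str
    gff3: str
    vcf: str
    samples: tuple[str, str]
    outdir: str
    domains: Optional[str] = None
    prior_gene_list: Optional[str] = None
    scan_params: ScanParams = field(default_factory=ScanParams)
    sv_filter: SVFilterParams = field(default_factory=SVFilterParams)
    require_difference: bool = False
    skip: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        scan_keys = {k: raw.pop(k) for k in ("window_size", "step", "het_threshold", "min_variants") if k in raw}
        sv_keys = {k: raw.pop(k) for k in ("min_depth", "max_depth", "min_quality") if k in raw}
        if "samples" in raw:
            raw["samples"] = tuple(raw["samples"])
        cfg = cls(**raw)
        if scan_keys:
            cfg.scan_params = ScanParams(**{**cfg.scan_params.__dict__, **scan_keys})
        if sv_keys:
            cfg.sv_filter = SVFilterParams(**{**cfg.sv_filter.__dict__, **sv_keys})
        return cfg

    def validate(self) -> None:
        for label, p in (("fasta", self.fasta), ("gff3", self.gff3), ("vcf", self.vcf)):
            if not p or not Path(p).exists():
                raise ConfigError(f"{label} path missing or does not exist: {p!r}")
        for label, p in (("domains", self.domains), ("prior_gene_list", self.prior_gene_list)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p!r}")
        if len(self.samples) != 2:
            raise ConfigError("exactly two sample names are required")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage, writing per-stage tables plus summary.json and
    report.md under the output directory. Returns the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_a, sample_b = config.samples
    summary: dict = {"samples": list(config.samples), "stages": {}}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **counts):
        # timings go to the log only, keeping summary.json reproducible
        summary["stages"][name] = counts
        log.info("stage %s finished in %.2fs %s", name, time.time() - t0, counts)

    t0 = stage("ingest")
    genome = io.read_fasta(config.fasta)
    models = io.read_gff3(config.gff3)
    variants = io.read_vcf(config.vcf, config.samples)
    domains = io.read_domains(config.domains) if config.domains else []
    prior = None
    if config.prior_gene_list:
        prior = [
            line.strip()
            for line in Path(config.prior_gene_list).read_text().splitlines()
            if line.strip()
        ]
    done("ingest", t0, n_variants=len(variants), n_genes=len(models), n_domains=len(domains))

    # SV validation filter runs before everything downstream
    svs = [v for v in variants if v.var_class == SV]
    kept_svs, decisions = stats_mod.filter_sv(svs, config.sv_filter)
    variants = [v for v in variants if v.var_class != SV] + kept_svs
    variants.sort(key=lambda v: (v.chrom, v.pos))
    from collections import Counter

    summary["sv_filter"] = {
        "input": len(svs),
        "retained": len(kept_svs),
        "rejected": dict(Counter(d.reason for d in decisions if not d.retained)),
    }

    effects = None
    if "annotate" not in config.skip:
        t0 = stage("annotate")
        effects = effects_mod.annotate_all(variants, models, genome)
        io.write_tsv(effects_mod.effects_table(effects), outdir / "effects.tsv")
        done("annotate", t0, n_effects=len(effects))

    contrasts = None
    if "contrast" not in config.skip:
        t0 = stage("contrast")
        contrasts = contrast_mod.contrast_all(variants, sample_a, sample_b)
        summary["contrast"] = contrast_mod.contrast_summary(contrasts, sample_a, sample_b)
        done("contrast", t0, n_loci=len(contrasts))

    if "scan" not in config.skip:
        t0 = stage("scan")
        regions = {}
        all_stats = []
        for sample in config.samples:
            sample_stats = []
            for chrom, length in genome.lengths.items():
                sample_stats.extend(
                    scan_mod.scan_chromosome(
                        variants, chrom, length, config.scan_params, sample
                    )
                )
            regions[sample] = scan_mod.merge_regions(sample_stats, sample)
            all_stats.extend(sample_stats)
            io.write_bed(regions[sample], outdir / f"homozygous_regions.{sample}.bed")
        io.write_tsv(scan_mod.window_table(all_stats), outdir / "window_stats.tsv")
        diff = scan_mod.differential_regions(
            regions[sample_a], regions[sample_b], min_span=config.scan_params.window_size
        )
        io.write_bed(
            [(c, s, e, smp) for c, (s, e), smp in diff], outdir / "differential_regions.bed"
        )
        summary["scan"] = {
            "regions": {s: len(regions[s]) for s in config.samples},
            "differential": len(diff),
        }
        done("scan", t0, n_windows=len(all_stats))

    if "stats" not in config.skip:
        t0 = stage("stats")
        summary["variation"] = stats_mod.variation_summary(
            variants, config.samples, genome, effects=effects, models=models
        )
        done("stats", t0)

    if "pfam" not in config.skip and domains and effects is not None:
        t0 = stage("pfam")
        results = pfam_mod.enrich_all(effects, domains)
        io.write_tsv(pfam_mod.enrichment_table(results), outdir / "pfam_enrichment.tsv")
        summary["pfam"] = {
            "n_families": len(results),
            "flagged": [r.family for r in results if r.flagged],
        }
        done("pfam", t0, n_families=len(results))

    if "candidates" not in config.skip and effects is not None:
        t0 = stage("candidates")
        cands = candidates_mod.select_candidates(
            effects,
            models,
            config.samples,
            prior_list=prior,
            require_difference=config.require_difference,
        )
        io.write_tsv(candidates_mod.candidate_table(cands), outdir / "candidates.tsv")
        io.write_bed(
            [(c.chrom, c.position, c.position + 1, c.gene_id) for c in cands],
            outdir / "candidates.bed",
        )
        io.write_tsv(
            candidates_mod.physical_map_table(cands), outdir / "physical_map.tsv"
        )
        summary["candidates"] = {
            "n": len(cands),
            "per_chromosome": candidates_mod.per_chromosome_counts(cands),
        }
        done("candidates", t0, n_candidates=len(cands))

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_report(summary, outdir / "report.md")
    return summary


def _write_report(summary: dict, path: Path) -> None:
    lines = ["# Genome-contrast report", ""]
    lines.append(f"Samples: {', '.join(summary['samples'])}")
    if "variation" in summary:
        v = summary["variation"]
        lines += [
            "",
            "## Variation summary",
            f"- variants: {v['n_variants']} ({v['counts']})",
            f"- Ts/Tv: {v.get('ts_tv_ratio')}",
        ]
        for s, d in v.get("per_sample", {}).items():
            snp = d.get("SNP", {})
            lines.append(
                f"- {s}: {snp.get('n', 0)} SNP calls, hom fraction "
                f"{snp.get('hom_fraction') if snp.get('hom_fraction') is None else round(snp['hom_fraction'], 4)}"
            )
    if "scan" in summary:
        lines += [
            "",
            "## Homozygosity scan",
            f"- regions per sample: {summary['scan']['regions']}",
            f"- differential regions: {summary['scan']['differential']}",
        ]
    if "pfam" in summary:
        lines += ["", "## Pfam enrichment", f"- flagged families: {summary['pfam']['flagged']}"]
    if "candidates" in summary:
        lines += [
            "",
            "## Candidate genes",
            f"- candidates: {summary['candidates']['n']}",
            f"- per chromosome: {summary['candidates']['per_chromosome']}",
        ]
    path.write_text("\n".join(lines) + "\n")
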