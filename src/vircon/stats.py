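"""Descriptive genome-contrast statistics and post-call filters.

Covers the Ts/Tv ratio, the signed indel-length spectrum (1–30 bp by
definition; anything longer is a structural variant), per-chromosome
and per-region variant densities over a flattened intergenic / genic /
exon / intron partition, and the structural-variant depth/quality
filter.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import IntegrityError
from .genomic_io import normalize_indel
from .models import (
    GENIC_CDS,
    GENIC_INTRON,
    INDEL,
    INTERGENIC,
    SNP,
    SV,
    GeneModel,
    EffectCall,
    ReferenceGenome,
    SVFilterParams,
    VariantRecord,
)

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: sentinel for an undefined ratio (no transversions observed)
UNDEFINED = float("nan")


def ts_tv(snps: Sequence[VariantRecord]) -> tuple[float, int, int]:
    """Transition/transversion ratio over SNP alt alleles.

    Multi-allelic records contribute one observation per alt. Returns
    ``(ratio, ts_count, tv_count)``; the ratio is NaN when no
    transversions were seen.
    """
    ts = tv = 0
    for v in snps:
        if v.var_class != SNP or len(v.ref_allele) != 1:
            continue
        for alt in v.alt_alleles:
            if len(alt) != 1 or alt == v.ref_allele:
                continue
            if (v.ref_allele, alt) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    ratio = ts / tv if tv else UNDEFINED
    return ratio, ts, tv


def indel_spectrum(indels: Sequence[VariantRecord]) -> dict[int, int]:
    """Signed net-length histogram (+k insertion, -k deletion), k in 1..30."""
    hist: Counter[int] = Counter()
    for v in indels:
        if v.var_class != INDEL:
            continue
        base = v.vcf_pos if v.vcf_pos is not None else v.pos
        contributed = False
        for alt in v.alt_alleles:
            if len(alt) == len(v.ref_allele):
                continue  # SNP-like alt of a mixed multi-allelic record
            _, deleted, inserted = normalize_indel(base, v.ref_allele, alt)
            hist[len(inserted) - len(deleted)] += 1
            contributed = True
        if not contributed:
            raise IntegrityError(
                f"{v.chrom}:{base + 1}: zero net length change is not an indel"
            )
    return dict(sorted(hist.items()))


# ------------------------------------------------------- region partition


@dataclass
class RegionSpans:
    """Base-pair span of each region class (flattened, no double count)."""

    genome_bp: int
    genic_bp: int
    exon_bp: int  # CDS-exon bases

    @property
    def intergenic_bp(self) -> int:
        return self.genome_bp - self.genic_bp

    @property
    def intron_bp(self) -> int:
        return self.genic_bp - self.exon_bp


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def region_composition(models: Sequence[GeneModel], genome: ReferenceGenome) -> RegionSpans:
    """Partition the genome into intergenic / genic and genic into
    exon / intron; overlapping gene spans are flattened first."""
    genome_bp = sum(genome.lengths.values())
    genic = 0
    exon = 0
    by_chrom_spans: dict[str, list[tuple[int, int]]] = {}
    by_chrom_cds: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        by_chrom_spans.setdefault(m.chrom, []).append(m.gene_span)
        by_chrom_cds.setdefault(m.chrom, []).extend(m.cds_segments)
    for chrom in by_chrom_spans:
        genic += _union_length(by_chrom_spans[chrom])
        exon += _union_length(by_chrom_cds.get(chrom, []))
    return RegionSpans(genome_bp=genome_bp, genic_bp=genic, exon_bp=exon)


def region_density(effects: Sequence[EffectCall], spans: RegionSpans) -> dict:
    """Variants per Mb in each region class, per variant class.

    A variant overlapping several genes is counted once, in its most
    gene-proximal region class (CDS > intron > intergenic).
    """
    rank = {GENIC_CDS: 0, GENIC_INTRON: 1, INTERGENIC: 3}
    best: dict[int, EffectCall] = {}
    for c in effects:
        key = id(c.variant)
        if key not in best or rank.get(c.region_class, 2) < rank.get(best[key].region_class, 2):
            best[key] = c
    counts: dict[str, Counter] = {"exon": Counter(), "intron": Counter(), "intergenic": Counter()}
    for c in best.values():
        bucket = {
            GENIC_CDS: "exon",
            GENIC_INTRON: "intron",
            INTERGENIC: "intergenic",
        }.get(c.region_class, "intron")
        counts[bucket][c.variant.var_class] += 1

    def density(n: int, bp: int) -> float:
        return n / (bp / 1e6) if bp else UNDEFINED

    out = {}
    for region, bp in (
        ("intergenic", spans.intergenic_bp),
        ("genic", spans.genic_bp),
        ("exon", spans.exon_bp),
        ("intron", spans.intron_bp),
    ):
        if region == "genic":
            cnt = counts["exon"] + counts["intron"]
        else:
            cnt = counts[region]
        out[region] = {
            "span_bp": bp,
            "snp_density_per_mb": density(cnt.get(SNP, 0), bp),
            "indel_density_per_mb": density(cnt.get(INDEL, 0), bp),
            "n_snp": cnt.get(SNP, 0),
            "n_indel": cnt.get(INDEL, 0),
        }
    return out


def per_mb_density(variants: Sequence[VariantRecord], genome: ReferenceGenome) -> dict[str, float]:
    by_chrom = Counter(v.chrom for v in variants)
    return {
        chrom: by_chrom.get(chrom, 0) / (length / 1e6)
        for chrom, length in sorted(genome.lengths.items())
    }


# ----------------------------------------------------------- SV filtering


@dataclass
class FilterDecision:
    variant: VariantRecord
    retained: bool
    reason: str = ""


def filter_sv(
    svs: Sequence[VariantRecord],
    params: SVFilterParams,
    sample: Optional[str] = None,
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Retain SVs with depth in [min_depth, max_depth] and quality
    strictly above min_quality; everything else is rejected with a
    recorded reason."""
    kept: list[VariantRecord] = []
    decisions: list[FilterDecision] = []
    for v in svs:
        if v.depth is None or (sample is not None and sample not in v.depth):
            decisions.append(FilterDecision(v, False, "no_depth"))
            continue
        depths = [v.depth[sample]] if sample is not None else list(v.depth.values())
        if not depths:
            decisions.append(FilterDecision(v, False, "no_depth"))
            continue
        depth = min(depths)
        if not (params.min_depth <= depth <= params.max_depth):
            decisions.append(FilterDecision(v, False, "depth"))
            continue
        if v.qual is None or v.qual <= params.min_quality:
            decisions.append(FilterDecision(v, False, "quality"))
            continue
        kept.append(v)
        decisions.append(FilterDecision(v, True))
    for d in decisions:
        if not d.retained:
            log.info(
                "SV at %s:%d rejected (%s)", d.variant.chrom, d.variant.pos + 1, d.reason
            )
    return kept, decisions


# ------------------------------------------------------------- summariser


def variation_summary(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    genome: ReferenceGenome,
    effects: Optional[Sequence[EffectCall]] = None,
    models: Optional[Sequence[GeneModel]] = None,
) -> dict:
    """One JSON-ready dict with the headline contrast statistics."""
    from .contrast import classify_zygosity
    from .models import HET, HOM_ALT, NONSYNONYMOUS, SYNONYMOUS

    summary: dict = {"n_variants": len(variants)}
    snps = [v for v in variants if v.var_class == SNP]
    indels = [v for v in variants if v.var_class == INDEL]
    svs = [v for v in variants if v.var_class == SV]
    ratio, ts, tv = ts_tv(snps)
    summary["counts"] = {"SNP": len(snps), "INDEL": len(indels), "SV": len(svs)}
    summary["ts_count"], summary["tv_count"] = ts, tv
    summary["ts_tv_ratio"] = None if math.isnan(ratio) else round(ratio, 4)
    summary["indel_length_histogram"] = {str(k): v for k, v in indel_spectrum(indels).items()}
    summary["per_mb_density"] = {k: round(v, 2) for k, v in per_mb_density(variants, genome).items()}

    per_sample = {}
    for s in samples:
        carried = {"SNP": Counter(), "INDEL": Counter()}
        for v in snps + indels:
            z = classify_zygosity(v, s)
            if z in (HOM_ALT, HET):
                carried[v.var_class][z] += 1
        per_sample[s] = {
            cls: {
                "n": sum(c.values()),
                "hom_fraction": (
                    c.get(HOM_ALT, 0) / sum(c.values()) if sum(c.values()) else None
                ),
            }
            for cls, c in carried.items()
        }
    summary["per_sample"] = per_sample

    if effects is not None and models is not None:
        spans = region_composition(models, genome)
        summary["region_density"] = {
            region: {k: (round(v, 3) if isinstance(v, float) else v) for k, v in d.items()}
            for region, d in region_density(effects, spans).items()
        }
        n_syn = sum(1 for c in effects if c.consequence == SYNONYMOUS)
        n_nonsyn = sum(1 for c in effects if c.consequence == NONSYNONYMOUS)
        summary["cds_nonsyn"], summary["cds_syn"] = n_nonsyn, n_syn
        summary["nonsyn_syn_ratio"] = round(n_nonsyn / n_syn, 4) if n_syn else None
    return summary
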