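"""Ts/Tv, indel spectrum, region partition/densities, and the SV
validation filter."""
import math

import pytest

from vircon.errors import IntegrityError
from vircon.models import ReferenceGenome, SVFilterParams, VariantRecord
from vircon.stats import (
    filter_sv,
    indel_spectrum,
    region_composition,
    region_density,
    ts_tv,
    variation_summary,
)


def _snp(ref, alt, pos=10):
    return VariantRecord(
        chrom="c", pos=pos, ref_allele=ref, alt_alleles=[alt],
        var_class="SNP", genotypes={"A": (1, 1)},
    )


def _indel(ref, alt, vcf_pos=10):
    return VariantRecord(
        chrom="c", pos=vcf_pos + 1, ref_allele=ref, alt_alleles=[alt],
        var_class="INDEL", genotypes={"A": (1, 1)}, vcf_pos=vcf_pos,
    )


def _sv(depth, qual, sv_type="DEL"):
    return VariantRecord(
        chrom="c", pos=100, ref_allele="A", alt_alleles=[f"<{sv_type}>"],
        var_class="SV", sv_type=sv_type, sv_span=(100, 500),
        genotypes={"A": (1, 1)}, qual=qual,
        depth={"A": depth} if depth is not None else None,
    )


# ------------------------------------------------------------------ TsTv


def test_ts_tv_basic():
    ratio, ts, tv = ts_tv([_snp("A", "G"), _snp("A", "T")])
    assert (ratio, ts, tv) == (1.0, 1, 1)


def test_ts_tv_undefined_without_transversions():
    ratio, ts, tv = ts_tv([_snp("A", "G"), _snp("C", "T")])
    assert math.isnan(ratio) and ts == 2 and tv == 0


def test_ts_tv_counts_each_alt_of_multiallelic():
    v = VariantRecord(
        chrom="c", pos=1, ref_allele="A", alt_alleles=["G", "T"],
        var_class="SNP", genotypes={"A": (1, 2)},
    )
    ratio, ts, tv = ts_tv([v])
    assert (ts, tv) == (1, 1)


def test_planted_ts_tv_recovered(small_bundle):
    """Realized Ts/Tv within 3 binomial SDs of the planted 1.57."""
    snps = [v for v in small_bundle.variants if v.var_class == "SNP"]
    _, ts, tv = ts_tv(snps)
    n = ts + tv
    p = small_bundle.config.ts_tv_target / (1 + small_bundle.config.ts_tv_target)
    sd = (p * (1 - p) / n) ** 0.5
    assert abs(ts / n - p) < 3 * sd


# --------------------------------------------------------- indel lengths


def test_indel_spectrum_signs_and_bins():
    hist = indel_spectrum(
        [_indel("CAC", "A"), _indel("A", "ACGT"), _indel("CA", "C")]
    )
    assert hist == {-2: 1, -1: 1, 3: 1}


def test_indel_spectrum_rejects_zero_net():
    with pytest.raises(IntegrityError):
        indel_spectrum([_indel("AC", "CA")])


def test_planted_spectrum_concentrated_in_1_to_4(small_bundle):
    hist = indel_spectrum([v for v in small_bundle.variants if v.var_class == "INDEL"])
    assert abs(max(hist, key=hist.get)) == 1  # mode is single-base
    small = sum(n for k, n in hist.items() if abs(k) <= 4)
    assert small / sum(hist.values()) > 0.8
    assert all(1 <= abs(k) <= 30 for k in hist)


# ------------------------------------------------------ region partition


def test_partition_law(small_bundle):
    spans = region_composition(small_bundle.models, small_bundle.genome)
    assert spans.intergenic_bp + spans.genic_bp == spans.genome_bp
    assert spans.exon_bp + spans.intron_bp == spans.genic_bp


def test_region_density_simple_case():
    from vircon.models import EffectCall, GeneModel

    genome = ReferenceGenome({"c": "A" * 2_000_000})
    gene = GeneModel("g", "c", "+", [(0, 500_000)], (0, 1_000_000))
    spans = region_composition([gene], genome)
    effects = [
        EffectCall(variant=_snp("A", "G", pos=1_500_000 + i), gene_id="intergenic",
                   region_class="intergenic")
        for i in range(100)
    ]
    d = region_density(effects, spans)
    assert d["intergenic"]["snp_density_per_mb"] == pytest.approx(100.0)
    assert d["exon"]["n_snp"] == 0


def test_region_density_no_genes_all_intergenic():
    genome = ReferenceGenome({"c": "A" * 1_000_000})
    spans = region_composition([], genome)
    assert spans.genic_bp == 0 and spans.intergenic_bp == 1_000_000


def test_planted_density_ordering_recovered(small_bundle):
    """The generator depletes coding and intronic SNPs relative to
    intergenic; the recovered per-Mb densities keep that ordering
    (intergenic > exon > intron)."""
    from vircon.effects import annotate_all

    effects = annotate_all(
        small_bundle.variants, small_bundle.models, small_bundle.genome
    )
    spans = region_composition(small_bundle.models, small_bundle.genome)
    d = region_density(effects, spans)
    assert (
        d["intergenic"]["snp_density_per_mb"]
        > d["exon"]["snp_density_per_mb"]
        > d["intron"]["snp_density_per_mb"]
    )


# ------------------------------------------------------------- SV filter


@pytest.mark.parametrize(
    "depth,qual,retained,reason",
    [
        (50, 30, True, ""),
        (150, 30, False, "depth"),
        (1, 30, False, "depth"),
        (50, 15, False, "quality"),
        (50, 20, False, "quality"),  # strictly greater than 20 required
        (None, 30, False, "no_depth"),
        (2, 21, True, ""),
        (100, 21, True, ""),
    ],
)
def test_filter_sv_rules(depth, qual, retained, reason):
    kept, decisions = filter_sv([_sv(depth, qual)], SVFilterParams())
    assert (len(kept) == 1) is retained
    assert decisions[0].reason == reason


def test_variation_summary_is_json_ready(small_bundle):
    import json

    s = variation_summary(
        small_bundle.variants, small_bundle.samples, small_bundle.genome
    )
    json.dumps(s)  # must not contain numpy scalars
    assert s["counts"]["SNP"] + s["counts"]["INDEL"] + s["counts"]["SV"] == s["n_variants"]
    assert s["ts_count"] + s["tv_count"] == s["counts"]["SNP"]
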