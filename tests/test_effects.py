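"""Consequence engine: splicing, translation, and agreement with the
brute-force rebuild-and-diff oracle across all variant classes."""
from collections import Counter

import numpy as np
import pytest

from vircon.effects import (
    GeneIndex,
    annotate_variant,
    classify_indel_consequence,
    classify_region,
    classify_snp_consequence,
    classify_sv_consequence,
    splice_cds,
    translate,
)
from vircon.errors import IntegrityError
from vircon.models import (
    GENIC_CDS,
    GENIC_INTRON,
    INTERGENIC,
    GeneModel,
    ReferenceGenome,
    VariantRecord,
)
from vircon.simulate import simulate_effect_panel

from _oracle import indel_consequence_and_truncation, snp_consequence


def _snp(chrom, pos, ref, alt):
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=[alt],
        var_class="SNP", genotypes={"S": (1, 1)},
    )


def _indel(chrom, vcf_pos, ref, alt):
    v = VariantRecord(
        chrom=chrom, pos=vcf_pos + 1, ref_allele=ref, alt_alleles=[alt],
        var_class="INDEL", genotypes={"S": (1, 1)}, vcf_pos=vcf_pos,
    )
    return v


# ------------------------------------------------------ splice/translate


def test_splice_cds_concatenates_in_transcription_order():
    genome = ReferenceGenome({"c": "ATGCCCAAA"})
    gene = GeneModel("g", "c", "+", [(0, 3), (6, 9)], (0, 9))
    assert splice_cds(gene, genome) == "ATGAAA"


def test_splice_cds_reverse_complements_minus_strand():
    genome = ReferenceGenome({"c": "ATGCAT"})
    gene = GeneModel("g", "c", "-", [(0, 6)], (0, 6))
    assert splice_cds(gene, genome) == "ATGCAT"  # palindromic control


def test_splice_cds_flags_non_codon_length():
    genome = ReferenceGenome({"c": "ATGCC"})
    gene = GeneModel("g", "c", "+", [(0, 5)], (0, 5))
    splice_cds(gene, genome)
    assert "cds_length_not_multiple_of_3" in gene.warnings


@pytest.mark.parametrize(
    "cds,protein",
    [("ATGTAA", "M"), ("ATGGCCTAA", "MA"), ("ATGAATTAATTT", "MN")],
)
def test_translate_stops_at_first_stop(cds, protein):
    assert translate(cds).aa_sequence == protein


def test_translate_1098nt_orf_gives_365_residues():
    rng = np.random.default_rng(3)
    from vircon.simulate import _NONSTOP_CODONS

    cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(364)) + "TGA"
    assert len(cds) == 1098
    assert translate(cds).length == 365


def test_translate_internal_n_becomes_x():
    assert translate("ATGANTTAA").aa_sequence == "MX"


# --------------------------------------------------------------- regions


def test_classify_region_cases():
    genome = ReferenceGenome({"c": "A" * 300})
    gene = GeneModel("g", "c", "+", [(100, 130), (160, 190)], (100, 200))
    index = GeneIndex([gene])
    assert classify_region(_snp("c", 50, "A", "G"), index) == [("intergenic", INTERGENIC)]
    assert classify_region(_snp("c", 110, "A", "G"), index) == [("g", GENIC_CDS)]
    assert classify_region(_snp("c", 140, "A", "G"), index) == [("g", GENIC_INTRON)]


def test_variant_overlapping_two_genes_yields_two_calls():
    genome = ReferenceGenome({"c": "A" * 400})
    g1 = GeneModel("g1", "c", "+", [(100, 190)], (100, 200))
    g2 = GeneModel("g2", "c", "+", [(150, 240)], (150, 250))
    index = GeneIndex([g1, g2])
    hits = classify_region(_snp("c", 170, "A", "G"), index)
    assert {g for g, _ in hits} == {"g1", "g2"}


# ------------------------------------------------------ SNP consequences

# gene: ATG GCC TAC TAA on the plus strand
_SEQ = "ATGGCCTACTAA" + "A" * 20
_GENE = GeneModel("g", "c", "+", [(0, 12)], (0, 12))
_GENOME = ReferenceGenome({"c": _SEQ})


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (5, "C", "T", "synonymous"),  # GCC -> GCT (Ala)
        (3, "G", "A", "nonsynonymous"),  # GCC -> ACC (Ala -> Thr)
        (8, "C", "A", "stopgain"),  # TAC -> TAA
        (10, "A", "C", "stop_lost"),  # TAA -> TCA
        (0, "A", "C", "start_lost"),  # ATG -> CTG
        (11, "A", "G", "synonymous"),  # TAA -> TAG (stop -> stop)
    ],
)
def test_snp_consequences(pos, ref, alt, expected):
    call = classify_snp_consequence(_snp("c", pos, ref, alt), _GENE, _GENOME)
    assert call.consequence == expected
    assert call.consequence == snp_consequence(_GENE, _SEQ, pos, alt)


def test_snp_ref_mismatch_raises_integrity_error():
    with pytest.raises(IntegrityError):
        classify_snp_consequence(_snp("c", 5, "G", "T"), _GENE, _GENOME)


def test_aa_change_notation():
    call = classify_snp_consequence(_snp("c", 3, "G", "A"), _GENE, _GENOME)
    assert call.aa_change == "p.Ala2Thr"


# ---------------------------------------------------- indel consequences


def test_frameshift_and_inframe_indels():
    seq = "ATG" + "GCC" * 20 + "TAA" + "T" * 10
    gene = GeneModel("g", "c", "+", [(0, 66)], (0, 66))
    genome = ReferenceGenome({"c": seq})
    fs = classify_indel_consequence(_indel("c", 8, seq[8:11], seq[8]), gene, genome)
    assert fs.consequence == "frameshift"
    inframe = classify_indel_consequence(_indel("c", 8, seq[8:12], seq[8]), gene, genome)
    assert inframe.consequence == "codon_deletion"
    ins = classify_indel_consequence(_indel("c", 8, seq[8], seq[8] + "AGG"), gene, genome)
    assert ins.consequence == "codon_insertion"


def test_boundary_spanning_indel_flagged_as_frameshift():
    seq = "ATGGCC" + "T" * 20 + "GCCTAA" + "A" * 10
    gene = GeneModel("g", "c", "+", [(0, 6), (26, 32)], (0, 32))
    genome = ReferenceGenome({"c": seq})
    # 6-bp deletion straddling the first exon/intron boundary
    call = classify_indel_consequence(_indel("c", 2, seq[2:9], seq[2]), gene, genome)
    assert call.consequence == "frameshift"
    assert call.boundary_flag


def test_frameshift_truncation_of_77_residues_on_365_aa_gene():
    """A frameshift placed so re-translation stops 77 residues early is
    reported with that truncation (the oracle picks the site)."""
    rng = np.random.default_rng(11)
    from vircon.simulate import _NONSTOP_CODONS

    seq = "ATG" + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(364)) + "TGA"
    gene = GeneModel("g", "c", "+", [(0, 1098)], (0, 1098))
    found = None
    for p in range(10, 1090):
        ref, alt = seq[p - 1 : p + 1], seq[p - 1]  # 1-bp deletion at p
        _, trunc = indel_consequence_and_truncation(gene, seq, p - 1, ref, alt)
        if trunc == 77:
            found = (p, ref, alt)
            break
    assert found is not None, "no site with truncation 77 in this sequence"
    p, ref, alt = found
    genome = ReferenceGenome({"c": seq})
    call = classify_indel_consequence(_indel("c", p - 1, ref, alt), gene, genome)
    assert call.consequence == "frameshift"
    assert call.truncation == 77


# ------------------------------------------------------- SV consequences


def test_sv_consequences():
    gene = GeneModel("g", "c", "+", [(200, 300), (400, 500)], (200, 500))

    def sv(span, sv_type="DEL"):
        return VariantRecord(
            chrom="c", pos=span[0], ref_allele="N", alt_alleles=[f"<{sv_type}>"],
            var_class="SV", sv_type=sv_type, sv_span=span, genotypes={"S": (1, 1)},
        )

    assert classify_sv_consequence(sv((100, 500)), gene).consequence == "sv_cds_overlap"
    assert classify_sv_consequence(sv((310, 390), "INV"), gene).consequence == "none"
    # translocation breakpoint inside a CDS segment
    assert classify_sv_consequence(sv((250, 251), "CTX"), gene).consequence == "sv_cds_overlap"


# ----------------------------------------------- oracle equivalence suite


def test_engine_matches_oracle_on_planted_panel():
    """Confusion matrix engine-vs-oracle is diagonal on a mixed panel of
    planted CDS variants covering every consequence class, including
    minus-strand genes and multi-exon splicing."""
    genome, models, panel = simulate_effect_panel(seed=5, n_per_class=40)
    index = GeneIndex(models)
    by_id = {m.gene_id: m for m in models}
    chrom_seq = genome.sequences["chr1"]
    confusion = Counter()
    for rec, want in panel:
        calls = [c for c in annotate_variant(rec, index, genome) if c.consequence != "none"]
        got = calls[0].consequence if calls else "none"
        confusion[(want, got)] += 1
        # independent re-check with the test oracle
        gene = by_id[calls[0].gene_id]
        if rec.var_class == "SNP":
            assert snp_consequence(gene, chrom_seq, rec.pos, rec.alt_alleles[0]) == got
        else:
            oracle_cons, oracle_trunc = indel_consequence_and_truncation(
                gene, chrom_seq, rec.vcf_pos, rec.ref_allele, rec.alt_alleles[0]
            )
            assert oracle_cons == got
            assert calls[0].truncation == oracle_trunc
    assert all(want == got for (want, got) in confusion), confusion


def test_strand_symmetry():
    """Reverse-complementing the locus and flipping strand preserves
    every consequence call."""
    from vircon.effects import revcomp

    genome, models, panel = simulate_effect_panel(seed=9, n_per_class=15)
    chrom_seq = genome.sequences["chr1"]
    L = len(chrom_seq)
    flipped_seq = revcomp(chrom_seq)
    flipped_genome = ReferenceGenome({"chr1": flipped_seq})
    flipped_models = {}
    for m in models:
        flipped_models[m.gene_id] = GeneModel(
            gene_id=m.gene_id,
            chrom="chr1",
            strand="-" if m.strand == "+" else "+",
            cds_segments=sorted((L - e, L - s) for s, e in m.cds_segments),
            gene_span=(L - m.gene_span[1], L - m.gene_span[0]),
        )
    index = GeneIndex(models)
    flipped_index = GeneIndex(list(flipped_models.values()))
    for rec, want in panel:
        if rec.var_class != "SNP":
            continue
        calls = [c for c in annotate_variant(rec, index, genome) if c.consequence != "none"]
        fpos = L - 1 - rec.pos
        frec = _snp("chr1", fpos, revcomp(rec.ref_allele), revcomp(rec.alt_alleles[0]))
        fcalls = [
            c for c in annotate_variant(frec, flipped_index, flipped_genome)
            if c.consequence != "none"
        ]
        assert [c.consequence for c in fcalls] == [c.consequence for c in calls]
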