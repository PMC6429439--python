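"""Variant consequence annotation against stranded multi-exon gene models.

Region classes (intergenic / intron / CDS) come from interval-tree
lookups over gene spans; coding consequences come from codon-level
editing of the spliced CDS. Frameshifts re-translate the mutant CDS so
the size of a premature truncation is reportable (the analysis cares
how much protein a selfing line lost, not just that a frameshift
exists).
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import CoordinateError, IntegrityError
from .genomic_io import normalize_indel
from .models import (
    CODON_DELETION,
    CODON_INSERTION,
    FRAMESHIFT,
    GENIC_CDS,
    GENIC_INTRON,
    INDEL,
    INTERGENIC,
    NONSYNONYMOUS,
    NO_CONSEQUENCE,
    SEVERITY_ORDER,
    SNP,
    START_LOST,
    STOPGAIN,
    STOP_LOST,
    SV,
    SV_CDS_OVERLAP,
    SYNONYMOUS,
    EffectCall,
    GeneModel,
    ProteinProduct,
    ReferenceGenome,
    VariantRecord,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------ CDS handling


def splice_cds(gene: GeneModel, genome: ReferenceGenome) -> str:
    """Concatenate CDS segments in transcription order (revcomp on "-")."""
    chrom_len = genome.lengths.get(gene.chrom)
    if chrom_len is None:
        raise CoordinateError(f"{gene.gene_id}: chromosome {gene.chrom} not in genome")
    for s, e in gene.cds_segments:
        if s < 0 or e > chrom_len:
            raise CoordinateError(
                f"{gene.gene_id}: CDS segment [{s},{e}) outside {gene.chrom} (len {chrom_len})"
            )
    plus = "".join(genome.fetch(gene.chrom, s, e) for s, e in gene.cds_segments)
    cds = plus if gene.strand == "+" else revcomp(plus)
    if len(cds) % 3 != 0 and "cds_length_not_multiple_of_3" not in gene.warnings:
        gene.warnings.append("cds_length_not_multiple_of_3")
    return cds


def translate(cds: str, gene_id: str = "") -> ProteinProduct:
    """Translate with the standard code, stopping at the first stop codon.

    Ambiguous codons (internal N) become residue X and are logged.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(usable).translate())
    stop = aa.find("*")
    if stop >= 0:
        aa = aa[:stop]
    if "X" in aa:
        log.info("%s: ambiguous codon(s) translated as X", gene_id or "<cds>")
    return ProteinProduct(gene_id=gene_id, aa_sequence=aa)


def genomic_to_cds_pos(gene: GeneModel, gpos: int) -> Optional[int]:
    """Map a genomic position to its 0-based offset in the spliced CDS."""
    offset = 0
    plus_offset = None
    for s, e in gene.cds_segments:
        if s <= gpos < e:
            plus_offset = offset + (gpos - s)
            break
        offset += e - s
    if plus_offset is None:
        return None
    if gene.strand == "+":
        return plus_offset
    return gene.cds_length - 1 - plus_offset


# --------------------------------------------------------- region classing


class GeneIndex:
    """Interval-tree index of gene spans for region classification."""

    def __init__(self, models: Sequence[GeneModel]):
        self.by_id = {m.gene_id: m for m in models}
        self.trees: dict[str, IntervalTree] = {}
        for m in models:
            s, e = m.gene_span
            if e > s:
                self.trees.setdefault(m.chrom, IntervalTree()).addi(s, e, m.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, max(end, start + 1))
        return sorted((self.by_id[iv.data] for iv in hits), key=lambda m: m.gene_id)


def variant_extent(variant: VariantRecord) -> tuple[int, int]:
    """Genomic footprint of the variant's altered bases."""
    if variant.var_class == SV and variant.sv_span:
        return variant.sv_span
    if variant.var_class == SNP:
        return variant.pos, variant.pos + len(variant.ref_allele)
    # indel: widest normalized deletion across alts (pure insertions get
    # a 1-bp footprint at the insertion point)
    start, end = variant.pos, variant.pos + 1
    base = variant.vcf_pos if variant.vcf_pos is not None else variant.pos
    for alt in variant.alt_alleles:
        if len(alt) == len(variant.ref_allele):
            continue
        npos, dseq, _ = normalize_indel(base, variant.ref_allele, alt)
        end = max(end, npos + max(len(dseq), 1))
        start = min(start, npos)
    return start, end


def classify_region(
    variant: VariantRecord, index: GeneIndex
) -> list[tuple[str, str]]:
    """Return [(gene_id_or_intergenic, region_class), ...].

    A variant overlapping two genes yields one entry per gene.
    """
    start, end = variant_extent(variant)
    genes = index.overlapping(variant.chrom, start, end)
    if not genes:
        return [("intergenic", INTERGENIC)]
    out = []
    for gene in genes:
        in_cds = any(s < end and start < e for s, e in gene.cds_segments)
        out.append((gene.gene_id, GENIC_CDS if in_cds else GENIC_INTRON))
    return out


# ------------------------------------------------------- SNP consequences


def classify_snp_consequence(
    variant: VariantRecord,
    gene: GeneModel,
    genome: ReferenceGenome,
    alt: Optional[str] = None,
) -> EffectCall:
    """Codon-level consequence of a single-nucleotide substitution."""
    alt = alt if alt is not None else variant.alt_alleles[0]
    gpos = variant.pos
    ref_base = variant.ref_allele
    genome_base = genome.fetch(variant.chrom, gpos, gpos + 1)
    if genome_base != ref_base:
        raise IntegrityError(
            f"{variant.chrom}:{gpos + 1}: VCF REF {ref_base} != genome {genome_base}"
        )
    cds = splice_cds(gene, genome)
    cpos = genomic_to_cds_pos(gene, gpos)
    if cpos is None:
        return EffectCall(variant=variant, gene_id=gene.gene_id, region_class=GENIC_INTRON)

    alt_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
    codon_i = cpos // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    model_warning = bool(gene.warnings)
    if len(codon) < 3:
        # trailing partial codon of a model whose length % 3 != 0
        return EffectCall(
            variant=variant, gene_id=gene.gene_id, region_class=GENIC_CDS,
            consequence=NONSYNONYMOUS, cds_pos=cpos, model_warning=True,
        )
    within = cpos - codon_i * 3
    mut_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mut_codon).translate())

    if codon_i == 0 and codon == "ATG" and mut_codon != "ATG":
        consequence = START_LOST
    elif aa_ref == "*" and aa_alt != "*":
        consequence = STOP_LOST
    elif aa_ref != "*" and aa_alt == "*":
        consequence = STOPGAIN
    elif aa_ref == aa_alt:
        consequence = SYNONYMOUS
    else:
        consequence = NONSYNONYMOUS

    aa_change = f"p.{_AA3[aa_ref]}{codon_i + 1}{_AA3[aa_alt]}"
    return EffectCall(
        variant=variant,
        gene_id=gene.gene_id,
        region_class=GENIC_CDS,
        consequence=consequence,
        aa_change=aa_change,
        cds_pos=cpos,
        model_warning=model_warning,
    )


# ------------------------------------------------------ indel consequences


def _segment_containing(gene: GeneModel, start: int, end: int) -> Optional[int]:
    for i, (s, e) in enumerate(gene.cds_segments):
        if s <= start and end <= e:
            return i
    return None


def mutant_spliced_cds(
    gene: GeneModel, genome: ReferenceGenome, npos: int, deleted: str, inserted: str
) -> Optional[str]:
    """Spliced CDS after applying an edit confined to one CDS segment.

    Returns None when the edit crosses a segment boundary.
    """
    seg_i = _segment_containing(gene, npos, npos + max(len(deleted), 1))
    if seg_i is None and len(deleted) == 0:
        # pure insertion exactly at a segment start still lands inside if
        # the insertion point is within [s, e)
        seg_i = _segment_containing(gene, npos, npos + 1)
    if seg_i is None:
        return None
    pieces = [genome.fetch(gene.chrom, s, e) for s, e in gene.cds_segments]
    s, _ = gene.cds_segments[seg_i]
    local = npos - s
    seg = pieces[seg_i]
    pieces[seg_i] = seg[:local] + inserted + seg[local + len(deleted) :]
    plus = "".join(pieces)
    return plus if gene.strand == "+" else revcomp(plus)


def classify_indel_consequence(
    variant: VariantRecord,
    gene: GeneModel,
    genome: ReferenceGenome,
    alt: Optional[str] = None,
) -> EffectCall:
    """Frameshift vs in-frame consequence of a short indel in the CDS."""
    alt = alt if alt is not None else variant.alt_alleles[0]
    base = variant.vcf_pos if variant.vcf_pos is not None else variant.pos
    npos, deleted, inserted = normalize_indel(base, variant.ref_allele, alt)
    net = len(inserted) - len(deleted)
    if net == 0:
        raise IntegrityError(
            f"{variant.chrom}:{base + 1}: zero net length change is not an indel"
        )
    cds = splice_cds(gene, genome)
    cpos = genomic_to_cds_pos(gene, npos)
    if cpos is None and deleted:
        # deletion starting in an intron may still clip CDS bases
        for off in range(len(deleted)):
            cpos = genomic_to_cds_pos(gene, npos + off)
            if cpos is not None:
                break
    if cpos is None:
        return EffectCall(variant=variant, gene_id=gene.gene_id, region_class=GENIC_INTRON)

    if net % 3 != 0:
        consequence = FRAMESHIFT
    else:
        consequence = CODON_DELETION if net < 0 else CODON_INSERTION

    mutant = mutant_spliced_cds(gene, genome, npos, deleted, inserted)
    boundary = mutant is None
    if boundary:
        # spec'd policy: a boundary-spanning indel disrupts the frame
        consequence = FRAMESHIFT
    truncation = None
    mut_len = None
    if mutant is not None and len(mutant) >= 3:
        ref_protein = translate(cds, gene.gene_id)
        mut_protein = translate(mutant, gene.gene_id)
        mut_len = mut_protein.length
        if mut_protein.length < ref_protein.length:
            truncation = ref_protein.length - mut_protein.length
    return EffectCall(
        variant=variant,
        gene_id=gene.gene_id,
        region_class=GENIC_CDS,
        consequence=consequence,
        cds_pos=cpos,
        truncation=truncation,
        mutant_protein_length=mut_len,
        boundary_flag=boundary,
        model_warning=bool(gene.warnings),
    )


# --------------------------------------------------------- SV consequences


def classify_sv_consequence(variant: VariantRecord, gene: GeneModel) -> EffectCall:
    """SV overlapping any CDS segment -> sv_cds_overlap; else none."""
    if variant.sv_span is None:
        log.warning(
            "SV at %s:%d has no resolvable span; no consequence", variant.chrom, variant.pos
        )
        return EffectCall(variant=variant, gene_id=gene.gene_id, region_class=GENIC_INTRON)
    start, end = variant.sv_span
    if variant.sv_type in ("ITX", "CTX"):
        # translocations: either breakpoint falling inside a CDS counts
        points = [start, max(end - 1, start)]
        hit = any(s <= p < e for p in points for s, e in gene.cds_segments)
    else:
        hit = any(s < end and start < e for s, e in gene.cds_segments)
    return EffectCall(
        variant=variant,
        gene_id=gene.gene_id,
        region_class=GENIC_CDS if hit else GENIC_INTRON,
        consequence=SV_CDS_OVERLAP if hit else NO_CONSEQUENCE,
    )


# ----------------------------------------------------------------- driver


def _most_severe(calls: list[EffectCall]) -> EffectCall:
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    return min(calls, key=lambda c: rank.get(c.consequence, len(rank)))


def annotate_variant(
    variant: VariantRecord, index: GeneIndex, genome: ReferenceGenome
) -> list[EffectCall]:
    """One EffectCall per overlapped gene (or a single intergenic call).

    Multi-allelic records are collapsed to the most severe consequence
    across alt alleles, matching record-level accounting.
    """
    out: list[EffectCall] = []
    for gene_id, region in classify_region(variant, index):
        if gene_id == "intergenic":
            out.append(EffectCall(variant=variant, gene_id="intergenic", region_class=INTERGENIC))
            continue
        gene = index.by_id[gene_id]
        if region != GENIC_CDS:
            out.append(EffectCall(variant=variant, gene_id=gene_id, region_class=region))
            continue
        if variant.var_class == SV:
            out.append(classify_sv_consequence(variant, gene))
            continue
        per_alt: list[EffectCall] = []
        for alt in variant.alt_alleles:
            if len(alt) == len(variant.ref_allele) == 1:
                per_alt.append(classify_snp_consequence(variant, gene, genome, alt))
            elif len(alt) == len(variant.ref_allele):
                # multi-base substitution: treat base-by-base, keep worst
                subs = [
                    classify_snp_consequence(
                        _as_snp(variant, i), gene, genome, alt[i]
                    )
                    for i in range(len(alt))
                    if variant.ref_allele[i] != alt[i]
                    and genomic_to_cds_pos(gene, variant.pos + i) is not None
                ]
                if subs:
                    per_alt.append(_most_severe(subs))
            else:
                per_alt.append(classify_indel_consequence(variant, gene, genome, alt))
        if per_alt:
            out.append(_most_severe(per_alt))
        else:
            out.append(EffectCall(variant=variant, gene_id=gene_id, region_class=GENIC_CDS))
    return out


def _as_snp(variant: VariantRecord, offset: int) -> VariantRecord:
    return VariantRecord(
        chrom=variant.chrom,
        pos=variant.pos + offset,
        ref_allele=variant.ref_allele[offset],
        alt_alleles=[a[offset] if len(a) > offset else a for a in variant.alt_alleles],
        var_class=SNP,
        genotypes=variant.genotypes,
        qual=variant.qual,
    )


def annotate_all(
    variants: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    genome: ReferenceGenome,
) -> list[EffectCall]:
    index = GeneIndex(models)
    calls: list[EffectCall] = []
    for v in variants:
        calls.extend(annotate_variant(v, index, genome))
    return calls


def effects_table(calls: Sequence[EffectCall]):
    """Flatten effect calls into the output TSV layout (1-based pos)."""
    import pandas as pd

    rows = [
        {
            "chrom": c.variant.chrom,
            "pos": c.variant.pos + 1,
            "ref": c.variant.ref_allele,
            "alt": ",".join(c.variant.alt_alleles),
            "gene_id": c.gene_id,
            "region_class": c.region_class,
            "consequence": c.consequence,
            "aa_change": c.aa_change,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "region_class", "consequence", "aa_change"],
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
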