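"""Brute-force consequence oracle used by the tests.

Independent of the package's annotation engine: it applies the variant
to the whole chromosome string, shifts gene-model coordinates past the
edit, re-splices the full mutant CDS, translates both proteins with
Bio.Seq, and classifies by diffing the two proteins.
"""
from __future__ import annotations

from Bio.Seq import Seq

from vircon.models import (
    CODON_DELETION,
    CODON_INSERTION,
    FRAMESHIFT,
    GeneModel,
    NONSYNONYMOUS,
    START_LOST,
    STOPGAIN,
    STOP_LOST,
    SYNONYMOUS,
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _splice(segments, strand, seq):
    plus = "".join(seq[s:e] for s, e in segments)
    return plus if strand == "+" else plus.translate(_COMP)[::-1]


def _protein(cds: str) -> str:
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = aa.find("*")
    return aa[:stop] if stop >= 0 else aa


def apply_edit(chrom_seq: str, vcf_pos: int, ref: str, alt: str) -> str:
    assert chrom_seq[vcf_pos : vcf_pos + len(ref)] == ref, "REF mismatch"
    return chrom_seq[:vcf_pos] + alt + chrom_seq[vcf_pos + len(ref) :]


def shifted_segments(gene: GeneModel, edit_pos: int, net: int):
    """Gene CDS segments after an indel of net length change at
    edit_pos (first altered base). Assumes the edit does not cross a
    segment boundary."""
    return [
        (s + net if s > edit_pos else s, e + net if e > edit_pos else e)
        for s, e in gene.cds_segments
    ]


def snp_consequence(gene: GeneModel, chrom_seq: str, gpos: int, alt: str) -> str:
    mut_seq = apply_edit(chrom_seq, gpos, chrom_seq[gpos], alt)
    ref_cds = _splice(gene.cds_segments, gene.strand, chrom_seq)
    mut_cds = _splice(gene.cds_segments, gene.strand, mut_seq)
    p_ref, p_mut = _protein(ref_cds), _protein(mut_cds)
    if ref_cds[:3] == "ATG" and mut_cds[:3] != "ATG":
        return START_LOST
    if p_mut == p_ref:
        return SYNONYMOUS
    if len(p_mut) < len(p_ref) and p_ref.startswith(p_mut):
        return STOPGAIN
    if len(p_mut) > len(p_ref) and p_mut.startswith(p_ref):
        return STOP_LOST
    return NONSYNONYMOUS


def indel_consequence_and_truncation(
    gene: GeneModel, chrom_seq: str, vcf_pos: int, ref: str, alt: str
):
    """(consequence, truncation) after applying an anchored indel."""
    net = len(alt) - len(ref)
    # first altered base: anchored representation shares its first base
    edit_pos = vcf_pos + 1 if ref[0] == alt[0] else vcf_pos
    mut_seq = apply_edit(chrom_seq, vcf_pos, ref, alt)
    segments = shifted_segments(gene, edit_pos, net)
    ref_cds = _splice(gene.cds_segments, gene.strand, chrom_seq)
    mut_cds = _splice(segments, gene.strand, mut_seq)
    p_ref, p_mut = _protein(ref_cds), _protein(mut_cds)
    if net % 3 != 0:
        consequence = FRAMESHIFT
    else:
        consequence = CODON_DELETION if net < 0 else CODON_INSERTION
    truncation = len(p_ref) - len(p_mut) if len(p_mut) < len(p_ref) else None
    return consequence, truncation
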