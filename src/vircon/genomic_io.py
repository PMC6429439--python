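"""Readers and writers for FASTA, GFF3, VCF, BED and TSV.

This is the only module that touches 1-based file conventions; every
object it hands out uses 0-based half-open coordinates. Reading relies
on Bio.SeqIO (FASTA), gffutils (GFF3) and cyvcf2 (VCF); the writers are
deliberately plain-text emitters so that the round-trip
write -> read -> objects is exact and inspectable.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .errors import ConfigError, FormatError
from .models import (
    INDEL,
    MISSING_GT,
    SNP,
    SV,
    SV_TYPES,
    DomainAnnotation,
    GeneModel,
    ReferenceGenome,
    VariantRecord,
)

log = logging.getLogger(__name__)

# ------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into memory, uppercasing the sequence.

    Raises FormatError for an empty file or a file whose first
    non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise FormatError(f"{path}: no FASTA records parsed")
    return ReferenceGenome(sequences=sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -------------------------------------------------------------------- GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3, keeping the first mRNA isoform per gene.

    GFF3 1-based inclusive coordinates become 0-based half-open. CDS
    features without a Parent are skipped with a warning; end < start is
    a format error.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    # group CDS by parent id
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent")
        if not parents:
            log.warning("CDS at %s:%s-%s has no Parent; skipped", cds.seqid, cds.start, cds.end)
            continue
        cds_by_parent.setdefault(parents[0], []).append((cds.start - 1, cds.end))

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            if len(mrnas) > 1:
                log.info(
                    "gene %s has %d mRNA isoforms; keeping %s",
                    gene_id, len(mrnas), mrnas[0].id,
                )
            segments = cds_by_parent.get(mrnas[0].id, [])
        else:  # CDS parented directly to the gene
            segments = cds_by_parent.get(gene_id, [])
        segments = sorted(segments)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_segments=segments,
                gene_span=(gene.start - 1, gene.end),
                biotype=(gene.attributes.get("biotype") or ["protein_coding"])[0],
            )
        )
    return models


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}: line {lineno}: fewer than 8 GFF3 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end < start")


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS features (one isoform per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chrom, g.gene_span[0])):
            gs, ge = m.gene_span
            fh.write(
                f"{m.chrom}\tvircon\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};biotype={m.biotype}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tvircon\tmRNA\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            # phase in transcription order
            segs = m.cds_segments if m.strand == "+" else list(reversed(m.cds_segments))
            consumed = 0
            phases = {}
            for s, e in segs:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for s, e in m.cds_segments:
                fh.write(
                    f"{m.chrom}\tvircon\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                    f"{phases[(s, e)]}\tID={m.gene_id}.cds;Parent={mrna_id}\n"
                )


# --------------------------------------------------------------------- VCF


def normalize_indel(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation of a length-changing allele pair.

    Returns ``(new_pos, deleted, inserted)`` where ``new_pos`` is the
    0-based position of the first altered base. The leading base is
    dropped as the VCF anchor even when ref and alt disagree there
    (allele tables transcribed from alignments are not always anchored:
    CAC -> A is treated as a 2-bp deletion of "AC" at pos+1).
    """
    if len(ref) == len(alt):
        return pos, ref, alt
    # strip shared suffix, keeping at least one base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # strip shared prefix
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    if i == 0:
        i = 1  # unconditionally drop the anchor base for indels
    return pos + i, ref[i:], alt[i:]


def indel_net_length(ref: str, alt: str) -> int:
    """Signed net length change (insertions positive)."""
    return len(alt) - len(ref)


def _classify_alleles(ref: str, alts: list[str], sv_type: str | None) -> str:
    if sv_type is not None or any(a.startswith("<") for a in alts):
        return SV
    if any(abs(len(a) - len(ref)) > 30 for a in alts):
        return SV
    if any(len(a) != len(ref) for a in alts):
        return INDEL
    return SNP  # includes multi-base substitutions


def read_vcf(path: str | Path, sample_names: Sequence[str]) -> list[VariantRecord]:
    """Read a VCF 4.x file, returning records for the requested samples.

    Multi-allelic records are kept intact. Records where every
    requested sample is missing are dropped with a log line.
    """
    path = Path(path)
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    missing = [s for s in sample_names if s not in header_samples]
    if missing:
        raise ConfigError(f"{path}: samples absent from VCF header: {missing}")
    idx = [header_samples.index(s) for s in sample_names]

    records: list[VariantRecord] = []
    n_dropped = 0
    for v in vcf:
        ref = v.REF.upper()
        alts = [a.upper() for a in v.ALT]
        sv_type = v.INFO.get("SVTYPE")
        var_class = _classify_alleles(ref, alts, sv_type)

        genotypes: dict[str, tuple[int, int]] = {}
        for name, i in zip(sample_names, idx):
            g = v.genotypes[i]
            genotypes[name] = (int(g[0]), int(g[1])) if len(g) >= 2 else MISSING_GT
        if all(gt[0] < 0 and gt[1] < 0 for gt in genotypes.values()):
            n_dropped += 1
            continue

        pos0 = v.POS - 1
        if var_class == INDEL:
            pos = min(normalize_indel(pos0, ref, a)[0] for a in alts)
        else:
            pos = pos0

        sv_span = None
        stype = None
        if var_class == SV:
            stype = (sv_type or "UNKNOWN").upper()
            if stype not in SV_TYPES:
                stype = "UNKNOWN"
            end = v.INFO.get("END")
            sv_span = (pos0, int(end)) if end is not None else (pos0, pos0 + len(ref))

        depth = None
        try:
            dp = v.format("DP")
        except KeyError:  # DP not declared in this VCF's header
            dp = None
        if dp is not None:
            depth = {
                name: int(dp[i][0]) for name, i in zip(sample_names, idx) if dp[i][0] >= 0
            }

        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=pos,
                ref_allele=ref,
                alt_alleles=alts,
                var_class=var_class,
                genotypes=genotypes,
                sv_type=stype,
                sv_span=sv_span,
                qual=float(v.QUAL) if v.QUAL is not None else None,
                depth=depth,
                vcf_pos=pos0,
            )
        )
    if n_dropped:
        log.info("%s: dropped %d records with all-missing genotypes", path, n_dropped)
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    sample_names: Sequence[str],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Emit a minimal VCF 4.2 text file (GT:DP per sample)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name in sorted(contigs):
                fh.write(f"##contig=<ID={name},length={contigs[name]}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for r in recs:
            pos1 = (r.vcf_pos if r.vcf_pos is not None else r.pos) + 1
            info = "."
            if r.var_class == SV:
                parts = [f"SVTYPE={r.sv_type or 'UNKNOWN'}"]
                if r.sv_span:
                    parts.append(f"END={r.sv_span[1]}")
                info = ";".join(parts)
            qual = f"{r.qual:g}" if r.qual is not None else "."
            cols = [
                r.chrom,
                str(pos1),
                ".",
                r.ref_allele,
                ",".join(r.alt_alleles),
                qual,
                "PASS",
                info,
                "GT:DP",
            ]
            for s in sample_names:
                gt = r.genotypes.get(s, MISSING_GT)
                gts = "./." if gt[0] < 0 else f"{gt[0]}/{gt[1]}"
                dp = str(r.depth.get(s, ".")) if r.depth else "."
                cols.append(f"{gts}:{dp}")
            fh.write("\t".join(cols) + "\n")


# --------------------------------------------------------------- BED / TSV


def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write (chrom, start, end[, name]) tuples or objects as BED."""
    rows = []
    for r in regions:
        if hasattr(r, "chrom") and hasattr(r, "span"):
            rows.append((r.chrom, r.span[0], r.span[1], getattr(r, "sample", ".")))
        else:
            t = tuple(r)
            rows.append(t if len(t) >= 4 else t + (".",) * (4 - len(t)))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read a protein-domain table: gene_id, family, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "family", "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: domain table needs columns {sorted(required)}")
    return [
        DomainAnnotation(
            gene_id=row.gene_id,
            family=row.family,
            aa_start=int(row.aa_start),
            aa_end=int(row.aa_end),
        )
        for row in df.itertuples()
    ]


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(d.gene_id, d.family, d.aa_start, d.aa_end) for d in domains],
        columns=["gene_id", "family", "aa_start", "aa_end"],
    )
    write_tsv(df, path)
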