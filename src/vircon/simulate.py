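"""Synthetic diploid resequencing bundle with known truth.

The generator emulates the downstream products of resequencing two
selfing lines against one reference: a random reference genome with
stranded multi-exon protein-coding genes, Pfam-style domain intervals,
and a joint two-sample VCF whose statistical structure matches the
study conditions — a transition/transversion ratio near 1.57, ~84%
homozygous calls genome-wide, indel lengths concentrated in 1–4 bp,
sample-specific homozygous blocks, and CDS variants spanning every
consequence class.

Every CDS variant's intended consequence is verified at generation
time by a rebuild-the-mutant-CDS-and-translate check that is
independent of the codon-level annotation engine, so the truth table
can serve as an oracle for the annotation confusion-matrix test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .effects import revcomp
from .errors import ConfigError
from .genomic_io import (
    write_domains,
    write_fasta,
    write_gff3,
    write_tsv,
    write_vcf,
)
from .models import (
    CODON_DELETION,
    CODON_INSERTION,
    FRAMESHIFT,
    INDEL,
    NONSYNONYMOUS,
    QUALIFYING_CONSEQUENCES,
    SNP,
    START_LOST,
    STOPGAIN,
    STOP_LOST,
    SV,
    SV_CDS_OVERLAP,
    SYNONYMOUS,
    DomainAnnotation,
    GeneModel,
    ReferenceGenome,
    VariantRecord,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_FAMILIES = (
    "LRR_1", "F-box", "NB-ARC", "Thioredoxin", "PPR",
    "Pkinase", "BTB", "UBA", "CaM_binding", "NAD_binding",
)

SNP_CLASSES = (SYNONYMOUS, NONSYNONYMOUS, STOPGAIN, STOP_LOST, START_LOST)
INDEL_CLASSES = (FRAMESHIFT, CODON_DELETION, CODON_INSERTION)
ALL_CLASSES = SNP_CLASSES + INDEL_CLASSES


@dataclass
class SimulationConfig:
    """Study conditions the bundle emulates. Defaults are the
    conditions the analysis was designed around (seven chromosomes,
    Ts/Tv 1.57, 84% homozygous calls, 1–4 bp indel majority), with
    densities scaled to desk size."""

    seed: int = 0
    n_chroms: int = 7
    chrom_length: int = 2_000_000
    n_genes_per_chrom: int = 40
    snp_rate: float = 3.5e-3
    indel_rate: float = 4e-4
    sv_per_chrom: int = 4
    ts_tv_target: float = 1.57
    hom_fraction: float = 0.84
    #: probability a variant locus is carried by (both, A only, B only)
    carrier_probs: tuple[float, float, float] = (0.70, 0.15, 0.15)
    #: planted homozygous blocks as (chrom, start, end, sample); None
    #: plants 30 window-aligned blocks across the chromosomes
    planted_blocks: Optional[list[tuple[str, int, int, str]]] = None
    n_planted_blocks: int = 30
    block_window: int = 100_000
    samples: tuple[str, str] = ("Ls-S2-53", "Ls-S2-76")
    n_candidate_genes: int = 20
    n_decoy_genes: int = 30
    n_effect_per_class: int = 6
    domain_density: float = 0.7
    #: relative background SNP retention per region class; coding and
    #: intronic variation is depleted relative to intergenic, giving
    #: the density ordering intergenic > exon > intron
    region_snp_weights: dict = field(
        default_factory=lambda: {"intergenic": 1.0, "exon": 0.6, "intron": 0.35}
    )

    def __post_init__(self) -> None:
        if not (0 < self.hom_fraction < 1):
            raise ConfigError("hom_fraction must be in (0, 1)")
        if min(self.snp_rate, self.indel_rate) < 0:
            raise ConfigError("rates must be non-negative")
        if abs(sum(self.carrier_probs) - 1.0) > 1e-9:
            raise ConfigError("carrier_probs must sum to 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class TruthTable:
    """What was planted: per-variant class/zygosity, per-sample blocks,
    and per-gene candidate status, all recomputed from actual plants."""

    variants: pd.DataFrame
    blocks: list[tuple[str, int, int, str]]
    genes: pd.DataFrame


@dataclass
class SimBundle:
    config: SimulationConfig
    genome: ReferenceGenome
    models: list[GeneModel]
    domains: list[DomainAnnotation]
    variants: list[VariantRecord]
    truth: TruthTable

    @property
    def samples(self) -> tuple[str, str]:
        return self.config.samples


# -------------------------------------------------------------- reference


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    gstart: int,
    strand: str,
    n_codons: int,
    n_exons: int,
    intron_range: tuple[int, int] = (50, 300),
) -> tuple[GeneModel, str]:
    """One gene: ATG + non-stop codons + stop, split into exons.

    Returns the model plus the genomic piece to splice into the
    chromosome (already reverse-complemented for "-" genes).
    """
    cds = (
        "ATG"
        + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons))
        + _STOPS[rng.integers(0, 3)]
    )
    # exon cut points with a minimum exon width of 20 nt
    cuts: list[int] = []
    for _ in range(200):
        if len(cuts) == n_exons - 1:
            break
        c = int(rng.integers(20, len(cds) - 20))
        if all(abs(c - o) >= 20 for o in cuts):
            cuts.append(c)
    cuts = sorted(cuts)
    bounds = [0] + cuts + [len(cds)]
    exons = [cds[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    introns = [
        "".join(rng.choice(list(_BASES), size=int(rng.integers(*intron_range))))
        for _ in range(len(exons) - 1)
    ]
    piece_parts = []
    offsets = []  # exon [start, end) offsets within the plus-frame piece
    at = 0
    for i, ex in enumerate(exons):
        offsets.append((at, at + len(ex)))
        piece_parts.append(ex)
        at += len(ex)
        if i < len(introns):
            piece_parts.append(introns[i])
            at += len(introns[i])
    piece = "".join(piece_parts)
    if strand == "-":
        length = len(piece)
        piece = revcomp(piece)
        offsets = sorted((length - e, length - s) for s, e in offsets)
    segments = [(gstart + s, gstart + e) for s, e in offsets]
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_segments=segments,
        gene_span=(gstart, gstart + len(piece)),
    )
    return model, piece


def generate_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReferenceGenome, list[GeneModel], list[DomainAnnotation]]:
    """Random genome with placed genes and domain intervals,
    deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: dict[str, np.ndarray] = {}
    models: list[GeneModel] = []
    domains: list[DomainAnnotation] = []
    gene_no = 0
    for chrom in config.chrom_names:
        arr = base_lut[rng.integers(0, 4, size=config.chrom_length)]
        n_genes = config.n_genes_per_chrom
        if n_genes:
            slot = config.chrom_length // n_genes
            intron_range = (50, 300) if slot >= 5000 else (30, 80)
            for i in range(n_genes):
                gene_no += 1
                gene_id = f"gene{gene_no:05d}"
                placed = False
                for _ in range(20):  # bounded retries within the slot
                    model, piece = _build_gene(
                        rng,
                        gene_id,
                        chrom,
                        gstart=i * slot + int(rng.integers(100, max(101, slot // 4))),
                        strand="+" if rng.random() < 0.5 else "-",
                        n_codons=int(rng.integers(60, 201)),
                        n_exons=int(rng.integers(1, 5)),
                        intron_range=intron_range,
                    )
                    if model.gene_span[1] < (i + 1) * slot - 50:
                        placed = True
                        break
                if not placed:
                    raise ConfigError(
                        f"could not place {gene_id} within its slot; "
                        "reduce gene size or count"
                    )
                s, e = model.gene_span
                arr[s:e] = np.frombuffer(piece.encode(), dtype=np.uint8)
                models.append(model)
                plen = model.cds_length // 3 - 1  # residues, stop excluded
                if rng.random() < config.domain_density:
                    for _ in range(int(rng.integers(1, 3))):
                        aa_start = int(rng.integers(1, max(2, plen - 10)))
                        aa_end = min(plen, aa_start + int(rng.integers(5, 41)))
                        domains.append(
                            DomainAnnotation(
                                gene_id=gene_id,
                                family=str(rng.choice(_FAMILIES)),
                                aa_start=aa_start,
                                aa_end=aa_end,
                            )
                        )
        sequences[chrom] = arr
    genome = ReferenceGenome(
        sequences={c: a.tobytes().decode() for c, a in sequences.items()}
    )
    return genome, models, domains


# ------------------------------------------- generation-time oracle check


def _splice(gene: GeneModel, chrom_seq: str) -> str:
    plus = "".join(chrom_seq[s:e] for s, e in gene.cds_segments)
    return plus if gene.strand == "+" else revcomp(plus)


def _translate_to_stop(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(usable).translate())
    stop = aa.find("*")
    return aa[:stop] if stop >= 0 else aa


def oracle_snp_class(gene: GeneModel, chrom_seq: str, gpos: int, alt: str) -> str:
    """Consequence of a SNP by whole-protein diff: substitute the base,
    re-splice the CDS, translate both proteins, compare."""
    ref_cds = _splice(gene, chrom_seq)
    pieces = [chrom_seq[s:e] for s, e in gene.cds_segments]
    for i, (s, e) in enumerate(gene.cds_segments):
        if s <= gpos < e:
            local = gpos - s
            pieces[i] = pieces[i][:local] + alt + pieces[i][local + 1 :]
            break
    plus = "".join(pieces)
    mut_cds = plus if gene.strand == "+" else revcomp(plus)
    p_ref = _translate_to_stop(ref_cds)
    p_mut = _translate_to_stop(mut_cds)
    if ref_cds[:3] == "ATG" and mut_cds[:3] != "ATG":
        return START_LOST
    if p_mut == p_ref:
        return SYNONYMOUS
    if len(p_mut) < len(p_ref) and p_ref.startswith(p_mut):
        return STOPGAIN
    if len(p_mut) > len(p_ref) and p_mut.startswith(p_ref):
        return STOP_LOST
    return NONSYNONYMOUS


def oracle_indel_class(net: int) -> str:
    if net % 3 != 0:
        return FRAMESHIFT
    return CODON_DELETION if net < 0 else CODON_INSERTION


# --------------------------------------------------------------- planting


def _cds_to_genomic(gene: GeneModel) -> list[int]:
    """Genomic position of every spliced-CDS offset, transcription order."""
    plus = [p for s, e in gene.cds_segments for p in range(s, e)]
    return plus if gene.strand == "+" else plus[::-1]


def _plant_blocks(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int, str]]:
    """Window-aligned sample-specific homozygous blocks, disjoint across
    samples with >= 2 buffer windows between any two blocks."""
    w = config.block_window
    n_windows = config.chrom_length // w
    per_chrom = [0] * config.n_chroms
    for i in range(config.n_planted_blocks):
        per_chrom[i % config.n_chroms] += 1
    blocks: list[tuple[str, int, int, str]] = []
    which = 0
    for chrom, k in zip(config.chrom_names, per_chrom):
        if k == 0:
            continue
        sizes = [int(rng.integers(2, 4)) for _ in range(k)]
        while sum(sizes) + 2 * (k - 1) > n_windows and max(sizes) > 2:
            sizes[sizes.index(max(sizes))] -= 1
        if sum(sizes) + 2 * (k - 1) > n_windows:
            raise ConfigError(f"cannot fit {k} blocks into {chrom}")
        slack = n_windows - sum(sizes) - 2 * (k - 1)
        pos = int(rng.integers(0, slack + 1)) if slack > 0 else 0
        slack -= pos
        for size in sizes:
            blocks.append((chrom, pos * w, (pos + size) * w, config.samples[which % 2]))
            which += 1
            extra = 1 if (slack > 0 and rng.random() < 0.5) else 0
            slack -= extra
            pos += size + 2 + extra
    return blocks


def _pick_genotype(
    chrom: str,
    pos: int,
    carrier: tuple[bool, bool],
    blocks_by_sample: dict[str, list[tuple[str, int, int]]],
    hom_out: dict[str, float],
    samples: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    gts: dict[str, tuple[int, int]] = {}
    for s, is_carrier in zip(samples, carrier):
        if not is_carrier:
            gts[s] = (0, 0)
            continue
        in_block = any(
            c == chrom and bs <= pos < be for c, bs, be in blocks_by_sample[s]
        )
        if in_block or rng.random() < hom_out[s]:
            gts[s] = (1, 1)
        else:
            gts[s] = (0, 1)
    return gts


def _draw_carrier(
    probs: tuple[float, float, float], rng: np.random.Generator
) -> tuple[bool, bool]:
    u = rng.random()
    if u < probs[0]:
        return True, True
    if u < probs[0] + probs[1]:
        return True, False
    return False, True


class _Planter:
    """Book-keeping for variant placement: occupied pads, truth rows."""

    PAD = 35

    def __init__(self, config: SimulationConfig, genome: ReferenceGenome):
        self.config = config
        self.genome = genome
        # positions blocked with a +/-PAD halo around accepted variants;
        # candidates only need to test their own footprint
        self.blocked: dict[str, set[int]] = {c: set() for c in genome.sequences}
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
        self.records: list[VariantRecord] = []
        self.truth_rows: list[dict] = []

    def occupy(self, chrom: str, start: int, end: int) -> bool:
        blocked = self.blocked[chrom]
        if any(p in blocked for p in range(start, end)):
            return False
        blocked.update(range(start - self.PAD, end + self.PAD))
        self.used[chrom].append((start, end))
        return True

    def add(
        self,
        record: VariantRecord,
        consequence: str,
        gene_id: str,
        samples: Sequence[str],
    ) -> None:
        self.records.append(record)
        row = {
            "chrom": record.chrom,
            "pos": record.pos,
            "var_class": record.var_class,
            "consequence": consequence,
            "gene_id": gene_id,
        }
        for s in samples:
            gt = record.genotypes[s]
            row[f"gt_{s}"] = f"{gt[0]}/{gt[1]}"
        self.truth_rows.append(row)


def _plant_cds_snp(
    planter: _Planter,
    gene: GeneModel,
    want: str,
    genotypes: dict[str, tuple[int, int]],
    rng: np.random.Generator,
    max_tries: int = 400,
) -> Optional[VariantRecord]:
    """Search for a (position, alt) in the gene's CDS whose oracle class
    is ``want``; returns None when the gene offers no such site."""
    chrom_seq = planter.genome.sequences[gene.chrom]
    cds_map = _cds_to_genomic(gene)
    L = len(cds_map)
    if want == START_LOST:
        pool = cds_map[:3]
    elif want == STOP_LOST:
        pool = cds_map[L - 3 :]
    elif want == STOPGAIN:
        pool = cds_map[3 : L - 3]
    else:
        pool = cds_map[3 : L - 3]
    for _ in range(max_tries):
        gpos = int(pool[rng.integers(0, len(pool))])
        ref = chrom_seq[gpos]
        alt = _BASES[rng.integers(0, 4)]
        if alt == ref:
            continue
        if oracle_snp_class(gene, chrom_seq, gpos, alt) != want:
            continue
        if not planter.occupy(gene.chrom, gpos, gpos + 1):
            continue
        rec = VariantRecord(
            chrom=gene.chrom,
            pos=gpos,
            ref_allele=ref,
            alt_alleles=[alt],
            var_class=SNP,
            genotypes=dict(genotypes),
            qual=float(rng.integers(30, 200)),
            depth={s: int(rng.integers(20, 60)) for s in planter.config.samples},
        )
        return rec
    return None


def _plant_cds_indel(
    planter: _Planter,
    gene: GeneModel,
    want: str,
    genotypes: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> Optional[VariantRecord]:
    """Plant an indel wholly inside one CDS segment, away from the
    start and stop codons."""
    chrom_seq = planter.genome.sequences[gene.chrom]
    if want == FRAMESHIFT:
        k = int(rng.integers(1, 3))  # 1 or 2 bp
    else:
        k = 3
    insertion = want == CODON_INSERTION
    cds_map = _cds_to_genomic(gene)
    protected = set(cds_map[:6]) | set(cds_map[-6:])
    candidates = [
        (s, e) for s, e in gene.cds_segments if e - s >= k + 10
    ]
    rng.shuffle(candidates)
    for s, e in candidates:
        for _ in range(40):
            p = int(rng.integers(s + 3, e - k - 3))
            if any(q in protected for q in range(p - 1, p + k + 1)):
                continue
            if not planter.occupy(gene.chrom, p - 1, p + k + 1):
                continue
            anchor = chrom_seq[p - 1]
            if insertion:
                ins = "".join(rng.choice(list(_BASES)) for _ in range(k))
                ref, alt = anchor, anchor + ins
            else:
                ref, alt = anchor + chrom_seq[p : p + k], anchor
            rec = VariantRecord(
                chrom=gene.chrom,
                pos=p,
                ref_allele=ref,
                alt_alleles=[alt],
                var_class=INDEL,
                genotypes=dict(genotypes),
                qual=float(rng.integers(30, 200)),
                depth={s2: int(rng.integers(20, 60)) for s2 in planter.config.samples},
                vcf_pos=p - 1,
            )
            assert oracle_indel_class(len(alt) - len(ref)) == want
            return rec
    return None


def _plant_cds_sv(
    planter: _Planter,
    gene: GeneModel,
    genotypes: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> Optional[VariantRecord]:
    """A deletion SV overlapping the gene's first CDS segment."""
    s, e = gene.cds_segments[0]
    start = max(0, s - int(rng.integers(50, 200)))
    end = min(len(planter.genome.sequences[gene.chrom]), e + int(rng.integers(50, 200)))
    if not planter.occupy(gene.chrom, start, end):
        return None
    chrom_seq = planter.genome.sequences[gene.chrom]
    return VariantRecord(
        chrom=gene.chrom,
        pos=start,
        ref_allele=chrom_seq[start],
        alt_alleles=["<DEL>"],
        var_class=SV,
        sv_type="DEL",
        sv_span=(start, end),
        genotypes=dict(genotypes),
        qual=float(rng.integers(25, 150)),
        depth={s2: int(rng.integers(5, 80)) for s2 in planter.config.samples},
    )


def plant_variants(
    config: SimulationConfig,
    genome: ReferenceGenome,
    models: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], TruthTable]:
    """Plant SNPs, indels and SVs with known truth (see module docstring)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    samples = list(config.samples)

    blocks = (
        list(config.planted_blocks)
        if config.planted_blocks is not None
        else _plant_blocks(config, rng)
    )
    for chrom, bs, be, sample in blocks:
        if chrom not in genome.sequences or be > len(genome.sequences[chrom]) or bs < 0:
            raise ConfigError(f"block ({chrom},{bs},{be}) outside chromosome bounds")
        if sample not in samples:
            raise ConfigError(f"block sample {sample!r} not in {samples}")
    blocks_by_sample = {
        s: [(c, bs, be) for c, bs, be, smp in blocks if smp == s] for s in samples
    }
    genome_bp = sum(genome.lengths.values())
    hom_out: dict[str, float] = {}
    for s in samples:
        b = sum(be - bs for _, bs, be in blocks_by_sample[s]) / genome_bp
        if b >= 1.0:  # blocks cover the whole genome: every call is hom
            hom_out[s] = 1.0
        else:
            hom_out[s] = min(1.0, max(0.0, (config.hom_fraction - b) / (1.0 - b)))

    planter = _Planter(config, genome)
    models_by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        models_by_chrom.setdefault(m.chrom, []).append(m)

    # ---- designated gene roles: candidates, decoys, effect-mix hosts
    shuffled = list(models)
    rng.shuffle(shuffled)
    n_cand, n_decoy = config.n_candidate_genes, config.n_decoy_genes
    if n_cand + n_decoy > len(shuffled):
        raise ConfigError("not enough genes for candidate + decoy roles")
    candidate_genes = shuffled[:n_cand]
    decoy_genes = shuffled[n_cand : n_cand + n_decoy]
    other_genes = shuffled[n_cand + n_decoy :]
    decoy_cds = {
        (m.chrom, s, e) for m in decoy_genes for s, e in m.cds_segments
    }

    def hom_or_het(sample: str, chrom: str, pos: int) -> tuple[int, int]:
        in_block = any(
            c == chrom and bs <= pos < be for c, bs, be in blocks_by_sample[sample]
        )
        if in_block or rng.random() < hom_out[sample]:
            return (1, 1)
        return (0, 1)

    # candidates: 1-2 qualifying variants carried by exactly one sample
    cand_kinds = [FRAMESHIFT, STOPGAIN, NONSYNONYMOUS, CODON_DELETION, SV_CDS_OVERLAP]
    for i, gene in enumerate(candidate_genes):
        target_sample = samples[i % 2]
        n_planted = 0
        for j in range(int(rng.integers(1, 3))):
            kind = cand_kinds[(i + j) % len(cand_kinds)]
            gts = {
                s: (
                    hom_or_het(s, gene.chrom, gene.gene_span[0])
                    if s == target_sample
                    else (0, 0)
                )
                for s in samples
            }
            if kind in SNP_CLASSES:
                rec = _plant_cds_snp(planter, gene, kind, gts, rng)
            elif kind in INDEL_CLASSES:
                rec = _plant_cds_indel(planter, gene, kind, gts, rng)
            else:
                rec = _plant_cds_sv(planter, gene, gts, rng)
            if rec is not None:
                planter.add(rec, kind, gene.gene_id, samples)
                n_planted += 1
        if n_planted == 0:  # guarantee at least one qualifying variant
            gts = {
                s: (hom_or_het(s, gene.chrom, gene.gene_span[0]) if s == target_sample else (0, 0))
                for s in samples
            }
            rec = _plant_cds_snp(planter, gene, NONSYNONYMOUS, gts, rng, max_tries=2000)
            if rec is None:
                raise ConfigError(f"could not plant a qualifying variant in {gene.gene_id}")
            planter.add(rec, NONSYNONYMOUS, gene.gene_id, samples)

    # decoys: synonymous-only, carried by either or both samples
    for gene in decoy_genes:
        for _ in range(int(rng.integers(1, 3))):
            carrier = _draw_carrier(config.carrier_probs, rng)
            gts = {
                s: (hom_or_het(s, gene.chrom, gene.gene_span[0]) if c else (0, 0))
                for s, c in zip(samples, carrier)
            }
            rec = _plant_cds_snp(planter, gene, SYNONYMOUS, gts, rng)
            if rec is not None:
                planter.add(rec, SYNONYMOUS, gene.gene_id, samples)

    # effect mix: every consequence class present in the bundle
    host_cycle = list(other_genes) if other_genes else list(candidate_genes)
    hi = 0
    for klass in ALL_CLASSES if (config.n_effect_per_class > 0 and host_cycle) else ():
        planted = 0
        attempts = 0
        while planted < config.n_effect_per_class and attempts < 10 * len(host_cycle):
            gene = host_cycle[hi % len(host_cycle)]
            hi += 1
            attempts += 1
            carrier = _draw_carrier(config.carrier_probs, rng)
            gts = {
                s: (hom_or_het(s, gene.chrom, gene.gene_span[0]) if c else (0, 0))
                for s, c in zip(samples, carrier)
            }
            if klass in SNP_CLASSES:
                rec = _plant_cds_snp(planter, gene, klass, gts, rng)
            else:
                rec = _plant_cds_indel(planter, gene, klass, gts, rng)
            if rec is not None:
                planter.add(rec, klass, gene.gene_id, samples)
                planted += 1
        if planted == 0:
            raise ConfigError(f"could not plant any {klass} variant")

    # ---- background SNPs and indels
    p_ts = config.ts_tv_target / (1.0 + config.ts_tv_target)
    tv_partners = {b: [x for x in _BASES if x != b and x != _TRANSITION[b]] for b in _BASES}
    cds_lookup: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for m in models:
        for s, e in m.cds_segments:
            cds_lookup.setdefault(m.chrom, []).append((s, e, m))
    for chrom in cds_lookup:
        cds_lookup[chrom].sort()

    def gene_at(chrom: str, pos: int) -> Optional[GeneModel]:
        for s, e, m in cds_lookup.get(chrom, []):
            if s <= pos < e:
                return m
            if s > pos:
                break
        return None

    for chrom, seq in genome.sequences.items():
        L = len(seq)
        forbidden = np.zeros(L, dtype=bool)
        for s, e in planter.used[chrom]:
            forbidden[max(0, s - 35) : min(L, e + 35)] = True
        for c, s, e in ((c, s, e) for c, s, e in decoy_cds if c == chrom):
            forbidden[s:e] = True

        # 0 intergenic, 1 intron, 2 exon — for region-dependent retention
        region_code = np.zeros(L, dtype=np.uint8)
        for m in models_by_chrom.get(chrom, []):
            gs, ge = m.gene_span
            region_code[gs:ge] = 1
        for m in models_by_chrom.get(chrom, []):
            for cs, ce in m.cds_segments:
                region_code[cs:ce] = 2
        w = config.region_snp_weights
        weights = (w.get("intergenic", 1.0), w.get("intron", 1.0), w.get("exon", 1.0))

        n_snps = int(round(L * config.snp_rate))
        pos_pool = rng.choice(L - 2, size=min(n_snps * 2, L - 2), replace=False) + 1
        snp_positions = [int(p) for p in pos_pool if not forbidden[p]][:n_snps]
        for p in sorted(snp_positions):
            if forbidden[p]:
                continue
            if rng.random() > weights[region_code[p]]:
                continue
            ref = seq[p]
            if ref not in _TRANSITION:
                continue
            if rng.random() < p_ts:
                alt = _TRANSITION[ref]
            else:
                alt = tv_partners[ref][rng.integers(0, 2)]
            carrier = _draw_carrier(config.carrier_probs, rng)
            gts = _pick_genotype(chrom, p, carrier, blocks_by_sample, hom_out, samples, rng)
            gene = gene_at(chrom, p)
            consequence = (
                oracle_snp_class(gene, seq, p, alt) if gene is not None else "none"
            )
            rec = VariantRecord(
                chrom=chrom, pos=p, ref_allele=ref, alt_alleles=[alt], var_class=SNP,
                genotypes=gts,
                qual=float(rng.integers(30, 200)),
                depth={s2: int(rng.integers(20, 60)) for s2 in samples},
            )
            planter.add(rec, consequence, gene.gene_id if gene else "intergenic", samples)
            forbidden[max(0, p - 3) : p + 3] = True

        # indels outside CDS (intergenic / intronic), 1-4 bp heavy tail to 30
        for m in models_by_chrom.get(chrom, []):
            for s, e in m.cds_segments:
                forbidden[max(0, s - 35) : min(L, e + 35)] = True
        n_indels = int(round(L * config.indel_rate))
        lengths = np.minimum(rng.geometric(0.55, size=n_indels), 30)
        pool = rng.choice(L - 40, size=min(n_indels * 3, L - 40), replace=False) + 1
        placed = 0
        for p in sorted(int(x) for x in pool):
            if placed >= n_indels:
                break
            k = int(lengths[placed])
            if forbidden[p - 1 : p + k + 1].any():
                continue
            anchor = seq[p - 1]
            if rng.random() < 0.5:
                ref, alt = anchor + seq[p : p + k], anchor  # deletion
            else:
                ins = "".join(rng.choice(list(_BASES)) for _ in range(k))
                ref, alt = anchor, anchor + ins  # insertion
            carrier = _draw_carrier(config.carrier_probs, rng)
            gts = _pick_genotype(chrom, p, carrier, blocks_by_sample, hom_out, samples, rng)
            rec = VariantRecord(
                chrom=chrom, pos=p, ref_allele=ref, alt_alleles=[alt], var_class=INDEL,
                genotypes=gts,
                qual=float(rng.integers(30, 200)),
                depth={s2: int(rng.integers(20, 60)) for s2 in samples},
                vcf_pos=p - 1,
            )
            planter.add(rec, "none", "intergenic", samples)
            forbidden[max(0, p - 40) : p + k + 40] = True
            placed += 1

        # background SVs in gene-free stretches (depth/quality all passing)
        for _ in range(config.sv_per_chrom):
            for _try in range(50):
                start = int(rng.integers(0, L - 25_000))
                end = start + int(rng.integers(2_000, 20_000))
                if any(
                    m.gene_span[0] < end and start < m.gene_span[1]
                    for m in models_by_chrom.get(chrom, [])
                ):
                    continue
                if not planter.occupy(chrom, start, end):
                    continue
                carrier = _draw_carrier(config.carrier_probs, rng)
                gts = _pick_genotype(
                    chrom, start, carrier, blocks_by_sample, hom_out, samples, rng
                )
                sv_type = ["DEL", "INV", "ITX", "CTX"][_try % 4]
                planter.add(
                    VariantRecord(
                        chrom=chrom, pos=start, ref_allele=seq[start],
                        alt_alleles=[f"<{sv_type}>"], var_class=SV,
                        sv_type=sv_type, sv_span=(start, end), genotypes=gts,
                        qual=float(rng.integers(25, 150)),
                        depth={s2: int(rng.integers(5, 80)) for s2 in samples},
                    ),
                    "none",
                    "intergenic",
                    samples,
                )
                break

    # ---- truth tables recomputed from what was actually planted
    variants_df = pd.DataFrame(planter.truth_rows).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    gene_rows = []
    qual_sets: dict[str, dict[str, set]] = {}
    for row in planter.truth_rows:
        if row["consequence"] in QUALIFYING_CONSEQUENCES:
            g = qual_sets.setdefault(row["gene_id"], {s: set() for s in samples})
            for s in samples:
                if row[f"gt_{s}"] not in ("0/0", "./."):
                    g[s].add((row["chrom"], row["pos"], row["consequence"]))
    for m in models:
        sets = qual_sets.get(m.gene_id, {s: set() for s in samples})
        qualifying = sorted(s for s in samples if sets[s])
        gene_rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "qualifies": bool(qualifying),
                "qualifying_samples": ",".join(qualifying),
                "differs_between_samples": sets[samples[0]] != sets[samples[1]],
            }
        )
    truth = TruthTable(
        variants=variants_df,
        blocks=blocks,
        genes=pd.DataFrame(gene_rows),
    )
    variants = sorted(planter.records, key=lambda r: (r.chrom, r.pos))
    return variants, truth


# ------------------------------------------------------------ entry points


def simulate_bundle(config: SimulationConfig) -> SimBundle:
    """Reference + gene models + domains + two-sample variants + truth,
    all from one RNG stream keyed by the config seed."""
    rng = np.random.default_rng(config.seed)
    genome, models, domains = generate_reference(config, rng)
    variants, truth = plant_variants(config, genome, models, rng)
    return SimBundle(
        config=config, genome=genome, models=models, domains=domains,
        variants=variants, truth=truth,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit ref.fa, genes.gff3, domains.tsv, calls.vcf and truth/*.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths = {
        "fasta": outdir / "ref.fa",
        "gff3": outdir / "genes.gff3",
        "domains": outdir / "domains.tsv",
        "vcf": outdir / "calls.vcf",
        "truth_variants": outdir / "truth" / "variants.tsv",
        "truth_blocks": outdir / "truth" / "blocks.tsv",
        "truth_genes": outdir / "truth" / "genes.tsv",
    }
    write_fasta(bundle.genome, paths["fasta"])
    write_gff3(bundle.models, paths["gff3"])
    write_domains(bundle.domains, paths["domains"])
    write_vcf(bundle.variants, list(bundle.samples), paths["vcf"], contigs=bundle.genome.lengths)
    write_tsv(bundle.truth.variants, paths["truth_variants"])
    write_tsv(
        pd.DataFrame(bundle.truth.blocks, columns=["chrom", "start", "end", "sample"]),
        paths["truth_blocks"],
    )
    write_tsv(bundle.truth.genes, paths["truth_genes"])
    return paths


# -------------------------------------------------- effect-oracle panel


def simulate_effect_panel(
    seed: int,
    n_per_class: int = 1000,
    classes: Sequence[str] = ALL_CLASSES,
) -> tuple[ReferenceGenome, list[GeneModel], list[tuple[VariantRecord, str]]]:
    """A dense panel of CDS variants with oracle-verified classes.

    Start- and stop-codon classes are limited to two plants per gene
    (each gene has one start and one stop), so the panel sizes its gene
    count from the requested quota. Used to exercise the annotation
    engine against truth at scale.
    """
    rng = np.random.default_rng(seed)
    # one start and one stop codon per gene, and plants keep a 35-bp
    # berth, so start/stop classes need roughly one gene each
    n_genes = max(60, n_per_class + 50)
    config = SimulationConfig(
        seed=seed,
        n_chroms=1,
        chrom_length=n_genes * 1500,
        n_genes_per_chrom=n_genes,
        n_candidate_genes=0,
        n_decoy_genes=0,
        domain_density=0.0,
    )
    genome, models, _ = generate_reference(config, rng)
    planter = _Planter(config, genome)
    gts = {s: (1, 1) for s in config.samples}
    panel: list[tuple[VariantRecord, str]] = []
    per_gene_limit = {START_LOST: 1, STOP_LOST: 1}
    # plant the single-site classes first so other plants do not crowd
    # the start/stop codons out with their 35-bp berth
    ordered = [k for k in (START_LOST, STOP_LOST) if k in classes]
    ordered += [k for k in classes if k not in ordered]
    for klass in ordered:
        planted = 0
        plants_in_gene: dict[str, int] = {}
        gi = 0
        spins = 0
        while planted < n_per_class and spins < 20 * len(models):
            gene = models[gi % len(models)]
            gi += 1
            spins += 1
            if plants_in_gene.get(gene.gene_id, 0) >= per_gene_limit.get(klass, 6):
                continue
            if klass in SNP_CLASSES:
                rec = _plant_cds_snp(planter, gene, klass, gts, rng, max_tries=60)
            else:
                rec = _plant_cds_indel(planter, gene, klass, gts, rng)
            if rec is not None:
                panel.append((rec, klass))
                plants_in_gene[gene.gene_id] = plants_in_gene.get(gene.gene_id, 0) + 1
                planted += 1
        if planted < n_per_class:
            raise ConfigError(
                f"panel quota not met for {klass}: {planted}/{n_per_class}"
            )
    return genome, models, panel
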