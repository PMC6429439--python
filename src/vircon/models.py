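"""Core domain types shared across the pipeline.

All coordinates inside the package are 0-based half-open. The 1-based
conventions of GFF3 and VCF are converted at the format boundary in
:mod:`vircon.genomic_io` and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------- constants

SNP = "SNP"
INDEL = "INDEL"
SV = "SV"

SV_TYPES = ("DEL", "INS", "INV", "ITX", "CTX", "UNKNOWN")

# region classes
INTERGENIC = "intergenic"
GENIC_INTRON = "genic_intron"
GENIC_EXON_UTR = "genic_exon_utr"
GENIC_CDS = "genic_cds"

# coding consequences
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOPGAIN = "stopgain"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
FRAMESHIFT = "frameshift"
CODON_DELETION = "codon_deletion"
CODON_INSERTION = "codon_insertion"
SV_CDS_OVERLAP = "sv_cds_overlap"
NO_CONSEQUENCE = "none"

#: consequences that make a gene a self-incompatibility candidate
QUALIFYING_CONSEQUENCES = frozenset(
    {
        NONSYNONYMOUS,
        STOPGAIN,
        STOP_LOST,
        START_LOST,
        FRAMESHIFT,
        CODON_DELETION,
        CODON_INSERTION,
        SV_CDS_OVERLAP,
    }
)

#: most-severe-first ordering used when a multi-allelic record is
#: collapsed to a single consequence label
SEVERITY_ORDER = (
    STOPGAIN,
    STOP_LOST,
    START_LOST,
    FRAMESHIFT,
    NONSYNONYMOUS,
    CODON_DELETION,
    CODON_INSERTION,
    SV_CDS_OVERLAP,
    SYNONYMOUS,
    NO_CONSEQUENCE,
)

# zygosity
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

MISSING_GT = (-1, -1)


# ---------------------------------------------------------------- containers


@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """Stranded multi-exon CDS for one gene.

    ``cds_segments`` are genomic ``[start, end)`` intervals sorted by
    start regardless of strand; transcription order is derived from
    ``strand`` when splicing.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds_segments: list[tuple[int, int]]
    gene_span: tuple[int, int]
    biotype: str = "protein_coding"
    warnings: list[str] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class VariantRecord:
    """One normalized variant with per-sample genotypes.

    ``pos`` is the 0-based genomic position of the first altered base
    after indel normalization. The original (anchored) allele strings
    are kept so multi-allelic joint genotypes stay interpretable.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    var_class: str  # SNP / INDEL / SV
    genotypes: dict[str, tuple[int, int]]
    sv_type: Optional[str] = None
    sv_span: Optional[tuple[int, int]] = None
    qual: Optional[float] = None
    depth: Optional[dict[str, int]] = None
    #: 0-based position of the anchored VCF record (POS-1); kept so that
    #: writing a record back to VCF reproduces the source line exactly
    vcf_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.vcf_pos is None:
            self.vcf_pos = self.pos

    def alleles_of(self, sample: str) -> Optional[set[str]]:
        """The set of allele strings the sample carries, or None if missing."""
        gt = self.genotypes.get(sample, MISSING_GT)
        if gt[0] < 0 or gt[1] < 0:
            return None
        pool = [self.ref_allele] + list(self.alt_alleles)
        return {pool[gt[0]], pool[gt[1]]}


@dataclass
class DomainAnnotation:
    """One Pfam-family interval in 1-based inclusive protein coordinates."""

    gene_id: str
    family: str
    aa_start: int
    aa_end: int


@dataclass
class EffectCall:
    """Region class plus coding consequence for one (variant, gene) pair."""

    variant: VariantRecord
    gene_id: str  # or "intergenic"
    region_class: str
    consequence: str = NO_CONSEQUENCE
    aa_change: str = ""
    cds_pos: Optional[int] = None
    truncation: Optional[int] = None  # residues lost to a premature stop
    mutant_protein_length: Optional[int] = None
    boundary_flag: bool = False
    model_warning: bool = False


@dataclass
class ProteinProduct:
    gene_id: str
    aa_sequence: str

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class LocusContrast:
    """Per-locus comparison of the two selfing lines."""

    variant: VariantRecord
    zygosity_a: str
    zygosity_b: str
    consistent: bool
    between_sample_variant: bool
    unresolvable: bool = False


@dataclass
class ScanParams:
    window_size: int = 100_000
    step: int = 100_000
    het_threshold: float = 0.10
    min_variants: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.het_threshold < 1):
            raise ValueError("het_threshold must be in (0, 1)")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


@dataclass
class WindowStat:
    chrom: str
    window: tuple[int, int]
    n_variants: int
    n_het: int
    status: str  # homozygous / heterozygous / no_call

    @property
    def het_fraction(self) -> float:
        return self.n_het / self.n_variants if self.n_variants else float("nan")


@dataclass
class HomozygousRegion:
    chrom: str
    span: tuple[int, int]
    sample: str


@dataclass
class SVFilterParams:
    min_depth: int = 2
    max_depth: int = 100
    min_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")


@dataclass
class DomainEnrichment:
    family: str
    n_nonsyn: int
    n_syn: int
    ratio: float
    chi2: float
    p_value: float
    flagged: bool


@dataclass
class CandidateGene:
    gene_id: str
    chrom: str
    position: int  # gene start, bp
    evidence: list[tuple[str, str, int]]  # (sample, consequence, variant pos)
    differs_between_samples: bool
    prior_match: bool
    zygosity_profile: dict[str, dict[str, int]]

    @property
    def position_mb(self) -> float:
        return self.position / 1e6
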