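"""Format boundary behaviour: coordinate conversion, indel
normalization, error handling, and deterministic writers."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vircon import genomic_io as io
from vircon.errors import ConfigError, FormatError
from vircon.models import INDEL, SNP, SV


# ---------------------------------------------------------------- FASTA


def test_read_fasta_loads_and_uppercases(tmp_path):
    p = tmp_path / "r.fa"
    p.write_text(">chr1\nacgt\n>chr2\nNNAA\n")
    g = io.read_fasta(p)
    assert g.sequences == {"chr1": "ACGT", "chr2": "NNAA"}
    assert g.lengths == {"chr1": 4, "chr2": 4}


@pytest.mark.parametrize("content", ["", "acgt\n"])
def test_read_fasta_rejects_malformed(tmp_path, content):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError):
        io.read_fasta(p)


# ----------------------------------------------------------------- GFF3

GFF = """##gff-version 3
chr1\t.\tgene\t101\t400\t.\t+\t.\tID=gA
chr1\t.\tmRNA\t101\t400\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\t.\tCDS\t101\t160\t.\t+\t0\tID=gA.c;Parent=gA.t1
chr1\t.\tCDS\t201\t260\t.\t+\t0\tID=gA.c;Parent=gA.t1
chr1\t.\tgene\t501\t700\t.\t-\t.\tID=gB
chr1\t.\tmRNA\t501\t700\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\t.\tCDS\t501\t550\t.\t-\t0\tID=gB.c;Parent=gB.t1
chr1\t.\tCDS\t601\t650\t.\t-\t2\tID=gB.c;Parent=gB.t1
"""


def test_read_gff3_converts_coordinates_and_orders_segments(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(GFF)
    models = {m.gene_id: m for m in io.read_gff3(p)}
    # 1-based inclusive 101..160 -> 0-based half-open [100, 160)
    assert models["gA"].cds_segments == [(100, 160), (200, 260)]
    assert models["gA"].gene_span == (100, 400)
    # minus-strand segments still stored in genomic order
    assert models["gB"].strand == "-"
    assert models["gB"].cds_segments == [(500, 550), (600, 650)]


def test_read_gff3_keeps_first_isoform(tmp_path):
    text = GFF + (
        "chr1\t.\tmRNA\t101\t400\t.\t+\t.\tID=gA.t2;Parent=gA\n"
        "chr1\t.\tCDS\t101\t130\t.\t+\t0\tID=gA.c2;Parent=gA.t2\n"
    )
    p = tmp_path / "iso.gff3"
    p.write_text(text)
    models = {m.gene_id: m for m in io.read_gff3(p)}
    assert models["gA"].cds_segments == [(100, 160), (200, 260)]


def test_read_gff3_rejects_reversed_interval(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("chr1\t.\tgene\t500\t100\t.\t+\t.\tID=g\n")
    with pytest.raises(FormatError):
        io.read_gff3(p)


def test_read_gff3_skips_orphan_cds(tmp_path, caplog):
    p = tmp_path / "orphan.gff3"
    p.write_text(GFF + "chr1\t.\tCDS\t801\t860\t.\t+\t0\tID=stray\n")
    models = io.read_gff3(p)
    assert {m.gene_id for m in models} == {"gA", "gB"}


# ------------------------------------------------------------------ VCF

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def _vcf(tmp_path, rows):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return p


def test_read_vcf_snp_and_sv(tmp_path):
    p = _vcf(
        tmp_path,
        [
            "chr1\t50\t.\tA\tG\t60\tPASS\t.\tGT\t1/1\t0/1",
            "chr1\t200\t.\tA\t<DEL>\t90\tPASS\tSVTYPE=DEL;END=900\tGT\t0/1\t0/0",
        ],
    )
    snp, sv = io.read_vcf(p, ["S1", "S2"])
    assert (snp.var_class, snp.pos, snp.genotypes["S1"]) == (SNP, 49, (1, 1))
    assert (sv.var_class, sv.sv_type, sv.sv_span) == (SV, "DEL", (199, 900))


def test_read_vcf_normalizes_unanchored_deletion(tmp_path):
    # CAC -> A at POS 101: a 2-bp deletion of "AC" at internal pos 101
    p = _vcf(tmp_path, ["chr1\t101\t.\tCAC\tA\t60\tPASS\t.\tGT\t1/1\t0/0"])
    (rec,) = io.read_vcf(p, ["S1", "S2"])
    assert rec.var_class == INDEL
    assert rec.pos == 101
    _, deleted, inserted = io.normalize_indel(100, "CAC", "A")
    assert (deleted, inserted) == ("AC", "")


def test_read_vcf_routes_long_indel_to_sv(tmp_path):
    ref = "A" + "CT" * 16  # 33 bp: net change 32 > 30
    p = _vcf(tmp_path, [f"chr1\t10\t.\t{ref}\tA\t60\tPASS\t.\tGT\t1/1\t0/0"])
    (rec,) = io.read_vcf(p, ["S1", "S2"])
    assert rec.var_class == SV


def test_read_vcf_drops_all_missing_and_checks_samples(tmp_path):
    p = _vcf(
        tmp_path,
        [
            "chr1\t50\t.\tA\tG\t60\tPASS\t.\tGT\t./.\t./.",
            "chr1\t60\t.\tC\tT\t60\tPASS\t.\tGT\t0/1\t./.",
        ],
    )
    recs = io.read_vcf(p, ["S1", "S2"])
    assert len(recs) == 1 and recs[0].pos == 59
    with pytest.raises(ConfigError):
        io.read_vcf(p, ["S1", "missing_sample"])


@pytest.mark.parametrize(
    "pos,ref,alt,expect",
    [
        (100, "CAC", "A", (101, "AC", "")),  # anchor differs from alt
        (100, "CA", "C", (101, "A", "")),  # anchored 1-bp deletion
        (100, "C", "CAT", (101, "", "AT")),  # anchored insertion
        (100, "CAAT", "CA", (102, "AT", "")),  # longer shared prefix
        (100, "A", "G", (100, "A", "G")),  # substitution untouched
    ],
)
def test_normalize_indel(pos, ref, alt, expect):
    assert io.normalize_indel(pos, ref, alt) == expect


@settings(max_examples=200, derandomize=True)
@given(
    prefix=st.text(alphabet="ACGT", min_size=1, max_size=8),
    core=st.text(alphabet="ACGT", min_size=1, max_size=30),
    context=st.text(alphabet="ACGT", min_size=5, max_size=20),
    is_deletion=st.booleans(),
)
def test_normalized_edit_reproduces_raw_substitution(prefix, core, context, is_deletion):
    """Applying the normalized (deleted, inserted) edit at its reported
    position reconstructs exactly the string produced by the raw
    REF -> ALT substitution."""
    ref, alt = (prefix + core, prefix) if is_deletion else (prefix, prefix + core)
    pos = len(context)
    seq = context + ref + context
    raw = seq[:pos] + alt + seq[pos + len(ref) :]
    npos, deleted, inserted = io.normalize_indel(pos, ref, alt)
    assert seq[npos : npos + len(deleted)] == deleted
    edited = seq[:npos] + inserted + seq[npos + len(deleted) :]
    assert edited == raw


# ------------------------------------------------------------ BED / TSV


def test_write_bed_sorts_and_handles_empty(tmp_path):
    p = tmp_path / "r.bed"
    io.write_bed([("chr2", 5, 10), ("chr1", 100, 200)], p)
    lines = p.read_text().splitlines()
    assert lines[0].startswith("chr1\t100\t200")
    io.write_bed([], tmp_path / "empty.bed")
    assert (tmp_path / "empty.bed").read_text() == ""


# ------------------------------------------------------------ round-trip


def test_bundle_round_trip_is_exact(small_bundle, bundle_paths):
    genome = io.read_fasta(bundle_paths["fasta"])
    assert genome.sequences == small_bundle.genome.sequences

    models = {m.gene_id: m for m in io.read_gff3(bundle_paths["gff3"])}
    assert len(models) == len(small_bundle.models)
    for m in small_bundle.models:
        r = models[m.gene_id]
        assert (r.chrom, r.strand, r.cds_segments, r.gene_span) == (
            m.chrom, m.strand, m.cds_segments, m.gene_span,
        )

    variants = io.read_vcf(bundle_paths["vcf"], list(small_bundle.samples))
    assert len(variants) == len(small_bundle.variants)
    key = lambda v: (v.chrom, v.vcf_pos, v.ref_allele)
    for a, b in zip(sorted(small_bundle.variants, key=key), sorted(variants, key=key)):
        assert (a.chrom, a.pos, a.ref_allele, a.alt_alleles, a.var_class, a.genotypes) == (
            b.chrom, b.pos, b.ref_allele, b.alt_alleles, b.var_class, b.genotypes,
        )


def test_snp_coordinate_law(small_bundle):
    """Every SNP's REF allele matches the reference base at its position."""
    for v in small_bundle.variants:
        if v.var_class == SNP:
            assert small_bundle.genome.fetch(v.chrom, v.pos, v.pos + 1) == v.ref_allele
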