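"""Zygosity classification and per-locus contrast of two selfing lines.

A locus is a "between-sample variant" when the two lines' allele
multisets differ and at least one line carries a non-reference allele
the other lacks. Phase is ignored (0/1 == 1/0): the underlying calls
are unphased.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError
from .models import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    LocusContrast,
    VariantRecord,
)


def classify_zygosity(variant: VariantRecord, sample: str) -> str:
    gt = variant.genotypes.get(sample, (-1, -1))
    a, b = gt
    if a < 0 or b < 0:
        return MISSING
    if a == b == 0:
        return HOM_REF
    if a == b:
        return HOM_ALT
    return HET


def _allele_multiset(variant: VariantRecord, sample: str) -> Counter | None:
    gt = variant.genotypes.get(sample, (-1, -1))
    if gt[0] < 0 or gt[1] < 0:
        return None
    pool = [variant.ref_allele] + list(variant.alt_alleles)
    return Counter((pool[gt[0]], pool[gt[1]]))


def contrast_locus(variant: VariantRecord, sample_a: str, sample_b: str) -> LocusContrast:
    za = classify_zygosity(variant, sample_a)
    zb = classify_zygosity(variant, sample_b)
    ma = _allele_multiset(variant, sample_a)
    mb = _allele_multiset(variant, sample_b)
    if ma is None or mb is None:
        return LocusContrast(
            variant=variant, zygosity_a=za, zygosity_b=zb,
            consistent=False, between_sample_variant=False, unresolvable=True,
        )
    consistent = ma == mb
    between = False
    if not consistent:
        ref = variant.ref_allele
        only_a = set(ma) - set(mb)
        only_b = set(mb) - set(ma)
        between = any(x != ref for x in only_a | only_b)
    return LocusContrast(
        variant=variant, zygosity_a=za, zygosity_b=zb,
        consistent=consistent, between_sample_variant=between,
    )


def contrast_all(
    variants: Sequence[VariantRecord], sample_a: str, sample_b: str
) -> list[LocusContrast]:
    return [contrast_locus(v, sample_a, sample_b) for v in variants]


def contrast_summary(
    contrasts: Sequence[LocusContrast], sample_a: str, sample_b: str
) -> dict:
    """Homozygote fractions per sample and between-sample locus counts."""
    out: dict = {"samples": [sample_a, sample_b]}
    for key, getter in (
        (sample_a, lambda c: c.zygosity_a),
        (sample_b, lambda c: c.zygosity_b),
    ):
        by_class: dict[str, dict[str, int]] = {}
        for c in contrasts:
            z = getter(c)
            if z in (MISSING, HOM_REF):
                continue  # not a call carried by this sample
            cls = c.variant.var_class
            d = by_class.setdefault(cls, {"hom": 0, "het": 0})
            d["hom" if z == HOM_ALT else "het"] += 1
        out[key] = {
            cls: {
                **counts,
                "hom_fraction": counts["hom"] / max(counts["hom"] + counts["het"], 1),
            }
            for cls, counts in by_class.items()
        }
    between = [c for c in contrasts if c.between_sample_variant]
    out["between_sample"] = dict(Counter(c.variant.var_class for c in between))
    out["unresolvable"] = sum(c.unresolvable for c in contrasts)
    return out


# ------------------------------------------------- worked-example fixture

#: column names of the in-package FIP2-like allele table
_FIXTURE_COLUMNS = ("type", "pos", "reference", "Ls-S2-53", "Ls-S2-76")


def load_fip2_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged FIP2-like allele table (reference vs two lines).

    Each allele cell may hold a comma-separated set (a heterozygous
    call transcribed from cloned-sequence alignments).
    """
    if path is None:
        src = resources.files("vircon.data").joinpath("fip2_variants.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_FIXTURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"FIP2 table missing columns: {sorted(missing)}")
    return df


@dataclass
class SampleDifferenceCount:
    """SNP and indel differences of one sample versus the reference column."""

    sample: str
    n_snp: int
    indel_lengths: list[int]  # absolute net bp per indel difference


def _parse_alleles(cell: str) -> set[str]:
    return {a.strip().upper() for a in str(cell).split(",") if a.strip()}


def count_table_snp_differences(rows: pd.DataFrame, sample: str) -> SampleDifferenceCount:
    """Count Syn/Nonsyn rows where the sample's allele set differs from
    the reference; frameshift rows are tallied separately as indels with
    their normalized net lengths.
    """
    if sample not in rows.columns:
        raise FormatError(f"sample column {sample!r} not in table")
    n_snp = 0
    indels: list[int] = []
    for _, row in rows.iterrows():
        vtype = str(row["type"]).strip().lower()
        ref_alleles = _parse_alleles(row["reference"])
        alleles = _parse_alleles(row[sample])
        if vtype in ("syn", "nonsyn"):
            if alleles - ref_alleles:
                n_snp += 1
        elif vtype in ("frame_shift", "frameshift"):
            ref = next(iter(ref_alleles))
            for a in alleles:
                if len(a) != len(ref):
                    indels.append(abs(len(a) - len(ref)))
        else:
            raise FormatError(f"unknown variation type {row['type']!r}")
    return SampleDifferenceCount(sample=sample, n_snp=n_snp, indel_lengths=sorted(indels))
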