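"""Per-Pfam-family nonsynonymous/synonymous SNP accounting.

Coding SNPs are mapped to protein residues, intersected with domain
intervals, and each family's nonsyn/syn split is contrasted with the
genome-wide CDS background in a 2x2 chi-square test (1 df, no
continuity correction). A family is flagged when it holds more than 30
nonsyn+syn SNPs combined and a nonsyn/syn ratio above 0.6 (a strict
mode requires each count above 30 separately).
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Sequence

import pandas as pd
from scipy.stats import chi2_contingency

from .models import (
    NONSYNONYMOUS,
    SYNONYMOUS,
    DomainAnnotation,
    DomainEnrichment,
    EffectCall,
)

log = logging.getLogger(__name__)

FLAG_MIN_TOTAL = 30
FLAG_MIN_RATIO = 0.6


def residue_of(cds_pos: int) -> int:
    """1-based protein residue index holding a spliced-CDS position."""
    return cds_pos // 3 + 1


def map_snp_to_domain(
    effect: EffectCall,
    domains: Sequence[DomainAnnotation],
    protein_length: int | None = None,
) -> list[str]:
    """Families whose intervals contain the SNP's residue (each family
    at most once, even with overlapping intervals)."""
    if effect.cds_pos is None:
        return []
    residue = residue_of(effect.cds_pos)
    if protein_length is not None and residue > protein_length:
        log.warning(
            "%s: residue %d beyond protein length %d", effect.gene_id, residue, protein_length
        )
    hits = {
        d.family
        for d in domains
        if d.gene_id == effect.gene_id and d.aa_start <= residue <= d.aa_end
    }
    return sorted(hits)


def family_counts(
    effects: Sequence[EffectCall], domains: Sequence[DomainAnnotation]
) -> dict[str, dict[str, int]]:
    """Per-family nonsyn and syn SNP tallies."""
    by_gene: dict[str, list[DomainAnnotation]] = defaultdict(list)
    for d in domains:
        by_gene[d.gene_id].append(d)
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {"nonsyn": 0, "syn": 0})
    for c in effects:
        if c.consequence not in (NONSYNONYMOUS, SYNONYMOUS):
            continue
        for family in map_snp_to_domain(c, by_gene.get(c.gene_id, [])):
            counts[family]["nonsyn" if c.consequence == NONSYNONYMOUS else "syn"] += 1
    return dict(counts)


def enrich(
    family: str,
    n_nonsyn: int,
    n_syn: int,
    background_nonsyn: int,
    background_syn: int,
    strict: bool = False,
) -> DomainEnrichment:
    """2x2 chi-square of (family vs rest-of-genome) x (nonsyn vs syn).

    The background totals are genome-wide CDS counts including the
    family itself; the rest-of-genome row is background minus family.
    A zero margin leaves the p-value undefined (NaN) and unflagged.
    """
    rest_nonsyn = background_nonsyn - n_nonsyn
    rest_syn = background_syn - n_syn
    table = [[n_nonsyn, n_syn], [rest_nonsyn, rest_syn]]
    margins = (
        n_nonsyn + n_syn,
        rest_nonsyn + rest_syn,
        n_nonsyn + rest_nonsyn,
        n_syn + rest_syn,
    )
    if any(m <= 0 for m in margins) or min(rest_nonsyn, rest_syn) < 0:
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=False)
    ratio = n_nonsyn / n_syn if n_syn else float("inf") if n_nonsyn else float("nan")
    if strict:
        flagged = n_nonsyn > FLAG_MIN_TOTAL and n_syn > FLAG_MIN_TOTAL and ratio > FLAG_MIN_RATIO
    else:
        flagged = (n_nonsyn + n_syn) > FLAG_MIN_TOTAL and ratio > FLAG_MIN_RATIO
    if math.isnan(p):
        flagged = False if (n_nonsyn + n_syn) == 0 else flagged
    return DomainEnrichment(
        family=family,
        n_nonsyn=n_nonsyn,
        n_syn=n_syn,
        ratio=ratio,
        chi2=chi2,
        p_value=p,
        flagged=flagged,
    )


def enrich_all(
    effects: Sequence[EffectCall],
    domains: Sequence[DomainAnnotation],
    strict: bool = False,
    bonferroni: bool = False,
) -> list[DomainEnrichment]:
    """Rank every family by nonsyn/syn ratio then chi-square."""
    bg_nonsyn = sum(1 for c in effects if c.consequence == NONSYNONYMOUS)
    bg_syn = sum(1 for c in effects if c.consequence == SYNONYMOUS)
    counts = family_counts(effects, domains)
    results = [
        enrich(fam, c["nonsyn"], c["syn"], bg_nonsyn, bg_syn, strict=strict)
        for fam, c in counts.items()
    ]
    if bonferroni and results:
        for r in results:
            if not math.isnan(r.p_value):
                r.p_value = min(1.0, r.p_value * len(results))
    return sorted(
        results,
        key=lambda r: (
            -(r.ratio if math.isfinite(r.ratio) else float("inf")),
            -(r.chi2 if math.isfinite(r.chi2) else -1.0),
            r.family,
        ),
    )


def enrichment_table(results: Sequence[DomainEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "n_nonsyn": r.n_nonsyn,
                "n_syn": r.n_syn,
                "ratio": round(r.ratio, 4) if math.isfinite(r.ratio) else r.ratio,
                "chi2": round(r.chi2, 6) if math.isfinite(r.chi2) else "",
                "p_value": r.p_value if math.isfinite(r.p_value) else "",
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
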