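"""Candidate self-incompatibility gene filter and physical-map table.

A gene becomes a candidate when it carries at least one
amino-acid-changing variant (nonsynonymous, stopgain, stop_lost,
start_lost, frameshift, in-frame codon indel, or an SV overlapping its
CDS) in at least one of the two lines. With ``require_difference`` the
qualifying variant sets of the two lines must additionally differ —
the genes where the lines' proteins diverge from each other, not just
from the reference.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Optional, Sequence

import pandas as pd

from .contrast import classify_zygosity
from .models import (
    HET,
    HOM_ALT,
    QUALIFYING_CONSEQUENCES,
    CandidateGene,
    EffectCall,
    GeneModel,
)

log = logging.getLogger(__name__)


def _carriers(effect: EffectCall, samples: Sequence[str]) -> list[str]:
    return [
        s
        for s in samples
        if classify_zygosity(effect.variant, s) in (HOM_ALT, HET)
    ]


def select_candidates(
    effects: Sequence[EffectCall],
    models: Sequence[GeneModel],
    samples: Sequence[str],
    prior_list: Optional[Sequence[str]] = None,
    require_difference: bool = False,
) -> list[CandidateGene]:
    """Apply the qualifying-consequence filter gene by gene.

    ``prior_list`` entries match by exact gene id or as case-insensitive
    keywords against the gene id / biotype text.
    """
    if prior_list is not None and len(prior_list) == 0:
        log.warning("empty prior gene list: prior_match will be false for all candidates")
    by_gene: dict[str, list[EffectCall]] = defaultdict(list)
    for c in effects:
        if c.consequence in QUALIFYING_CONSEQUENCES and c.gene_id != "intergenic":
            by_gene[c.gene_id].append(c)

    model_by_id = {m.gene_id: m for m in models}
    prior_exact = set(prior_list or [])
    prior_keywords = [p.lower() for p in (prior_list or [])]

    out: list[CandidateGene] = []
    for gene_id, calls in by_gene.items():
        evidence: list[tuple[str, str, int]] = []
        qual_sets: dict[str, set] = {s: set() for s in samples}
        zyg: dict[str, Counter] = {s: Counter() for s in samples}
        for c in calls:
            for s in _carriers(c, samples):
                evidence.append((s, c.consequence, c.variant.pos))
                qual_sets[s].add((c.variant.chrom, c.variant.pos, c.consequence))
                zyg[s][classify_zygosity(c.variant, s)] += 1
        if not evidence:
            continue
        differs = len(samples) == 2 and qual_sets[samples[0]] != qual_sets[samples[1]]
        if require_difference and not differs:
            continue
        model = model_by_id.get(gene_id)
        chrom = model.chrom if model else calls[0].variant.chrom
        position = model.gene_span[0] if model else min(c.variant.pos for c in calls)
        text = f"{gene_id} {model.biotype if model else ''}".lower()
        prior = gene_id in prior_exact or any(k in text for k in prior_keywords)
        out.append(
            CandidateGene(
                gene_id=gene_id,
                chrom=chrom,
                position=position,
                evidence=sorted(evidence),
                differs_between_samples=differs,
                prior_match=prior,
                zygosity_profile={
                    s: {"hom": zyg[s][HOM_ALT], "het": zyg[s][HET]} for s in samples
                },
            )
        )
    return sorted(out, key=lambda c: (c.chrom, c.position, c.gene_id))


def physical_map_table(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Per-chromosome candidate lists with Mb positions."""
    rows = [
        {
            "chrom": c.chrom,
            "gene_id": c.gene_id,
            "position_bp": c.position,
            "position_mb": round(c.position_mb, 3),
            "n_evidence": len(c.evidence),
            "differs_between_samples": c.differs_between_samples,
            "prior_match": c.prior_match,
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "gene_id", "position_bp", "position_mb",
            "n_evidence", "differs_between_samples", "prior_match",
        ],
    )
    return df.sort_values(["chrom", "position_bp"], kind="stable").reset_index(drop=True)


def per_chromosome_counts(candidates: Sequence[CandidateGene]) -> dict[str, int]:
    return dict(sorted(Counter(c.chrom for c in candidates).items()))


def candidate_table(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "position_bp": c.position,
                "evidence": ";".join(f"{s}:{cons}@{pos + 1}" for s, cons, pos in c.evidence),
                "differs_between_samples": c.differs_between_samples,
                "prior_match": c.prior_match,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "position_bp", "evidence", "differs_between_samples", "prior_match"],
    )
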