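"""Sliding-window heterozygosity scan and homozygous-region calling.

For each sample, windows tile each chromosome (step = window size by
default). A window's variants are the loci where the sample carries at
least one alternate allele; the window is called homozygous when the
heterozygous fraction among those calls is below the threshold and the
window holds enough calls to judge. Consecutive homozygous windows
merge into regions; regions present in exactly one sample are the
differential regions the two selfing lines disagree on.
"""
from __future__ import annotations

from typing import Sequence

from .errors import CoordinateError
from .models import (
    HET,
    HOM_ALT,
    INDEL,
    SNP,
    HomozygousRegion,
    ScanParams,
    VariantRecord,
    WindowStat,
)
from .contrast import classify_zygosity

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
NO_CALL = "no_call"


def scan_chromosome(
    variants: Sequence[VariantRecord],
    chrom: str,
    chrom_length: int,
    params: ScanParams,
    sample: str,
    classes: tuple[str, ...] = (SNP,),
) -> list[WindowStat]:
    """Per-window call counts and status for one sample on one chromosome.

    ``classes`` selects which variant classes enter the tally (SNPs by
    default; pass ``(SNP, INDEL)`` to include indels).
    """
    if chrom_length <= 0:
        raise CoordinateError(f"{chrom}: non-positive length {chrom_length}")
    windows = []
    start = 0
    while start < chrom_length:
        windows.append((start, min(start + params.window_size, chrom_length)))
        start += params.step

    n = [0] * len(windows)
    n_het = [0] * len(windows)
    for v in variants:
        if v.chrom != chrom or v.var_class not in classes:
            continue
        if v.pos >= chrom_length:
            raise CoordinateError(f"{chrom}:{v.pos}: variant beyond chromosome end")
        z = classify_zygosity(v, sample)
        if z not in (HOM_ALT, HET):
            continue  # not a call carried by this sample
        if params.step == params.window_size:
            hit = [v.pos // params.step]
        else:
            first = max(0, (v.pos - params.window_size) // params.step + 1)
            hit = [
                i
                for i in range(first, min(v.pos // params.step + 1, len(windows)))
                if windows[i][0] <= v.pos < windows[i][1]
            ]
        for i in hit:
            if i < len(windows):
                n[i] += 1
                if z == HET:
                    n_het[i] += 1

    stats = []
    for i, (ws, we) in enumerate(windows):
        if n[i] < params.min_variants:
            status = NO_CALL
        elif n_het[i] / n[i] < params.het_threshold:
            status = HOMOZYGOUS
        else:
            status = HETEROZYGOUS
        stats.append(WindowStat(chrom=chrom, window=(ws, we), n_variants=n[i], n_het=n_het[i], status=status))
    return stats


def merge_regions(
    window_stats: Sequence[WindowStat],
    sample: str,
    bridge_no_call: bool = False,
) -> list[HomozygousRegion]:
    """Merge maximal runs of consecutive homozygous windows.

    ``no_call`` windows break runs unless ``bridge_no_call`` is set, in
    which case they are skipped over (but never start or end a region).
    """
    regions: list[HomozygousRegion] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in window_stats:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, stats in by_chrom.items():
        stats = sorted(stats, key=lambda w: w.window[0])
        run_start = None
        run_end = None
        for w in stats:
            if w.status == HOMOZYGOUS:
                if run_start is None:
                    run_start = w.window[0]
                run_end = w.window[1]
            elif w.status == NO_CALL and bridge_no_call and run_start is not None:
                continue
            else:
                if run_start is not None:
                    regions.append(HomozygousRegion(chrom=chrom, span=(run_start, run_end), sample=sample))
                run_start = run_end = None
        if run_start is not None:
            regions.append(HomozygousRegion(chrom=chrom, span=(run_start, run_end), sample=sample))
    return sorted(regions, key=lambda r: (r.chrom, r.span[0]))


def _subtract(span: tuple[int, int], others: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval difference span \\ union(others)."""
    pieces = [span]
    for os, oe in others:
        nxt = []
        for s, e in pieces:
            if oe <= s or os >= e:
                nxt.append((s, e))
                continue
            if s < os:
                nxt.append((s, os))
            if oe < e:
                nxt.append((oe, e))
        pieces = nxt
    return pieces


def differential_regions(
    regions_a: Sequence[HomozygousRegion],
    regions_b: Sequence[HomozygousRegion],
    min_span: int = 100_000,
) -> list[tuple[str, tuple[int, int], str]]:
    """Spans homozygous in exactly one sample.

    Sub-window slivers (shorter than ``min_span``) are discarded.
    """
    out: list[tuple[str, tuple[int, int], str]] = []
    for regions, others in ((regions_a, regions_b), (regions_b, regions_a)):
        for r in regions:
            other_spans = [o.span for o in others if o.chrom == r.chrom]
            for s, e in _subtract(r.span, other_spans):
                if e - s >= min_span:
                    out.append((r.chrom, (s, e), r.sample))
    return sorted(out, key=lambda t: (t[0], t[1][0], t[2]))


def window_table(stats: Sequence[WindowStat]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.window[0],
                "end": w.window[1],
                "n_variants": w.n_variants,
                "n_het": w.n_het,
                "het_fraction": round(w.het_fraction, 6) if w.n_variants else "",
                "status": w.status,
            }
            for w in sorted(stats, key=lambda w: (w.chrom, w.window[0]))
        ]
    )
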