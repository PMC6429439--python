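# Methods

## Problem setting

Two selfing lines of a diploid plant are resequenced and called
against a shared reference genome. Selfing fixes chromosome segments
to homozygosity in a line-specific pattern, so two lines that differ
in a trait (here, the strength of the self-incompatibility response)
can be contrasted at three levels: where each genome is homozygous,
where the two variant sets disagree with each other, and which genes
carry protein-changing variants. `vircon` implements that downstream
contrast; read mapping and variant calling are upstream of it and out
of scope.

## Coordinates and normalization

All internal coordinates are 0-based half-open; GFF3 and VCF 1-based
conventions are converted only in `genomic_io`. Indels are reduced to
a minimal representation: the leading base is dropped as the VCF
anchor — even when ref and alt disagree at that base, because allele
tables transcribed from alignments are not always anchored — then any
remaining shared prefix/suffix is stripped and the position advanced.
A `CAC → A` record is thus a 2-bp deletion of `AC` one base
downstream, which is how deletion lengths are reported everywhere.
Multi-allelic records are kept intact (not split) so that joint
two-sample genotypes remain interpretable; a record-level consequence
is the most severe across alt alleles (stopgain / stop_lost /
start_lost / frameshift > nonsynonymous / codon indel / SV-over-CDS >
synonymous).

Indels are by definition 1–30 bp net change; anything longer, and any
symbolic allele, is handled as a structural variant.

## Consequence engine

Gene models are stranded multi-exon CDS sets; the first mRNA isoform
of a gene is used. The spliced CDS is the concatenation of segments in
transcription order (reverse-complemented on the minus strand).
SNP consequences are computed at the codon level: the affected codon
is mutated and translated; a destroyed ATG at codon 1 is `start_lost`,
stop→non-stop is `stop_lost`, non-stop→stop is `stopgain`, otherwise
synonymous or nonsynonymous. Indels are classified by net length
(`net % 3 != 0` → frameshift, else codon_deletion / codon_insertion);
for frameshifts the mutant CDS is rebuilt and re-translated so the
truncation (reference protein length minus mutant protein length) is
reported — the biological quantity of interest when a line's protein
ends prematurely. An indel crossing an exon/intron boundary is
reported as a frameshift with a boundary flag; no splice-site classes
are defined. SVs intersecting any CDS segment (for translocations:
either breakpoint falling inside a CDS) are `sv_cds_overlap`. Genes
with a malformed frame (length not a multiple of 3, missing start) are
still classified but carry a model-quality warning.

The engine is validated against an independent brute-force oracle that
applies the variant to the chromosome sequence, shifts downstream
segment coordinates, re-splices the full mutant CDS, translates both
proteins and classifies by diffing them. The test suite requires a
diagonal confusion matrix over planted panels covering every class on
both strands and multi-exon genes.

## Two-sample contrast

Genotypes are unphased (`0/1 ≡ 1/0`). A locus is a between-sample
variant when the two lines' allele multisets differ and at least one
line carries a non-reference allele the other lacks; loci are counted,
not alleles. A locus missing in either sample is excluded from the
between-sample set and reported in an `unresolvable` tally. Per-sample
"calls" are the loci where that sample carries at least one alternate
allele; homozygote fractions are computed over calls (hom-alt vs het),
matching how per-sample call sets are reported upstream.

## Homozygosity scan

Windows tile each chromosome (step = window by default; an overlapping
step is available but Mb-scale region reporting does not need
sub-window resolution, and tiling makes the per-chromosome count
conservation exact). Defaults: window 100 kb, heterozygous-call
fraction threshold 0.10, minimum 10 calls per window — the floor
prevents variant-poor windows from being vacuously "homozygous".
Heterozygosity is the fraction of heterozygous calls among a sample's
calls in the window, not per-bp heterozygosity; that is the reading
under which a percentage threshold applies to variant calls. Region
calling uses SNP calls by default (indels can be included via the
`classes` argument). Consecutive homozygous windows merge into maximal
regions; `no_call` windows break runs unless bridging is enabled.
Differential regions are the interval difference of the two lines'
region sets, discarding sub-window slivers.

## Variation statistics and filters

Ts/Tv counts one observation per alt allele (transitions A↔G, C↔T);
an all-transition set yields an undefined (NaN) sentinel rather than a
division error. The indel spectrum is a signed histogram over ±1..30.
Region densities use a flattened partition: overlapping gene spans are
unioned before span accounting so every base is counted once;
intergenic + genic = genome and exon + intron = genic hold exactly.
"Exon" here means CDS exon (the gene models carry CDS features); a
variant overlapping several genes is counted once in its most
gene-proximal class. The SV validation filter retains records with
depth within [2, 100] and quality strictly above 20; rejected records
are logged with reasons (`depth`, `quality`, `no_depth`).

## Pfam enrichment

A coding SNP maps to protein residue `cds_pos // 3 + 1`; a family is
hit when the residue lies inside any of its intervals (overlapping
intervals of the same family count once). Each family's nonsyn/syn
split is tested against the genome-wide CDS background in a 2×2
chi-square (family vs rest-of-genome × nonsyn vs syn, 1 df, no
continuity correction); the contingency layout is a documented choice
since only the test and its p-threshold are prescribed. A family is
flagged when nonsyn + syn > 30 combined and nonsyn/syn > 0.6 — the
combined reading is the natural one for "more than 30 nonsyn and syn
SNPs"; a strict mode requiring each count > 30 is available. No
multiple-testing correction is applied by default (a single p < 0.001
threshold is the intended use); a Bonferroni option exists.

## Candidate filter

A gene is a candidate when it carries ≥ 1 qualifying consequence
(nonsynonymous, stopgain, stop_lost, start_lost, frameshift,
codon_deletion, codon_insertion, sv_cds_overlap) in ≥ 1 line. With
`require_difference` the per-line sets of qualifying (variant,
consequence) pairs must differ — the operationalization of "genes
differing between the samples", with the reference implicitly sample
zero. Prior-knowledge matching is by exact gene id or case-insensitive
keyword; the filter is mechanical and deterministic — curation of a
prior gene list is the user's input, not the package's output.

## Synthetic data

The generator emulates the statistical structure of the study
conditions, not the breeding process: homozygous blocks are planted
directly rather than simulated through recombination and selfing
generations, since the analysis consumes only the block structure.
Defaults (the conditions the package is validated at):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 7 × 2 Mb | the species' chromosome count, desk-scaled lengths |
| SNP rate | 3.5 × 10⁻³ /bp | ~3,500 SNPs/Mb, a ~4× desk-scale reduction of the ~12,900/Mb observed in the motivating data |
| indel rate | 4 × 10⁻⁴ /bp | keeps the empirical SNP:indel ratio (~6:1) |
| Ts/Tv target | 1.57 | transition probability 1.57/2.57 per SNP |
| hom fraction | 0.84 | genome-wide target; the out-of-block homozygous probability is solved from the planted block mass so the overall fraction hits the target |
| indel lengths | geometric(0.55), capped at 30 | mode 1 bp, >95% within 1–4 bp |
| carrier pattern | (0.70, 0.15, 0.15) | both / only line A / only line B, giving a between-sample variant set |
| blocks | 30, window-aligned, 2–4 windows | sample-alternating, ≥ 2 buffer windows, disjoint across lines so differential assignment has an exact truth |
| region SNP weights | intergenic 1.0 / exon 0.6 / intron 0.35 | region-dependent densities with the ordering intergenic > exon > genic > intron |

Gene models are built to be valid by construction (ATG + non-stop
codons + single stop, 1–4 exons, both strands); every CDS variant the
generator plants — engineered consequence-class variants, candidate
and decoy plants, and random background SNPs that land in CDS — is
classified at generation time by rebuilding and translating the mutant
CDS, and the per-gene candidate truth is recomputed from what was
actually planted. Decoy genes' CDS is excluded from random background
so they stay synonymous-only by construction. All draws come from one
`numpy` Generator keyed by the seed; identical seeds give
byte-identical output files.

What the generator does **not** emulate: caller error (genotyping
error, missingness patterns), linkage disequilibrium beyond the
planted blocks, mapping artifacts near repeats, multi-allelic sites,
and realistic gene length / intron-size distributions. Passing tests
therefore demonstrate the correctness of the downstream contrast
machinery under clean calls, not robustness to upstream calling error.

## Problem sizes and numerics

The validation suite runs a full bundle (7 × 2 Mb, ~55,000 variants)
and an 8,000-variant consequence panel (1,000 per class) — sizes
chosen so the whole suite completes in well under a minute while
keeping binomial standard errors small; statistic-recovery checks are
evaluated on 10,000-call subsamples with 3-SD tolerances. Ratios with
empty denominators return NaN sentinels (Ts/Tv with no transversions,
chi-square with a zero margin) and are never silently coerced.
Deterministic tie-breaks: regions and tables sort by (chrom, start);
enrichment results by descending ratio, then chi-square, then family
name.

## Known limitations

- One isoform per gene; UTR exons are not modelled (region class
  `genic_exon_utr` is reserved but unused with CDS-only models).
- The consequence set is closed; splice-site and regulatory classes
  are intentionally absent.
- `count_table_snp_differences` reports normalized indel lengths; for
  the packaged FIP2-like table the second frameshift row normalizes
  to a 31-bp deletion for line Ls-S2-53, which is reported as-is.
- No plotting: outputs are BED/TSV/JSON tables intended for downstream
  tools.
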