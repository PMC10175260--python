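# Methods

This note documents the models, conventions and design choices behind
`scoredel`, and what the synthetic-data generators do and do not emulate.

## Coordinates, sequences, conventions

All coordinates are 0-based half-open `[start, end)`, identical to BED;
BED input is taken as-is and any 1-based display is formatting only.
Sequences are uppercased on load and restricted to `{A,C,G,T,N}`; other
IUPAC codes are rejected by default (or mapped to N on request). `N` is
handled conservatively throughout: it never satisfies a PAM pattern letter
(not even `N`), protospacers containing `N` are not designable, and in
mismatch counting `N` on either side counts as a mismatch. Soft-masked
(lowercase) genome bases are uppercased and treated as ordinary sequence;
no masking rule is applied.

## Guide model

Guides are SpCas9 sgRNAs: a 20-nt protospacer immediately 5′ of an NGG PAM
(IUPAC patterns accepted; spacer orientation throughout). Both strands are
scanned; a site is reported only when the full 23-nt protospacer+PAM
footprint lies inside the query interval, so a site is unambiguously
"within" an LCR. The blunt double-strand break is placed 3 bp 5′ of the
PAM, between protospacer positions 17 and 18 — the standard SpCas9
convention, required for deletion-size arithmetic. In genome coordinates
the cut boundary is `protospacer_start + 17` (plus strand) or
`protospacer_start + 3` (minus strand). No on-target efficiency scoring is
performed; candidate ranking is outside the model.

## Shared-guide search and product prediction

A *shared* guide has at least one exact, PAM-compatible occurrence in each
of the two designated LCRs — full complementarity at both target repeats is
what makes one sgRNA cut twice, so near-matches are never accepted as
on-target; they are the off-target module's concern. All occurrences are
listed; guides with multiple occurrences in one repeat are flagged and all
cut pairs enumerated, and guides occurring on opposite strands in the two
repeats are flagged rather than dropped (the junction model assumes
same-orientation repeats, the 22q11.2 situation).

For a cut pair (cut_a < cut_b), the deletion product has size
`cut_b − cut_a` and junction `genome[cut_a−k, cut_a) + genome[cut_b,
cut_b+k)`; the inversion product reverse-complements the intervening
segment in place and both of its junctions are reported. The flank `k`
defaults to 30 bases — wide enough to design junction-spanning primers —
and is configurable. Duplication products are not predicted: inter-chromatid
events are not derivable from a single haplotype sequence (they are noted as
possible outcomes in reports). Repair indels are not modelled; junctions are
the ideal blunt religation.

## Specificity filter

The filter is a plain Hamming rule: a guide is rejected when any
PAM-adjacent site outside the designated on-target intervals lies at fewer
than `min_mismatches` (default 4) mismatches — i.e. sites at ≥ 4
mismatches are tolerated. Mismatches are counted uniformly over all 20
positions (no seed-region weighting) and bulges are not modelled. Off-target
sites require an NGG PAM by default; a policy flag (`--allow-nag`) also
admits NAG, off by default as the stricter choice. The *exempt* set — sites
that never count against a guide — defaults to the two LCRs plus the
intervening CNV segment: the guide's own on-target copies are the point of
the design. The scan depth defaults to `min_mismatches − 1` (sites at the
acceptance boundary need not be materialised).

Two scan implementations ship: a per-position pure-Python brute force, kept
as a first-class always-available mode, and a numpy-vectorised scan used by
default. The tests hold them equal to each other and to an independent
per-offset oracle across thresholds 0–4.

## Cross-assembly verification

Repeat annotation is exactly where reference updates bite, so designs are
re-verified independently on every provided assembly: the shared-in-both-
LCRs property *and* the specificity filter are both re-run per assembly
(the stricter reading), with exempt intervals rebuilt from each assembly's
own annotations. Assemblies are linked by LCR annotation *names*, never
coordinates — no liftover. The overall verdict is the strict conjunction
over assemblies.

## qPCR clone screen

Relative copy number uses the comparative-Ct chain: replicate Cts are
aggregated by arithmetic mean (no outlier rejection), ΔCt is taken against
the reference gene (RPPH1 by default) within each sample, ΔΔCt against the
calibrator sample, RCN = 2^−ΔΔCt. Perfect doubling per cycle is assumed;
no efficiency correction or standard curves. Clone calls partition screened
genes into in-region and flanking sets: *deletion* requires every in-region
RCN ≤ 0.7 with every flanking RCN in [0.8, 1.2]; *no deletion* requires
every screened gene in the normal window; anything else is *ambiguous*.
The cut points 0.7 / 0.8–1.2 are explicit midpoints between the
heterozygous expectation (0.5) and the diploid expectation (1.0); they are
configurable, and any visual/lab acceptance boundary they stand in for
should be re-derived for other assay designs.

In-silico PCR is exact-match only (no mismatches, no 3′-anchoring or
thermodynamics): a product is reported wherever the forward primer matches
one strand and the reverse complement of the reverse primer occurs
downstream on the same strand within `max_product` (default 5000). Product
length is the inclusive outer-primer span — forward 5′ end through the
reverse primer's 5′-most base — the convention under which advertised qPCR
product sizes (e.g. the bundled seven-pair 22q11.2 panel: TBX1 101 bp …
RPPH1 120 bp) are reproduced.

## Dosage summaries

Per-feature log2 fold change is `log2((mean_del + c) / (mean_ctl + c))`
with pseudocount `c = 0.5` for log stability (configurable); group means
are taken over samples first, then the log — matching how dosage figures
are usually drawn. Features are partitioned purely by coordinate overlap
with the declared region; features on other contigs or without coordinates
are excluded and counted. Deliberately *not* implemented: normalization
from raw counts, dispersion shrinkage, significance testing, FDR — the
input is a pre-normalized matrix and the output is the dosage picture, not
differential-expression calls.

## Synthetic-data generators

All generators draw every random quantity from one `numpy` Generator seeded
per call; no global state. Same (params, seed) ⇒ byte-identical output.

**Locus generator.** Layout `[flank 10 kb][LCR 5 kb][spacer 50 kb]
[LCR 5 kb][flank 10 kb]` by default — a 22q11.2-like geometry with the
~1.5-Mb A–B segment scaled to 50 kb so whole-locus scans run in
milliseconds. LCR backgrounds are drawn from a dinucleotide-constrained
chain that never emits GG or CC, and a deterministic repair pass then
destroys (mirrored across both copies) any PAM that arises at
insert/background boundaries. Consequently the planted protospacer+TGG sites
are the *only* guide sites inside the repeats, which is what makes "the
planted guide is recovered exactly" a well-posed truth statement — in
identical repeats every background NGG site would otherwise be a shared
guide. When a user-supplied protospacer itself contains GG/CC, context
sites whose PAM is locked inside the protected footprint cannot be
repaired; they are counted in the truth table (`n_context_guides`) and the
guarantee weakens from exactness to membership. Divergence (identity < 1)
mutates LCR-B at uniformly chosen positions outside planted footprints, so
truth tables stay valid. Decoy off-target sites are planted in the left
flank at exact Hamming distances from the first planted guide, outside the
default exempt span. What this generator does **not** emulate: real LCR22
internal duplication structure, interspersed repeats, GC heterogeneity, or
a genome-scale background — passing tests show the algorithms are correct
on their contracts, not that any particular 20-mer is specific in a real
human genome (that is what running the tool on real FASTA/BED input is
for).

**Ct generator.** Ct = base_ct(gene) − log2(cn/2) + N(0, sd) per replicate;
one lost copy costs exactly one cycle under ideal doubling. Noise is
i.i.d. per replicate — no plate, pipetting or efficiency structure. Default
base Cts (TBX1 26, CRKL 25, RPPH1 20 in the examples) are ordinary genomic
qPCR magnitudes; their values cancel in ΔΔCt. Note the noise propagation:
with per-replicate sd σ and triplicates, ΔΔCt has sd 2σ/√3 (≈ 0.23 at
σ = 0.2), so at σ = 0.2 a diploid gene falls outside the [0.8, 1.2] window
roughly a quarter of the time and a 50-clone screen will *not* classify
every clone correctly; reliable per-clone calls at that noise level would
need wider windows, more replicates, or repeat measurement. The acceptance
script reports the measured accuracy at σ ∈ {0.1, 0.2}.

**Expression generator.** Control feature means are log-normal (median 200,
σ_log = 1); deletion-group in-region means are scaled by the dosage factor
(0.5 = heterozygous); counts are negative-binomial with
var = m + dispersion·m² (Poisson at dispersion 0); defaults 200 in-region
and 800 flanking features, 3 samples per group, dispersion 0.1. It makes no
attempt at library-size variation, count normalization artefacts, or
correlated genes.

## Numerical and degenerate-input choices

Ties and orderings are deterministic everywhere: guide sites sort by
(start, strand), shared guides lexicographically by protospacer, off-target
sites by (contig, start, strand). Empty shared-guide sets are a warning
plus empty outputs, not an error. Junctions are clipped at contig ends.
Equal-boundary cut pairs are rejected (no zero-size products). The RCN of
the reference gene is 1 by construction and asserted in tests.

## Known limitations

- Exact-text matching everywhere (shared guides, primers): a single SNP in
  a real repeat copy defeats a "shared" call; divergence handling beyond
  exactness is deliberately out of scope.
- No bulge-tolerant or scored off-target search (no CFD/MIT), no
  chromatin context.
- Cross-assembly checks need consistent annotation names; there is no
  coordinate liftover or alt-contig awareness.
- The clone-call thresholds are screening heuristics, not clinical
  genotyping; confirmation (e.g. SNP array) is assumed downstream.
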