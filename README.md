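# scoredel

Single-guide CRISPR deletion design for CNVs flanked by low-copy repeats
(LCRs), with the downstream clone-screening computations.

## The problem

Recurrent microdeletions such as 22q11.2 are flanked by long, highly
homologous segmental-duplication blocks (LCR22 A–D). The SCORE strategy
(single-guide CRISPR/Cas targeting of repetitive elements) exploits that
homology: instead of delivering two sgRNAs, a **single** sgRNA whose 20-nt
protospacer occurs — with an NGG PAM — in *both* CNV-flanking LCRs produces
two simultaneous Cas9 double-strand breaks, and non-homologous end joining
of the two blunt cut boundaries deletes (or inverts) the intervening
segment. Engineered clones are then genotyped by genomic qPCR: the relative
copy number of marker genes inside the deletion (e.g. *TBX1*, *HIRA*,
*COMT*) is compared with markers flanking it (e.g. *MAPK1*, *BID*, or *CRKL*
for an A–B design) by the comparative-Ct method,

RCN = 2^(−ΔΔCt),  ΔΔCt = (Ct_gene − Ct_ref)_clone − (Ct_gene − Ct_ref)_calibrator,

with *RPPH1* as the endogenous reference; a heterozygous deletion is
expected at RCN ≈ 0.5 inside the region and ≈ 1.0 outside, and at
expression log2 fold change ≈ −1 for in-region transcripts/proteins.

`scoredel` is for anyone engineering such models: it enumerates SpCas9 guide
sites, finds protospacers shared by two designated LCRs, predicts the
deletion/inversion products and their junction sequences, applies the
specificity rule *reject any guide with a non-exempt site under four
mismatches* (uniform Hamming count over the 20-mer, NGG PAM required at the
site; NAG optional), cross-verifies designs on multiple assemblies
(e.g. GRCh38 and GRCh37, linked by LCR annotation names), and computes the
qPCR screen (ΔΔCt, clone calls, exact-match in-silico PCR) and region-dosage
summaries. Seeded simulators generate every input — synthetic LCR loci with
planted guides and graded decoys, Ct tables with known copy number,
expression matrices with a dosage effect — each with a truth table.

## Worked example

Simulate a 22q11.2-like locus at desk scale (5-kb repeats, 50-kb spacer, one
planted guide) and run the full design pipeline:

```
$ scoredel simulate --seed 11 --out demo/locus
locus written: demo/locus/genome.fa (80000 bp, expected deletion 55000 bp)

$ scoredel design --assembly syn=demo/locus/genome.fa:demo/locus/annotations.bed \
    --lcr-a LCR_A --lcr-b LCR_B --out demo/design
accepted designs: 1 (reports in demo/design)
```

`demo/design/design_report.tsv` holds one row per shared guide × cut pair:

```
protospacer           n_occurrences_a  n_occurrences_b  cut_a  cut_b  deletion_size
ACGAATAATGCGCATGTGTA  1                1                10120  65120  55000
```

The recovered protospacer is exactly the planted one (see
`demo/locus/truth.json`), each repeat holds one occurrence, and the
predicted deletion — the distance between the two blunt cut boundaries,
each 3 bp 5′ of its PAM — is 55,000 bp, the truth-table value. The report
also carries the 60-bp deletion junction centred on the rejoined boundary;
because the two repeats are identical and the occurrences sit at the same
offset, the junction contains an intact protospacer+PAM (the site is
reconstituted after deletion). `run_report.json` records the stage counts
(shared 1 → post-filter 1 → accepted 1) and all parameters.

The other subcommands (`offtarget`, `verify`, `screen-qpcr`, `pcr`,
`dosage`, `simulate`) expose the individual computations; the same
functionality is available as a library (`import scoredel`).

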