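"""qPCR clone-screening computations.

Engineered clones are genotyped by genomic qPCR: the relative copy number
(RCN) of marker genes inside the intended deletion is compared against
markers flanking it, using the comparative-Ct (2^-ΔΔCt) method against an
endogenous reference gene (RPPH1 by default) and an unedited calibrator
sample. A heterozygous deletion halves the template, so in-region markers
are expected near RCN 0.5 while flanking markers stay near 1.0.

Replicate Ct values are aggregated by arithmetic mean before any Δ is taken;
no outlier rejection and no amplification-efficiency correction is applied
(perfect doubling per cycle is assumed).

`insilico_pcr` is an exact-match amplicon finder used to validate screening
primer pairs against a genome: no mismatches, no 3'-anchoring model, product
length counted as the inclusive span from the forward primer's 5' end
through the reverse primer's 5'-most base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome_io import GenomeSequence, reverse_complement

DEFAULT_REFERENCE_GENE = "RPPH1"


class CtTableError(ValueError):
    """Raised for structurally invalid or incomplete Ct tables."""


class ScreenConfigError(ValueError):
    """Raised for invalid gene partitions or thresholds."""


@dataclass(frozen=True)
class PrimerPair:
    """One genomic qPCR primer pair, both primers written 5'->3'."""

    gene: str
    forward: str
    reverse: str
    expected_size: int | None = None

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 15:
                raise ValueError(f"{self.gene} {label} primer shorter than 15 nt")
            bad = set(primer.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"{self.gene} {label} primer has invalid bases {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand_of_forward: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CtTable:
    """Replicate Ct measurements per (sample, gene).

    ``ct`` maps (sample, gene) -> list of replicate Ct values (cycles).
    """

    ct: Mapping[tuple[str, str], Sequence[float]]
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator_sample: str = ""

    def __post_init__(self) -> None:
        self.ct = {k: list(v) for k, v in self.ct.items()}
        if not self.ct:
            raise CtTableError("empty Ct table")
        for (sample, gene), values in self.ct.items():
            if not values:
                raise CtTableError(f"no replicates for ({sample}, {gene})")
            if any(v <= 0 for v in values):
                raise CtTableError(f"non-positive Ct for ({sample}, {gene})")
        if self.reference_gene not in self.genes:
            raise CtTableError(f"reference gene {self.reference_gene!r} not in table")
        if self.calibrator_sample and self.calibrator_sample not in self.samples:
            raise CtTableError(f"calibrator sample {self.calibrator_sample!r} not in table")
        if not self.calibrator_sample:
            raise CtTableError("calibrator_sample must be named")

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sample, _ in self.ct:
            seen.setdefault(sample, None)
        return list(seen)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, gene in self.ct:
            seen.setdefault(gene, None)
        return list(seen)

    @classmethod
    def from_tsv(cls, path, reference_gene: str = DEFAULT_REFERENCE_GENE,
                 calibrator_sample: str = "") -> "CtTable":
        """Read a long-format TSV with columns sample, gene, replicate, ct."""
        df = pd.read_csv(path, sep="\t")
        required = {"sample", "gene", "ct"}
        if not required.issubset(df.columns):
            raise CtTableError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        ct: dict[tuple[str, str], list[float]] = {}
        for row in df.itertuples(index=False):
            ct.setdefault((str(row.sample), str(row.gene)), []).append(float(row.ct))
        return cls(ct=ct, reference_gene=reference_gene, calibrator_sample=calibrator_sample)

    def to_tsv(self, path) -> None:
        rows = []
        for (sample, gene), values in self.ct.items():
            for i, v in enumerate(values, start=1):
                rows.append({"sample": sample, "gene": gene, "replicate": i, "ct": v})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CallThresholds:
    """RCN windows used to call clone genotype.

    The cut points sit between the heterozygous expectation (0.5) and the
    diploid expectation (1.0): deletion requires every in-region RCN at or
    below ``del_max`` while flanking markers stay inside the normal window.
    """

    del_max: float = 0.7
    normal_min: float = 0.8
    normal_max: float = 1.2


@dataclass(frozen=True)
class CopyNumberCall:
    sample: str
    per_gene_rcn: Mapping[str, float]
    call: str


def relative_copy_number(table: CtTable) -> pd.DataFrame:
    """2^-ΔΔCt relative copy number per (sample, gene).

    Replicates are averaged per cell, ΔCt is taken against the reference gene
    within each sample, ΔΔCt against the calibrator sample, and RCN =
    2^-ΔΔCt. The reference gene's RCN is identically 1. Every sample must
    provide every gene; missing cells raise with the full list.
    """
    samples, genes = table.samples, table.genes
    missing = [
        (s, g) for s in samples for g in genes if (s, g) not in table.ct
    ]
    if missing:
        raise CtTableError(f"missing (sample, gene) cells: {missing}")
    mean_ct = pd.DataFrame(
        {g: [sum(table.ct[(s, g)]) / len(table.ct[(s, g)]) for s in samples] for g in genes},
        index=pd.Index(samples, name="sample"),
    )
    delta_ct = mean_ct.sub(mean_ct[table.reference_gene], axis=0)
    ddct = delta_ct - delta_ct.loc[table.calibrator_sample]
    return 2.0 ** (-ddct)


def classify_clones(
    rcn: pd.DataFrame,
    in_region_genes: Sequence[str],
    flanking_genes: Sequence[str],
    thresholds: CallThresholds = CallThresholds(),
) -> list[CopyNumberCall]:
    """Call deletion / no_deletion / ambiguous per sample from RCN values.

    deletion: every in-region RCN <= del_max AND every flanking RCN inside
    [normal_min, normal_max]. no_deletion: every screened gene inside the
    normal window. Anything else is ambiguous.
    """
    if not in_region_genes or not flanking_genes:
        raise ScreenConfigError("in-region and flanking gene lists must be non-empty")
    overlap = set(in_region_genes) & set(flanking_genes)
    if overlap:
        raise ScreenConfigError(f"gene lists overlap: {sorted(overlap)}")
    for g in (*in_region_genes, *flanking_genes):
        if g not in rcn.columns:
            raise ScreenConfigError(f"gene {g!r} absent from RCN table")
    t = thresholds
    calls = []
    for sample, row in rcn.iterrows():
        in_vals = [row[g] for g in in_region_genes]
        fl_vals = [row[g] for g in flanking_genes]
        fl_normal = all(t.normal_min <= v <= t.normal_max for v in fl_vals)
        in_normal = all(t.normal_min <= v <= t.normal_max for v in in_vals)
        if all(v <= t.del_max for v in in_vals) and fl_normal:
            call = "deletion"
        elif in_normal and fl_normal:
            call = "no_deletion"
        else:
            call = "ambiguous"
        screened = {g: float(row[g]) for g in (*in_region_genes, *flanking_genes)}
        calls.append(CopyNumberCall(sample=str(sample), per_gene_rcn=screened, call=call))
    return calls


def insilico_pcr(
    genome: GenomeSequence,
    pair: PrimerPair,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Exact-match in-silico PCR of one primer pair against one contig.

    A product is reported wherever the forward primer matches one strand and
    the reverse complement of the reverse primer occurs downstream on the
    same strand, within ``max_product``. Both orientations are searched.
    Product length is the inclusive outer-primer span (this convention
    reproduces the sizes qPCR assays advertise).
    """
    seq = genome.sequence
    products: list[Amplicon] = []
    # plus orientation: F ... revcomp(R) on the plus strand; minus orientation
    # (forward primer annealing to the minus strand) reads R ... revcomp(F)
    # on the plus strand.
    orientations = (
        ("+", pair.forward, reverse_complement(pair.reverse)),
        ("-", pair.reverse, reverse_complement(pair.forward)),
    )
    for strand, left_site, right_site in orientations:
        for i in _find_all(seq, left_site):
            j = seq.find(right_site, i + len(left_site))
            while j != -1:
                end = j + len(right_site)
                if end - i > max_product:
                    break
                products.append(
                    Amplicon(contig_id=genome.contig_id, start=i, end=end,
                             strand_of_forward=strand)
                )
                j = seq.find(right_site, j + 1)
    products.sort(key=lambda a: (a.start, a.end, a.strand_of_forward))
    return products


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def read_primer_panel(path=None) -> list[PrimerPair]:
    """Load a primer panel TSV (gene, forward, reverse, expected_size).

    With no path, loads the bundled 22q11.2 screening panel (the seven
    genomic qPCR pairs for TBX1, HIRA, COMT, CRKL, BID, MAPK1 and RPPH1).
    """
    if path is None:
        source = resources.files("scoredel.data").joinpath("primers_22q11.tsv")
        df = pd.read_csv(source.open(), sep="\t")
    else:
        df = pd.read_csv(Path(path), sep="\t")
    pairs = []
    for row in df.itertuples(index=False):
        size = None
        if "expected_size" in df.columns and pd.notna(row.expected_size):
            size = int(row.expected_size)
        pairs.append(
            PrimerPair(gene=str(row.gene), forward=str(row.forward),
                       reverse=str(row.reverse), expected_size=size)
        )
    return pairs


def calls_to_tsv(calls: Sequence[CopyNumberCall], path) -> None:
    genes = sorted({g for c in calls for g in c.per_gene_rcn})
    with open(path, "w") as fh:
        fh.write("sample\tcall\t" + "\t".join(f"rcn_{g}" for g in genes) + "\n")
        for c in calls:
            vals = "\t".join(f"{c.per_gene_rcn.get(g, float('nan')):.6g}" for g in genes)
            fh.write(f"{c.sample}\t{c.call}\t{vals}\n")


def calls_to_json(calls: Sequence[CopyNumberCall], path) -> None:
    payload = [
        {"sample": c.sample, "call": c.call, "per_gene_rcn": dict(c.per_gene_rcn)}
        for c in calls
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
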