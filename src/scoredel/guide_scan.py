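"""SpCas9 guide-site enumeration: 20-mer protospacer + NGG PAM, both strands.

A guide site is reported in *spacer orientation*: the protospacer reads 5'→3'
as the sgRNA spacer would, with the PAM immediately 3' of it. On the minus
strand the stored ``protospacer_start`` is still the leftmost genomic base of
the protospacer footprint, so coordinates stay plus-strand/BED-like.

The blunt Cas9 cut falls between protospacer positions 17 and 18 (3 bp 5' of
the PAM), which in genome coordinates is ``protospacer_start + 17`` on the
plus strand and ``protospacer_start + 3`` on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    IntervalError,
    reverse_complement,
)

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN

# IUPAC code -> concrete bases it matches. Deliberately excludes N as a
# *genome* base: an N in the genome never matches any pattern letter.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class PamRule:
    """A 3-letter IUPAC PAM pattern, default NGG (SpCas9)."""

    pattern: str = "NGG"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) != PAM_LEN or any(c not in IUPAC for c in pat):
            raise ValueError(f"PAM pattern must be 3 IUPAC letters, got {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    def matches(self, trimer: str) -> bool:
        """True when a genomic 3-mer (spacer orientation) satisfies the pattern."""
        if len(trimer) != PAM_LEN:
            return False
        return all(base in IUPAC[pat] for base, pat in zip(trimer, self.pattern))


@dataclass(frozen=True)
class GuideSite:
    """One protospacer occurrence with PAM, strand and cut position.

    ``protospacer`` and ``pam`` are spacer-oriented 5'→3' text; on the minus
    strand they are the reverse complement of the plus-strand genome slice.
    """

    protospacer: str
    pam: str
    contig_id: str
    strand: str
    protospacer_start: int
    source_interval: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.protospacer)}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def cut_boundary(self) -> int:
        """0-based inter-base coordinate of the blunt cut, 3 bp 5' of the PAM."""
        if self.strand == "+":
            return self.protospacer_start + PROTOSPACER_LEN - 3
        return self.protospacer_start + 3

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic [start, end) spanned by protospacer + PAM."""
        if self.strand == "+":
            return (self.protospacer_start, self.protospacer_start + SITE_LEN)
        return (self.protospacer_start - PAM_LEN, self.protospacer_start + PROTOSPACER_LEN)


def cut_coordinate(site: GuideSite) -> int:
    """The blunt-cut boundary of a guide site (see :class:`GuideSite`)."""
    return site.cut_boundary


def enumerate_guides(
    genome: GenomeSequence,
    interval: GenomicInterval,
    pam: PamRule = PamRule(),
) -> list[GuideSite]:
    """Every guide site whose protospacer+PAM footprint lies fully inside ``interval``.

    Both strands are scanned. Protospacers containing N are skipped (not
    designable). Results are sorted by ``protospacer_start`` then strand and
    contain no duplicates.
    """
    if interval.contig_id != genome.contig_id:
        raise IntervalError(
            f"interval contig {interval.contig_id!r} != genome contig {genome.contig_id!r}"
        )
    if interval.start < 0 or interval.end > genome.length:
        raise IntervalError(
            f"interval [{interval.start},{interval.end}) outside contig "
            f"{genome.contig_id!r} (length {genome.length})"
        )
    seq = genome.sequence
    sites: list[GuideSite] = []
    label = interval.name
    # window [a, a+23) fully inside the interval
    for a in range(interval.start, interval.end - SITE_LEN + 1):
        window = seq[a : a + SITE_LEN]
        # plus strand: protospacer then PAM
        proto, trimer = window[:PROTOSPACER_LEN], window[PROTOSPACER_LEN:]
        if "N" not in proto and pam.matches(trimer):
            sites.append(
                GuideSite(proto, trimer, genome.contig_id, "+", a, source_interval=label)
            )
        # minus strand: PAM (revcomp) then protospacer (revcomp)
        proto_m = reverse_complement(window[PAM_LEN:])
        trimer_m = reverse_complement(window[:PAM_LEN])
        if "N" not in proto_m and pam.matches(trimer_m):
            sites.append(
                GuideSite(
                    proto_m, trimer_m, genome.contig_id, "-", a + PAM_LEN,
                    source_interval=label,
                )
            )
    sites.sort(key=lambda s: (s.protospacer_start, s.strand))
    return sites


def guides_to_tsv(sites: list[GuideSite], path) -> None:
    """Write a guide table (TSV)."""
    with open(path, "w") as fh:
        fh.write("protospacer\tpam\tcontig\tstrand\tstart\tcut_boundary\tsource_interval\n")
        for s in sites:
            fh.write(
                f"{s.protospacer}\t{s.pam}\t{s.contig_id}\t{s.strand}\t"
                f"{s.protospacer_start}\t{s.cut_boundary}\t{s.source_interval}\n"
            )


def guides_to_bed(sites: list[GuideSite], path) -> None:
    """Write BED6 protospacer footprints (name = protospacer, score = 0)."""
    with open(path, "w") as fh:
        for s in sites:
            if s.strand == "+":
                start, end = s.protospacer_start, s.protospacer_start + PROTOSPACER_LEN
            else:
                start, end = s.protospacer_start, s.protospacer_start + PROTOSPACER_LEN
            fh.write(f"{s.contig_id}\t{start}\t{end}\t{s.protospacer}\t0\t{s.strand}\n")
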