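"""Genome and annotation I/O with the coordinate conventions used package-wide.

All coordinates are 0-based half-open ``[start, end)``, exactly as in BED.
Sequences are uppercased on load and restricted to the alphabet ``{A,C,G,T,N}``;
``N`` is treated conservatively downstream (it never matches any base in guide
or primer matching). Any 1-based display is formatting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class IntervalError(ValueError):
    """Raised for invalid genomic intervals or malformed BED records."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: an identifier and its DNA sequence.

    The sequence is normalized to uppercase over the alphabet {A,C,G,T,N}.
    """

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"contig {self.contig_id!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a contig."""

    contig_id: str
    start: int
    end: int
    name: str = ""
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"interval {self.name or self.contig_id}: start {self.start} < 0")
        if self.start >= self.end:
            raise IntervalError(
                f"interval {self.name or self.contig_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class AssemblyContext:
    """A named genome assembly: contig sequences plus LCR/region annotations.

    Annotation names are the stable key used to match regions between
    assemblies (e.g. the same "LCR22A" label on GRCh38 and GRCh37
    coordinates); there is no coordinate liftover.
    """

    assembly: str
    genomes: Mapping[str, GenomeSequence] = field(default_factory=dict)
    lcr_annotations: Sequence[GenomicInterval] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [iv.name for iv in self.lcr_annotations if iv.name]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IntervalError(
                f"assembly {self.assembly!r}: duplicate annotation names {dupes}"
            )
        for iv in self.lcr_annotations:
            if iv.contig_id not in self.genomes:
                raise IntervalError(
                    f"assembly {self.assembly!r}: annotation {iv.name!r} references "
                    f"unknown contig {iv.contig_id!r}"
                )
            if iv.end > self.genomes[iv.contig_id].length:
                raise IntervalError(
                    f"assembly {self.assembly!r}: annotation {iv.name!r} extends past "
                    f"the end of contig {iv.contig_id!r}"
                )

    @classmethod
    def from_files(cls, assembly: str, fasta_path, bed_path) -> "AssemblyContext":
        genomes = {g.contig_id: g for g in read_fasta(fasta_path)}
        intervals = read_intervals(bed_path, assembly=assembly)
        return cls(assembly=assembly, genomes=genomes, lcr_annotations=tuple(intervals))

    def get_interval(self, name: str) -> GenomicInterval:
        for iv in self.lcr_annotations:
            if iv.name == name:
                return iv
        raise KeyError(f"assembly {self.assembly!r} has no annotation named {name!r}")

    def sequence_of(self, interval: GenomicInterval) -> str:
        contig = self.genomes[interval.contig_id]
        if interval.end > contig.length:
            raise IntervalError(
                f"interval {interval.name or interval.contig_id} out of bounds on "
                f"{interval.contig_id} (length {contig.length})"
            )
        return contig.sequence[interval.start : interval.end]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(f"cannot reverse-complement characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path, ambiguity: str = "reject") -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence records.

    Parameters
    ----------
    path
        FASTA file path.
    ambiguity
        "reject" (default) errors on IUPAC ambiguity codes other than N;
        "map-to-n" silently converts them to N.
    """
    if ambiguity not in ("reject", "map-to-n"):
        raise ValueError(f"ambiguity must be 'reject' or 'map-to-n', got {ambiguity!r}")
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first.strip():
            raise FastaFormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FastaFormatError(f"{path}: line 1 does not start with '>'")
    records: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if ambiguity == "map-to-n":
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        records.append(GenomeSequence(contig_id=rec.id, sequence=seq))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_intervals(path, assembly: str = "") -> list[GenomicInterval]:
    """Read BED3/BED4 records as-is (0-based half-open), preserving input order."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}: record {lineno} has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalError(f"{path}: record {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 else ""
            try:
                intervals.append(
                    GenomicInterval(
                        contig_id=fields[0], start=start, end=end,
                        name=name, assembly=assembly,
                    )
                )
            except IntervalError as exc:
                raise IntervalError(f"{path}: record {lineno}: {exc}") from exc
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.contig_id, str(iv.start), str(iv.end)]
            if iv.name:
                fields.append(iv.name)
            handle.write("\t".join(fields) + "\n")
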