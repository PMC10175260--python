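"""The SCORE design core.

SCORE (single-guide CRISPR/Cas targeting of repetitive elements) exploits the
high sequence homology of the low-copy-repeat (LCR) blocks flanking recurrent
CNVs: one sgRNA whose protospacer occurs in *both* flanking LCRs produces two
simultaneous double-strand breaks, and non-homologous end joining of the two
cut boundaries deletes (or inverts) the intervening segment. This module
finds such shared guides and predicts the rearranged products.

"Shared" requires an exact protospacer + PAM-compatible occurrence in both
LCRs — the guide must cut both repeats with full complementarity; near-match
sites elsewhere are the off-target module's concern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .genome_io import (
    AssemblyContext,
    GenomeSequence,
    GenomicInterval,
    IntervalError,
    reverse_complement,
)
from .guide_scan import GuideSite, PamRule, enumerate_guides


@dataclass(frozen=True)
class ScoreGuide:
    """A protospacer with at least one guide site inside each of two LCRs.

    ``multi_site_flag`` marks guides with more than one occurrence in either
    repeat (all cut pairs must then be enumerated); ``opposite_strand_flag``
    marks guides whose occurrences sit on opposite strands in the two LCRs —
    the deletion-junction model below assumes same-orientation repeats (the
    22q11.2 situation), so these are surfaced rather than silently modeled.
    """

    protospacer: str
    occurrences_a: tuple[GuideSite, ...]
    occurrences_b: tuple[GuideSite, ...]

    def __post_init__(self) -> None:
        if not self.occurrences_a or not self.occurrences_b:
            raise ValueError("a ScoreGuide needs >= 1 occurrence in each LCR")
        for site in (*self.occurrences_a, *self.occurrences_b):
            if site.protospacer != self.protospacer:
                raise ValueError("occurrence protospacer differs from guide protospacer")

    @property
    def multi_site_flag(self) -> bool:
        return len(self.occurrences_a) > 1 or len(self.occurrences_b) > 1

    @property
    def opposite_strand_flag(self) -> bool:
        strands = {s.strand for s in self.occurrences_a} | {
            s.strand for s in self.occurrences_b
        }
        return len(strands) > 1


@dataclass(frozen=True)
class RearrangementProduct:
    """A predicted deletion or inversion from cutting at two boundaries.

    ``junction`` is 2k bases centered on the (left) rejoined boundary:
    for a deletion, ``genome[cut_a-k:cut_a] + genome[cut_b:cut_b+k]``; for an
    inversion, the left junction ``genome[cut_a-k:cut_a] +
    revcomp(genome[cut_b-k:cut_b])`` with the right junction stored in
    ``junction_right``. Duplication products (inter-chromatid) are not
    predictable from a single haplotype sequence and are not modeled.
    """

    kind: str
    cut_a: int
    cut_b: int
    junction: str
    junction_right: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "inversion"):
            raise ValueError(f"kind must be 'deletion' or 'inversion', got {self.kind!r}")
        if self.cut_a >= self.cut_b:
            raise ValueError("cut_a must be < cut_b")

    @property
    def size(self) -> int:
        return self.cut_b - self.cut_a


def find_shared_guides(
    assembly: AssemblyContext,
    lcr_a: GenomicInterval,
    lcr_b: GenomicInterval,
    pam: PamRule = PamRule(),
) -> list[ScoreGuide]:
    """Every protospacer with >= 1 PAM-adjacent occurrence in each LCR.

    ``lcr_a`` must lie entirely left of ``lcr_b`` on the same contig.
    Occurrences are exhaustively listed; output is ordered lexicographically
    by protospacer.
    """
    if lcr_a.contig_id != lcr_b.contig_id:
        raise IntervalError("LCR intervals must be on the same contig")
    if lcr_a.overlaps(lcr_b):
        raise IntervalError(
            f"LCR intervals overlap: [{lcr_a.start},{lcr_a.end}) and "
            f"[{lcr_b.start},{lcr_b.end})"
        )
    if lcr_a.start >= lcr_b.start:
        raise IntervalError("lcr_a must lie left of lcr_b")
    genome = assembly.genomes[lcr_a.contig_id]
    sites_a = enumerate_guides(genome, lcr_a, pam)
    sites_b = enumerate_guides(genome, lcr_b, pam)
    by_proto_a: dict[str, list[GuideSite]] = {}
    for s in sites_a:
        by_proto_a.setdefault(s.protospacer, []).append(s)
    by_proto_b: dict[str, list[GuideSite]] = {}
    for s in sites_b:
        by_proto_b.setdefault(s.protospacer, []).append(s)
    shared = sorted(set(by_proto_a) & set(by_proto_b))
    return [
        ScoreGuide(
            protospacer=p,
            occurrences_a=tuple(by_proto_a[p]),
            occurrences_b=tuple(by_proto_b[p]),
        )
        for p in shared
    ]


def predict_products(
    assembly: AssemblyContext,
    site_a: GuideSite,
    site_b: GuideSite,
    k: int = 30,
) -> list[RearrangementProduct]:
    """Deletion and inversion products for one cut pair.

    ``k`` is the junction flank length (default 30, a primer-design-friendly
    window); junctions are clipped at contig ends. When either LCR holds
    multiple occurrences the caller enumerates all cut pairs.
    """
    if site_a.contig_id != site_b.contig_id:
        raise IntervalError("cut sites must be on the same contig")
    cut_a, cut_b = site_a.cut_boundary, site_b.cut_boundary
    if cut_a >= cut_b:
        raise IntervalError(f"cut_a ({cut_a}) must be < cut_b ({cut_b})")
    genome = assembly.genomes[site_a.contig_id]
    if cut_b > genome.length:
        raise IntervalError("cut boundary out of contig bounds")
    seq = genome.sequence
    left = seq[max(0, cut_a - k) : cut_a]
    right = seq[cut_b : cut_b + k]
    deletion = RearrangementProduct(
        kind="deletion", cut_a=cut_a, cut_b=cut_b, junction=left + right
    )
    inv_left = left + reverse_complement(seq[max(0, cut_b - k) : cut_b])
    inv_right = reverse_complement(seq[cut_a : cut_a + k]) + right
    inversion = RearrangementProduct(
        kind="inversion", cut_a=cut_a, cut_b=cut_b,
        junction=inv_left, junction_right=inv_right,
    )
    return [deletion, inversion]


def apply_product(sequence: str, product: RearrangementProduct) -> str:
    """Materialize the full rearranged contig sequence for a product."""
    a, b = product.cut_a, product.cut_b
    if product.kind == "deletion":
        return sequence[:a] + sequence[b:]
    return sequence[:a] + reverse_complement(sequence[a:b]) + sequence[b:]


def enumerate_cut_pairs(guide: ScoreGuide) -> list[tuple[GuideSite, GuideSite]]:
    """All (site in LCR-A, site in LCR-B) pairs with ordered cut boundaries."""
    pairs = []
    for sa in guide.occurrences_a:
        for sb in guide.occurrences_b:
            if sa.cut_boundary < sb.cut_boundary:
                pairs.append((sa, sb))
    return pairs


def design_report_rows(
    assembly: AssemblyContext,
    guides: Sequence[ScoreGuide],
    k: int = 30,
) -> list[dict]:
    """One row per shared guide x cut pair, for the design-report TSV."""
    rows = []
    for g in guides:
        for sa, sb in enumerate_cut_pairs(g):
            deletion, _ = predict_products(assembly, sa, sb, k=k)
            rows.append(
                {
                    "protospacer": g.protospacer,
                    "n_occurrences_a": len(g.occurrences_a),
                    "n_occurrences_b": len(g.occurrences_b),
                    "cut_a": sa.cut_boundary,
                    "cut_b": sb.cut_boundary,
                    "deletion_size": deletion.size,
                    "deletion_junction": deletion.junction,
                    "multi_site": g.multi_site_flag,
                    "opposite_strand": g.opposite_strand_flag,
                }
            )
    return rows


def write_design_report(rows: Sequence[dict], path) -> None:
    cols = [
        "protospacer", "n_occurrences_a", "n_occurrences_b", "cut_a", "cut_b",
        "deletion_size", "deletion_junction", "multi_site", "opposite_strand",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_run_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
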