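"""Mismatch-tolerant genome-wide guide search and the specificity filter.

The specificity rule is a plain Hamming-distance cutoff: a candidate guide is
rejected when any PAM-adjacent site outside the designated on-target (exempt)
intervals lies at fewer than ``min_mismatches`` mismatches from the
protospacer (default 4, i.e. "reject when < 4 mismatches"). Mismatches are
counted uniformly over all 20 protospacer positions; bulges are not modeled;
N in the genome counts as a mismatch.

Two scan implementations are provided and kept equivalent by tests:

* :func:`scan_offtargets_bruteforce` — a plain per-position Python loop, the
  always-available reference mode;
* the default numpy-vectorized scan in :func:`scan_offtargets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_io import AssemblyContext, GenomicInterval, reverse_complement
from .guide_scan import IUPAC, PAM_LEN, PROTOSPACER_LEN, PamRule
from .score_design import ScoreGuide


class MismatchLengthError(ValueError):
    """Raised when sequences passed to count_mismatches are not 20 nt."""


@dataclass(frozen=True)
class OffTargetSite:
    """A PAM-adjacent genomic site within scan range of a guide."""

    contig_id: str
    strand: str
    protospacer_start: int
    mismatches: int
    pam_observed: str
    exempt: bool


@dataclass(frozen=True)
class SpecificityPolicy:
    """The off-target acceptance rule.

    A guide passes when every non-exempt PAM-adjacent site has at least
    ``min_mismatches`` mismatches. ``exempt_intervals`` are the designated
    on-target regions (typically both LCRs and the intervening CNV segment);
    a site is exempt when its protospacer footprint overlaps any of them.
    ``allow_nag`` additionally admits NAG PAMs at off-target sites (off by
    default: stricter).
    """

    min_mismatches: int = 4
    pam: PamRule = field(default_factory=PamRule)
    exempt_intervals: tuple[GenomicInterval, ...] = ()
    max_scan_mismatches: Optional[int] = None
    allow_nag: bool = False

    def __post_init__(self) -> None:
        if self.min_mismatches < 1:
            raise ValueError(f"min_mismatches must be >= 1, got {self.min_mismatches}")
        object.__setattr__(self, "exempt_intervals", tuple(self.exempt_intervals))

    @property
    def scan_limit(self) -> int:
        if self.max_scan_mismatches is not None:
            return self.max_scan_mismatches
        return self.min_mismatches - 1

    def pam_rules(self) -> tuple[PamRule, ...]:
        rules = [self.pam]
        if self.allow_nag:
            rules.append(PamRule("NAG"))
        return tuple(rules)


def count_mismatches(guide_protospacer: str, site_20mer: str) -> int:
    """Hamming distance between two 20-mers; N counts as a mismatch."""
    if len(guide_protospacer) != PROTOSPACER_LEN or len(site_20mer) != PROTOSPACER_LEN:
        raise MismatchLengthError(
            f"both sequences must be {PROTOSPACER_LEN} nt "
            f"(got {len(guide_protospacer)} and {len(site_20mer)})"
        )
    g, s = guide_protospacer.upper(), site_20mer.upper()
    return sum(
        1 for a, b in zip(g, s) if a != b or a == "N" or b == "N"
    )


def _is_exempt(contig_id: str, start: int, exempt: Sequence[GenomicInterval]) -> bool:
    # exempt when the 20-nt protospacer footprint overlaps any exempt interval
    end = start + PROTOSPACER_LEN
    return any(
        iv.contig_id == contig_id and start < iv.end and iv.start < end
        for iv in exempt
    )


def scan_offtargets_bruteforce(
    guide_protospacer: str,
    assembly: AssemblyContext,
    policy: SpecificityPolicy,
) -> list[OffTargetSite]:
    """Exhaustive per-position scan; the reference implementation.

    Checks every genomic offset on both strands: a site is emitted when a
    3-mer matching the PAM rule is immediately 3' of the 20-mer (in spacer
    orientation) and the Hamming distance is within ``policy.scan_limit``.
    """
    guide = guide_protospacer.upper()
    limit = policy.scan_limit
    rules = policy.pam_rules()
    sites: list[OffTargetSite] = []
    for contig in assembly.genomes.values():
        seq = contig.sequence
        n = len(seq)
        for a in range(0, n - (PROTOSPACER_LEN + PAM_LEN) + 1):
            # plus strand
            trimer = seq[a + PROTOSPACER_LEN : a + PROTOSPACER_LEN + PAM_LEN]
            if any(r.matches(trimer) for r in rules):
                mm = count_mismatches(guide, seq[a : a + PROTOSPACER_LEN])
                if mm <= limit:
                    sites.append(
                        OffTargetSite(
                            contig.contig_id, "+", a, mm, trimer,
                            _is_exempt(contig.contig_id, a, policy.exempt_intervals),
                        )
                    )
            # minus strand: protospacer footprint [a+3, a+23), PAM [a, a+3)
            trimer_m = reverse_complement(seq[a : a + PAM_LEN])
            if any(r.matches(trimer_m) for r in rules):
                site = reverse_complement(seq[a + PAM_LEN : a + PAM_LEN + PROTOSPACER_LEN])
                mm = count_mismatches(guide, site)
                if mm <= limit:
                    sites.append(
                        OffTargetSite(
                            contig.contig_id, "-", a + PAM_LEN, mm, trimer_m,
                            _is_exempt(contig.contig_id, a + PAM_LEN, policy.exempt_intervals),
                        )
                    )
    sites.sort(key=lambda s: (s.contig_id, s.protospacer_start, s.strand))
    return sites


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pattern_mask(arr: np.ndarray, pattern: str, offset: int, length: int) -> np.ndarray:
    """Boolean mask over start positions where arr[start+offset : ...] matches
    the IUPAC pattern (genome N never matches)."""
    n_pos = len(arr) - length + 1
    mask = np.ones(n_pos, dtype=bool)
    for j, pat in enumerate(pattern):
        allowed = IUPAC[pat]
        col = arr[offset + j : offset + j + n_pos]
        ok = np.zeros(n_pos, dtype=bool)
        for b in allowed:
            ok |= col == ord(b)
        mask &= ok
    return mask


def _hamming_profile(arr: np.ndarray, guide: str, offset: int, length: int) -> np.ndarray:
    """Mismatch count of guide vs every window arr[start+offset : +20]."""
    n_pos = len(arr) - length + 1
    mm = np.zeros(n_pos, dtype=np.int16)
    n_code = ord("N")
    for j, g in enumerate(guide):
        col = arr[offset + j : offset + j + n_pos]
        mm += ((col != ord(g)) | (col == n_code)).astype(np.int16)
    return mm


def scan_offtargets(
    guide_protospacer: str,
    assembly: AssemblyContext,
    policy: SpecificityPolicy,
) -> list[OffTargetSite]:
    """Vectorized both-strand scan, equivalent to the brute-force reference."""
    guide = guide_protospacer.upper()
    if len(guide) != PROTOSPACER_LEN:
        raise MismatchLengthError(f"protospacer must be {PROTOSPACER_LEN} nt")
    limit = policy.scan_limit
    rules = policy.pam_rules()
    guide_rc = reverse_complement(guide)
    site_len = PROTOSPACER_LEN + PAM_LEN
    sites: list[OffTargetSite] = []
    for contig in assembly.genomes.values():
        seq = contig.sequence
        if len(seq) < site_len:
            continue
        arr = _encode(seq)
        # plus strand: window = protospacer[0:20] + pam[20:23]
        pam_ok = np.zeros(len(arr) - site_len + 1, dtype=bool)
        for r in rules:
            pam_ok |= _pattern_mask(arr, r.pattern, PROTOSPACER_LEN, site_len)
        mm_plus = _hamming_profile(arr, guide, 0, site_len)
        for a in np.nonzero(pam_ok & (mm_plus <= limit))[0]:
            a = int(a)
            sites.append(
                OffTargetSite(
                    contig.contig_id, "+", a, int(mm_plus[a]),
                    seq[a + PROTOSPACER_LEN : a + site_len],
                    _is_exempt(contig.contig_id, a, policy.exempt_intervals),
                )
            )
        # minus strand: window = revcomp(pam)[0:3] + revcomp(protospacer)[3:23]
        pam_ok_m = np.zeros(len(arr) - site_len + 1, dtype=bool)
        for r in rules:
            rc_pattern = "".join(
                _IUPAC_COMPLEMENT[c] for c in reversed(r.pattern)
            )
            pam_ok_m |= _pattern_mask(arr, rc_pattern, 0, site_len)
        mm_minus = _hamming_profile(arr, guide_rc, PAM_LEN, site_len)
        for a in np.nonzero(pam_ok_m & (mm_minus <= limit))[0]:
            a = int(a)
            start = a + PAM_LEN
            sites.append(
                OffTargetSite(
                    contig.contig_id, "-", start, int(mm_minus[a]),
                    reverse_complement(seq[a : a + PAM_LEN]),
                    _is_exempt(contig.contig_id, start, policy.exempt_intervals),
                )
            )
    sites.sort(key=lambda s: (s.contig_id, s.protospacer_start, s.strand))
    return sites


_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


@dataclass(frozen=True)
class RejectionRecord:
    """A rejected guide and every non-exempt site that violated the rule."""

    guide: ScoreGuide
    offending_sites: tuple[OffTargetSite, ...]


@dataclass(frozen=True)
class FilterResult:
    accepted: tuple[ScoreGuide, ...]
    rejected: tuple[RejectionRecord, ...]


def apply_specificity_filter(
    guides: Iterable[ScoreGuide],
    assembly: AssemblyContext,
    policy: SpecificityPolicy,
    method: str = "numpy",
) -> FilterResult:
    """Partition guides into accepted / rejected under the mismatch rule.

    A guide is rejected iff any non-exempt site lies at fewer than
    ``policy.min_mismatches`` mismatches; the rejection record lists every
    offending site.
    """
    scan = scan_offtargets if method == "numpy" else scan_offtargets_bruteforce
    accepted: list[ScoreGuide] = []
    rejected: list[RejectionRecord] = []
    for guide in guides:
        hits = scan(guide.protospacer, assembly, policy)
        offending = tuple(
            s for s in hits if not s.exempt and s.mismatches < policy.min_mismatches
        )
        if offending:
            rejected.append(RejectionRecord(guide=guide, offending_sites=offending))
        else:
            accepted.append(guide)
    return FilterResult(accepted=tuple(accepted), rejected=tuple(rejected))


def offtargets_to_tsv(guide: str, sites: Sequence[OffTargetSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("guide\tcontig\tstart\tstrand\tmismatches\tpam\texempt\n")
        for s in sites:
            fh.write(
                f"{guide}\t{s.contig_id}\t{s.protospacer_start}\t{s.strand}\t"
                f"{s.mismatches}\t{s.pam_observed}\t{str(s.exempt).lower()}\n"
            )
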