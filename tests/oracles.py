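"""Independent reference implementations used to check the package.

Everything here is deliberately naive (per-offset string slicing, explicit
base sets) and shares no code path with the package's scanners.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def pam_ok(trimer: str, pattern: str) -> bool:
    # a genomic N never satisfies any pattern letter
    return len(trimer) == 3 and all(
        base in _IUPAC_SETS[p] for base, p in zip(trimer, pattern)
    )


def hamming20(a: str, b: str) -> int:
    assert len(a) == len(b) == 20
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def naive_guides(seq: str, start: int, end: int, pattern: str = "NGG"):
    """Every (protospacer, pam, strand, protospacer_start) with the full
    23-nt footprint inside [start, end), found by trying each offset.

    The minus strand is handled by scanning the reverse complement of the
    slice and mapping coordinates back, which is independent of any
    direct-scan implementation.
    """
    sites = []
    for i in range(start, end - 22):
        proto, trimer = seq[i : i + 20], seq[i + 20 : i + 23]
        if "N" not in proto and pam_ok(trimer, pattern):
            sites.append((proto, trimer, "+", i))
    piece = seq[start:end]
    rc = revcomp(piece)
    L = len(piece)
    for p in range(0, L - 22):
        proto, trimer = rc[p : p + 20], rc[p + 20 : p + 23]
        if "N" not in proto and pam_ok(trimer, pattern):
            # plus-strand coordinate of the protospacer's leftmost base
            genome_start = start + (L - p - 20)
            sites.append((proto, trimer, "-", genome_start))
    sites.sort(key=lambda s: (s[3], s[2]))
    return sites


def naive_offtargets(guide: str, seq: str, max_mm: int, patterns=("NGG",)):
    """Every PAM-adjacent site within max_mm mismatches, by trying each
    offset on each strand: (strand, protospacer_start, mismatches, pam)."""
    sites = []
    n = len(seq)
    for i in range(0, n - 22):
        trimer = seq[i + 20 : i + 23]
        if any(pam_ok(trimer, p) for p in patterns):
            mm = hamming20(guide, seq[i : i + 20])
            if mm <= max_mm:
                sites.append(("+", i, mm, trimer))
        trimer_m = revcomp(seq[i : i + 3])
        if any(pam_ok(trimer_m, p) for p in patterns):
            mm = hamming20(guide, revcomp(seq[i + 3 : i + 23]))
            if mm <= max_mm:
                sites.append(("-", i + 3, mm, trimer_m))
    sites.sort(key=lambda s: (s[1], s[0]))
    return sites
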