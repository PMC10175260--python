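"""Seeded generators for every input the toolkit consumes.

Three simulators, each fully reproducible from an integer seed and each
shipping a machine-readable truth table:

* :func:`simulate_locus` — a single-contig locus laid out as
  ``[flank][LCR-A][spacer][LCR-B][flank]`` with protospacer+PAM sites planted
  at identical offsets in both repeats and graded decoy sites (controlled
  Hamming distance) planted in the flanks. It stands in, at reduced scale,
  for an LCR-flanked CNV locus such as 22q11.2 A-B.
* :func:`simulate_ct` — genomic qPCR Ct tables with known per-gene copy
  number (Ct = base - log2(cn/2) + Gaussian noise per replicate).
* :func:`simulate_expression` — negative-binomial expression matrices with a
  heterozygous dosage effect confined to a declared region.

LCR backgrounds are drawn from a dinucleotide-constrained chain that never
emits GG or CC, then swept by a deterministic PAM-destruction repair pass, so
the *only* guide sites inside the repeats are the planted ones (and, when a
user-supplied protospacer itself contains GG/CC, any context sites whose PAM
is locked inside the protected footprint — these are counted in the truth
table). Without this, identical repeats would share every background NGG
site and "the planted guide" would be ill-defined. Flanks and the spacer are
unconstrained random sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clone_screen import CtTable
from .dosage import FeatureMatrix
from .genome_io import (
    AssemblyContext,
    GenomeSequence,
    GenomicInterval,
    write_fasta,
    write_intervals,
)
from .guide_scan import PROTOSPACER_LEN, SITE_LEN, PamRule, enumerate_guides

_BASES = np.array(list("ACGT"))


class CapacityError(ValueError):
    """Raised when requested plants/decoys cannot fit in the locus."""


@dataclass(frozen=True)
class PlantedGuide:
    protospacer: str
    offset_in_lcr: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantedDecoy:
    protospacer_source: str
    protospacer: str
    location: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class SyntheticLocusTruth:
    """Ground truth for one simulated locus."""

    lcr_a: GenomicInterval
    lcr_b: GenomicInterval
    planted_guides: tuple[PlantedGuide, ...]
    decoys: tuple[PlantedDecoy, ...]
    expected_deletion_size: int
    seed: int
    n_context_guides: int = 0


@dataclass
class SimulatedLocus:
    genome: GenomeSequence
    intervals: tuple[GenomicInterval, ...]
    truth: SyntheticLocusTruth
    assembly_label: str = "synthetic"

    @property
    def assembly(self) -> AssemblyContext:
        return AssemblyContext(
            assembly=self.assembly_label,
            genomes={self.genome.contig_id: self.genome},
            lcr_annotations=self.intervals,
        )

    @property
    def lcr_a(self) -> GenomicInterval:
        return self.truth.lcr_a

    @property
    def lcr_b(self) -> GenomicInterval:
        return self.truth.lcr_b

    def write(self, outdir) -> dict[str, Path]:
        """Write genome.fa, annotations.bed and truth.json into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "bed": outdir / "annotations.bed",
            "truth": outdir / "truth.json",
        }
        write_fasta([self.genome], paths["fasta"])
        write_intervals(self.intervals, paths["bed"])
        truth = asdict(self.truth)
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, default=str)
            fh.write("\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _no_gg_cc_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Sequence with no GG and no CC dinucleotide (hence no NGG/CCN PAM)."""
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = np.empty(length, dtype=np.int64)
    prev = -1
    # draw in bulk and veto forbidden repeats; indices: A=0 C=1 G=2 T=3
    draws = rng.choice(4, size=2 * length + 16, p=base_p)
    pos = 0
    for i in range(length):
        while True:
            if pos >= len(draws):
                draws = rng.choice(4, size=2 * length, p=base_p)
                pos = 0
            b = draws[pos]
            pos += 1
            if not ((b == 2 and prev == 2) or (b == 1 and prev == 1)):
                break
        out[i] = b
        prev = b
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _encode_str(seq: str) -> np.ndarray:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([lut[c] for c in seq], dtype=np.int64)


def draw_protospacer(rng: np.random.Generator, gc: float = 0.5) -> str:
    """A random 20-mer containing no GG/CC dinucleotide (repair-friendly)."""
    return _decode(_no_gg_cc_seq(rng, PROTOSPACER_LEN, gc))


def simulate_locus(
    lcr_length: int = 5_000,
    identity: float = 1.0,
    inter_lcr_length: int = 50_000,
    flank_length: int = 10_000,
    n_planted: int = 1,
    decoy_spec: Sequence[int] = (),
    gc: float = 0.5,
    seed: int = 0,
    protospacers: Optional[Sequence[str]] = None,
    contig_id: str = "chr22_syn",
) -> SimulatedLocus:
    """Simulate an LCR-flanked CNV locus with planted guides and decoys.

    Defaults emulate a 22q11.2-like geometry at desk scale: ~5-kb repeats
    separated by a 50-kb spacer (a scaled-down stand-in for the ~1.5-Mb A-B
    segment). ``identity`` is the fraction of LCR-B positions left unmutated
    relative to LCR-A (planted footprints are protected from divergence, so
    the truth table stays valid). ``decoy_spec`` plants one flank decoy per
    entry at exactly that Hamming distance from the first planted guide.
    """
    if lcr_length < 100:
        raise ValueError(f"lcr_length must be >= 100, got {lcr_length}")
    if inter_lcr_length < 1:
        raise ValueError(f"inter_lcr_length must be >= 1, got {inter_lcr_length}")
    if not (0.0 < identity <= 1.0):
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    rng = np.random.default_rng(seed)

    if protospacers is None:
        protos = [draw_protospacer(rng, gc) for _ in range(n_planted)]
    else:
        protos = [p.upper() for p in protospacers]
        n_planted = len(protos)
    # non-overlapping plant offsets, clear of LCR edges
    margin = 40
    slot = SITE_LEN + 40
    capacity = (lcr_length - 2 * margin) // slot
    if n_planted > capacity:
        raise CapacityError(
            f"{n_planted} planted guides do not fit in a {lcr_length}-bp LCR"
        )
    offsets = sorted(
        rng.choice(capacity, size=n_planted, replace=False) * slot + margin
    )

    lcr_a = _no_gg_cc_seq(rng, lcr_length, gc)
    for proto, off in zip(protos, offsets):
        lcr_a[off : off + SITE_LEN] = _encode_str(proto + "TGG")
    lcr_b = lcr_a.copy()
    protected = np.zeros(lcr_length, dtype=bool)
    for off in offsets:
        protected[off : off + SITE_LEN] = True
    if identity < 1.0:
        n_mut = int(round((1.0 - identity) * lcr_length))
        candidates = np.nonzero(~protected)[0]
        if n_mut > len(candidates):
            raise CapacityError("requested divergence exceeds unprotected positions")
        mut_pos = rng.choice(candidates, size=n_mut, replace=False)
        shifts = rng.integers(1, 4, size=n_mut)
        lcr_b[mut_pos] = (lcr_b[mut_pos] + shifts) % 4

    left = _random_seq(rng, flank_length, gc)
    spacer = _random_seq(rng, inter_lcr_length, gc)
    right = _random_seq(rng, flank_length, gc)

    # decoys: flank sites at exact Hamming distance from the first guide
    decoys: list[PlantedDecoy] = []
    if decoy_spec:
        if not protos:
            raise CapacityError("decoys require at least one planted guide")
        source = protos[0]
        next_pos = 100
        for mm in decoy_spec:
            if not (0 <= mm <= PROTOSPACER_LEN):
                raise ValueError(f"decoy mismatch count {mm} out of range")
            if next_pos + SITE_LEN + 10 > flank_length:
                raise CapacityError("left flank too short for requested decoys")
            decoy_arr = _encode_str(source)
            pos_mut = rng.choice(PROTOSPACER_LEN, size=mm, replace=False)
            decoy_arr[pos_mut] = (decoy_arr[pos_mut] + rng.integers(1, 4, size=mm)) % 4
            decoy = _decode(decoy_arr)
            left[next_pos : next_pos + SITE_LEN] = _encode_str(decoy + "TGG")
            decoys.append(
                PlantedDecoy(
                    protospacer_source=source, protospacer=decoy,
                    location=next_pos, strand="+", mismatches=int(mm),
                )
            )
            next_pos += SITE_LEN + 40

    a_start = flank_length
    b_start = flank_length + lcr_length + inter_lcr_length
    full = np.concatenate([left, lcr_a, spacer, lcr_b, right])

    iv_a = GenomicInterval(contig_id, a_start, a_start + lcr_length, "LCR_A", "synthetic")
    iv_b = GenomicInterval(contig_id, b_start, b_start + lcr_length, "LCR_B", "synthetic")
    iv_cnv = GenomicInterval(
        contig_id, iv_a.end, iv_b.start, "CNV_region", "synthetic"
    )

    full, n_context = _repair_lcr_pams(full, iv_a, iv_b, offsets)

    genome = GenomeSequence(contig_id=contig_id, sequence=_decode(full))
    planted = tuple(
        PlantedGuide(protospacer=p, offset_in_lcr=int(o), strand="+")
        for p, o in zip(protos, offsets)
    )
    # same offset in both repeats -> cut boundaries differ by the LCR spacing
    expected_deletion_size = iv_b.start - iv_a.start
    truth = SyntheticLocusTruth(
        lcr_a=iv_a, lcr_b=iv_b, planted_guides=planted, decoys=tuple(decoys),
        expected_deletion_size=expected_deletion_size, seed=seed,
        n_context_guides=n_context,
    )
    locus = SimulatedLocus(
        genome=genome, intervals=(iv_a, iv_b, iv_cnv), truth=truth
    )
    _check_truth(locus)
    return locus


def _repair_lcr_pams(
    full: np.ndarray,
    iv_a: GenomicInterval,
    iv_b: GenomicInterval,
    offsets: Sequence[int],
) -> tuple[np.ndarray, int]:
    """Destroy every un-planted PAM inside the LCRs, mirrored across copies.

    Guide sites whose PAM bases are all locked inside a planted footprint
    (possible when a user-supplied protospacer contains GG/CC) cannot be
    repaired and are counted as context guides.
    """
    lcr_len = iv_a.length
    protected = np.zeros(lcr_len, dtype=bool)
    for off in offsets:
        protected[off : off + SITE_LEN] = True
    expected = {(int(off) + PROTOSPACER_LEN, "+") for off in offsets}  # PAM start, offset units
    pam = PamRule("NGG")
    context: set[tuple[int, str]] = set()
    for _ in range(200):
        genome = GenomeSequence(iv_a.contig_id, _decode(full))
        extras = []
        for iv in (iv_a, iv_b):
            for site in enumerate_guides(genome, iv, pam):
                off = site.protospacer_start - iv.start
                key = (off, site.strand)
                if site.strand == "+" and (off + PROTOSPACER_LEN, "+") in expected:
                    continue
                if key in context:
                    continue
                extras.append((iv, site, off))
        if not extras:
            break
        for iv, site, off in extras:
            if site.strand == "+":
                # PAM GG at protospacer offsets +21, +22 (spacer orientation)
                crit = [off + PROTOSPACER_LEN + 1, off + PROTOSPACER_LEN + 2]
                repl = 0  # A
            else:
                # plus-strand CC at [start-3, start-1)
                crit = [off - 3, off - 2]
                repl = 3  # T
            free = [c for c in crit if 0 <= c < lcr_len and not protected[c]]
            if not free:
                context.add((off, site.strand))
                continue
            c = free[0]
            full[iv_a.start + c] = repl
            full[iv_b.start + c] = repl
    else:
        raise CapacityError("PAM repair did not converge")
    return full, len(context)


def _check_truth(locus: SimulatedLocus) -> None:
    """Verify planted guides occur exactly once per repeat at the recorded offset."""
    genome = locus.genome
    for pg in locus.truth.planted_guides:
        for iv in (locus.lcr_a, locus.lcr_b):
            start = iv.start + pg.offset_in_lcr
            found = genome.sequence[start : start + PROTOSPACER_LEN]
            if found != pg.protospacer:
                raise CapacityError(
                    f"planted guide corrupted at {iv.name}+{pg.offset_in_lcr}"
                )


def simulate_ct(
    truth_copy_number: Mapping[tuple[str, str], int],
    base_ct: Mapping[str, float],
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "RPPH1",
    calibrator_sample: str = "calibrator",
) -> CtTable:
    """Simulate a genomic-qPCR Ct table from known copy numbers.

    Each replicate Ct = base_ct[gene] - log2(copy_number / 2) + N(0, sd): one
    lost copy raises Ct by exactly one cycle under ideal doubling. The
    calibrator sample must be present with copy number 2 everywhere.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    samples = sorted({s for s, _ in truth_copy_number})
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} missing from truth")
    genes = sorted(base_ct)
    for g in genes:
        cn = truth_copy_number.get((calibrator_sample, g))
        if cn != 2:
            raise ValueError(
                f"calibrator must have copy number 2 for every gene (got {cn} for {g})"
            )
    rng = np.random.default_rng(seed)
    ct: dict[tuple[str, str], list[float]] = {}
    for sample in samples:
        for gene in genes:
            cn = truth_copy_number[(sample, gene)]
            mean = base_ct[gene] - np.log2(cn / 2.0)
            noise = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
            ct[(sample, gene)] = [float(mean + e) for e in noise]
    return CtTable(ct=ct, reference_gene=reference_gene, calibrator_sample=calibrator_sample)


def simulate_expression(
    n_in_region: int = 200,
    n_flanking: int = 800,
    dosage_factor: float = 0.5,
    n_per_group: int = 3,
    dispersion: float = 0.1,
    seed: int = 0,
    contig_id: str = "chr22_syn",
    region: Optional[GenomicInterval] = None,
    mean_log: float = float(np.log(200.0)),
    sd_log: float = 1.0,
) -> tuple[FeatureMatrix, GenomicInterval]:
    """Simulate a normalized expression matrix with an in-region dosage effect.

    Control-group feature means are log-normal; deletion-group means for
    in-region features are scaled by ``dosage_factor`` (0.5 = heterozygous
    loss); counts are negative-binomial with var = m + dispersion * m^2
    (Poisson at dispersion 0). Returns the matrix and the region interval.
    """
    if n_in_region < 1 or n_flanking < 1 or n_per_group < 1:
        raise ValueError("feature and sample counts must be positive")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    rng = np.random.default_rng(seed)
    if region is None:
        region = GenomicInterval(contig_id, 1_000_000, 2_000_000, "CNV_region")
    n_total = n_in_region + n_flanking
    mu_ctl = rng.lognormal(mean=mean_log, sigma=sd_log, size=n_total)
    mu_del = mu_ctl.copy()
    mu_del[:n_in_region] *= dosage_factor

    def sample(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu).astype(float)
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p).astype(float)

    del_cols = {f"del_{i+1}": sample(mu_del) for i in range(n_per_group)}
    ctl_cols = {f"ctl_{i+1}": sample(mu_ctl) for i in range(n_per_group)}
    features = [f"feat_{i:05d}" for i in range(n_total)]
    values = pd.DataFrame({**del_cols, **ctl_cols}, index=pd.Index(features, name="feature"))

    coords: dict[str, GenomicInterval] = {}
    width = 1_000
    in_starts = rng.integers(region.start, region.end - width, size=n_in_region)
    n_left = n_flanking // 2
    left_starts = rng.integers(0, max(1, region.start - width), size=n_left)
    right_starts = rng.integers(
        region.end, region.end + 2_000_000, size=n_flanking - n_left
    )
    starts = np.concatenate([in_starts, left_starts, right_starts])
    for feature, start in zip(features, starts):
        coords[feature] = GenomicInterval(contig_id, int(start), int(start) + width, feature)
    groups = {s: "deletion" for s in del_cols} | {s: "control" for s in ctl_cols}
    matrix = FeatureMatrix(values=values, coordinates=coords, group_labels=groups)
    return matrix, region
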