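"""Cross-assembly verification of guide designs.

A guide designed on one reference can be an artifact of that reference:
repeat regions in particular change between assembly releases. Designs are
therefore re-checked independently on every provided assembly (both the
shared-in-both-LCRs property and the off-target filter), and the overall
verdict is the strict conjunction over assemblies. Assemblies are linked by
LCR annotation *names* (e.g. "LCR22A"), never by coordinates — there is no
liftover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome_io import AssemblyContext, GenomicInterval
from .offtarget import SpecificityPolicy, apply_specificity_filter
from .score_design import ScoreGuide, find_shared_guides


class AssemblyConfigError(ValueError):
    """Raised when an assembly lacks a required LCR annotation."""


@dataclass(frozen=True)
class AssemblyVerdict:
    shared_in_lcrs: bool
    specificity_pass: bool
    occurrence_counts: tuple[int, int]

    @property
    def passes(self) -> bool:
        return self.shared_in_lcrs and self.specificity_pass


@dataclass(frozen=True)
class VerificationReport:
    protospacer: str
    per_assembly: Mapping[str, AssemblyVerdict]

    @property
    def overall_pass(self) -> bool:
        return all(v.passes for v in self.per_assembly.values())


def default_exempt_intervals(
    lcr_a: GenomicInterval, lcr_b: GenomicInterval
) -> tuple[GenomicInterval, ...]:
    """The on-target exemption: both LCRs plus the intervening CNV segment."""
    span = GenomicInterval(
        contig_id=lcr_a.contig_id, start=lcr_a.start, end=lcr_b.end,
        name="on_target_span", assembly=lcr_a.assembly,
    )
    return (lcr_a, lcr_b, span)


def verify_guides(
    guides: Sequence[ScoreGuide],
    assemblies: Sequence[AssemblyContext],
    lcr_a_name: str,
    lcr_b_name: str,
    policy: SpecificityPolicy,
) -> list[VerificationReport]:
    """Re-run the shared-guide search and specificity filter per assembly.

    Exempt intervals are derived per assembly from its own LCR annotations
    (both LCRs and the intervening span), so the policy's coordinates never
    leak across assemblies. ``overall_pass`` is true only when every assembly
    passes both checks.
    """
    if not assemblies:
        raise AssemblyConfigError("at least one assembly is required")
    per_assembly_results: dict[str, dict[str, AssemblyVerdict]] = {}
    for ctx in assemblies:
        try:
            lcr_a = ctx.get_interval(lcr_a_name)
            lcr_b = ctx.get_interval(lcr_b_name)
        except KeyError as exc:
            raise AssemblyConfigError(
                f"assembly {ctx.assembly!r} lacks a required LCR annotation: {exc}"
            ) from exc
        local_policy = SpecificityPolicy(
            min_mismatches=policy.min_mismatches,
            pam=policy.pam,
            exempt_intervals=default_exempt_intervals(lcr_a, lcr_b),
            max_scan_mismatches=policy.max_scan_mismatches,
            allow_nag=policy.allow_nag,
        )
        shared = {
            g.protospacer: g
            for g in find_shared_guides(ctx, lcr_a, lcr_b, pam=policy.pam)
        }
        shared_here = [g for g in shared.values() if g.protospacer in {q.protospacer for q in guides}]
        filt = apply_specificity_filter(shared_here, ctx, local_policy)
        accepted = {g.protospacer for g in filt.accepted}
        verdicts: dict[str, AssemblyVerdict] = {}
        for q in guides:
            g = shared.get(q.protospacer)
            if g is None:
                verdicts[q.protospacer] = AssemblyVerdict(
                    shared_in_lcrs=False, specificity_pass=False,
                    occurrence_counts=(0, 0),
                )
            else:
                verdicts[q.protospacer] = AssemblyVerdict(
                    shared_in_lcrs=True,
                    specificity_pass=g.protospacer in accepted,
                    occurrence_counts=(len(g.occurrences_a), len(g.occurrences_b)),
                )
        per_assembly_results[ctx.assembly] = verdicts
    reports = []
    for q in guides:
        reports.append(
            VerificationReport(
                protospacer=q.protospacer,
                per_assembly={
                    label: per_assembly_results[label][q.protospacer]
                    for label in per_assembly_results
                },
            )
        )
    return reports


def verification_to_rows(reports: Sequence[VerificationReport]) -> list[dict]:
    rows = []
    for r in reports:
        for label, v in r.per_assembly.items():
            rows.append(
                {
                    "protospacer": r.protospacer,
                    "assembly": label,
                    "shared_in_lcrs": v.shared_in_lcrs,
                    "specificity_pass": v.specificity_pass,
                    "occurrences_a": v.occurrence_counts[0],
                    "occurrences_b": v.occurrence_counts[1],
                    "overall_pass": r.overall_pass,
                }
            )
    return rows


def write_verification_tsv(reports: Sequence[VerificationReport], path) -> None:
    cols = [
        "protospacer", "assembly", "shared_in_lcrs", "specificity_pass",
        "occurrences_a", "occurrences_b", "overall_pass",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in verification_to_rows(reports):
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
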