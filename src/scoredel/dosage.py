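"""Region-dosage summaries from expression or protein-abundance matrices.

A heterozygous deletion removes one of two gene copies, so transcripts and
proteins encoded inside the deleted region are expected near log2 fold
change -1 in deletion clones, while features flanking the region on the same
chromosome should center on 0. This module computes exactly that picture:
per-feature log2 fold change (deletion vs control group means, with a small
pseudocount for log stability) and the mean over the in-region and flanking
feature sets, partitioned purely by coordinate overlap with the region.

No differential-expression testing (shrinkage, dispersion fitting, FDR) is
performed here — the input is a pre-normalized matrix and the output is the
dosage summary, nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval

GROUP_DELETION = "deletion"
GROUP_CONTROL = "control"


class MatrixError(ValueError):
    """Raised for malformed feature matrices or group maps."""


@dataclass
class FeatureMatrix:
    """Normalized abundances per (feature, sample) with feature coordinates.

    ``coordinates`` maps feature id -> GenomicInterval (may omit features,
    which are then excluded from region summaries with a warning count);
    ``group_labels`` maps sample -> "deletion" | "control".
    """

    values: pd.DataFrame
    coordinates: Mapping[str, GenomicInterval]
    group_labels: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.group_labels.values()) - {GROUP_DELETION, GROUP_CONTROL}
        if unknown:
            raise MatrixError(f"unknown group labels: {sorted(unknown)}")
        missing = set(self.values.columns) - set(self.group_labels)
        if missing:
            raise MatrixError(f"samples without group label: {sorted(missing)}")
        groups = set(self.group_labels[s] for s in self.values.columns)
        if groups != {GROUP_DELETION, GROUP_CONTROL}:
            raise MatrixError("need at least one sample in each group")
        if (self.values.to_numpy() < 0).any():
            raise MatrixError("abundances must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "FeatureMatrix":
        """Read a matrix TSV (feature, contig, start, end, then one column per
        sample) and a two-column group map TSV (sample, group)."""
        df = pd.read_csv(matrix_path, sep="\t")
        required = ["feature", "contig", "start", "end"]
        if list(df.columns[:4]) != required:
            raise MatrixError(f"{matrix_path}: first four columns must be {required}")
        coords = {}
        for row in df.itertuples(index=False):
            if pd.notna(row.contig) and pd.notna(row.start) and pd.notna(row.end):
                coords[str(row.feature)] = GenomicInterval(
                    contig_id=str(row.contig), start=int(row.start), end=int(row.end),
                    name=str(row.feature),
                )
        values = df.set_index("feature").drop(columns=["contig", "start", "end"])
        groups_df = pd.read_csv(groups_path, sep="\t")
        group_labels = dict(zip(groups_df.iloc[:, 0].astype(str), groups_df.iloc[:, 1].astype(str)))
        return cls(values=values, coordinates=coords, group_labels=group_labels)


@dataclass(frozen=True)
class DosageSummary:
    per_feature_l2fc: pd.Series
    in_region_features: tuple[str, ...]
    flanking_features: tuple[str, ...]
    in_region_mean: float
    flanking_mean: float
    region: GenomicInterval
    n_excluded: int

    def to_json(self, path) -> None:
        payload = {
            "region": {
                "contig": self.region.contig_id,
                "start": self.region.start,
                "end": self.region.end,
                "name": self.region.name,
            },
            "in_region_mean_l2fc": self.in_region_mean,
            "flanking_mean_l2fc": self.flanking_mean,
            "n_in_region": len(self.in_region_features),
            "n_flanking": len(self.flanking_features),
            "n_excluded": self.n_excluded,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        in_set = set(self.in_region_features)
        fl_set = set(self.flanking_features)
        with open(path, "w") as fh:
            fh.write("feature\tl2fc\tset\n")
            for feature, l2fc in self.per_feature_l2fc.items():
                which = (
                    "in_region" if feature in in_set
                    else "flanking" if feature in fl_set
                    else "excluded"
                )
                fh.write(f"{feature}\t{l2fc:.6g}\t{which}\n")


def region_log2fc(
    matrix: FeatureMatrix,
    region: GenomicInterval,
    pseudocount: float = 0.5,
) -> DosageSummary:
    """Per-feature log2 fold change and region/flanking set means.

    l2fc = log2((mean over deletion samples + pseudocount) /
    (mean over control samples + pseudocount)). Features whose interval
    overlaps ``region`` form the in-region set; all other features on the
    same contig form the flanking set; features without coordinates or on
    other contigs are excluded (counted in ``n_excluded``).
    """
    del_samples = matrix.samples_in(GROUP_DELETION)
    ctl_samples = matrix.samples_in(GROUP_CONTROL)
    mean_del = matrix.values[del_samples].mean(axis=1)
    mean_ctl = matrix.values[ctl_samples].mean(axis=1)
    l2fc = np.log2((mean_del + pseudocount) / (mean_ctl + pseudocount))
    in_region, flanking = [], []
    n_excluded = 0
    for feature in matrix.values.index:
        iv = matrix.coordinates.get(str(feature))
        if iv is None or iv.contig_id != region.contig_id:
            n_excluded += 1
            continue
        if iv.overlaps(region):
            in_region.append(str(feature))
        else:
            flanking.append(str(feature))
    in_mean = float(l2fc.loc[in_region].mean()) if in_region else float("nan")
    fl_mean = float(l2fc.loc[flanking].mean()) if flanking else float("nan")
    return DosageSummary(
        per_feature_l2fc=l2fc,
        in_region_features=tuple(in_region),
        flanking_features=tuple(flanking),
        in_region_mean=in_mean,
        flanking_mean=fl_mean,
        region=region,
        n_excluded=n_excluded,
    )
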