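"""From filtered read alignments to the normalized vOTU detection table.

A vOTU counts as detected in a sample only when >= 75% of its contig
length is covered >= 1x by reads recruited at >= 90% nucleotide
identity; its abundance is then the trimmed mean of the per-base depth
vector ("tpmean"), normalized by the sample's sequencing depth.  Both
thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import AlignmentRecord

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_BREADTH = 0.75
DEFAULT_TRIM = 0.10
# any fixed per-sample scale preserves downstream statistics; 1e7 keeps
# typical entries in a readable range
DEFAULT_SCALE = 1e7


@dataclass
class CoverageProfile:
    """Per-base depth vector for one contig."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)


def read_identity(aln: AlignmentRecord) -> float:
    """Read-centric identity: 1 - NM / aligned read length.

    Insertions in the read count against identity; reference deletions
    do not consume read bases and therefore do not enter the
    denominator.
    """
    if aln.aligned_read_len == 0:
        raise ValueError(f"read {aln.read_id} has zero aligned length")
    return 1.0 - aln.edit_distance / aln.aligned_read_len


def coverage_profile(
    alns: list[AlignmentRecord],
    contig_id: str,
    contig_len: int,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> CoverageProfile:
    """Per-base depth from alignments on one contig, identity-filtered."""
    depth = np.zeros(contig_len + 1, dtype=np.int64)
    for aln in alns:
        if aln.contig_id != contig_id:
            continue
        if aln.end > contig_len:
            raise ValueError(
                f"alignment of {aln.read_id} exceeds {contig_id} bounds "
                f"({aln.end} > {contig_len})"
            )
        if read_identity(aln) >= min_identity:
            depth[aln.start] += 1
            depth[aln.end] -= 1
    return CoverageProfile(contig_id, np.cumsum(depth[:-1]))


def breadth(profile: CoverageProfile) -> float:
    """Fraction of positions covered by at least one read."""
    return float(np.count_nonzero(profile.depth)) / len(profile.depth)


def trimmed_mean_depth(profile: CoverageProfile, trim: float = DEFAULT_TRIM) -> float:
    """Mean depth after dropping the floor(trim*L) highest and lowest values.

    Reduces to the plain mean when floor(trim*L) == 0.
    """
    if not (0 <= trim < 0.5):
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    depth = np.sort(profile.depth)
    k = int(trim * len(depth))
    if k:
        depth = depth[k:-k]
    return float(depth.mean())


def build_detection_table(
    profiles: dict[str, dict[str, CoverageProfile]],
    library_sizes: dict[str, int],
    breadth_thresh: float = DEFAULT_MIN_BREADTH,
    trim: float = DEFAULT_TRIM,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """vOTU x sample table of breadth-gated normalized abundances.

    ``profiles`` maps sample -> contig_id -> CoverageProfile.  An entry
    is ``tpmean * scale / library_size`` when the breadth gate passes and
    0 otherwise; zero means "not detected".
    """
    votus = sorted({cid for per_sample in profiles.values() for cid in per_sample})
    samples = list(profiles)
    table = pd.DataFrame(0.0, index=votus, columns=samples)
    for sample, per_contig in profiles.items():
        lib = library_sizes[sample]
        for cid, prof in per_contig.items():
            if prof.depth.any() and lib == 0:
                raise ValueError(f"sample {sample} has alignments but library size 0")
            if lib and breadth(prof) >= breadth_thresh:
                table.loc[cid, sample] = trimmed_mean_depth(prof, trim) * scale / lib
    table.index.name = "votu_id"
    return table


def per_sample_richness(table: pd.DataFrame) -> pd.Series:
    """Number of detected (nonzero) vOTUs per sample."""
    return (table > 0).sum(axis=0)


def fold_difference(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Ratio of two mean richness values plus its printed form.

    The printed form is the nearest integer when the ratio is >= 10 and
    one decimal place below that.
    """
    if mean_b == 0:
        raise ValueError("fold_difference undefined for zero denominator")
    ratio = mean_a / mean_b
    printed = f"{round(ratio):d}" if ratio >= 10 else f"{round(ratio, 1):.1f}"
    return ratio, printed
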