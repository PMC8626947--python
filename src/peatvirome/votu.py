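"""Species-level dereplication of viral contigs into vOTUs.

Viral contigs are grouped with the community-standard rule for
species-level viral populations: two contigs belong to the same vOTU
when they share >= 95% nucleotide identity across >= 85% of the length
of the shorter contig.  Clustering is greedy and longest-first, with
each contig joining the first (oldest) representative it qualifies
against -- the centroid semantics of the classic dereplication tools.

"Global identity" is computed from a semi-global alignment with free
terminal gaps, relative to the aligned span of the shorter contig; both
orientations are evaluated and the better one kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from .formats import SeqRecord


@dataclass(frozen=True)
class PairIdentity:
    """Identity over the aligned span and coverage of the shorter contig."""

    identity: float
    shorter_cov: float
    orientation: str = "+"

    def passes(self, id_thresh: float = 0.95, cov_thresh: float = 0.85) -> bool:
        return self.identity >= id_thresh and self.shorter_cov >= cov_thresh


@dataclass
class VotuCluster:
    """One vOTU: the longest member is the representative."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    rep_length: int = 0


def pair_identity(a: SeqRecord, b: SeqRecord, try_rc: bool = True) -> PairIdentity:
    """Alignment identity between two contigs, shorter aligned to longer.

    Identity is matches over alignment columns spanning the shorter
    sequence; ``shorter_cov`` is the aligned (non-terminal-gap) fraction
    of the shorter sequence.  With ``try_rc`` the reverse complement of
    the shorter is also evaluated and the better identity kept.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("pair_identity requires non-empty sequences")
    longer, shorter = (a, b) if len(a) >= len(b) else (b, a)
    target = _align.encode(longer.sequence)
    query = _align.encode(shorter.sequence)
    stats = _align.align(target, query)
    best = PairIdentity(stats.identity, stats.paired / len(shorter), "+")
    if try_rc:
        rc = _align.encode(_align.revcomp(shorter.sequence))
        stats_rc = _align.align(target, rc)
        cand = PairIdentity(stats_rc.identity, stats_rc.paired / len(shorter), "-")
        if cand.identity > best.identity:
            best = cand
    return best


def greedy_cluster(
    contigs: list[SeqRecord],
    id_thresh: float = 0.95,
    cov_thresh: float = 0.85,
    try_rc: bool = True,
    prefilter: bool = True,
    min_kmer_frac: float = 0.25,
) -> list[VotuCluster]:
    """Greedy longest-first dereplication into vOTUs.

    Contigs are sorted by (length descending, id ascending); the first
    unassigned contig founds a cluster and each later contig joins the
    first representative, in creation order, that it matches at
    ``id_thresh`` identity over ``cov_thresh`` of its own length.  The
    canonical sort makes the partition invariant to input file order.

    ``prefilter`` skips alignments against representatives sharing fewer
    than ``min_kmer_frac`` exact k-mers with the contig (in either
    orientation); pairs at or above the species threshold always share
    far more, so the shortcut does not change the partition.
    """
    if not contigs:
        raise ValueError("greedy_cluster requires at least one contig")
    order = sorted(contigs, key=lambda r: (-len(r), r.id))
    clusters: list[VotuCluster] = []
    reps: list[SeqRecord] = []
    rep_codes: list[np.ndarray] = []
    for contig in order:
        enc = _align.encode(contig.sequence)
        codes = _align.kmer_codes(enc)
        codes_rc = (
            _align.kmer_codes(_align.encode(_align.revcomp(contig.sequence)))
            if try_rc
            else None
        )
        placed = False
        for ci, rep in enumerate(reps):
            if prefilter:
                frac = _align.code_overlap(rep_codes[ci], codes)
                if try_rc:
                    frac = max(frac, _align.code_overlap(rep_codes[ci], codes_rc))
                if frac < min_kmer_frac:
                    continue
            pid = pair_identity(rep, contig, try_rc=try_rc)
            if pid.passes(id_thresh, cov_thresh):
                clusters[ci].member_ids.append(contig.id)
                placed = True
                break
        if not placed:
            clusters.append(
                VotuCluster(contig.id, member_ids=[contig.id], rep_length=len(contig))
            )
            reps.append(contig)
            rep_codes.append(codes)
    return clusters


def cluster_map(clusters: list[VotuCluster]) -> dict[str, str]:
    """member id -> representative id."""
    out: dict[str, str] = {}
    for cl in clusters:
        for member in cl.member_ids:
            out[member] = cl.representative_id
    return out
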