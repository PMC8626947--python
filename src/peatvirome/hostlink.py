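"""CRISPR-mediated virus-host linkage.

A CRISPR array links a vOTU to a host MAG when (a) its repeat occurs
exactly (100% identity, either strand) in a MAG contig and (b) one of
its spacers matches a vOTU sequence with at most one substitution
(Hamming distance over the full spacer, both strands, no indels).  For
spacers of >= 20 nt, one allowed mismatch is the substitution-only
equivalent of the 95%-identity short-BLAST convention.

Host taxonomy strings are GTDB-style rank-prefixed, semicolon-separated
labels; for vOTUs linked to several hosts the deepest shared rank is
reported as a consistency check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import revcomp
from .formats import SeqRecord

logger = logging.getLogger(__name__)

MIN_SPACER_LEN = 20
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class CrisprArray:
    """One assembled CRISPR array: a repeat and its ordered spacers."""

    array_id: str
    repeat: str
    spacers: list[str]
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.repeat:
            raise ValueError(f"array {self.array_id} has an empty repeat")
        if any(not s for s in self.spacers):
            raise ValueError(f"array {self.array_id} contains an empty spacer")


@dataclass(frozen=True)
class SpacerHit:
    target_id: str
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class LinkageRecord:
    votu_id: str
    mag_id: str
    array_id: str
    spacer_index: int
    mismatches: int
    strand: str
    mag_taxonomy: str
    multi_host_anchor: bool = False


def arrays_from_table(df: pd.DataFrame) -> list[CrisprArray]:
    """Assemble CrisprArray objects from the long-form array TSV
    (columns array_id, repeat, spacer_index, spacer; spacer_index -1
    marks a repeat-only array)."""
    arrays = []
    for aid, grp in df.groupby("array_id", sort=True):
        spacers = [
            str(s)
            for idx, s in sorted(zip(grp["spacer_index"], grp["spacer"]))
            if idx >= 0
        ]
        sample = str(grp["source_sample"].iloc[0]) if "source_sample" in grp else ""
        arrays.append(
            CrisprArray(str(aid), str(grp["repeat"].iloc[0]), spacers, sample)
        )
    return arrays


def match_repeat(repeat: str, mag_contigs: list[SeqRecord]) -> list[SpacerHit]:
    """Exact (100% identity) occurrences of the repeat, either strand."""
    hits = []
    rc = revcomp(repeat)
    for contig in mag_contigs:
        seq = contig.sequence
        for probe, strand in ((repeat, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append(SpacerHit(contig.id, start, strand, 0))
                start = seq.find(probe, start + 1)
    return hits


def _hamming_scan(spacer: np.ndarray, target: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    m = len(spacer)
    if len(target) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    mm = (windows != spacer).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mismatch)[0]]


def match_spacer(
    spacer: str, votu_seqs: list[SeqRecord], max_mismatch: int = 1
) -> list[SpacerHit]:
    """All positions where the spacer matches a vOTU within the mismatch
    budget (full-length Hamming distance, both strands, no indels).

    Spacers shorter than 20 nt are rejected with a warning (one mismatch
    would break the 95% identity convention below that length).
    """
    if len(spacer) < MIN_SPACER_LEN:
        logger.warning("spacer of length %d < %d rejected", len(spacer), MIN_SPACER_LEN)
        return []
    hits: list[SpacerHit] = []
    probes = (
        (np.frombuffer(spacer.encode(), dtype=np.uint8), "+"),
        (np.frombuffer(revcomp(spacer).encode(), dtype=np.uint8), "-"),
    )
    for rec in votu_seqs:
        target = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        for probe, strand in probes:
            for pos, mm in _hamming_scan(probe, target, max_mismatch):
                hits.append(SpacerHit(rec.id, pos, strand, mm))
    return hits


def link(
    arrays: list[CrisprArray],
    mags: dict[str, list[SeqRecord]],
    votus: list[SeqRecord],
    taxonomy: dict[str, str] | None = None,
    max_mismatch: int = 1,
) -> list[LinkageRecord]:
    """Virus-host linkages: repeat anchors the array to a MAG, spacer
    anchors it to a vOTU.

    One deduplicated record per (vOTU, MAG, spacer) triple.  Arrays whose
    repeat matches more than one MAG emit all linkages flagged
    ``multi_host_anchor``.
    """
    taxonomy = taxonomy or {}
    out: dict[tuple[str, str, str, int], LinkageRecord] = {}
    for arr in arrays:
        anchored = [
            mag_id for mag_id, contigs in sorted(mags.items()) if match_repeat(arr.repeat, contigs)
        ]
        if not anchored:
            continue
        multi = len(anchored) > 1
        for k, spacer in enumerate(arr.spacers):
            for hit in match_spacer(spacer, votus, max_mismatch):
                for mag_id in anchored:
                    key = (hit.target_id, mag_id, arr.array_id, k)
                    rec = LinkageRecord(
                        votu_id=hit.target_id,
                        mag_id=mag_id,
                        array_id=arr.array_id,
                        spacer_index=k,
                        mismatches=hit.mismatches,
                        strand=hit.strand,
                        mag_taxonomy=taxonomy.get(mag_id, ""),
                        multi_host_anchor=multi,
                    )
                    prev = out.get(key)
                    if prev is None or hit.mismatches < prev.mismatches:
                        out[key] = rec
    return sorted(
        out.values(), key=lambda r: (r.votu_id, r.mag_id, r.array_id, r.spacer_index)
    )


def parse_taxonomy(tax: str) -> dict[str, str]:
    """Rank -> label from a GTDB-style string (empty labels dropped)."""
    out = {}
    for part in tax.split(";"):
        part = part.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if part.startswith(prefix) and part[len(prefix):]:
                out[rank] = part[len(prefix):]
    return out


def consensus_host_check(linkages: list[LinkageRecord]) -> pd.DataFrame:
    """Deepest shared taxonomic rank of the hosts per multiply-linked vOTU.

    vOTUs with one host report "n/a"; hosts with no shared rank report
    "none".
    """
    rows = []
    by_votu: dict[str, dict[str, str]] = {}
    for rec in linkages:
        by_votu.setdefault(rec.votu_id, {})[rec.mag_id] = rec.mag_taxonomy
    for votu_id in sorted(by_votu):
        hosts = by_votu[votu_id]
        if len(hosts) < 2:
            rows.append((votu_id, len(hosts), "n/a"))
            continue
        parsed = [parse_taxonomy(t) for t in hosts.values()]
        deepest = "none"
        for rank in RANKS:
            labels = {p.get(rank) for p in parsed}
            if None in labels or len(labels) != 1:
                break
            deepest = rank
        rows.append((votu_id, len(hosts), deepest))
    return pd.DataFrame(rows, columns=["votu_id", "n_hosts", "deepest_shared_rank"])


def linkage_table(linkages: list[LinkageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.votu_id,
                r.mag_id,
                r.array_id,
                r.spacer_index,
                r.mismatches,
                r.strand,
                r.mag_taxonomy,
                r.multi_host_anchor,
            )
            for r in linkages
        ],
        columns=[
            "votu_id",
            "mag_id",
            "array_id",
            "spacer_index",
            "mismatches",
            "strand",
            "mag_taxonomy",
            "multi_host_anchor",
        ],
    )
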