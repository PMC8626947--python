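"""Genus-level viral clusters (VCs) from shared predicted-protein content.

Genomes are profiled by the protein clusters (PCs) they carry; each
genome pair is scored by the upper-tail hypergeometric probability of
sharing at least the observed number of PCs, Bonferroni-corrected over
the evaluated pairs and expressed as -log10(p).  Pairs scoring >= 1 form
a similarity graph that is partitioned by Markov clustering (MCL,
inflation 2.0) into VCs; each VC approximates a viral genus.  Singleton
VCs are counted as VCs throughout.

Taxonomy transfers to every member of a VC that contains a reference
genome; a VC whose habitat set includes marine or freshwater makes all
of its members "aquatic-like".
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _align
from .formats import SeqRecord

logger = logging.getLogger(__name__)

AQUATIC = frozenset({"marine", "freshwater"})
TERRESTRIAL = frozenset({"soil", "peat"})


@dataclass
class ProteinCluster:
    pc_id: str
    member_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GenomeProfile:
    genome_id: str
    pc_set: frozenset[str]


@dataclass
class ViralCluster:
    """One genus-level cluster; singletons allowed and counted as VCs."""

    vc_id: str
    member_ids: list[str]
    habitat_set: set[str] = field(default_factory=set)
    taxonomy: str | None = None

    @property
    def is_singleton(self) -> bool:
        return len(self.member_ids) == 1


@dataclass(frozen=True)
class ClusteringSummary:
    """Arithmetic of a vOTU -> VC partition (singleton VCs included)."""

    n_votus: int
    n_vcs: int
    n_multi_vcs: int
    n_singleton_vcs: int
    votus_in_multi: int
    pct_singleton_vcs: int
    pct_votus_in_singletons: int

    @classmethod
    def from_counts(cls, n_votus: int, n_vcs: int, n_multi_vcs: int) -> "ClusteringSummary":
        """Derive the remaining cells from the three independent counts."""
        singletons = n_vcs - n_multi_vcs
        return cls(
            n_votus=n_votus,
            n_vcs=n_vcs,
            n_multi_vcs=n_multi_vcs,
            n_singleton_vcs=singletons,
            votus_in_multi=n_votus - singletons,
            pct_singleton_vcs=_round_half_away(100 * singletons / n_vcs),
            pct_votus_in_singletons=_round_half_away(100 * singletons / n_votus),
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cluster_proteins(
    proteins: list[SeqRecord],
    genome_map: pd.DataFrame | None = None,
    aai_thresh: float = 0.60,
    cov_thresh: float = 0.80,
    prefilter: bool = True,
    min_kmer_frac: float = 0.10,
) -> list[ProteinCluster]:
    """Greedy centroid clustering of proteins by global amino-acid identity.

    Longest-first with lexicographic tie-break; a protein joins the first
    centroid it matches at ``aai_thresh`` identity over ``cov_thresh`` of
    the shorter protein.  ``genome_map`` is accepted for interface
    symmetry with the profile builder and not consulted here.
    """
    del genome_map
    clusters: list[ProteinCluster] = []
    centroids: list[np.ndarray] = []
    centroid_codes: list[np.ndarray] = []
    order = sorted(proteins, key=lambda r: (-len(r), r.id))
    for prot in order:
        enc = _align.encode(prot.sequence)
        codes = _align.kmer_codes(enc, k=5, alphabet="protein")
        placed = False
        for ci, cen in enumerate(centroids):
            if prefilter and _align.code_overlap(centroid_codes[ci], codes) < min_kmer_frac:
                continue
            target, query = (cen, enc) if len(cen) >= len(enc) else (enc, cen)
            stats = _align.align(target, query)
            shorter = min(len(cen), len(enc))
            if stats.identity >= aai_thresh and stats.paired / shorter >= cov_thresh:
                clusters[ci].member_ids.append(prot.id)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(f"PC{len(clusters):05d}", [prot.id]))
            centroids.append(enc)
            centroid_codes.append(codes)
    return clusters


def genome_profiles(
    pcs: list[ProteinCluster], genome_map: pd.DataFrame
) -> list[GenomeProfile]:
    """Per-genome PC presence sets from the protein -> genome map."""
    prot_pc = {p: pc.pc_id for pc in pcs for p in pc.member_ids}
    by_genome: dict[str, set[str]] = {}
    for prot, genome in zip(genome_map["protein_id"], genome_map["genome_id"]):
        by_genome.setdefault(genome, set())
        if prot in prot_pc:
            by_genome[genome].add(prot_pc[prot])
    return [GenomeProfile(g, frozenset(s)) for g, s in sorted(by_genome.items())]


def pair_score(
    pa: GenomeProfile, pb: GenomeProfile, universe_size: int, n_pairs: int
) -> float:
    """Hypergeometric similarity score between two genome profiles.

    ``-log10`` of the Bonferroni-corrected upper-tail probability of
    sharing at least the observed number of PCs when |pa| and |pb| PCs
    are drawn from a universe of ``universe_size``.  Genomes sharing no
    PCs score 0.
    """
    c = len(pa.pc_set & pb.pc_set)
    if c == 0:
        return 0.0
    p = float(hypergeom.sf(c - 1, universe_size, len(pa.pc_set), len(pb.pc_set)))
    corrected = min(1.0, p * max(1, n_pairs))
    if corrected <= 0:
        return float(np.finfo(float).max / 1e10)
    return max(0.0, -math.log10(corrected))


def build_vc_graph(profiles: list[GenomeProfile], min_score: float = 1.0) -> nx.Graph:
    """Similarity graph over all genomes; isolated nodes are kept."""
    universe = set()
    for p in profiles:
        universe |= p.pc_set
    M = len(universe)
    n = len(profiles)
    n_pairs = n * (n - 1) // 2
    g = nx.Graph()
    g.add_nodes_from(p.genome_id for p in profiles)
    for i in range(n):
        for j in range(i + 1, n):
            s = pair_score(profiles[i], profiles[j], M, n_pairs)
            if s >= min_score:
                g.add_edge(profiles[i].genome_id, profiles[j].genome_id, weight=s)
    return g


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[ViralCluster]:
    """Markov clustering of the similarity graph into VCs.

    The column-stochastic flow matrix is iterated
    (expand -> inflate -> prune -> renormalize) to convergence; clusters
    are the connected components of the limit matrix's support, so every
    node lands in exactly one cluster and isolated nodes become
    singleton VCs.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    A = A + np.eye(len(nodes))  # self-loops stabilize the flow
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; using current flow", max_iter)
    support = nx.from_numpy_array((M + M.T) > prune)
    comps = sorted(
        (sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)),
        key=lambda c: c[0],
    )
    return [ViralCluster(f"VC{k:04d}", members) for k, members in enumerate(comps)]


def annotate_habitats(vcs: list[ViralCluster], habitat: dict[str, str]) -> list[ViralCluster]:
    """Fill each VC's habitat set with the union of member labels."""
    for vc in vcs:
        vc.habitat_set = {habitat[m] for m in vc.member_ids if m in habitat}
    return vcs


def assign_taxonomy(
    vcs: list[ViralCluster], reference_labels: dict[str, str]
) -> list[ViralCluster]:
    """Transfer taxonomy from reference members to whole VCs.

    A VC is classified iff it contains at least one reference genome;
    conflicting reference labels yield "ambiguous" (still classified).
    """
    for vc in vcs:
        labels = {reference_labels[m] for m in vc.member_ids if m in reference_labels}
        if not labels:
            vc.taxonomy = None
        elif len(labels) == 1:
            vc.taxonomy = labels.pop()
        else:
            vc.taxonomy = "ambiguous"
    return vcs


def mean_pairwise_aai(
    vc: ViralCluster,
    proteins_by_genome: dict[str, list[SeqRecord]],
    min_identity: float = 0.30,
) -> float | None:
    """Mean over genome pairs of mean best-reciprocal protein identity.

    Reciprocal best matches below ``min_identity`` are discarded as
    non-homologous, the usual homology floor of amino-acid-identity
    tools; without it, accessory proteins with no true ortholog would
    pair with random partners and depress the mean.  Undefined (None)
    for singleton VCs.
    """
    members = [m for m in vc.member_ids if m in proteins_by_genome]
    if len(members) < 2:
        return None
    pair_vals = []
    enc_cache = {
        g: [_align.encode(p.sequence) for p in proteins_by_genome[g]] for g in members
    }
    for ai in range(len(members)):
        for bi in range(ai + 1, len(members)):
            pa, pb = enc_cache[members[ai]], enc_cache[members[bi]]
            ident = np.zeros((len(pa), len(pb)))
            for i, ea in enumerate(pa):
                for j, eb in enumerate(pb):
                    t, q = (ea, eb) if len(ea) >= len(eb) else (eb, ea)
                    ident[i, j] = _align.align(t, q).identity
            best_ab = ident.argmax(axis=1)
            best_ba = ident.argmax(axis=0)
            recip = [
                ident[i, best_ab[i]]
                for i in range(len(pa))
                if best_ba[best_ab[i]] == i and ident[i, best_ab[i]] >= min_identity
            ]
            if recip:
                pair_vals.append(float(np.mean(recip)))
    return float(np.mean(pair_vals)) if pair_vals else None


def summarize_clustering(votu_ids: list[str], vcs: list[ViralCluster]) -> ClusteringSummary:
    """Partition arithmetic for a set of vOTUs and their VCs."""
    votus = set(votu_ids)
    mine = [vc for vc in vcs if votus & set(vc.member_ids)]
    n_multi = sum(1 for vc in mine if len(set(vc.member_ids) & votus) > 1)
    return ClusteringSummary.from_counts(len(votus), len(mine), n_multi)


@dataclass(frozen=True)
class HabitatOverlap:
    combination_counts: dict[frozenset, int]
    n_soil_vcs: int
    n_soil_shared_aquatic: int
    pct_soil_shared_aquatic: float


def habitat_overlap(vcs: list[ViralCluster]) -> HabitatOverlap:
    """Exclusive/shared habitat combinations across VCs.

    A "soil" VC contains at least one soil or peat member; it is shared
    with aquatic when it also contains a marine or freshwater member.
    Combination counts partition the VC universe.
    """
    combos = Counter(frozenset(vc.habitat_set) for vc in vcs)
    soil_vcs = [vc for vc in vcs if vc.habitat_set & TERRESTRIAL]
    shared = [vc for vc in soil_vcs if vc.habitat_set & AQUATIC]
    pct = 100 * len(shared) / len(soil_vcs) if soil_vcs else 0.0
    return HabitatOverlap(dict(combos), len(soil_vcs), len(shared), pct)


def aquatic_like_votus(vcs: list[ViralCluster]) -> set[str]:
    """vOTUs sharing a VC with at least one marine or freshwater vOTU."""
    out: set[str] = set()
    for vc in vcs:
        if vc.habitat_set & AQUATIC:
            out.update(vc.member_ids)
    return out
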