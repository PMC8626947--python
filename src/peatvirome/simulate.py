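"""Synthetic peat viral communities with known ground truth.

Every downstream stage of the pipeline is testable against data whose
structure is planted and recorded: genus-structured viral pangenomes
with within-species variants above the 95% species boundary and
between-species divergence well below it, habitat labels assigned per
species, microbial hosts carrying CRISPR arrays whose spacers are copied
(with 0 or 1 substitutions) from viral protospacers, depth-structured
negative-binomial abundances with an aquatic-like trait enriched in the
surface group, and substitution-error reads with truth alignments.

Mutations are substitutions only, so every planted identity is exactly
computable.  All variants of a species are mutated at one shared set of
"variable" positions drawn per species: this pins every same-species
pairwise identity at or above ``within_species_ani`` (independently
mutated variants would drift to roughly twice the divergence and cross
the species boundary).  Protein sequences are emitted directly -- gene
calling is out of scope.

One root seed determines every emitted byte; each stage draws from its
own child stream with a fixed spawn key, so regenerating a later stage
does not disturb earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .formats import SeqRecord

logger = logging.getLogger(__name__)

HABITATS = ("soil", "peat", "marine", "freshwater")
AQUATIC = frozenset({"marine", "freshwater"})
NT = np.frombuffer(b"ACGT", dtype=np.uint8)
AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# fixed spawn keys for per-stage child RNG streams
_STAGE = {"community": 0, "hosts": 1, "abundance": 2, "reads": 3}


@dataclass(frozen=True)
class TruthConfig:
    """Parameters of the synthetic community (defaults are the study design).

    Sizes are chosen to look like a desk-scale peat study: a few dozen
    viral genera dominated by soil/peat habitats with a minority of
    aquatic genera and occasional cross-habitat genera, four sampled
    depth levels, and three planted depth-differential vOTU groups with
    an aquatic-like enrichment in the surface group.
    """

    seed: int = 0
    n_habitats: int = 4
    n_genera: int = 25
    species_per_genus: int = 6
    variants_per_species: int = 2
    genome_len_range: tuple[int, int] = (10_000, 12_000)
    pangenome_size: int = 30
    core_fraction: float = 0.4
    within_species_ani: float = 0.97
    between_species_ani: float = 0.85
    n_hosts: int = 12
    spacers_per_host: int = 4
    spacer_len: int = 32
    spacer_mismatch_prob: float = 0.15
    n_samples: int = 20
    depth_levels: tuple[str, ...] = ("10-20", "40-50", "100-125", "150-175")
    nb_mean_range: tuple[float, float] = (5.0, 50.0)
    nb_dispersion: float = 0.3
    aquatic_enrichment_odds: float = 4.0
    read_len: int = 150
    error_rate: float = 0.005
    # habitat structure: per-genus home-habitat weights over the habitat
    # labels in use, and the chance a terrestrial genus harbors one
    # aquatic species (which makes the whole genus aquatic-like)
    habitat_weights: tuple[float, ...] = (0.45, 0.40, 0.10, 0.05)
    cross_habitat_prob: float = 0.2
    # depth-differential design: planted group sizes (surface, mid, deep)
    # and the fold change between favored and other depth levels
    da_group_sizes: tuple[int, int, int] = (32, 15, 15)
    da_effect: float = 4.0
    library_size_range: tuple[int, int] = (8_000, 12_000)
    protein_len_range: tuple[int, int] = (200, 400)
    protein_divergence: float = 0.15
    accessory_prob: float = 0.5
    host_genome_len: int = 20_000
    repeat_len: int = 28

    def __post_init__(self) -> None:
        if not (0 < self.between_species_ani < 0.90 < 0.95 <= self.within_species_ani <= 1):
            raise ValueError(
                "require 0 < between_species_ani < 0.90 < 0.95 <= within_species_ani <= 1"
            )
        if not (1 <= self.n_habitats <= len(HABITATS)):
            raise ValueError(f"n_habitats must be in [1, {len(HABITATS)}]")
        for name in (
            "n_genera",
            "species_per_genus",
            "variants_per_species",
            "pangenome_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_hosts", "spacers_per_host", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def habitats(self) -> tuple[str, ...]:
        return HABITATS[: self.n_habitats]

    def rng(self, stage: str) -> np.random.Generator:
        """Child RNG stream for one generation stage (fixed spawn key)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE[stage],))
        )


@dataclass
class HostTruth:
    taxonomy: str
    # one tuple per planted spacer: (votu, spacer_index, mismatches, strand)
    linked: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class TruthTables:
    """Planted structure of one synthetic community."""

    contig_species: dict[str, str]
    species_genus: dict[str, str]
    votu_habitat: dict[str, str]
    aquatic_like: dict[str, bool]
    species_rep: dict[str, str]
    protein_family: dict[str, str]
    contigs: list[SeqRecord] = field(default_factory=list)
    host_info: dict[str, HostTruth] = field(default_factory=dict)
    da_groups: dict[str, int] = field(default_factory=dict)
    counts: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.species_genus)

    def rep_record(self, species: str) -> SeqRecord:
        rep_id = self.species_rep[species]
        for rec in self.contigs:
            if rec.id == rep_id:
                return rec
        raise KeyError(rep_id)


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> np.ndarray:
    return alphabet[rng.integers(0, len(alphabet), length)]


def _mutate(
    seq: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    alphabet: np.ndarray,
) -> np.ndarray:
    """Substitute each given position with a different symbol."""
    out = seq.copy()
    for pos in positions:
        choices = alphabet[alphabet != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_community(
    config: TruthConfig,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame, pd.DataFrame, TruthTables]:
    """Build the viral community: contigs, proteins, labels and truth.

    Returns ``(contigs, proteins, genome_map, habitat_table, truth)``.
    Genus pangenomes are drawn from a shared per-genus protein pool;
    species founders diverge from the genus backbone to
    ``between_species_ani`` (pairwise well under 0.90), and variants
    within a species stay at or above ``within_species_ani`` pairwise.
    """
    rng = config.rng("community")
    weights = np.asarray(config.habitat_weights[: config.n_habitats], dtype=float)
    weights = weights / weights.sum()
    habitats = config.habitats
    aquatic_labels = [h for h in habitats if h in AQUATIC]

    contigs: list[SeqRecord] = []
    proteins: list[SeqRecord] = []
    genome_rows: list[tuple[str, str]] = []
    contig_species: dict[str, str] = {}
    species_genus: dict[str, str] = {}
    votu_habitat: dict[str, str] = {}
    species_rep: dict[str, str] = {}
    protein_family: dict[str, str] = {}
    genus_habitats: dict[str, set[str]] = {}

    for g in range(config.n_genera):
        genus_id = f"g{g:03d}"
        glen = int(rng.integers(config.genome_len_range[0], config.genome_len_range[1] + 1))
        backbone = _random_seq(rng, glen, NT)
        home = str(rng.choice(np.array(habitats, dtype=object), p=weights))
        mixed = (
            home not in AQUATIC
            and aquatic_labels
            and rng.random() < config.cross_habitat_prob
        )
        aquatic_species = int(rng.integers(config.species_per_genus)) if mixed else -1

        # genus pangenome: founder protein per family, first block is core
        n_core = max(1, round(config.core_fraction * config.pangenome_size))
        fam_seqs = []
        for f in range(config.pangenome_size):
            plen = int(rng.integers(config.protein_len_range[0], config.protein_len_range[1] + 1))
            fam_seqs.append(_random_seq(rng, plen, AA))

        for s in range(config.species_per_genus):
            species_id = f"{genus_id}s{s:02d}"
            species_genus[species_id] = genus_id
            if s == aquatic_species:
                habitat = str(rng.choice(np.array(aquatic_labels, dtype=object)))
            else:
                habitat = home
            votu_habitat[species_id] = habitat
            genus_habitats.setdefault(genus_id, set()).add(habitat)

            n_mut = round((1 - config.between_species_ani) * glen)
            founder_pos = rng.choice(glen, size=n_mut, replace=False)
            founder = _mutate(backbone, founder_pos, rng, NT)
            n_var = round((1 - config.within_species_ani) * glen)
            variable_pos = rng.choice(glen, size=n_var, replace=False)

            # species protein complement: all core + random accessory
            accessory = [
                f
                for f in range(n_core, config.pangenome_size)
                if rng.random() < config.accessory_prob
            ]
            families = list(range(n_core)) + accessory
            sp_proteins = {}
            for f in families:
                fam = fam_seqs[f]
                n_pm = round(config.protein_divergence * len(fam))
                pos = rng.choice(len(fam), size=n_pm, replace=False)
                sp_proteins[f] = _mutate(fam, pos, rng, AA)

            for v in range(config.variants_per_species):
                contig_id = f"{species_id}v{v:02d}"
                if v == 0:
                    seq = founder
                    species_rep[species_id] = contig_id
                else:
                    seq = _mutate(founder, variable_pos, rng, NT)
                    cut = int(rng.integers(0, max(1, int(0.02 * glen)) + 1))
                    if cut:
                        seq = seq[:-cut]
                contigs.append(SeqRecord(contig_id, _to_str(seq)))
                contig_species[contig_id] = species_id
                for f in families:
                    pid = f"{contig_id}p{f:03d}"
                    proteins.append(SeqRecord(pid, _to_str(sp_proteins[f])))
                    genome_rows.append((pid, contig_id))
                    protein_family[pid] = f"{genus_id}f{f:03d}"

    aquatic_like = {
        sp: bool(genus_habitats[species_genus[sp]] & AQUATIC) for sp in species_genus
    }
    genome_map = pd.DataFrame(genome_rows, columns=["protein_id", "genome_id"])
    habitat_table = pd.DataFrame(
        sorted(votu_habitat.items()), columns=["votu_id", "habitat"]
    )
    truth = TruthTables(
        contig_species=contig_species,
        species_genus=species_genus,
        votu_habitat=votu_habitat,
        aquatic_like=aquatic_like,
        species_rep=species_rep,
        protein_family=protein_family,
        contigs=contigs,
    )
    return contigs, proteins, genome_map, habitat_table, truth


def generate_hosts(
    config: TruthConfig, truth: TruthTables
) -> tuple[list[SeqRecord], pd.DataFrame, pd.DataFrame]:
    """Microbial hosts with planted CRISPR arrays.

    Each host carries one array (one repeat, ``spacers_per_host``
    spacers).  Every spacer is copied from a substring of a chosen vOTU
    representative, on a random strand, with one substitution planted at
    probability ``spacer_mismatch_prob``.  Host taxonomy strings follow a
    family/genus hierarchy so consensus-host checks are testable.

    Returns ``(host_contigs, array_table, mag_table)`` and records the
    planted linkages in ``truth.host_info``.
    """
    rng = config.rng("hosts")
    reps = [truth.rep_record(sp) for sp in truth.species_ids]
    if not reps:
        raise ValueError("community must be generated before hosts")
    min_len = min(len(r) for r in reps)
    if config.spacer_len > min_len:
        raise ValueError(
            f"spacer_len {config.spacer_len} exceeds shortest vOTU length {min_len}"
        )

    n_families = max(1, config.n_hosts // 3)
    host_contigs: list[SeqRecord] = []
    array_rows = []
    mag_rows = []
    truth.host_info = {}
    for h in range(config.n_hosts):
        host_id = f"mag{h:03d}"
        fam = h % n_families
        genus = f"{fam}{h % 2}"
        taxonomy = (
            "d__Bacteria;p__Phylum00;c__Class00;o__Order00;"
            f"f__Family{fam:02d};g__Genus{genus};s__Species{h:03d}"
        )
        repeat = _to_str(_random_seq(rng, config.repeat_len, NT))
        spacers: list[str] = []
        info = HostTruth(taxonomy=taxonomy)
        for k in range(config.spacers_per_host):
            rep = reps[int(rng.integers(len(reps)))]
            pos = _unique_protospacer_pos(rng, rep, reps, truth, config)
            proto = np.frombuffer(
                rep.sequence[pos : pos + config.spacer_len].encode(), dtype=np.uint8
            )
            mm = 1 if rng.random() < config.spacer_mismatch_prob else 0
            spacer = (
                _mutate(proto, rng.choice(config.spacer_len, size=1), rng, NT)
                if mm
                else proto.copy()
            )
            strand = "-" if rng.random() < 0.5 else "+"
            spacer_str = _to_str(spacer)
            if strand == "-":
                spacer_str = _revcomp(spacer_str)
            spacers.append(spacer_str)
            species = truth.contig_species[rep.id]
            info.linked.append((species, k, mm, strand))
        truth.host_info[host_id] = info

        cassette = repeat + "".join(sp + repeat for sp in spacers)
        genome = _to_str(_random_seq(rng, config.host_genome_len, NT))
        ins = int(rng.integers(0, config.host_genome_len + 1))
        host_contigs.append(SeqRecord(host_id, genome[:ins] + cassette + genome[ins:]))
        mag_rows.append((host_id, taxonomy))
        array_id = f"arr{h:03d}"
        if spacers:
            for k, sp in enumerate(spacers):
                array_rows.append((array_id, host_id, "s00", repeat, k, sp))
        else:
            array_rows.append((array_id, host_id, "s00", repeat, -1, ""))

    array_table = pd.DataFrame(
        array_rows,
        columns=["array_id", "planted_host", "source_sample", "repeat", "spacer_index", "spacer"],
    )
    mag_table = pd.DataFrame(mag_rows, columns=["mag_id", "taxonomy"])
    return host_contigs, array_table, mag_table


def _revcomp(seq: str) -> str:
    from ._align import revcomp

    return revcomp(seq)


def _min_hamming(window: np.ndarray, target: np.ndarray) -> int:
    if len(target) < len(window):
        return len(window)
    sw = np.lib.stride_tricks.sliding_window_view(target, len(window))
    return int((sw != window).sum(axis=1).min())


def _unique_protospacer_pos(
    rng: np.random.Generator,
    rep: SeqRecord,
    reps: list[SeqRecord],
    truth: TruthTables,
    config: TruthConfig,
    min_dist: int = 4,
    max_tries: int = 25,
) -> int:
    """Protospacer start position unique to the source vOTU.

    Real spacer-protospacer matches identify a single viral population;
    within a synthetic genus, sister species retain enough backbone
    identity that an arbitrary window can occasionally sit within one
    mismatch of another species.  Windows are therefore redrawn until
    they are at least ``min_dist`` substitutions away from every other
    same-genus representative on both strands, so a planted spacer can
    only ever link back to its source vOTU.
    """
    genus = truth.species_genus[truth.contig_species[rep.id]]
    siblings = [
        r
        for r in reps
        if r.id != rep.id
        and truth.species_genus[truth.contig_species[r.id]] == genus
    ]
    sib_enc = [
        (
            np.frombuffer(r.sequence.encode(), dtype=np.uint8),
            np.frombuffer(_revcomp(r.sequence).encode(), dtype=np.uint8),
        )
        for r in siblings
    ]
    pos = 0
    for _ in range(max_tries):
        pos = int(rng.integers(0, len(rep) - config.spacer_len + 1))
        window = np.frombuffer(
            rep.sequence[pos : pos + config.spacer_len].encode(), dtype=np.uint8
        )
        if all(
            min(_min_hamming(window, fwd), _min_hamming(window, rc)) >= min_dist
            for fwd, rc in sib_enc
        ):
            return pos
    logger.warning("no unique protospacer window found for %s; using last draw", rep.id)
    return pos


def generate_abundance(
    config: TruthConfig, truth: TruthTables
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial vOTU x sample counts with a planted depth design.

    Terrestrial (soil/peat) vOTUs receive log-uniform baseline means;
    aquatic-habitat vOTUs are absent (zero counts), as in a peat
    community referenced against a cross-ecosystem database.  Three
    planted groups are differentially abundant: group 1 favored at the
    surface level, group 2 at the second level, group 3 at the two
    deepest levels.  Aquatic-like vOTUs are over-represented in group 1
    with selection odds ``aquatic_enrichment_odds``.  Counts are scaled
    per sample by library-size factors.
    """
    if truth.counts is not None:
        logger.info("regenerating abundance over existing truth counts")
    rng = config.rng("abundance")
    species = truth.species_ids
    samples = [f"s{i:02d}" for i in range(config.n_samples)]
    levels = [
        config.depth_levels[i * len(config.depth_levels) // max(1, config.n_samples)]
        for i in range(config.n_samples)
    ]
    lib_sizes = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, config.n_samples
    )
    meta = pd.DataFrame(
        {"sample_id": samples, "depth_level": levels, "library_size": lib_sizes}
    )
    counts = pd.DataFrame(0, index=species, columns=samples, dtype=np.int64)
    counts.index.name = "votu_id"
    truth.sample_meta = meta
    truth.da_groups = {sp: 0 for sp in species}
    if config.n_samples == 0:
        truth.counts = counts
        return counts, meta

    terrestrial = [sp for sp in species if truth.votu_habitat[sp] not in AQUATIC]
    lo, hi = config.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), len(terrestrial)))
    base_mean = dict(zip(terrestrial, base))

    # planted differential groups
    pool = list(terrestrial)
    sizes = [min(s, max(0, len(pool) - sum(config.da_group_sizes[:i])))
             for i, s in enumerate(config.da_group_sizes)]
    w = np.array(
        [config.aquatic_enrichment_odds if truth.aquatic_like[sp] else 1.0 for sp in pool]
    )
    surface = list(
        rng.choice(np.array(pool, dtype=object), size=sizes[0], replace=False, p=w / w.sum())
    ) if sizes[0] else []
    remaining = [sp for sp in pool if sp not in set(surface)]
    mid = list(
        rng.choice(np.array(remaining, dtype=object), size=min(sizes[1], len(remaining)), replace=False)
    ) if sizes[1] else []
    remaining = [sp for sp in remaining if sp not in set(mid)]
    deep = list(
        rng.choice(np.array(remaining, dtype=object), size=min(sizes[2], len(remaining)), replace=False)
    ) if sizes[2] else []
    for sp in surface:
        truth.da_groups[sp] = 1
    for sp in mid:
        truth.da_groups[sp] = 2
    for sp in deep:
        truth.da_groups[sp] = 3

    level_names = list(config.depth_levels)
    sf = lib_sizes / lib_sizes.mean()
    n_shape = 1.0 / config.nb_dispersion
    for si, sample in enumerate(samples):
        lv = level_names.index(levels[si])
        mu = np.zeros(len(species))
        for vi, sp in enumerate(species):
            if sp not in base_mean:
                continue
            m = base_mean[sp]
            grp = truth.da_groups[sp]
            favored = (
                (grp == 1 and lv == 0)
                or (grp == 2 and lv == 1)
                or (grp == 3 and lv >= 2)
            )
            if grp and favored:
                m *= config.da_effect
            mu[vi] = m * sf[si]
        pos = mu > 0
        col = np.zeros(len(species), dtype=np.int64)
        col[pos] = rng.negative_binomial(n_shape, n_shape / (n_shape + mu[pos]))
        counts[sample] = col

    truth.counts = counts
    return counts, meta


def generate_reads(
    truth: TruthTables, counts: pd.DataFrame, config: TruthConfig
) -> dict[str, tuple[list[SeqRecord], list[tuple[str, str, int, str, str, int]]]]:
    """Reads per sample plus truth alignments.

    For each sample, exactly ``library_size`` reads are drawn from vOTU
    representative contigs with probabilities proportional to the counts
    column, uniform start positions and substitution errors at
    ``error_rate``; the truth alignment tuples record the generating
    coordinates and an NM value equal to the planted substitution count.
    vOTUs shorter than the read length are skipped with a warning.
    """
    rng = config.rng("reads")
    if truth.sample_meta is None:
        raise ValueError("generate_abundance must run before generate_reads")
    lib = dict(zip(truth.sample_meta["sample_id"], truth.sample_meta["library_size"]))
    reps = {sp: truth.rep_record(sp) for sp in counts.index}
    usable = np.array([len(reps[sp]) >= config.read_len for sp in counts.index])
    for sp, ok in zip(counts.index, usable):
        if not ok:
            logger.warning("vOTU %s shorter than read length; skipped", sp)

    out: dict[str, tuple[list[SeqRecord], list]] = {}
    for sample in counts.columns:
        weights = counts[sample].to_numpy(dtype=float) * usable
        total = weights.sum()
        reads: list[SeqRecord] = []
        alns: list[tuple[str, str, int, str, str, int]] = []
        if total > 0:
            n_reads = rng.multinomial(lib[sample], weights / total)
            r = 0
            for sp, n in zip(counts.index, n_reads):
                rep = reps[sp]
                enc = np.frombuffer(rep.sequence.encode(), dtype=np.uint8)
                for _ in range(int(n)):
                    start = int(rng.integers(0, len(rep) - config.read_len + 1))
                    frag = enc[start : start + config.read_len].copy()
                    n_err = int(rng.binomial(config.read_len, config.error_rate))
                    if n_err:
                        pos = rng.choice(config.read_len, size=n_err, replace=False)
                        frag = _mutate(frag, pos, rng, NT)
                    strand = "-" if rng.random() < 0.5 else "+"
                    read_id = f"{sample}r{r:06d}"
                    r += 1
                    ref_oriented = _to_str(frag)
                    # FASTQ carries the read as sequenced; the truth SAM
                    # stores the reference-oriented sequence with flag 16
                    sequenced = _revcomp(ref_oriented) if strand == "-" else ref_oriented
                    reads.append(SeqRecord(read_id, sequenced))
                    alns.append((read_id, rep.id, start, strand, ref_oriented, n_err))
        out[sample] = (reads, alns)
    return out
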