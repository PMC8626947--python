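"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> cluster -> detect -> vc ->
ecology -> hostlink -> dispersion on a synthetic community (or any
subset of stages), writes every product as TSV/FASTA/FASTQ/SAM under an
output directory and records a manifest (config echo, input hashes,
package version) for reproducible reruns.  The screen stage runs when a
prediction table is supplied; it has no synthetic counterpart because
predictor scores are external input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, ecology, hostlink, phylo, screen, simulate, vc, votu
from . import __version__
from .formats import (
    read_fasta,
    read_sam,
    write_fasta,
    write_fastq,
    write_sam,
    write_table,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "cluster", "detect", "vc", "ecology", "hostlink", "dispersion")


@dataclass
class RunConfig:
    """Thresholds and paths shared by the pipeline stages."""

    out_dir: str = "peatvirome_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    min_identity: float = 0.90
    min_breadth: float = 0.75
    trim: float = 0.10
    scale: float = 1e7
    ani_thresh: float = 0.95
    cov_thresh: float = 0.85
    vc_min_score: float = 1.0
    inflation: float = 2.0
    padj: float = 0.05
    k_groups: int = 3
    max_mismatch: int = 1
    n_perm: int = 999
    n_sim: int = 1000
    min_len: int = 10_000
    truth: simulate.TruthConfig = field(default_factory=simulate.TruthConfig)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_identity", 0, 1),
            ("min_breadth", 0, 1),
            ("ani_thresh", 0, 1),
            ("cov_thresh", 0, 1),
            ("padj", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must be in [0, 0.5)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the requested stages; returns the report directory.

    Any stage failure aborts with the stage name in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = simulate.TruthConfig(**{**asdict(config.truth), "seed": config.seed})
    artifacts: dict[str, Path] = {}
    state: dict = {}

    stage = "init"
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s", stage)
            globals()[f"_stage_{stage}"](config, cfg, out, state, artifacts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "truth"},
        "truth_config": asdict(cfg),
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _stage_simulate(config, cfg, out, state, artifacts):
    contigs, proteins, gmap, habitat, truth = simulate.generate_community(cfg)
    hosts, arrays, mags = simulate.generate_hosts(cfg, truth)
    counts, meta = simulate.generate_abundance(cfg, truth)
    reads = simulate.generate_reads(truth, counts, cfg)
    state.update(
        truth=truth, contigs=contigs, proteins=proteins, genome_map=gmap,
        habitat=habitat, hosts=hosts, arrays=arrays, mags=mags,
        counts=counts, meta=meta, reads=reads,
    )
    write_fasta(contigs, out / "contigs.fasta")
    write_fasta(proteins, out / "proteins.fasta")
    write_fasta(hosts, out / "mag_contigs.fasta")
    write_table(gmap, out / "genome_map.tsv")
    write_table(habitat, out / "habitats.tsv")
    write_table(arrays, out / "crispr_arrays.tsv")
    write_table(mags, out / "mags.tsv")
    write_table(counts.reset_index(), out / "true_counts.tsv")
    write_table(meta, out / "sample_metadata.tsv")
    refs = {truth.species_rep[sp]: len(truth.rep_record(sp)) for sp in truth.species_ids}
    for sample, (fq, alns) in reads.items():
        write_fastq(fq, out / f"reads_{sample}.fastq")
        write_sam(out / f"truth_{sample}.sam", refs, alns)
    for name in ("contigs.fasta", "proteins.fasta", "mag_contigs.fasta", "genome_map.tsv",
                 "habitats.tsv", "crispr_arrays.tsv", "mags.tsv", "true_counts.tsv",
                 "sample_metadata.tsv"):
        artifacts[name] = out / name


def _stage_cluster(config, cfg, out, state, artifacts):
    contigs = state.get("contigs") or read_fasta(out / "contigs.fasta")
    clusters = votu.greedy_cluster(
        contigs, id_thresh=config.ani_thresh, cov_thresh=config.cov_thresh
    )
    state["clusters"] = clusters
    rows = []
    for cl in clusters:
        for m in cl.member_ids:
            rows.append((cl.representative_id, m, cl.rep_length))
    write_table(
        pd.DataFrame(rows, columns=["representative", "member", "rep_length"]),
        out / "votu_clusters.tsv",
    )
    by_id = {c.id: c for c in contigs}
    write_fasta(
        [by_id[cl.representative_id] for cl in clusters], out / "votu_representatives.fasta"
    )
    artifacts["votu_clusters.tsv"] = out / "votu_clusters.tsv"


def _stage_detect(config, cfg, out, state, artifacts):
    truth = state["truth"]
    meta = state["meta"]
    lib = dict(zip(meta["sample_id"], meta["library_size"].astype(int)))
    refs = {truth.species_rep[sp]: len(truth.rep_record(sp)) for sp in truth.species_ids}
    profiles: dict[str, dict[str, detection.CoverageProfile]] = {}
    for sample in meta["sample_id"]:
        alns = read_sam(out / f"truth_{sample}.sam")
        by_contig: dict[str, list] = {}
        for a in alns:
            by_contig.setdefault(a.contig_id, []).append(a)
        profiles[sample] = {
            cid: detection.coverage_profile(
                by_contig.get(cid, []), cid, clen, min_identity=config.min_identity
            )
            for cid, clen in refs.items()
        }
    table = detection.build_detection_table(
        profiles, lib, breadth_thresh=config.min_breadth, trim=config.trim, scale=config.scale
    )
    state["detection"] = table
    write_table(table.reset_index(), out / "detection_table.tsv")
    richness = detection.per_sample_richness(table)
    rich_df = richness.rename("richness").rename_axis("sample_id").reset_index()
    write_table(rich_df, out / "richness.tsv")
    artifacts["detection_table.tsv"] = out / "detection_table.tsv"


def _stage_vc(config, cfg, out, state, artifacts):
    truth = state["truth"]
    proteins = state["proteins"]
    gmap = state["genome_map"]
    rep_ids = set(truth.species_rep.values())
    rep_prot = gmap[gmap["genome_id"].isin(rep_ids)]
    keep = set(rep_prot["protein_id"])
    pcs = vc.cluster_proteins([p for p in proteins if p.id in keep])
    profiles = vc.genome_profiles(pcs, rep_prot)
    graph = vc.build_vc_graph(profiles, min_score=config.vc_min_score)
    vcs = vc.mcl(graph, inflation=config.inflation)
    habitat = {truth.species_rep[sp]: h for sp, h in truth.votu_habitat.items()}
    vc.annotate_habitats(vcs, habitat)
    state["vcs"] = vcs
    rows = [
        (x.vc_id, m, ";".join(sorted(x.habitat_set)), x.taxonomy or "")
        for x in vcs
        for m in x.member_ids
    ]
    write_table(
        pd.DataFrame(rows, columns=["vc_id", "member", "habitats", "taxonomy"]),
        out / "vc_membership.tsv",
    )
    summary = vc.summarize_clustering([p.genome_id for p in profiles], vcs)
    write_table(pd.DataFrame([asdict(summary)]), out / "vc_summary.tsv")
    overlap = vc.habitat_overlap(vcs)
    write_table(
        pd.DataFrame(
            [(";".join(sorted(k)), v) for k, v in sorted(overlap.combination_counts.items(),
                                                          key=lambda kv: sorted(kv[0]))],
            columns=["habitat_combination", "n_vcs"],
        ),
        out / "habitat_overlap.tsv",
    )
    artifacts["vc_membership.tsv"] = out / "vc_membership.tsv"
    artifacts["vc_summary.tsv"] = out / "vc_summary.tsv"


def _stage_ecology(config, cfg, out, state, artifacts):
    truth = state["truth"]
    counts = state["counts"]
    meta = state["meta"]
    nonzero = counts.index[(counts > 0).any(axis=1)]
    counts_nz = counts.loc[nonzero]
    hel = ecology.hellinger(counts_nz.T)
    dm = ecology.bray_curtis(hel)
    coords, rel = ecology.pcoa(dm)
    write_table(coords.reset_index(names="sample_id"), out / "pcoa_coordinates.tsv")
    perm = ecology.permanova(dm, meta["depth_level"], n_perm=config.n_perm, seed=config.seed)
    da = ecology.nb_lrt(counts_nz, meta["depth_level"], alpha_sig=config.padj)
    groups = ecology.depth_groups(da.significant, counts_nz, meta["depth_level"], k=config.k_groups)
    da.groups = groups
    table = da.table.copy()
    table["group"] = pd.Series(groups).reindex(table.index).fillna(0).astype(int)
    write_table(table.reset_index(), out / "differential_abundance.tsv")
    vcs = state.get("vcs")
    enrich_rows = []
    if vcs is not None:
        aquatic = vc.aquatic_like_votus(vcs)
        aquatic_sp = {sp for sp in truth.species_ids if truth.species_rep[sp] in aquatic}
        universe = set(counts_nz.index)
        group_sets: dict[int, set] = {}
        for votu_id, g in groups.items():
            group_sets.setdefault(g, set()).add(votu_id)
        for res in ecology.trait_enrichment(group_sets, aquatic_sp, universe):
            enrich_rows.append(asdict(res) | {"significant": res.significant})
        write_table(pd.DataFrame(enrich_rows), out / "trait_enrichment.tsv")
    write_table(
        pd.DataFrame(
            [{"test": "permanova_depth", "statistic": perm.pseudo_f, "p": perm.p}]
        ),
        out / "community_tests.tsv",
    )
    artifacts["differential_abundance.tsv"] = out / "differential_abundance.tsv"


def _stage_hostlink(config, cfg, out, state, artifacts):
    truth = state["truth"]
    arrays = hostlink.arrays_from_table(state["arrays"])
    mags = {rec.id: [rec] for rec in state["hosts"]}
    reps = [truth.rep_record(sp) for sp in truth.species_ids]
    taxonomy = dict(zip(state["mags"]["mag_id"], state["mags"]["taxonomy"]))
    links = hostlink.link(arrays, mags, reps, taxonomy, max_mismatch=config.max_mismatch)
    state["links"] = links
    write_table(hostlink.linkage_table(links), out / "host_linkages.tsv")
    write_table(hostlink.consensus_host_check(links), out / "host_consensus.tsv")
    artifacts["host_linkages.tsv"] = out / "host_linkages.tsv"


def _stage_dispersion(config, cfg, out, state, artifacts):
    truth = state["truth"]
    rng = np.random.default_rng(config.seed)
    tree = phylo.simulate_tree(max(8, len(truth.species_ids)), seed=config.seed)
    tips = [t.name for t in tree.tips()]
    species = truth.species_ids
    aquatic = [sp for sp in species if truth.aquatic_like[sp]]
    frac = len(aquatic) / len(species) if species else 0.5
    n_ones = max(1, min(len(tips) - 1, int(round(frac * len(tips)))))
    states = dict(zip(tips, rng.permutation([1] * n_ones + [0] * (len(tips) - n_ones))))
    res = phylo.fritz_purvis_d(tree, states, n_sim=config.n_sim, seed=config.seed)
    write_table(pd.DataFrame([asdict(res)]), out / "dispersion.tsv")
    artifacts["dispersion.tsv"] = out / "dispersion.tsv"


def run_screen(prediction_tsv: Path, out_path: Path, min_len: int = 10_000) -> pd.DataFrame:
    """Apply the viral-prediction filter to an external predictor table."""
    from .formats import read_table

    df = read_table(prediction_tsv, required=["contig_id", "length"])
    accepted = screen.filter_viral_predictions(screen.prediction_rows_from_table(df), min_len)
    outdf = pd.DataFrame(sorted(accepted.items()), columns=["contig_id", "provenance"])
    write_table(outdf, out_path)
    return outdf
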