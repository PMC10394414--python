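"""End-to-end pipeline: scan → discretize → cluster → classify → dedup →
similarity → prune → network/dendrogram → GRINS → stats.

Every run echoes its resolved configuration and writes a manifest of
per-stage counts; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional, Union

from . import grins as grins_mod
from . import io as pio
from . import network as net_mod
from . import similarity as sim_mod
from . import stats as stats_mod
from .dedup import dedup_identical
from .mining import (
    DEFAULT_MIN_LEN_AA,
    DEFAULT_MIN_SCORE,
    assemble_cluster,
    call_candidate_clusters,
    discretize_hits,
    scan_ks,
)
from .records import Catalog, MiningParams

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclasses.dataclass
class PipelineConfig:
    """Resolved inputs + thresholds of one pipeline run."""

    genomes: str
    proteins: str
    protein_locations: str
    domains: str
    metadata: Optional[str] = None
    consensus_ks: Optional[str] = None
    hits: Optional[str] = None  # pre-computed BLAST tabular hits
    out: str = "pksminer_out"
    min_score: float = DEFAULT_MIN_SCORE
    min_len_aa: int = DEFAULT_MIN_LEN_AA
    seed: int = 0
    log_level: str = "INFO"
    params: MiningParams = dataclasses.field(default_factory=MiningParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the stage-count manifest."""
    t0 = time.time()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    pio.write_params(params, outdir / "params.yaml")
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest: dict = {"stages": {}}

    def _log(stage: str, count: int):
        manifest["stages"][stage] = count
        logger.info("stage %-12s n=%d t=%.1fs", stage, count, time.time() - t0)

    # --- ingest -----------------------------------------------------------
    records = pio.read_fasta(config.genomes, "nucleotide")
    proteins = pio.read_fasta(config.proteins, "protein")
    locations = {r["protein_id"]: r for r in pio.read_protein_locations(config.protein_locations)}
    for p in proteins:
        loc = locations.get(p.id)
        if loc:
            p.record_id, p.start, p.end = loc["record_id"], loc["start"], loc["end"]
    domains = pio.read_domain_table(config.domains)
    meta = pio.read_metadata(config.metadata) if config.metadata else {}
    _log("ingest", len(records))

    # --- scan / hits ------------------------------------------------------
    hits_by_record: dict[str, list] = {}
    if config.hits:
        for h in pio.read_blast_tab(config.hits):
            hits_by_record.setdefault(h.record_id, []).append(h)
    else:
        if not config.consensus_ks:
            raise StageError("scan", "need either --hits or --consensus-ks")
        consensus = pio.read_fasta(config.consensus_ks, "protein")[0].sequence
        for rec in records:
            hits_by_record[rec.id] = scan_ks(
                rec, consensus, config.min_score, config.min_len_aa
            )
    n_hits = sum(len(v) for v in hits_by_record.values())
    all_hits = [h for rec in records for h in hits_by_record.get(rec.id, [])]
    pio.write_blast_tab(all_hits, outdir / "hits.tsv")
    _log("scan", n_hits)

    # --- discretize + cluster calling ------------------------------------
    clusters = []
    n_domains = 0
    with open(outdir / "ks_domains.bed", "w") as bed:
        for rec in records:
            hits = hits_by_record.get(rec.id, [])
            if not hits:
                continue
            ks = discretize_hits(hits, params.min_separation)
            n_domains += len(ks)
            for d in ks:
                bed.write(f"{d.record_id}\t{d.start}\t{d.end}\tKS\t{d.n_source_hits}\n")
            for ci, (rid, start, end, doms) in enumerate(
                call_candidate_clusters(ks, params.max_gap, params.min_ks)
            ):
                try:
                    cluster = assemble_cluster(
                        f"{rid}_c{ci}", rec, (start, end), doms,
                        proteins, domains, meta.get(rid),
                    )
                except ValueError as exc:
                    raise StageError("cluster", f"record {rid}: {exc}") from exc
                clusters.append(cluster)
    _log("ks_domains", n_domains)
    _log("clusters", len(clusters))
    if not clusters:
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return manifest

    # --- dedup ------------------------------------------------------------
    retained, removed_identical = dedup_identical(clusters)
    _log("dedup", len(retained))

    # --- similarity + prune ----------------------------------------------
    matrix = sim_mod.similarity_matrix(retained)
    pio.write_matrix(matrix, outdir / "similarity.tsv")
    pio.write_edges(matrix, outdir / "edges.tsv", threshold=0.0)
    catalog = sim_mod.remove_redundant(retained, matrix, params.redundancy_threshold)
    catalog.removed.update(removed_identical)
    catalog = Catalog(
        clusters=catalog.clusters,
        removed=_resolve_chains(catalog.removed, {c.cluster_id for c in catalog.clusters}),
        similarity=catalog.similarity,
    )
    pio.write_catalog(catalog, outdir / "catalog.tsv", "tsv")
    pio.write_catalog(catalog, outdir / "catalog.json", "json")
    _log("catalog", len(catalog))

    # --- network + dendrogram --------------------------------------------
    attrs = {
        c.cluster_id: {
            "pks_type": c.pks_type,
            "known_product": c.known_product,
            "phylum": c.phylum,
        }
        for c in catalog.clusters
    }
    graph = net_mod.build_network(catalog.similarity, params.network_threshold, attrs)
    net_mod.export_network(graph, outdir / "network.graphml", "graphml")
    net_mod.export_network(graph, outdir / "network.sif", "sif")
    _log("network_edges", graph.number_of_edges())
    if len(catalog) >= 2:
        tree = net_mod.build_dendrogram(catalog.similarity)
        net_mod.write_newick(tree, outdir / "dendrogram.nwk")

    # --- GRINS ------------------------------------------------------------
    detections = {
        c.cluster_id: grins_mod.detect_grins(c, params.grins)
        for c in catalog.clusters
    }
    grins_mod.write_grins_bed(detections, outdir / "grins.bed")
    grins_mod.write_grins_table(detections, outdir / "grins.tsv")
    prevalence = grins_mod.grins_prevalence(catalog, detections, "pks_type")
    prevalence.to_csv(outdir / "grins_prevalence.tsv", sep="\t", index=False)
    _log("grins_regions", sum(len(v) for v in detections.values()))

    # --- stats ------------------------------------------------------------
    stats: dict = {}
    stats["type_distribution"] = stats_mod.type_distribution(catalog)
    stats["phylum_distribution"] = stats_mod.phylum_distribution(catalog)
    if len(catalog) > 0:
        stats["orphan_fraction"] = stats_mod.orphan_fraction(catalog)
    incr, cum = stats_mod.discovery_timeseries(catalog)
    stats["discovery_incremental"] = {str(k): v for k, v in incr.items()}
    stats["discovery_cumulative"] = {str(k): v for k, v in cum.items()}
    try:
        dt, r2 = stats_mod.doubling_time(cum)
        stats["doubling_time_years"] = round(dt, 4)
        stats["doubling_time_r2"] = round(r2, 4)
    except ValueError:
        pass
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _log("stats", len(stats))

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest_path = outdir / "manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "elapsed_s"}
    with open(manifest_path, "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _resolve_chains(removed: dict[str, str], retained: set[str]) -> dict[str, str]:
    """Collapse removed→removed chains so every value is a retained id."""
    out = {}
    for k, v in removed.items():
        seen = {k}
        while v not in retained and v in removed and v not in seen:
            seen.add(v)
            v = removed[v]
        out[k] = v
    return out
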