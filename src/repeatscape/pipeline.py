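"""One-shot orchestration of all stages from a single config document.

Results only ever go to files; logging goes to stderr.  Rerunning with the
same config and seed reproduces byte-identical TSVs (fixed float formats,
sorted keys, seeded RNGs throughout).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
import pandas as pd

from . import __version__
from .clustering import ClusteringParams, greedy_cluster
from .enrichment import EnrichmentParams, scan_categories
from .io_formats import (
    read_gene_annotation,
    read_genome_index,
    read_library_fasta,
    read_repeat_annotation,
    read_tree,
    write_table,
)
from .ordination import pca, rank_abundance
from .pgls import pgls_fit
from .quantify import OccupancyTable, category_occupancy, relative_class_frequencies, window_density

log = logging.getLogger("repeatscape")

#: artifact names the manifest must list, in production order
ARTIFACTS = (
    "occupancy_class.tsv",
    "occupancy_cluster.tsv",
    "pca_scores.tsv",
    "rad.tsv",
    "windows.bed",
    "enrichment.tsv",
    "pgls.json",
)


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> None:
    genomes = config.get("genomes")
    if not genomes:
        raise ConfigError("config must list at least one genome")
    for g in genomes:
        for key in ("genome_id", "out", "index"):
            if key not in g:
                raise ConfigError(f"genome entry missing {key!r}")
        for key in ("out", "index", "gff3"):
            if key in g and not Path(g[key]).exists():
                raise ConfigError(f"{g['genome_id']}: missing input file {g[key]}")
    for key in ("library", "tree", "traits"):
        if key in config and not Path(config[key]).exists():
            raise ConfigError(f"missing input file {config[key]}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def full_run(config: dict, outdir) -> dict:
    """Run every stage and write the result bundle plus a run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    counts: dict[str, int] = {}

    # --- parse + cluster -------------------------------------------------
    library = read_library_fasta(config["library"]) if "library" in config else []
    cluster_map: dict[str, str] = {}
    if library:
        params = ClusteringParams(**config.get("clustering", {}))
        assignment = _cluster_stage([(r.name, r.sequence) for r in library], params)
        write_table(assignment.to_frame(), outdir / "clusters.tsv")
        cluster_map = {
            name: f"cl{cid:05d}" for name, cid in assignment.cluster_of.items()
        }
        counts["clusters"] = assignment.n_clusters

    genomes = {}
    for entry in config["genomes"]:
        gid = entry["genome_id"]
        index = read_genome_index(entry["index"], genome_id=gid)
        hits, _ = read_repeat_annotation(entry["out"], genome_id=gid, index=index)
        for h in hits:
            h.cluster_id = cluster_map.get(h.repeat_name)
        genes = (
            read_gene_annotation(entry["gff3"], index=index) if "gff3" in entry else []
        )
        genomes[gid] = (index, hits, genes)
        counts[f"hits:{gid}"] = len(hits)

    # --- occupancy -------------------------------------------------------
    by_class = OccupancyTable.from_rows(
        [_occ(hits, index, "class") for index, hits, _ in genomes.values()]
    )
    frame = by_class.proportions.copy()
    frame["total"] = by_class.totals
    write_table(frame, outdir / "occupancy_class.tsv", index=True)

    cluster_ready = all(
        all(h.cluster_id is not None for h in hits) for _, hits, _ in genomes.values()
    ) and any(len(hits) for _, hits, _ in genomes.values())
    if cluster_ready:
        by_cluster = OccupancyTable.from_rows(
            [_occ(hits, index, "cluster") for index, hits, _ in genomes.values()]
        )
    else:  # degenerate fallback keeps the bundle shape stable
        by_cluster = by_class
    write_table(by_cluster.proportions, outdir / "occupancy_cluster.tsv", index=True)

    # --- ordination + RAD ------------------------------------------------
    preset = config.get("pca", {})
    if len(genomes) >= 2 and by_class.proportions.shape[1] >= 2:
        rel = relative_class_frequencies(by_class.proportions)
        result = pca(rel, scale=bool(preset.get("scale", False)))
        write_table(result.scores, outdir / "pca_scores.tsv", index=True)
        write_table(result.loadings, outdir / "pca_loadings.tsv", index=True)
        write_table(
            pd.DataFrame(
                {"component": result.scores.columns, "variance_explained": result.variance_explained}
            ),
            outdir / "pca_variance.tsv",
        )
    else:
        raise RuntimeError("stage 'ordinate' failed: need >= 2 genomes and categories")

    top_n = int(config.get("rad", {}).get("top_n", 100))
    rad_frames = []
    for gid in genomes:
        rad = rank_abundance(by_cluster.proportions.loc[gid], gid, top_n=top_n)
        t = rad.table.copy()
        t.insert(0, "genome_id", gid)
        rad_frames.append(t)
    write_table(pd.concat(rad_frames, ignore_index=True), outdir / "rad.tsv")

    # --- windows ---------------------------------------------------------
    window_size = int(config.get("window_size", 100_000))
    bed_frames = []
    for gid, (index, hits, _) in genomes.items():
        track = window_density(hits, index, window_size=window_size)
        t = track.windows.copy()
        t.insert(0, "genome_id", gid)
        bed_frames.append(t)
        counts[f"windows:{gid}"] = len(t)
    pd.concat(bed_frames, ignore_index=True)[
        ["seq_id", "start", "end", "proportion", "genome_id"]
    ].to_csv(outdir / "windows.bed", sep="\t", header=False, index=False, float_format="%.6g")

    # --- enrichment ------------------------------------------------------
    enrich_cfg = config.get("enrichment", {})
    rows = []
    if enrich_cfg:
        gid = enrich_cfg["genome_id"]
        index, hits, genes = genomes[gid]
        focal_ids = set(enrich_cfg["focal_genes"])
        focal = [g for g in genes if g.gene_id in focal_ids or g.family_id in focal_ids]
        if not focal:
            raise RuntimeError(
                f"stage 'enrich' failed: no genes matched focal set in {gid}"
            )
        params = EnrichmentParams(
            flank=int(enrich_cfg.get("flank", 1000)),
            n_resamples=int(enrich_cfg.get("n_resamples", 499)),
            fdr_level=float(enrich_cfg.get("fdr_level", 0.1)),
            seed=seed,
        )
        results = scan_categories(
            focal, hits, genes, enrich_cfg["categories"], index, params,
            gene_set_id=enrich_cfg.get("gene_set_id", "focal"),
        )
        rows = [r.as_row() for r in results]
        counts["enrichment_tests"] = len(rows)
    write_table(
        pd.DataFrame(rows, columns=["gene_set", "category", "m", "observed",
                                    "null_mean", "fold", "p_emp", "q_bh"]),
        outdir / "enrichment.tsv",
    )

    # --- pgls ------------------------------------------------------------
    pgls_report: dict = {}
    if "tree" in config and "traits" in config:
        tree = read_tree(config["tree"])
        traits = pd.read_csv(config["traits"], sep="\t")
        cols = config.get("pgls", {})
        fit = pgls_fit(
            traits, tree,
            x_col=cols.get("x_col", "assembly_mb"),
            y_col=cols.get("y_col", "repeat_prop"),
        )
        pgls_report = fit.as_dict()
    with open(outdir / "pgls.json", "w") as fh:
        json.dump(pgls_report, fh, indent=1, sort_keys=True)

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "artifacts": list(ARTIFACTS),
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


_cluster_stage = _stage("cluster")(greedy_cluster)


@_stage("quantify")
def _occ(hits, index, group_by):
    return category_occupancy(hits, index, group_by=group_by)
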