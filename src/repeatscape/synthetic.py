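"""Seed-deterministic synthetic inputs with known planted truth.

Repeat copies are placed without intra-class overlap using a budgeted
stars-and-bars scheme, so realized densities track their targets closely; a
planted enrichment multiplies the placement budget for one category inside
the flank regions of a chosen gene set so the expected flank/background
density ratio equals the planted fold.  Every generated artifact is a pure
function of (config, seed), and the truth record stores both planted and
realized quantities so estimator error can be separated from sampling noise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import enrichment as enr
from .io_formats import (
    GeneRecord,
    GenomeIndex,
    LibraryRecord,
    PhyloTree,
    tree_from_newick,
    write_gene_annotation,
    write_genome_index,
    write_library_fasta,
    write_repeat_annotation,
)
from .pgls import tree_vcv
from .quantify import GenomeIntervals

__all__ = [
    "PlantedEnrichment",
    "SimulationConfig",
    "SimulatedGenome",
    "make_library",
    "plant_genome",
    "simulate_bm_traits",
    "random_ultrametric_tree",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CLASSES: dict[str, float] = {
    "LINE/BovB": 0.04,
    "DNA/TcMar-Tc1": 0.04,
    "DNA/TcMar-Tigger": 0.03,
    "Unknown": 0.03,
}


@dataclass
class PlantedEnrichment:
    gene_set_id: str
    m: int
    category: str
    fold: float
    flank: int = 1000

    def __post_init__(self) -> None:
        if self.fold < 0:
            raise ValueError("planted fold must be >= 0")
        if self.m < 1:
            raise ValueError("focal set size must be >= 1")


@dataclass
class SimulationConfig:
    seed: int
    genome_id: str = "sim"
    seq_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000}
    )
    classes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    families_per_class: int = 3
    family_length_range: tuple[int, int] = (300, 800)
    divergence_range: tuple[float, float] = (0.0, 25.0)
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 3000)
    enrichments: list[PlantedEnrichment] = field(default_factory=list)
    max_fill: float = 0.85  # cap on the fillable fraction of any segment

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for cls, d in self.classes.items():
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"density for {cls} out of [0, 1]: {d}")
        cats = [e.category for e in self.enrichments]
        if len(set(cats)) != len(cats):
            raise ValueError("at most one planted enrichment per category")


def make_library(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[LibraryRecord]:
    """Random consensus sequences, ``families_per_class`` per class."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.family_length_range
    records = []
    i = 0
    for cls in config.classes:
        for _ in range(config.families_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")
            records.append(LibraryRecord(f"fam{i:04d}", cls, seq))
            i += 1
    return records


# ---------------------------------------------------------------------------
# Placement machinery
# ---------------------------------------------------------------------------


def _draw_copy_lengths(
    rng: np.random.Generator, target_bp: float, families: Sequence[LibraryRecord]
) -> list[int]:
    """Family indices drawn until cumulative length is closest to target."""
    chosen: list[int] = []
    cum = 0
    while True:
        fam = int(rng.integers(len(families)))
        length = len(families[fam].sequence)
        if abs(cum + length - target_bp) >= abs(cum - target_bp):
            break  # adding would not improve; stop at the closest total
        chosen.append(fam)
        cum += length
    return chosen


def _place_in_segments(
    rng: np.random.Generator,
    segments: Sequence[tuple[str, int, int]],
    density: float,
    families: Sequence[LibraryRecord],
    max_fill: float,
) -> list[tuple[str, int, int, int]]:
    """Place non-overlapping copies at ``density`` pooled over ``segments``.

    Returns (seq_id, start, end, family_index) tuples.  Copies are assigned to
    segments with probability proportional to remaining capacity, then spread
    uniformly within each segment via the stars-and-bars construction.
    """
    seg_lens = np.array([e - s for _, s, e in segments], dtype=float)
    total = seg_lens.sum()
    if total <= 0 or density <= 0:
        return []
    if density > max_fill:
        raise ValueError(
            f"requested density {density:.3f} exceeds the feasible fill "
            f"fraction {max_fill}; lower the density or the planted fold"
        )
    target = density * total
    fam_idx = _draw_copy_lengths(rng, target, families)
    if not fam_idx:
        return []
    capacity = max_fill * seg_lens
    used = np.zeros(len(segments))
    per_seg: list[list[int]] = [[] for _ in segments]
    for fi in fam_idx:
        length = len(families[fi].sequence)
        free = capacity - used
        feasible = free >= length
        if not feasible.any():
            continue  # quantization leftover; realized density is recorded anyway
        probs = np.where(feasible, free, 0.0)
        probs /= probs.sum()
        pick = int(rng.choice(len(segments), p=probs))
        per_seg[pick].append(fi)
        used[pick] += length
    placed: list[tuple[str, int, int, int]] = []
    for (seq, s, e), fams in zip(segments, per_seg):
        if not fams:
            continue
        fams = list(fams)
        rng.shuffle(fams)
        lengths = np.array([len(families[f].sequence) for f in fams])
        free_space = (e - s) - lengths.sum()
        gaps = np.sort(rng.uniform(0, free_space, size=len(fams)))
        offsets = np.concatenate(([0], np.cumsum(lengths[:-1])))
        starts = (s + gaps + offsets).astype(np.int64)
        for fi, cs, length in zip(fams, starts, lengths):
            placed.append((seq, int(cs), int(cs + length), fi))
    return placed


def _complement_segments(
    index: GenomeIndex, regions: Mapping[str, np.ndarray]
) -> list[tuple[str, int, int]]:
    out = []
    for seq, length in index.lengths.items():
        prev = 0
        for s, e in regions.get(seq, np.empty((0, 2), dtype=np.int64)):
            if s > prev:
                out.append((seq, prev, int(s)))
            prev = int(e)
        if prev < length:
            out.append((seq, prev, length))
    return out


def _place_genes(
    rng: np.random.Generator, config: SimulationConfig, index: GenomeIndex
) -> list[GeneRecord]:
    lo, hi = config.gene_length_range
    seqs = list(index.lengths)
    seq_lens = np.array([index.lengths[s] for s in seqs], dtype=float)
    counts = rng.multinomial(config.n_genes, seq_lens / seq_lens.sum())
    genes: list[GeneRecord] = []
    gi = 0
    for seq, k in zip(seqs, counts):
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        if lengths.sum() > 0.5 * index.lengths[seq]:
            raise ValueError(
                f"gene models would occupy more than half of {seq}; "
                "reduce n_genes or gene lengths"
            )
        free_space = index.lengths[seq] - lengths.sum()
        gaps = np.sort(rng.uniform(0, free_space, size=k))
        offsets = np.concatenate(([0], np.cumsum(lengths[:-1])))
        starts = (gaps + offsets).astype(np.int64)
        for s, length in zip(starts, lengths):
            genes.append(
                GeneRecord(
                    gene_id=f"g{gi:05d}",
                    seq_id=seq,
                    start=int(s),
                    end=int(s + length),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            gi += 1
    return genes


@dataclass
class SimulatedGenome:
    """One synthetic genome: annotations, gene models, library, and truth."""

    config: SimulationConfig
    index: GenomeIndex
    library: list[LibraryRecord]
    hits: list  # RepeatHit
    genes: list[GeneRecord]
    truth: dict

    def focal_genes(self, gene_set_id: str) -> list[GeneRecord]:
        ids = set(self.truth["gene_sets"][gene_set_id])
        return [g for g in self.genes if g.gene_id in ids]

    def write(self, outdir, genome_fasta: bool = False) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gid = self.config.genome_id
        paths = {
            "out": str(outdir / f"{gid}.out"),
            "gff3": str(outdir / f"{gid}.gff3"),
            "index": str(outdir / f"{gid}.fai"),
            "library": str(outdir / "library.fasta"),
            "truth": str(outdir / "truth.json"),
        }
        write_repeat_annotation(self.hits, paths["out"])
        write_gene_annotation(self.genes, paths["gff3"])
        write_genome_index(self.index, paths["index"])
        write_library_fasta(self.library, paths["library"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        if genome_fasta:
            paths["fasta"] = str(outdir / f"{gid}.fasta")
            self.write_genome_fasta(paths["fasta"])
        return paths

    def write_genome_fasta(self, path) -> None:
        """Materialize sequences: random background with mutated copies pasted in."""
        from .clustering import reverse_complement

        rng = np.random.default_rng(self.config.seed + 1_000_003)
        fam_by_name = {r.name: r for r in self.library}
        with open(path, "w") as fh:
            for seq_id, length in self.index.lengths.items():
                arr = _BASES[rng.integers(0, 4, size=length)].copy()
                for h in self.hits:
                    if h.seq_id != seq_id:
                        continue
                    consensus = fam_by_name[h.repeat_name].sequence
                    if h.strand == "-":
                        consensus = reverse_complement(consensus)
                    copy = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
                    n_mut = int(round(h.divergence_pct / 100.0 * len(copy)))
                    if n_mut:
                        pos = rng.choice(len(copy), size=n_mut, replace=False)
                        copy[pos] = _BASES[rng.integers(0, 4, size=n_mut)]
                    arr[h.start : h.start + len(copy)] = copy[: length - h.start]
                fh.write(f">{seq_id}\n")
                seq = bytes(arr).decode("ascii")
                for i in range(0, length, 80):
                    fh.write(seq[i : i + 80] + "\n")


def plant_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate one genome's worth of inputs with planted repeat structure."""
    from .io_formats import RepeatHit

    rng = np.random.default_rng(config.seed)
    index = GenomeIndex(config.genome_id, dict(config.seq_lengths))
    library = make_library(config, rng)
    fam_cluster = {rec.name: f"cl{i:04d}" for i, rec in enumerate(library)}
    by_class: dict[str, list[LibraryRecord]] = {}
    for rec in library:
        by_class.setdefault(rec.class_string, []).append(rec)

    genes = _place_genes(rng, config, index)

    # focal gene sets (one sample per distinct gene_set_id)
    gene_sets: dict[str, list[GeneRecord]] = {}
    for e in config.enrichments:
        if e.gene_set_id not in gene_sets:
            picks = rng.choice(len(genes), size=e.m, replace=False)
            chosen = [genes[i] for i in sorted(picks)]
            for g in chosen:
                g.family_id = e.gene_set_id
            gene_sets[e.gene_set_id] = chosen
        elif len(gene_sets[e.gene_set_id]) != e.m:
            raise ValueError(f"conflicting sizes for gene set {e.gene_set_id!r}")

    enr_by_class = {e.category: e for e in config.enrichments}
    lo_div, hi_div = config.divergence_range

    hits: list[RepeatHit] = []
    placements: dict[str, list[tuple[str, int, int, int]]] = {}
    for cls, density in config.classes.items():
        fams = by_class[cls]
        planted = enr_by_class.get(cls)
        if planted is not None and planted.fold != 1.0:
            focal_regions = enr.flank_regions(
                gene_sets[planted.gene_set_id], planted.flank, index
            )
            focal_segments = [
                (seq, int(s), int(e))
                for seq, arr in focal_regions.items()
                for s, e in arr
            ]
            comp_segments = _complement_segments(index, focal_regions)
            placed = _place_in_segments(
                rng, focal_segments, planted.fold * density, fams, config.max_fill
            )
            placed += _place_in_segments(
                rng, comp_segments, density, fams, config.max_fill
            )
        else:
            segments = [(seq, 0, length) for seq, length in index.lengths.items()]
            placed = _place_in_segments(rng, segments, density, fams, config.max_fill)
        placements[cls] = placed
        for seq, s, e, fi in placed:
            fam = fams[fi]
            hits.append(
                RepeatHit(
                    seq_id=seq,
                    start=s,
                    end=e,
                    strand="+" if rng.random() < 0.5 else "-",
                    repeat_name=fam.name,
                    repeat_class=cls,
                    divergence_pct=float(np.round(rng.uniform(lo_div, hi_div), 1)),
                    score=float(rng.integers(200, 5000)),
                    cluster_id=fam_cluster[fam.name],
                )
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end, h.repeat_name))

    truth = _truth_record(config, index, hits, genes, gene_sets)
    return SimulatedGenome(config, index, library, hits, genes, truth)


def _truth_record(config, index, hits, genes, gene_sets) -> dict:
    size = index.assembly_size
    realized_class = {}
    for cls in config.classes:
        gi = GenomeIntervals.from_hits([h for h in hits if h.repeat_class == cls])
        realized_class[cls] = gi.total_bp / size
    union = GenomeIntervals.from_hits(hits)
    enrich_truth = []
    for e in config.enrichments:
        focal = gene_sets[e.gene_set_id]
        regions = enr.flank_regions(focal, e.flank, index)
        region_bp = sum(int((a[:, 1] - a[:, 0]).sum()) for a in regions.values())
        gi = GenomeIntervals.from_hits(
            [h for h in hits if h.repeat_class == e.category]
        )
        focal_bp = gi.intersect_bp(regions)
        comp_bp = size - region_bp
        bg_bp = gi.total_bp - focal_bp
        focal_density = focal_bp / region_bp
        bg_density = bg_bp / comp_bp
        enrich_truth.append(
            {
                "gene_set_id": e.gene_set_id,
                "category": e.category,
                "m": e.m,
                "flank": e.flank,
                "planted_fold": e.fold,
                "realized_focal_density": focal_density,
                "realized_background_density": bg_density,
                "realized_fold": (focal_density / bg_density) if bg_density > 0 else None,
            }
        )
    return {
        "seed": config.seed,
        "genome_id": config.genome_id,
        "assembly_size": size,
        "target_class_density": dict(config.classes),
        "realized_class_density": realized_class,
        "realized_union_bp": union.total_bp,
        "realized_total_proportion": union.total_bp / size,
        "gene_sets": {k: [g.gene_id for g in v] for k, v in gene_sets.items()},
        "enrichments": enrich_truth,
    }


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------


def random_ultrametric_tree(n_tips: int, seed: int, depth: float = 1.0) -> PhyloTree:
    """Random coalescent-style ultrametric tree with root-to-tip depth ``depth``."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    heights = np.cumsum(rng.exponential(1.0, size=n_tips - 1))
    heights *= depth / heights[-1]
    nodes: list[tuple[str, float]] = [(f"t{i + 1}", 0.0) for i in range(n_tips)]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (ra, ha), (rb, hb) = nodes[i], nodes[j]
        merged = (f"({ra}:{h - ha:.10f},{rb}:{h - hb:.10f})", float(h))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return tree_from_newick(nodes[0][0] + ";")


def simulate_bm_traits(
    tree: PhyloTree,
    a: float,
    b: float,
    sigma2: float,
    x_values: Mapping[str, float],
    seed: int,
    x_col: str = "assembly_mb",
    y_col: str = "repeat_prop",
) -> pd.DataFrame:
    """y = a + b*x + eps with eps ~ MVN(0, sigma2 * V(tree)); seed-deterministic."""
    labels, V = tree_vcv(tree)
    missing = [l for l in labels if l not in x_values]
    if missing:
        raise ValueError(f"x_values missing tips: {missing}")
    rng = np.random.default_rng(seed)
    x = np.array([x_values[l] for l in labels], dtype=float)
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        eps = np.zeros(len(labels))
    else:
        L = np.linalg.cholesky(sigma2 * V)
        eps = L @ rng.standard_normal(len(labels))
    y = a + b * x + eps
    return pd.DataFrame({"genome_id": labels, x_col: x, y_col: y})
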