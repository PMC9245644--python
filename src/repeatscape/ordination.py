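"""Ordination of genomes in repeat space and rank-abundance profiling.

Two documented presets: class-level PCA runs on within-repeatome relative
frequencies, cluster-level PCA on proportion-of-genome-length occupancies.
The default PCA is centered and unscaled (inputs are commensurate
proportions); pass ``scale=True`` for correlation-matrix behaviour.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "pca",
    "RankAbundance",
    "rank_abundance",
    "cross_genome_rank_table",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame          # genomes x components
    loadings: pd.DataFrame        # categories x components (orthonormal cols)
    variance_explained: np.ndarray
    center: pd.Series
    scaled: bool

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Principal components of a genomes-x-categories matrix via SVD.

    Columns are centered; with ``scale`` they are additionally divided by
    their sample standard deviation (zero-variance columns are dropped with a
    warning first).  Loading columns have unit norm and a deterministic sign:
    the largest-magnitude element of each is positive.  With all components
    retained, ``centered data == scores @ loadings.T`` to numerical tolerance.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows (genomes)")
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 columns (categories)")
    if matrix.isna().any().any():
        raise ValueError("PCA input contains missing cells")
    X = matrix.astype(float)
    if scale:
        std = X.std(axis=0, ddof=1)
        dead = std.index[std == 0.0]
        if len(dead):
            warnings.warn(
                f"dropping zero-variance columns before scaling: {list(dead)}",
                stacklevel=2,
            )
            X = X.drop(columns=list(dead))
            std = std.drop(list(dead))
            if X.shape[1] < 2:
                raise ValueError("fewer than 2 columns left after dropping")
    center = X.mean(axis=0)
    Xc = X - center
    if scale:
        Xc = Xc / std
    U, s, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    # deterministic sign: largest-|loading| element of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    n = Xc.shape[0]
    eigvals = s**2 / (n - 1)
    total_var = Xc.to_numpy().var(axis=0, ddof=1).sum()
    var_explained = eigvals / total_var if total_var > 0 else np.zeros_like(eigvals)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp_names)
    return PCAResult(scores, loadings, var_explained, center, scale)


@dataclass
class RankAbundance:
    """Clusters of one genome ordered by decreasing abundance."""

    genome_id: str
    table: pd.DataFrame  # rank, cluster_id, abundance
    top_n: Optional[int]


def rank_abundance(
    abundances: Union[Mapping[str, float], pd.Series],
    genome_id: str,
    top_n: Optional[int] = 100,
) -> RankAbundance:
    """Sort cluster abundances descending (ties by cluster_id) and rank them.

    Zero-abundance clusters are treated as absent.  ``top_n=None`` keeps all.
    """
    series = pd.Series(dict(abundances), dtype=float)
    series = series[series > 0]
    frame = (
        series.rename("abundance")
        .rename_axis("cluster_id")
        .reset_index()
        .sort_values(["abundance", "cluster_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    if top_n is not None:
        frame = frame.head(top_n)
    return RankAbundance(genome_id, frame, top_n)


def cross_genome_rank_table(
    rads: Mapping[str, RankAbundance],
    reference_genome: str,
    k: int = 15,
) -> pd.DataFrame:
    """Rank of the reference genome's top-k clusters in every other genome.

    ``rads`` should hold *untruncated* rank tables (``top_n=None``) so ranks
    beyond the display cutoff are resolvable; clusters absent from a genome
    get NA.
    """
    if reference_genome not in rads:
        raise KeyError(f"reference genome {reference_genome!r} not in rads")
    ref = rads[reference_genome].table.head(k)
    out = ref[["rank", "cluster_id"]].rename(columns={"rank": f"rank_{reference_genome}"})
    for gid, rad in rads.items():
        if gid == reference_genome:
            continue
        lookup = rad.table.set_index("cluster_id")["rank"]
        out[f"rank_{gid}"] = [
            lookup.get(c, pd.NA) for c in out["cluster_id"]
        ]
    return out.reset_index(drop=True)
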