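"""Phylogenetic generalized least squares under a Brownian-motion covariance.

The error covariance is proportional to V, where V[i, j] is the shared
root-to-MRCA path length of tips i and j.  Estimation uses a Cholesky
factorization of V (never an explicit inverse); with a star phylogeny V is
proportional to the identity and the fit reduces to ordinary least squares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular

from .io_formats import PhyloTree

__all__ = ["tree_vcv", "PGLSFit", "pgls_fit"]


def tree_vcv(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Brownian covariance matrix: shared path length from root to each MRCA.

    Returns ``(tip_labels, V)`` with V[i, i] the root-to-tip depth of tip i.
    """
    t = tree.tree
    depth: dict = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaves = [leaf for leaf in t.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)
    tip_depth = np.array([depth[leaf] for leaf in leaves])
    pdm = t.phylogenetic_distance_matrix()
    V = np.empty((n, n))
    for i in range(n):
        V[i, i] = tip_depth[i]
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            V[i, j] = V[j, i] = 0.5 * (tip_depth[i] + tip_depth[j] - patristic)
    return labels, V


@dataclass
class PGLSFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    tstat: float
    df: int
    pvalue: float
    sigma2: float
    residuals: np.ndarray            # raw residuals, tree tip order
    whitened_residuals: np.ndarray   # L^-1 (y - X beta)

    def as_dict(self) -> dict:
        return {
            "a": self.intercept,
            "b": self.slope,
            "se_a": self.se_intercept,
            "se_b": self.se_slope,
            "t": self.tstat,
            "df": self.df,
            "p": self.pvalue,
            "sigma2": self.sigma2,
        }


def pgls_fit(
    traits: pd.DataFrame,
    tree: PhyloTree,
    x_col: str = "assembly_mb",
    y_col: str = "repeat_prop",
    id_col: str = "genome_id",
) -> PGLSFit:
    """Regress ``y_col`` on ``x_col`` with Brownian phylogenetic covariance.

    Every trait row's id must be a tree tip; rows are reordered to match the
    tree internally.  df = n - 2; the two-sided p comes from Student's t and
    is floored at the smallest positive double for perfect fits.
    """
    labels, V = tree_vcv(tree)
    table = traits.set_index(id_col) if id_col in traits.columns else traits
    missing = [l for l in labels if l not in table.index]
    if missing:
        raise ValueError(f"trait table lacks tree tips: {missing}")
    extra = [i for i in table.index if i not in set(labels)]
    if extra:
        raise ValueError(f"trait rows not present in tree: {extra}")
    table = table.loc[labels]
    if table[[x_col, y_col]].isna().any().any():
        raise ValueError("trait table contains missing values")
    n = len(labels)
    if n < 3:
        raise ValueError("PGLS needs at least 3 tips")

    x = table[x_col].to_numpy(float)
    y = table[y_col].to_numpy(float)
    X = np.column_stack([np.ones(n), x])
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance is singular (zero-length terminal or "
            "identical tip paths); all branch lengths must be positive"
        ) from exc
    L = np.tril(c)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = y - X @ beta
    rw = solve_triangular(L, resid, lower=True)
    df = n - 2
    sigma2 = float(rw @ rw) / df
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore"):
        tstat = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1])
    p = 2.0 * stats.t.sf(abs(tstat), df)
    p = max(float(p), np.finfo(float).tiny)  # overflow-safe floor
    return PGLSFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        tstat=float(tstat),
        df=df,
        pvalue=p,
        sigma2=sigma2,
        residuals=resid,
        whitened_residuals=rw,
    )
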