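"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately avoids the library code paths it checks: plain
Python DP for alignment, per-base boolean masks for interval arithmetic,
explicit matrix inverses for regression, and hand enumeration for the greedy
clustering rule.
"""
from __future__ import annotations

import numpy as np


def nw_identity(a: str, b: str) -> float:
    """Matching-column fraction of a global alignment, naive full-table DP.

    Match +1, mismatch -1, gap -1; traceback ties resolved diagonal > up >
    left; inputs put in canonical order (longer first, then lexicographic)
    exactly as the contract states.
    """
    a, b = a.upper(), b.upper()
    if (len(b), b) > (len(a), a):
        a, b = b, a
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        H[i][0] = -i
    for j in range(m + 1):
        H[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - 1, H[i][j - 1] - 1)
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and H[i][j] == H[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


def greedy_cluster_reference(library, threshold):
    """Reference greedy rule: length-descending order, first centroid match.

    Uses :func:`nw_identity` for every comparison (no prefilter).  Returns
    (cluster_of, centroid_of) dicts with integer cluster ids.
    """
    items = sorted(((name, seq.upper()) for name, seq in library),
                   key=lambda it: (-len(it[1]), it[0]))
    centroids = []  # (cid, seq)
    cluster_of, centroid_of = {}, {}
    for name, seq in items:
        for cid, cseq in centroids:
            if nw_identity(seq, cseq) >= threshold:
                cluster_of[name] = cid
                break
        else:
            cid = len(centroids)
            centroids.append((cid, seq))
            cluster_of[name] = cid
            centroid_of[cid] = name
    return cluster_of, centroid_of


def bitmask_coverage(intervals, length: int) -> np.ndarray:
    """Per-base boolean mask from half-open intervals on one sequence."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def bitmask_total(intervals, length: int) -> int:
    return int(bitmask_coverage(intervals, length).sum())


def pca_eigen_oracle(X: np.ndarray):
    """Eigendecomposition of the explicit covariance matrix of centered X."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order], Xc


def gls_dense_oracle(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS by explicit inverse: beta, se, t for the slope, sigma2."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.inv(XtVi @ X) @ XtVi @ y
    r = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(r @ Vi @ r) / df
    cov = sigma2 * np.linalg.inv(XtVi @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, beta[1] / se[1], sigma2


def vcv_path_oracle(newick: str):
    """Shared root-to-MRCA path lengths by explicit path enumeration.

    Parses the newick with dendropy, records each leaf's root-to-leaf edge
    path, and sums the lengths of the shared prefix for every pair.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(path))
    labels = sorted(paths)
    n = len(labels)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = 0.0
            for (na, la), (nb, lb) in zip(paths[labels[i]], paths[labels[j]]):
                if na != nb:
                    break
                shared += la
            V[i, j] = shared
    return labels, V
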