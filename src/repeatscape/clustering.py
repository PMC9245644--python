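"""Greedy centroid clustering of repeat consensus sequences at a fixed identity.

Identity between two sequences is the fraction of matching columns over all
columns (gaps included) of a global alignment under unit match/mismatch/gap
costs (match +1, mismatch -1, gap -1).  Ties during traceback are resolved
diagonal > up > left; to keep the value symmetric the two inputs are put in a
canonical order (longer first, ties by lexicographic name of the string
itself) before aligning.

The clustering rule: sequences are processed in length-descending order (ties
broken by name), each is compared against existing centroids in creation
order after an optional shared-k-mer prefilter, and joins the first centroid
with identity >= theta, else founds a new centroid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusteringParams",
    "ClusterAssignment",
    "pairwise_identity",
    "greedy_cluster",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ClusteringParams:
    identity_threshold: float = 0.80
    kmer_size: int = 8
    min_kmer_fraction: float = 0.05
    both_strands: bool = False
    min_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")
        if self.min_kmer_fraction < 0:
            raise ValueError("min_kmer_fraction must be >= 0")


@dataclass
class ClusterAssignment:
    """Partition of a library into centroid-defined clusters."""

    cluster_of: dict[str, int] = field(default_factory=dict)
    centroid_of: dict[int, str] = field(default_factory=dict)
    identity_to_centroid: dict[str, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_of)

    def members(self, cluster_id: int) -> list[str]:
        return [n for n, c in self.cluster_of.items() if c == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_name": name,
                "cluster_id": cid,
                "centroid_name": self.centroid_of[cid],
                "identity": self.identity_to_centroid[name],
            }
            for name, cid in sorted(self.cluster_of.items())
        ]
        return pd.DataFrame(
            rows, columns=["sequence_name", "cluster_id", "centroid_name", "identity"]
        )


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------


def _nw_matrix(a: str, b: str) -> np.ndarray:
    """Needleman-Wunsch score matrix (match +1, mismatch -1, gap -1).

    Row recurrence uses a running-max trick so each row is fully vectorized:
    cur[j] = max(d[j], cur[j-1] - 1) == max_{k<=j}(d[k] + k) - j.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    idx = np.arange(m + 1, dtype=np.int32)
    H[0] = -idx
    d = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(bv == av[i - 1], 1, -1).astype(np.int32)
        d[0] = -i
        np.maximum(prev[:-1] + sub, prev[1:] - 1, out=d[1:])
        H[i] = np.maximum.accumulate(d + idx) - idx
    return H


def _traceback_identity(a: str, b: str, H: np.ndarray) -> float:
    i, j = len(a), len(b)
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = 1 if a[i - 1] == b[j - 1] else -1
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += s == 1
                i -= 1
                j -= 1
                columns += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in a global alignment of ``a`` and ``b``.

    Symmetric by construction; 1.0 for identical sequences.  Raises on empty
    input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    # canonical order => identity(a, b) == identity(b, a) despite tie-breaks
    if (len(b), b) > (len(a), a):
        a, b = b, a
    H = _nw_matrix(a, b)
    return _traceback_identity(a, b, H)


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> frozenset:
    if len(seq) < k:
        return frozenset()
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _prefilter_pass(query_kmers: frozenset, centroid_kmers: frozenset, min_frac: float) -> bool:
    if min_frac <= 0.0 or not query_kmers:
        return True
    shared = len(query_kmers & centroid_kmers)
    return shared / len(query_kmers) >= min_frac


def greedy_cluster(
    library: Sequence[tuple[str, str]],
    params: Optional[ClusteringParams] = None,
) -> ClusterAssignment:
    """Cluster ``(name, sequence)`` pairs greedily at ``identity_threshold``.

    Deterministic: the order of processing and first-match assignment are
    fully specified, so identical inputs give byte-identical tables.
    """
    params = params or ClusteringParams()
    names = [name for name, _ in library]
    if len(set(names)) != len(names):
        raise ValueError("library sequence names must be unique")

    items = [(name, seq.upper()) for name, seq in library if len(seq) >= params.min_length]
    items.sort(key=lambda it: (-len(it[1]), it[0]))

    assignment = ClusterAssignment()
    centroids: list[tuple[int, str, str, frozenset]] = []  # (cid, name, seq, kmers)
    for name, seq in items:
        qk = _kmer_set(seq, params.kmer_size)
        qk_rc = (
            _kmer_set(reverse_complement(seq), params.kmer_size)
            if params.both_strands
            else frozenset()
        )
        assigned = False
        for cid, _cname, cseq, ck in centroids:
            fwd_ok = _prefilter_pass(qk, ck, params.min_kmer_fraction)
            rc_ok = params.both_strands and _prefilter_pass(
                qk_rc, ck, params.min_kmer_fraction
            )
            if not (fwd_ok or rc_ok):
                continue
            ident = pairwise_identity(seq, cseq) if fwd_ok else 0.0
            if params.both_strands and rc_ok:
                ident = max(ident, pairwise_identity(reverse_complement(seq), cseq))
            if ident >= params.identity_threshold:
                assignment.cluster_of[name] = cid
                assignment.identity_to_centroid[name] = ident
                assigned = True
                break
        if not assigned:
            cid = len(centroids)
            centroids.append((cid, name, seq, qk))
            assignment.cluster_of[name] = cid
            assignment.centroid_of[cid] = name
            assignment.identity_to_centroid[name] = 1.0
    return assignment
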