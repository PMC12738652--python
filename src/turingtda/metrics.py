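"""Wasserstein distances between persistence diagrams, the composite
node metric on the Turing space, and hierarchical clustering with
silhouette-based model selection.

The q-Wasserstein distance W_{p,q} matches diagram points to each other or
to the diagonal, with ground cost the l_p norm on (birth, death) pairs and
the convention infinity - infinity = 0.  Finite problems are solved exactly
by optimal assignment on the diagonal-augmented bipartite problem; q =
infinity (bottleneck) by threshold feasibility search.

Each Turing-space node carries four barcodes (degrees 0 and 1 for each
species); the node metric d1 sums the four W_{2,2} distances, dinf takes
their max, and d2 takes the root of the sum of squares (the literal printed
form of d2, which coincides with d1, is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .persistence import PersistenceDiagram

__all__ = [
    "BarcodeSet",
    "ClusteringResult",
    "wasserstein",
    "node_distance",
    "distance_matrix",
    "cluster",
    "silhouette",
    "select_clustering",
]

_CHANNELS = ("b0u", "b1u", "b0v", "b1v")


@dataclass(frozen=True)
class BarcodeSet:
    """The four barcodes of one parameter node: degrees 0/1 for species u
    and v (possibly cleaned)."""

    node_id: int
    b0u: PersistenceDiagram
    b1u: PersistenceDiagram
    b0v: PersistenceDiagram
    b1v: PersistenceDiagram

    def channels(self) -> tuple[PersistenceDiagram, ...]:
        return (self.b0u, self.b1u, self.b0v, self.b1v)


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    linkage: str
    k: int
    silhouette: float


# --------------------------------------------------------------------------
# diagram distances
# --------------------------------------------------------------------------

def _point_dist(x, y, p: float) -> float:
    """l_p distance between diagram points; infinite deaths cancel
    (inf - inf = 0) and an infinite-finite pairing costs infinity."""
    db = abs(x[0] - y[0])
    xi, yi = math.isinf(x[1]), math.isinf(y[1])
    if xi and yi:
        dd = 0.0
    elif xi or yi:
        return math.inf
    else:
        dd = abs(x[1] - y[1])
    if math.isinf(p):
        return max(db, dd)
    return (db ** p + dd ** p) ** (1.0 / p)


def _diag_dist(x, p: float) -> float:
    """l_p distance from a point to the diagonal."""
    if math.isinf(x[1]):
        return math.inf
    gap = x[1] - x[0]
    if math.isinf(p):
        return 0.5 * gap
    return gap * 2.0 ** (1.0 / p - 1.0)


def _finite_assignment(pts1, pts2, p: float, q: float) -> float:
    """Sum of q-th powers of the optimal diagonal-augmented matching."""
    n1, n2 = len(pts1), len(pts2)
    if n1 == 0 and n2 == 0:
        return 0.0
    size = n1 + n2
    costs = np.zeros((size, size))
    for i, x in enumerate(pts1):
        for j, y in enumerate(pts2):
            costs[i, j] = _point_dist(x, y, p) ** q
    d1 = [_diag_dist(x, p) ** q for x in pts1]
    d2 = [_diag_dist(y, p) ** q for y in pts2]
    big = (max(costs.max() if size else 0.0, max(d1 + d2, default=0.0)) + 1.0) * (
        size + 1
    )
    costs[:n1, n2:] = big
    costs[n1:, :n2] = big
    for i in range(n1):
        costs[i, n2 + i] = d1[i]
    for j in range(n2):
        costs[n1 + j, j] = d2[j]
    rows, cols = linear_sum_assignment(costs)
    return float(costs[rows, cols].sum())


def _bottleneck_feasible(pts1, pts2, p: float, t: float) -> bool:
    """Is there a matching whose largest cost is <= t?"""
    n1, n2 = len(pts1), len(pts2)
    size = n1 + n2
    if size == 0:
        return True
    tol = t * (1.0 + 1e-12) + 1e-15
    bad = np.zeros((size, size))
    for i, x in enumerate(pts1):
        for j, y in enumerate(pts2):
            bad[i, j] = 0.0 if _point_dist(x, y, p) <= tol else 1.0
    bad[:n1, n2:] = 1.0
    bad[n1:, :n2] = 1.0
    for i, x in enumerate(pts1):
        bad[i, n2 + i] = 0.0 if _diag_dist(x, p) <= tol else 1.0
    for j, y in enumerate(pts2):
        bad[n1 + j, j] = 0.0 if _diag_dist(y, p) <= tol else 1.0
    rows, cols = linear_sum_assignment(bad)
    return float(bad[rows, cols].sum()) == 0.0


def _bottleneck(pts1, pts2, p: float) -> float:
    candidates = {0.0}
    for x in pts1:
        candidates.add(_diag_dist(x, p))
    for y in pts2:
        candidates.add(_diag_dist(y, p))
    for x in pts1:
        for y in pts2:
            candidates.add(_point_dist(x, y, p))
    cands = sorted(c for c in candidates if math.isfinite(c))
    lo, hi = 0, len(cands) - 1
    if not _bottleneck_feasible(pts1, pts2, p, cands[hi]):
        return math.inf
    while lo < hi:
        mid = (lo + hi) // 2
        if _bottleneck_feasible(pts1, pts2, p, cands[mid]):
            hi = mid
        else:
            lo = mid + 1
    return cands[lo]


def wasserstein(
    D1: PersistenceDiagram | tuple,
    D2: PersistenceDiagram | tuple,
    p: float = 2.0,
    q: float = 2.0,
) -> float:
    """q-Wasserstein distance W_{p,q} between two diagrams (q = infinity
    gives the bottleneck distance).

    Infinite bars may only match infinite bars (their death difference is
    zero by the infinity - infinity convention); diagrams with mismatched
    infinite-bar counts are at distance +infinity.
    """
    if p < 1 or q < 1:
        raise ValueError("p and q must lie in [1, inf]")
    pairs1 = D1.pairs if isinstance(D1, PersistenceDiagram) else tuple(D1)
    pairs2 = D2.pairs if isinstance(D2, PersistenceDiagram) else tuple(D2)
    inf1 = sorted(b for b, d in pairs1 if math.isinf(d))
    inf2 = sorted(b for b, d in pairs2 if math.isinf(d))
    if len(inf1) != len(inf2):
        return math.inf
    fin1 = [(b, d) for b, d in pairs1 if math.isfinite(d)]
    fin2 = [(b, d) for b, d in pairs2 if math.isfinite(d)]
    inf_costs = [abs(a - b) for a, b in zip(inf1, inf2)]
    if math.isinf(q):
        fin_part = _bottleneck(fin1, fin2, p)
        return max([fin_part] + inf_costs) if inf_costs else fin_part
    total = _finite_assignment(fin1, fin2, p, q) + sum(c ** q for c in inf_costs)
    return total ** (1.0 / q)


# --------------------------------------------------------------------------
# node metric and clustering
# --------------------------------------------------------------------------

def node_distance(
    A: BarcodeSet,
    B: BarcodeSet,
    variant: str = "d1",
    literal_d2: bool = False,
) -> float:
    """Composite distance between two nodes' barcode sets.

    d1 = sum of the four W_{2,2} channel distances; dinf = their max;
    d2 = sqrt of the sum of squares (set ``literal_d2`` for the printed
    sum-of-roots form, which equals d1).
    """
    ws = [
        wasserstein(a, b, 2.0, 2.0) for a, b in zip(A.channels(), B.channels())
    ]
    if variant == "d1":
        return float(sum(ws))
    if variant == "dinf":
        return float(max(ws))
    if variant == "d2":
        if literal_d2:
            return float(sum(ws))
        return float(math.sqrt(sum(w * w for w in ws)))
    raise ValueError(f"unknown variant {variant!r}")


def distance_matrix(
    nodes: list[BarcodeSet], variant: str = "d1", literal_d2: bool = False
) -> np.ndarray:
    """Symmetric pairwise node-distance matrix."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    n = len(nodes)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = node_distance(
                nodes[i], nodes[j], variant, literal_d2
            )
    return D


def cluster(matrix: np.ndarray, linkage: str = "average", k: int = 2) -> np.ndarray:
    """Agglomerative clustering on a precomputed distance matrix.

    Linkages are restricted to single/complete/average, which are valid
    for an arbitrary metric (centroid-type linkages need a Euclidean
    embedding).  Returns labels in 1..k.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of nodes {n}")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if k == n:
        return np.arange(1, n + 1)
    Z = scipy_linkage(squareform(matrix, checks=False), method=linkage)
    return fcluster(Z, t=k, criterion="maxclust")


def silhouette(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score over nodes for a precomputed distance
    matrix; singleton clusters contribute 0."""
    from sklearn.metrics import silhouette_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(matrix), labels, metric="precomputed"))


def select_clustering(
    matrix: np.ndarray,
    linkages: tuple[str, ...] = ("single", "complete", "average"),
    k_range: range | tuple[int, ...] = range(2, 13),
) -> ClusteringResult:
    """Grid search over linkage and cluster count, returning the
    clustering with the highest silhouette score (ties broken by smaller
    k, then by linkage order)."""
    n = np.asarray(matrix).shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no valid cluster counts")
    best: ClusteringResult | None = None
    for k in sorted(ks):
        for link in linkages:
            labels = cluster(matrix, link, k)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette(matrix, labels)
            if best is None or score > best.silhouette + 1e-12:
                best = ClusteringResult(
                    labels=labels, linkage=link, k=k, silhouette=score
                )
    if best is None:
        raise ValueError("no valid clustering found")
    return best
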