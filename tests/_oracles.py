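"""Independent brute-force oracles used to validate the persistence and
matching implementations.

Persistent homology is recomputed here from first principles: ranks and
kernels of the boundary matrices over F_p at every filtration level give
the persistent Betti numbers, from which bar multiplicities follow by
inclusion-exclusion.  Diagram distances are recomputed by exhaustive
enumeration of all matchings.  Nothing in this module calls the package's
reduction or assignment code.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


# --------------------------------------------------------------------------
# linear algebra over F_p
# --------------------------------------------------------------------------

def rref_mod_p(M: np.ndarray, p: int) -> tuple[np.ndarray, list[int]]:
    """Row-reduced echelon form over F_p; returns (R, pivot columns)."""
    R = np.array(M, dtype=np.int64) % p
    rows, cols = R.shape
    pivots = []
    r = 0
    for c in range(cols):
        pivot = None
        for i in range(r, rows):
            if R[i, c] % p:
                pivot = i
                break
        if pivot is None:
            continue
        R[[r, pivot]] = R[[pivot, r]]
        R[r] = (R[r] * pow(int(R[r, c]), p - 2, p)) % p
        for i in range(rows):
            if i != r and R[i, c]:
                R[i] = (R[i] - R[i, c] * R[r]) % p
        pivots.append(c)
        r += 1
        if r == rows:
            break
    return R, pivots


def rank_mod_p(M: np.ndarray, p: int) -> int:
    if M.size == 0:
        return 0
    return len(rref_mod_p(M, p)[1])


def kernel_basis_mod_p(M: np.ndarray, p: int) -> np.ndarray:
    """Columns spanning the kernel of M over F_p (shape cols x dim_ker)."""
    rows, cols = M.shape
    if cols == 0:
        return np.zeros((0, 0), dtype=np.int64)
    if rows == 0:
        return np.eye(cols, dtype=np.int64)
    R, pivots = rref_mod_p(M, p)
    free = [c for c in range(cols) if c not in pivots]
    basis = np.zeros((cols, len(free)), dtype=np.int64)
    for j, fc in enumerate(free):
        basis[fc, j] = 1
        for r, pc in enumerate(pivots):
            basis[pc, j] = (-R[r, fc]) % p
    return basis


# --------------------------------------------------------------------------
# brute-force persistent homology
# --------------------------------------------------------------------------

def _simplices_by_dim(fc):
    """(level, simplex) lists per dimension from a FilteredComplex."""
    cx = fc.complex
    vid = {v: i for i, v in enumerate(cx.vertices)}
    out = {
        0: [(int(fc.vertex_levels[vid[v]]), (v,)) for v in cx.vertices],
        1: [(int(l), e) for e, l in zip(cx.edges, fc.edge_levels)],
        2: [(int(l), t) for t, l in zip(cx.triangles, fc.triangle_levels)],
    }
    for d in out:
        out[d].sort()
    return out


def _boundary_matrix(k_simps, km1_simps, p):
    """Boundary matrix from k-simplices (columns) to (k-1)-simplices."""
    index = {s: i for i, (_, s) in enumerate(km1_simps)}
    M = np.zeros((len(km1_simps), len(k_simps)), dtype=np.int64)
    for j, (_, s) in enumerate(k_simps):
        for i in range(len(s)):
            face = s[:i] + s[i + 1 :]
            M[index[face], j] = (-1) ** i % p
    return M


def persistent_betti(fc, k: int, s: int, t: int, p: int) -> int:
    """Rank of the map H_k(F_s) -> H_k(F_t), computed from boundary-matrix
    ranks and kernels (no column reduction)."""
    if s == 0:
        return 0
    by_dim = _simplices_by_dim(fc)

    def upto(d, level):
        return [(l, s_) for l, s_ in by_dim[d] if l <= level]

    k_s = upto(k, s)
    k_t = upto(k, t)
    if not k_s:
        return 0
    # kernel of d_k on F_s
    if k == 0:
        Z = np.eye(len(k_s), dtype=np.int64)
    else:
        Z = kernel_basis_mod_p(_boundary_matrix(k_s, upto(k - 1, s), p), p)
    if Z.shape[1] == 0:
        return 0
    # embed Z into the k-chain space of F_t (F_s columns come first in the
    # level-sorted order)
    Z_t = np.zeros((len(k_t), Z.shape[1]), dtype=np.int64)
    pos = {s_: i for i, (_, s_) in enumerate(k_t)}
    for i, (_, s_) in enumerate(k_s):
        Z_t[pos[s_]] = Z[i]
    B = _boundary_matrix(upto(k + 1, t), k_t, p)
    dim_z = rank_mod_p(Z_t, p)
    dim_b = rank_mod_p(B, p)
    dim_zb = rank_mod_p(np.concatenate([Z_t, B], axis=1), p)
    return dim_z - (dim_z + dim_b - dim_zb)


def barcodes_bruteforce(fc, p: int = 2) -> dict[int, tuple]:
    """Barcodes in degrees 0 and 1 via persistent Betti numbers and
    inclusion-exclusion; zero-length bars excluded, essential bars get
    death = inf.  Returns sorted pair tuples per degree."""
    T = int(fc.n_levels)

    out = {}
    for k in (0, 1):
        betti = {
            (s, t): persistent_betti(fc, k, s, t, p)
            for s in range(0, T + 1)
            for t in range(s, T + 1)
        }
        bars = []
        for b in range(1, T + 1):
            for d in range(b + 1, T + 1):
                mu = (
                    betti[(b, d - 1)]
                    - betti[(b, d)]
                    - betti[(b - 1, d - 1)]
                    + betti[(b - 1, d)]
                )
                bars.extend([(float(b), float(d))] * mu)
            mu_inf = betti[(b, T)] - betti[(b - 1, T)]
            bars.extend([(float(b), math.inf)] * mu_inf)
        out[k] = tuple(sorted(bars))
    return out


def random_filtered_complex(rng: np.random.Generator, n_vertices: int = 8,
                            n_levels: int = 5):
    """Random filtered 2-complex with monotone levels (faces enter no
    later than cofaces)."""
    from turingtda.persistence import FilteredComplex, SimplicialComplex2D

    verts = tuple(range(n_vertices))
    all_edges = list(combinations(verts, 2))
    keep = rng.random(len(all_edges)) < 0.55
    edges = tuple(e for e, k in zip(all_edges, keep) if k)
    eset = set(edges)
    tris = tuple(
        t
        for t in combinations(verts, 3)
        if {(t[0], t[1]), (t[0], t[2]), (t[1], t[2])} <= eset
        and rng.random() < 0.6
    )
    vlev = rng.integers(1, n_levels + 1, n_vertices)
    elev = np.array(
        [
            min(n_levels, max(vlev[a], vlev[b]) + rng.integers(0, 2))
            for a, b in edges
        ],
        dtype=int,
    )
    eidx = {e: i for i, e in enumerate(edges)}
    tlev = np.array(
        [
            min(
                n_levels,
                max(
                    elev[eidx[(t[0], t[1])]],
                    elev[eidx[(t[0], t[2])]],
                    elev[eidx[(t[1], t[2])]],
                )
                + rng.integers(0, 2),
            )
            for t in tris
        ],
        dtype=int,
    )
    cx = SimplicialComplex2D(vertices=verts, edges=edges, triangles=tris)
    return FilteredComplex(
        complex=cx,
        vertex_levels=vlev,
        edge_levels=elev,
        triangle_levels=tlev,
        n_levels=n_levels,
    )


# --------------------------------------------------------------------------
# brute-force diagram distances
# --------------------------------------------------------------------------

def _lp(db: float, dd: float, p: float) -> float:
    if math.isinf(p):
        return max(db, dd)
    return (db ** p + dd ** p) ** (1.0 / p)


def _pdist(x, y, p):
    if math.isinf(x[1]) and math.isinf(y[1]):
        return abs(x[0] - y[0])
    if math.isinf(x[1]) or math.isinf(y[1]):
        return math.inf
    return _lp(abs(x[0] - y[0]), abs(x[1] - y[1]), p)


def _ddist(x, p):
    if math.isinf(x[1]):
        return math.inf
    half = 0.5 * (x[1] - x[0])
    return _lp(half, half, p)


def wasserstein_exhaustive(pairs1, pairs2, p: float, q: float) -> float:
    """Minimum over every matching (subsets matched bijectively, the rest
    to the diagonal)."""
    pairs1, pairs2 = list(pairs1), list(pairs2)
    n1, n2 = len(pairs1), len(pairs2)
    best = math.inf
    for k in range(min(n1, n2) + 1):
        for sub1 in combinations(range(n1), k):
            for sub2 in permutations(range(n2), k):
                costs = [
                    _pdist(pairs1[i], pairs2[j], p)
                    for i, j in zip(sub1, sub2)
                ]
                costs += [_ddist(pairs1[i], p) for i in range(n1) if i not in sub1]
                costs += [_ddist(pairs2[j], p) for j in range(n2) if j not in sub2]
                if math.isinf(q):
                    val = max(costs, default=0.0)
                else:
                    if any(math.isinf(c) for c in costs):
                        val = math.inf
                    else:
                        val = sum(c ** q for c in costs) ** (1.0 / q)
                best = min(best, val)
    return best


def random_diagram(rng: np.random.Generator, max_points: int = 4,
                   allow_infinite: bool = False):
    n = int(rng.integers(0, max_points + 1))
    pairs = []
    for _ in range(n):
        b = float(np.round(rng.uniform(0, 5), 3))
        if allow_infinite and rng.random() < 0.2:
            pairs.append((b, math.inf))
        else:
            pairs.append((b, b + float(np.round(rng.uniform(0.001, 5), 3))))
    return tuple(pairs)
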