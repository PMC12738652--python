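"""Persistent homology of star filtrations of scalar fields on a
triangulated grid.

The rectangle is triangulated by splitting each grid cell along a fixed
diagonal.  A scalar field on the vertices induces a lower-star (sublevel)
or upper-star (superlevel) filtration: by default the field's range is cut
into ``n_levels`` = 20 equal slices, and a simplex enters the filtration at
the smallest level at which all of its vertices pass the moving threshold.
Because thresholds are fractions of the field range, the filtration
normalises amplitude, letting diagrams of different simulations be compared
directly.  Setting ``n_levels=None`` instead filters by the exact sorted
vertex values (one level per distinct value), which is the discretisation-
free object that the stability theorem speaks about.

Degree-0 and degree-1 barcodes are computed by standard column reduction of
the level-sorted boundary matrix over a prime field (F_2 by default, with
bitmask columns; any prime via modular arithmetic).  Zero-length pairs
(birth = death) are discarded; essential classes get death = infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import Field, RectGrid

__all__ = [
    "SimplicialComplex2D",
    "FilteredComplex",
    "PersistenceDiagram",
    "triangulate_grid",
    "star_filtration",
    "filtration_from_simplices",
    "compute_barcodes",
    "clean_barcode",
    "bar_values",
    "length_histogram",
]

Simplex = tuple[int, ...]


@dataclass(frozen=True)
class SimplicialComplex2D:
    """A 2-dimensional simplicial complex given by explicit simplex lists.

    Vertices are integer ids; edges and triangles are sorted tuples.  The
    complex must be closed under taking faces.
    """

    vertices: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    triangles: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        eset = set(self.edges)
        for e in self.edges:
            if not set(e) <= vset:
                raise ValueError(f"edge {e} has a missing vertex")
        for t in self.triangles:
            for i in range(3):
                f = tuple(sorted(t[:i] + t[i + 1 :]))
                if f not in eset:
                    raise ValueError(f"triangle {t} has a missing face {f}")

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.triangles)


def triangulate_grid(grid: RectGrid, diagonal: str = "lowleft-upright") -> SimplicialComplex2D:
    """Triangulate the vertex grid, splitting each cell along a fixed
    diagonal (default lower-left to upper-right).

    Vertex ids follow grid order (``iy * nx + ix``).
    """
    nx, ny = grid.nx, grid.ny
    idx = np.arange(nx * ny).reshape(ny, nx)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    a = idx[:-1, :-1].ravel()  # lower-left of each cell
    b = idx[:-1, 1:].ravel()  # lower-right
    c = idx[1:, :-1].ravel()  # upper-left
    d = idx[1:, 1:].ravel()  # upper-right
    if diagonal == "lowleft-upright":
        diag = np.stack([a, d], axis=1)
        tris = np.concatenate(
            [np.stack([a, b, d], axis=1), np.stack([a, c, d], axis=1)]
        )
    elif diagonal == "lowright-upleft":
        diag = np.stack([b, c], axis=1)
        tris = np.concatenate(
            [np.stack([a, b, c], axis=1), np.stack([b, c, d], axis=1)]
        )
    else:
        raise ValueError(f"unknown diagonal {diagonal!r}")
    edges = np.concatenate([horiz, vert, diag])
    edges = np.sort(edges, axis=1)
    tris = np.sort(tris, axis=1)
    return SimplicialComplex2D(
        vertices=tuple(range(nx * ny)),
        edges=tuple(map(tuple, edges.tolist())),
        triangles=tuple(map(tuple, tris.tolist())),
    )


@dataclass
class FilteredComplex:
    """A simplicial complex with an integer filtration level per simplex.

    Levels run 1..n_levels (or 1..#distinct values in exact mode) and
    satisfy level(face) <= level(coface).  ``thresholds[j-1]`` is the
    field value of the j-th threshold: a vertex with value u enters a
    lower filtration at the first j with u <= thresholds[j-1] (and an
    upper filtration at the first j with u >= thresholds[j-1]).
    """

    complex: SimplicialComplex2D
    vertex_levels: np.ndarray
    edge_levels: np.ndarray
    triangle_levels: np.ndarray
    n_levels: int
    direction: str = "lower"
    thresholds: np.ndarray | None = None
    species: str = ""

    def __post_init__(self) -> None:
        self.vertex_levels = np.asarray(self.vertex_levels, dtype=int)
        self.edge_levels = np.asarray(self.edge_levels, dtype=int)
        self.triangle_levels = np.asarray(self.triangle_levels, dtype=int)
        vid = {v: i for i, v in enumerate(self.complex.vertices)}
        for (a, b), lv in zip(self.complex.edges, self.edge_levels):
            if lv < max(self.vertex_levels[vid[a]], self.vertex_levels[vid[b]]):
                raise ValueError("filtration nesting violated on an edge")
        eid = {e: i for i, e in enumerate(self.complex.edges)}
        for t, lv in zip(self.complex.triangles, self.triangle_levels):
            for i in range(3):
                f = tuple(sorted(t[:i] + t[i + 1 :]))
                if lv < self.edge_levels[eid[f]]:
                    raise ValueError("filtration nesting violated on a triangle")


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) pairs in one homology degree; death may
    be math.inf for essential classes."""

    degree: int
    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for b, d in self.pairs:
            if d < b:
                raise ValueError(f"bar ({b}, {d}) has death < birth")
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))

    @property
    def finite_pairs(self) -> tuple[tuple[float, float], ...]:
        return tuple(p for p in self.pairs if math.isfinite(p[1]))

    @property
    def essential_pairs(self) -> tuple[tuple[float, float], ...]:
        return tuple(p for p in self.pairs if math.isinf(p[1]))

    def __len__(self) -> int:
        return len(self.pairs)


def _vertex_levels(values: np.ndarray, direction: str, n_levels: int | None):
    """Per-vertex levels and the level -> threshold map."""
    w = values if direction == "lower" else -values
    if n_levels is None:
        uniq = np.unique(w)
        levels = np.searchsorted(uniq, w) + 1
        thresholds = uniq if direction == "lower" else -uniq
        return levels, len(uniq), thresholds
    wmin, wmax = float(w.min()), float(w.max())
    rng = wmax - wmin
    if rng == 0.0:
        # degenerate constant field: everything at level 1
        levels = np.ones(len(w), dtype=int)
    else:
        levels = np.ceil((w - wmin) * n_levels / rng).astype(int)
        np.clip(levels, 1, n_levels, out=levels)
    j = np.arange(1, n_levels + 1)
    tw = wmin + rng * j / n_levels
    thresholds = tw if direction == "lower" else -tw
    return levels, n_levels, thresholds


def star_filtration(
    field_: Field,
    complex_: SimplicialComplex2D,
    direction: str = "lower",
    n_levels: int | None = 20,
) -> FilteredComplex:
    """Lower- or upper-star filtration of a vertex field.

    With quantisation, threshold j of a lower filtration is
    ``min + (max - min) j / n_levels`` (for upper, ``max - (max - min)
    j / n_levels``), j = 1..n_levels, so the filtration is exhaustive and
    amplitude-normalised.  A simplex's level is the max of its vertices'
    levels.  ``n_levels=None`` filters by exact values.
    """
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    values = field_.values
    if len(values) != len(complex_.vertices):
        raise ValueError("field does not match the complex's vertex set")
    vlev, n_eff, thresholds = _vertex_levels(values, direction, n_levels)
    edges = np.asarray(complex_.edges, dtype=int)
    tris = np.asarray(complex_.triangles, dtype=int)
    elev = vlev[edges].max(axis=1) if len(edges) else np.zeros(0, dtype=int)
    tlev = vlev[tris].max(axis=1) if len(tris) else np.zeros(0, dtype=int)
    return FilteredComplex(
        complex=complex_,
        vertex_levels=vlev,
        edge_levels=elev,
        triangle_levels=tlev,
        n_levels=n_eff,
        direction=direction,
        thresholds=np.asarray(thresholds, dtype=float),
        species=field_.species,
    )


def filtration_from_simplices(
    levels: Mapping[Sequence[int], int], direction: str = "lower"
) -> FilteredComplex:
    """Build a filtered complex from an explicit simplex -> level map.

    Intended for hand-specified filtrations (worked examples, tests).
    """
    verts, edges, tris = [], [], []
    vl, el, tl = [], [], []
    for s, lv in levels.items():
        s = tuple(sorted(s))
        if len(s) == 1:
            verts.append(s[0])
            vl.append(lv)
        elif len(s) == 2:
            edges.append(s)
            el.append(lv)
        elif len(s) == 3:
            tris.append(s)
            tl.append(lv)
        else:
            raise ValueError("only simplices of dimension <= 2 are supported")
    order = np.argsort(verts)
    cx = SimplicialComplex2D(
        vertices=tuple(np.asarray(verts)[order]),
        edges=tuple(edges),
        triangles=tuple(tris),
    )
    n_levels = max(vl + el + tl)
    return FilteredComplex(
        complex=cx,
        vertex_levels=np.asarray(vl)[order],
        edge_levels=np.asarray(el, dtype=int),
        triangle_levels=np.asarray(tl, dtype=int),
        n_levels=n_levels,
        direction=direction,
    )


# --------------------------------------------------------------------------
# boundary-matrix reduction
# --------------------------------------------------------------------------

def _sorted_simplices(fc: FilteredComplex):
    """Simplices sorted by (level, dim, vertex tuple); returns the sorted
    list of (level, dim, simplex) and the simplex -> position map."""
    items: list[tuple[int, int, Simplex]] = []
    vid = {v: i for i, v in enumerate(fc.complex.vertices)}
    for v in fc.complex.vertices:
        items.append((int(fc.vertex_levels[vid[v]]), 0, (v,)))
    for e, lv in zip(fc.complex.edges, fc.edge_levels):
        items.append((int(lv), 1, e))
    for t, lv in zip(fc.complex.triangles, fc.triangle_levels):
        items.append((int(lv), 2, t))
    items.sort()
    pos = {s: i for i, (_, _, s) in enumerate(items)}
    return items, pos


def _boundary(s: Simplex) -> list[tuple[Simplex, int]]:
    """Faces of a simplex with alternating orientation signs."""
    if len(s) == 1:
        return []
    out = []
    for i in range(len(s)):
        out.append((s[:i] + s[i + 1 :], (-1) ** i))
    return out


def _reduce_f2(items, pos):
    """Column reduction over F_2 with bitmask columns."""
    reduced: list[int] = []
    pivot_of: dict[int, int] = {}
    pairs = []
    for j, (_, _, s) in enumerate(items):
        col = 0
        for f, _sgn in _boundary(s):
            col ^= 1 << pos[f]
        while col:
            low = col.bit_length() - 1
            other = pivot_of.get(low)
            if other is None:
                break
            col ^= reduced[other]
        reduced.append(col)
        if col:
            pivot_of[col.bit_length() - 1] = j
    return pivot_of, [bool(c) for c in reduced]


def _reduce_fp(items, pos, p: int):
    """Column reduction over F_p with sparse dict columns."""
    reduced: list[dict[int, int]] = []
    pivot_of: dict[int, int] = {}
    for j, (_, _, s) in enumerate(items):
        col = {}
        for f, sgn in _boundary(s):
            col[pos[f]] = sgn % p
        col = {r: c for r, c in col.items() if c}
        while col:
            low = max(col)
            other = pivot_of.get(low)
            if other is None:
                break
            oc = reduced[other]
            factor = (col[low] * pow(oc[low], p - 2, p)) % p
            for r, c in oc.items():
                nv = (col.get(r, 0) - factor * c) % p
                if nv:
                    col[r] = nv
                else:
                    col.pop(r, None)
        reduced.append(col)
        if col:
            pivot_of[max(col)] = j
    return pivot_of, [bool(c) for c in reduced]


def compute_barcodes(
    fc: FilteredComplex, p: int = 2, degrees: Iterable[int] = (0, 1)
) -> dict[int, PersistenceDiagram]:
    """Degree-0/1 barcodes of the filtration by boundary-matrix reduction
    over F_p.

    Bars are reported in filtration-level units; zero-length pairs are
    dropped and essential classes get death = infinity.
    """
    if p < 2:
        raise ValueError("p must be a prime >= 2")
    items, pos = _sorted_simplices(fc)
    if p == 2:
        pivot_of, nonzero = _reduce_f2(items, pos)
    else:
        pivot_of, nonzero = _reduce_fp(items, pos, p)
    bars: dict[int, list[tuple[float, float]]] = {d: [] for d in degrees}
    paired = set()
    for low, j in pivot_of.items():
        paired.add(low)
        paired.add(j)
        b_level, b_dim, _ = items[low]
        d_level, _, _ = items[j]
        if d_level > b_level and b_dim in bars:
            bars[b_dim].append((float(b_level), float(d_level)))
    for j, (level, dim, _) in enumerate(items):
        if j not in paired and not nonzero[j] and dim in bars:
            bars[dim].append((float(level), math.inf))
    return {d: PersistenceDiagram(degree=d, pairs=tuple(v)) for d, v in bars.items()}


def clean_barcode(diag: PersistenceDiagram, min_length: float) -> PersistenceDiagram:
    """Drop finite bars shorter than ``min_length``; infinite bars are
    always kept."""
    if min_length < 0:
        raise ValueError("min_length must be nonnegative")
    kept = tuple(
        (b, d) for b, d in diag.pairs if math.isinf(d) or d - b >= min_length
    )
    return PersistenceDiagram(degree=diag.degree, pairs=kept)


def bar_values(
    diag: PersistenceDiagram, thresholds: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """Bars with level indices replaced by their threshold values (death
    infinity is preserved).  Used to compare diagrams in field units."""
    out = []
    for b, d in diag.pairs:
        tb = float(thresholds[int(b) - 1])
        td = math.inf if math.isinf(d) else float(thresholds[int(d) - 1])
        out.append((tb, td))
    return tuple(out)


def length_histogram(
    diagrams: Iterable[PersistenceDiagram],
    smoothing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Histogram of finite bar lengths with a suggested noise cutoff.

    The counts over integer length bins are smoothed with a small
    Gaussian kernel; when the smoothed density is multimodal, the
    suggested cutoff is the argmin between the two smallest-length
    modes, otherwise None.
    Returns (counts, bin_edges, cutoff).
    """
    from scipy.ndimage import gaussian_filter1d

    lengths = [
        d - b
        for diag in diagrams
        for b, d in diag.pairs
        if math.isfinite(d)
    ]
    if not lengths:
        raise ValueError("no finite bars")
    lmax = int(math.ceil(max(lengths)))
    edges = np.arange(0.5, lmax + 1.5)
    counts, _ = np.histogram(lengths, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), smoothing)
    peaks = [
        i
        for i in range(len(smooth))
        if (i == 0 or smooth[i] > smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] > smooth[i + 1])
        and counts[i] > 0
    ]
    if len(peaks) < 2:
        return counts, edges, None
    p1, p2 = sorted(peaks)[:2]
    valley = p1 + int(np.argmin(smooth[p1 : p2 + 1]))
    cutoff = float(valley + 1)  # bin i holds lengths near i + 1
    return counts, edges, cutoff
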