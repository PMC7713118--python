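"""Cubical 0- and 1-dimensional persistent homology of grayscale images.

The filtration is the sublevel filtration of the pixel grid: pixels enter at
their intensity, and a pixel is connected to its eight horizontal, vertical
and diagonal neighbours.  Connected components (H0) are tracked with a
union-find structure (path compression + union by rank) processing pixels in
increasing ``(value, row, col)`` order, so the engine runs in O(n alpha(n)) and
— unlike off-the-shelf persistence libraries — records the *pixel* at which
every component is born and dies.  When two components merge the elder rule
applies: the component with the later birth dies, ties broken
lexicographically by ``(value, row, col)``.

Loops (H1) are obtained through the standard digital-topology duality: a hole
of the 8-connected sublevel set is a bounded 4-connected component of the
strict superlevel complement.  They are computed as 0-dimensional persistence
of the complement processed in decreasing intensity order, with a virtual node
joining all image-border pixels (whose component — the unbounded background —
is discarded); a hole is born at the intensity closing its surrounding cycle
and dies at the intensity filling its interior.

A brute-force Betti-curve oracle (BFS component counting per threshold) is
provided as an independent cross-check, along with the bottleneck distance
between diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import label as _label
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .images import validate_gray

__all__ = [
    "PersistencePoint",
    "Diagram",
    "compute_h0",
    "compute_h1",
    "betti_curve_oracle",
    "bottleneck_distance",
]

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class PersistencePoint:
    """A single birth/death pair of a topological feature.

    ``death`` is ``math.inf`` for the one component per image that never dies.
    ``birth_pixel`` is the (row, col) of the feature's birth; for H0 this is
    the component's minimum, for H1 the pixel completing the surrounding cycle.
    """

    birth: float
    death: float
    dimension: int
    birth_pixel: tuple[int, int] | None = None
    death_pixel: tuple[int, int] | None = None

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    def __post_init__(self) -> None:
        if self.death < self.birth:
            raise ValueError(f"death {self.death} < birth {self.birth}")
        if self.dimension not in (0, 1):
            raise ValueError(f"dimension must be 0 or 1, got {self.dimension}")


@dataclass
class Diagram:
    """A persistence diagram: a multiset of points of one dimension.

    Every point of the diagonal is implicitly part of the diagram for distance
    purposes.
    """

    points: list[PersistencePoint] = field(default_factory=list)
    dimension: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def finite(self) -> list[PersistencePoint]:
        return [p for p in self.points if math.isfinite(p.death)]

    @property
    def infinite(self) -> list[PersistencePoint]:
        return [p for p in self.points if math.isinf(p.death)]

    def finite_lifetimes(self) -> np.ndarray:
        return np.array([p.lifetime for p in self.finite], dtype=float)

    def alive_count(self, t: float) -> int:
        """Number of features alive at threshold t (born <= t, dead after t)."""
        return sum(1 for p in self.points if p.birth <= t < p.death)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for p in self.points:
            rows.append(
                {
                    "dimension": p.dimension,
                    "birth": p.birth,
                    "death": "INF" if math.isinf(p.death) else p.death,
                    "birth_row": p.birth_pixel[0] if p.birth_pixel else "",
                    "birth_col": p.birth_pixel[1] if p.birth_pixel else "",
                    "death_row": p.death_pixel[0] if p.death_pixel else "",
                    "death_col": p.death_pixel[1] if p.death_pixel else "",
                    "lifetime": "INF" if math.isinf(p.death) else p.lifetime,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "dimension",
                "birth",
                "death",
                "birth_row",
                "birth_col",
                "death_row",
                "death_col",
                "lifetime",
            ],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Diagram":
        import pandas as pd

        df = pd.read_csv(path, keep_default_na=False)
        pts = []
        for _, r in df.iterrows():
            death = math.inf if str(r["death"]) == "INF" else float(r["death"])
            bp = (
                (int(r["birth_row"]), int(r["birth_col"]))
                if str(r["birth_row"]) != ""
                else None
            )
            dp = (
                (int(r["death_row"]), int(r["death_col"]))
                if str(r["death_row"]) != ""
                else None
            )
            pts.append(PersistencePoint(float(r["birth"]), death, int(r["dimension"]), bp, dp))
        dim = pts[0].dimension if pts else 0
        return cls(pts, dim)


class _UnionFind:
    """Union-find with path compression and union by rank.

    Each root carries the birth key ``(value, row, col)`` of its component's
    eldest pixel; the caller decides which root survives a merge.
    """

    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def link(self, a: int, b: int) -> int:
        """Link roots a and b; return the surviving root."""
        if self.rank[a] < self.rank[b]:
            a, b = b, a
        self.parent[b] = a
        if self.rank[a] == self.rank[b]:
            self.rank[a] += 1
        return a


def compute_h0(img: np.ndarray, connectivity: int = 8) -> Diagram:
    """0-dimensional persistence of the sublevel filtration of ``img``.

    Pixels are processed in increasing ``(value, row, col)`` order.  A
    component is born at its minimum pixel; when two components meet at a pixel
    of value ``v`` the younger one (larger birth key) dies there with
    ``death = v``.  Exactly one point has infinite death, born at the global
    minimum.  The total number of points equals the number of local minima of
    the image under the same tie-break.
    """
    arr = validate_gray(img)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    h, w = arr.shape
    flat = arr.ravel()
    order = np.lexsort(
        (np.tile(np.arange(w), h), np.repeat(np.arange(h), w), flat)
    )
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]

    uf = _UnionFind(h * w)
    # birth key of each root: (value, row, col); lexicographically smaller = elder
    birth: dict[int, tuple[float, int, int]] = {}
    added = np.zeros(h * w, dtype=bool)
    points: list[PersistencePoint] = []

    for idx in order:
        r, c = divmod(int(idx), w)
        v = flat[idx]
        birth[idx] = (v, r, c)
        added[idx] = True
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w:
                nidx = nr * w + nc
                if added[nidx]:
                    ra, rb = uf.find(int(idx)), uf.find(nidx)
                    if ra == rb:
                        continue
                    ka, kb = birth[ra], birth[rb]
                    elder_key, young_key = (ka, kb) if ka < kb else (kb, ka)
                    if young_key[0] < v:
                        # zero-persistence pairs (a pixel joining a component
                        # at its own value) are not features and are dropped
                        points.append(
                            PersistencePoint(
                                birth=young_key[0],
                                death=float(v),
                                dimension=0,
                                birth_pixel=(young_key[1], young_key[2]),
                                death_pixel=(r, c),
                            )
                        )
                    survivor = uf.link(ra, rb)
                    loser = rb if survivor == ra else ra
                    birth[survivor] = elder_key
                    birth.pop(loser, None)

    # every remaining root is an immortal component (one per connected image)
    roots = {uf.find(int(i)) for i in range(h * w)}
    for root in roots:
        bv, br, bc = birth[root]
        points.append(
            PersistencePoint(
                birth=float(bv), death=math.inf, dimension=0, birth_pixel=(br, bc)
            )
        )
    points.sort(key=lambda p: (-(p.lifetime), p.birth))
    return Diagram(points, dimension=0)


def compute_h1(img: np.ndarray) -> Diagram:
    """1-dimensional persistence of the sublevel filtration of ``img``.

    Computed by duality: holes of the 8-connected sublevel set ``{f <= t}`` are
    the bounded 4-connected components of the strict complement ``{f > t}``.
    Complement pixels are processed in decreasing ``(value, row, col)`` order
    with a virtual node permanently joining all image-border pixels.  When a
    complement component (interior pocket) of maximum intensity ``B`` merges
    with an elder component through a pixel of value ``v``, the hole it
    represents is recorded with ``birth = v`` (the cycle around it completes
    when that pixel enters the sublevel set) and ``death = B`` (the pocket
    fills when its last pixel enters).  The virtual node's component — the
    unbounded background — yields no point.
    """
    arr = validate_gray(img)
    h, w = arr.shape
    flat = arr.ravel()
    # decreasing value; deterministic (row, col) tie-break
    order = np.lexsort(
        (np.tile(np.arange(w), h), np.repeat(np.arange(h), w), -flat)
    )
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]

    n = h * w
    virtual = n
    uf = _UnionFind(n + 1)
    # birth key in superlevel time: (-value, row, col); smaller = elder (higher max)
    birth: dict[int, tuple[float, int, int]] = {virtual: (-math.inf, -1, -1)}
    # track the pixel attaining a component's maximum, for death_pixel reporting
    max_pixel: dict[int, tuple[int, int]] = {virtual: (-1, -1)}
    added = np.zeros(n, dtype=bool)
    points: list[PersistencePoint] = []

    def merge(a: int, b: int, v: float, pix: tuple[int, int]) -> None:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            return
        ka, kb = birth[ra], birth[rb]
        if ka < kb:
            elder_root, young_root = ra, rb
        else:
            elder_root, young_root = rb, ra
        young_key = birth[young_root]
        death = -young_key[0]  # the pocket's maximum intensity
        points.append(
            PersistencePoint(
                birth=float(v),
                death=float(death),
                dimension=1,
                birth_pixel=pix,
                death_pixel=max_pixel[young_root],
            )
        )
        survivor = uf.link(ra, rb)
        loser = rb if survivor == ra else ra
        birth[survivor] = min(ka, kb)
        max_pixel[survivor] = max_pixel[elder_root]
        birth.pop(loser, None)
        max_pixel.pop(loser, None)

    for idx in order:
        r, c = divmod(int(idx), w)
        v = float(flat[idx])
        birth[int(idx)] = (-v, r, c)
        max_pixel[int(idx)] = (r, c)
        added[idx] = True
        if r == 0 or c == 0 or r == h - 1 or c == w - 1:
            merge(int(idx), virtual, v, (r, c))
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w:
                nidx = nr * w + nc
                if added[nidx]:
                    merge(int(idx), nidx, v, (r, c))

    # drop zero-persistence artefacts of border-joins at equal value
    pts = [p for p in points if p.lifetime > 0]
    pts.sort(key=lambda p: (-p.lifetime, p.birth))
    return Diagram(pts, dimension=1)


def betti_curve_oracle(
    img: np.ndarray, dimension: int, thresholds: Iterable[float]
) -> list[int]:
    """Brute-force Betti numbers per threshold, independent of the union-find engine.

    ``beta0(t)`` counts 8-connected components of ``{f <= t}``; ``beta1(t)``
    counts bounded (border-free) 4-connected components of ``{f > t}``.
    Intended for small images as a test oracle.
    """
    arr = validate_gray(img)
    if dimension not in (0, 1):
        raise ValueError("dimension must be 0 or 1")
    out = []
    for t in thresholds:
        if dimension == 0:
            labels, count = _label(arr <= t, structure=_EIGHT)
            out.append(int(count))
        else:
            labels, count = _label(arr > t, structure=_FOUR)
            border = np.unique(
                np.concatenate(
                    [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
                )
            )
            bounded = set(range(1, count + 1)) - set(border.tolist())
            out.append(len(bounded))
    return out


def _finite_match_feasible(
    pts1: np.ndarray, pts2: np.ndarray, d: float, tol: float = 1e-12
) -> bool:
    """Is there a perfect bottleneck matching of cost <= d (diagonal allowed)?"""
    n1, n2 = len(pts1), len(pts2)
    size = n1 + n2
    rows, cols = [], []
    if n1 and n2:
        cost = np.maximum(
            np.abs(pts1[:, 0, None] - pts2[None, :, 0]),
            np.abs(pts1[:, 1, None] - pts2[None, :, 1]),
        )
        ii, jj = np.nonzero(cost <= d + tol)
        rows.extend(ii.tolist())
        cols.extend(jj.tolist())
    diag1 = (pts1[:, 1] - pts1[:, 0]) / 2.0 if n1 else np.empty(0)
    diag2 = (pts2[:, 1] - pts2[:, 0]) / 2.0 if n2 else np.empty(0)
    for i in range(n1):  # point i of D1 onto its diagonal projection
        if diag1[i] <= d + tol:
            rows.append(i)
            cols.append(n2 + i)
    for j in range(n2):  # diagonal copy matched to point j of D2
        if diag2[j] <= d + tol:
            rows.append(n1 + j)
            cols.append(j)
    # diagonal copies match each other at zero cost
    for j in range(n2):
        for i in range(n1):
            rows.append(n1 + j)
            cols.append(n2 + i)
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(size, size)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum()) == size


def bottleneck_distance(d1: Diagram, d2: Diagram) -> float:
    """Exact bottleneck distance between two diagrams of the same dimension.

    Points may match the diagonal at cost ``(death - birth) / 2``.  Points of
    infinite death can only match each other (convention ``inf - inf = 0``),
    at cost ``|birth - birth'|``; unequal counts of infinite points give an
    infinite distance.  Computed by binary search over candidate costs with a
    bipartite-matching feasibility test — exact for the small diagrams images
    produce.
    """
    if d1.dimension != d2.dimension:
        raise ValueError("diagrams must have the same dimension")
    inf1 = sorted(p.birth for p in d1.infinite)
    inf2 = sorted(p.birth for p in d2.infinite)
    if len(inf1) != len(inf2):
        return math.inf
    inf_cost = max((abs(a - b) for a, b in zip(inf1, inf2)), default=0.0)

    pts1 = np.array([(p.birth, p.death) for p in d1.finite], dtype=float).reshape(-1, 2)
    pts2 = np.array([(p.birth, p.death) for p in d2.finite], dtype=float).reshape(-1, 2)
    if len(pts1) == 0 and len(pts2) == 0:
        return inf_cost

    candidates = {0.0}
    for pts in (pts1, pts2):
        candidates.update(((pts[:, 1] - pts[:, 0]) / 2.0).tolist())
    if len(pts1) and len(pts2):
        cross = np.maximum(
            np.abs(pts1[:, 0, None] - pts2[None, :, 0]),
            np.abs(pts1[:, 1, None] - pts2[None, :, 1]),
        )
        candidates.update(cross.ravel().tolist())
    cand = sorted(c for c in candidates if c >= 0)
    lo, hi = 0, len(cand) - 1
    # smallest candidate for which a perfect matching exists
    while lo < hi:
        mid = (lo + hi) // 2
        if _finite_match_feasible(pts1, pts2, cand[mid]):
            hi = mid
        else:
            lo = mid + 1
    return max(inf_cost, cand[lo])
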