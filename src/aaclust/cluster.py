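"""Agglomerative hierarchical clustering over composition vectors.

Distances are Euclidean over the 20 frequency columns.  The merge hierarchy
is built natively for the seven classical linkage schemes:

* ``single``, ``complete``, ``average`` (UPGMA), ``weighted`` (WPGMA) and
  ``ward`` use the nearest-neighbor-chain algorithm, which is valid for these
  reducible schemes and needs O(n^2) distance evaluations;
* ``centroid`` and ``median`` use the generic repeated-global-minimum
  algorithm, because the chain algorithm is invalid for non-reducible
  schemes; their dendrograms may contain inversions, which are preserved.

Inter-cluster distances are maintained with the Lance–Williams update.  For
ward, centroid and median the update runs on *squared* Euclidean distances
and merge heights are reported as square roots ("Euclidean in, Euclidean
out"), so two singleton clusters always merge at exactly their Euclidean
distance.

Ties between candidate merges are broken deterministically: the pair with
the smaller (min cluster index, max cluster index) wins, where leaves are
clusters 0..n-1 and the k-th merge creates cluster n+k.

:func:`naive_linkage` is a deliberately independent O(n^3) implementation
that recomputes every inter-cluster distance from its definition (min/max/
mean over original pairwise distances; centroid and variance terms from
quadratic forms of the squared-distance matrix).  It exists as a testing
oracle for :func:`linkage` and shares only the tie-break rule with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CompositionTable

__all__ = [
    "SCHEMES",
    "MONOTONE_SCHEMES",
    "DistanceMatrix",
    "Dendrogram",
    "euclidean_condensed",
    "linkage",
    "naive_linkage",
    "cut",
    "write_merges",
    "read_merges",
]

SCHEMES = ("single", "complete", "average", "weighted", "ward", "centroid", "median")

#: Schemes whose merge heights are guaranteed non-decreasing.
MONOTONE_SCHEMES = frozenset(("single", "complete", "average", "weighted", "ward"))

_NN_CHAIN_SCHEMES = MONOTONE_SCHEMES
#: Schemes whose Lance-Williams recurrence runs on squared distances.
_SQUARED_SCHEMES = frozenset(("ward", "centroid", "median"))


@dataclass
class DistanceMatrix:
    """Pairwise distances in canonical condensed order ((i,j), i<j, lexicographic)."""

    n: int
    condensed: np.ndarray

    def __post_init__(self) -> None:
        self.condensed = np.asarray(self.condensed, dtype=np.float64)
        expected = self.n * (self.n - 1) // 2
        if self.condensed.shape != (expected,):
            raise ValueError(
                f"condensed length {self.condensed.shape} does not match n={self.n}"
            )

    def as_square(self) -> np.ndarray:
        """Full symmetric (n, n) matrix with zero diagonal."""
        sq = np.zeros((self.n, self.n))
        iu = np.triu_indices(self.n, k=1)
        sq[iu] = self.condensed
        return sq + sq.T


@dataclass
class Dendrogram:
    """Full merge history over ``n_leaves`` points.

    ``merges`` has one row per merge: (left, right, height, size), where
    left/right are cluster indices (leaves 0..n-1; the k-th merge creates
    cluster n+k), ``height`` is the merge distance and ``size`` the number of
    leaves in the new cluster.  The layout matches a scipy linkage matrix.
    """

    n_leaves: int
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=np.float64)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("merges must have shape (n_leaves - 1, 4)")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def has_inversions(self) -> bool:
        """True if some merge is lower than an earlier one (centroid/median only)."""
        return bool(np.any(np.diff(self.heights) < -1e-12))


def euclidean_condensed(table) -> DistanceMatrix:
    """Condensed Euclidean distance matrix over a composition table (or array).

    Computed row-chunked, so memory beyond the condensed output stays O(n)
    even for very large inputs.
    """
    X = table.matrix if isinstance(table, CompositionTable) else np.asarray(table, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite value in feature matrix")
    n = X.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(n - 1):
        diff = X[i + 1 :] - X[i]
        out[pos : pos + n - 1 - i] = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        pos += n - 1 - i
    return DistanceMatrix(n=n, condensed=out)


# -- condensed-layout helpers ------------------------------------------------


def _row_positions(n: int, i: int) -> np.ndarray:
    """Condensed positions of pairs (i, j) for every j (position i is a dummy)."""
    j = np.arange(n)
    pos = np.empty(n, dtype=np.intp)
    upper = j > i
    lower = j < i
    pos[upper] = i * n - i * (i + 1) // 2 + (j[upper] - i - 1)
    jj = j[lower]
    pos[lower] = jj * n - jj * (jj + 1) // 2 + (i - jj - 1)
    pos[i] = 0
    return pos


def _validate(dist: DistanceMatrix, scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown linkage scheme {scheme!r}; choose from {SCHEMES}")
    if dist.n < 2:
        raise ValueError("clustering needs at least 2 points")
    if not np.all(np.isfinite(dist.condensed)):
        raise ValueError("non-finite distance")
    if np.any(dist.condensed < 0):
        raise ValueError("negative distance")


# -- nearest-neighbor chain (reducible schemes) ------------------------------


def _lw_update(scheme, dxk, dyk, dxy, sx, sy, sk):
    if scheme == "single":
        return np.minimum(dxk, dyk)
    if scheme == "complete":
        return np.maximum(dxk, dyk)
    if scheme == "average":
        return (sx * dxk + sy * dyk) / (sx + sy)
    if scheme == "weighted":
        return 0.5 * (dxk + dyk)
    if scheme == "ward":  # on squared distances
        return ((sx + sk) * dxk + (sy + sk) * dyk - sk * dxy) / (sx + sy + sk)
    if scheme == "centroid":  # on squared distances
        return (sx * dxk + sy * dyk) / (sx + sy) - sx * sy * dxy / (sx + sy) ** 2
    if scheme == "median":  # on squared distances
        return 0.5 * dxk + 0.5 * dyk - 0.25 * dxy
    raise AssertionError(scheme)


def _nn_chain(dist: DistanceMatrix, scheme: str) -> np.ndarray:
    n = dist.n
    D = dist.condensed.copy()
    if scheme == "ward":
        D **= 2
    size = np.ones(n, dtype=np.intp)
    active = np.ones(n, dtype=bool)
    raw = np.empty((n - 1, 3))
    chain: list[int] = []
    for m in range(n - 1):
        if not chain:
            chain.append(int(np.flatnonzero(active)[0]))
        while True:
            x = chain[-1]
            prev = chain[-2] if len(chain) > 1 else -1
            row = D[_row_positions(n, x)].copy()
            row[x] = np.inf
            row[~active] = np.inf
            y = int(np.argmin(row))  # ties: smallest slot index
            if prev >= 0 and row[prev] <= row[y]:
                y = prev  # prefer the predecessor so the chain terminates
            if y == prev:
                break
            chain.append(y)
        chain.pop()
        chain.pop()
        pos_x = _row_positions(n, x)
        pos_y = _row_positions(n, y)
        dxy = D[pos_x[y]]
        raw[m] = (x, y, dxy)
        keep, drop = (x, y) if x < y else (y, x)
        others = np.flatnonzero(active)
        others = others[(others != x) & (others != y)]
        if others.size:
            new = _lw_update(
                scheme, D[pos_x[others]], D[pos_y[others]], dxy,
                size[x], size[y], size[others],
            )
            pos_keep = pos_x if keep == x else pos_y
            D[pos_keep[others]] = new
        size[keep] = size[x] + size[y]
        active[drop] = False
    if scheme == "ward":
        raw[:, 2] = np.sqrt(np.maximum(raw[:, 2], 0.0))
    return raw


def _label_sorted(raw: np.ndarray, n: int) -> np.ndarray:
    """Sort raw (slot, slot, height) merges by height and assign canonical ids."""
    order = np.argsort(raw[:, 2], kind="stable")
    parent = np.arange(2 * n - 1, dtype=np.intp)
    size = np.ones(2 * n - 1, dtype=np.intp)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    Z = np.empty((n - 1, 4))
    for k, idx in enumerate(order):
        x, y, h = raw[idx]
        rx, ry = find(int(x)), find(int(y))
        a, b = (rx, ry) if rx < ry else (ry, rx)
        new = n + k
        parent[rx] = parent[ry] = new
        size[new] = size[rx] + size[ry]
        Z[k] = (a, b, h, size[new])
    return Z


# -- generic algorithm (centroid / median) -----------------------------------


def _argmin_tiebreak(M: np.ndarray, ids: np.ndarray, active: np.ndarray):
    """Global minimum of M over active pairs; ties broken by cluster ids."""
    Mv = M.copy()
    Mv[~active, :] = np.inf
    Mv[:, ~active] = np.inf
    np.fill_diagonal(Mv, np.inf)
    m = Mv.min()
    ps, qs = np.nonzero(Mv == m)
    best = None
    for p, q in zip(ps, qs):
        if p >= q:
            continue
        key = (min(ids[p], ids[q]), max(ids[p], ids[q]))
        if best is None or key < best[0]:
            best = (key, int(p), int(q))
    assert best is not None
    return best[1], best[2], float(m)


def _generic_linkage(dist: DistanceMatrix, scheme: str) -> np.ndarray:
    n = dist.n
    M = dist.as_square() ** 2  # centroid/median run on squared distances
    np.fill_diagonal(M, np.inf)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n, dtype=np.intp)
    size = np.ones(n, dtype=np.intp)
    Z = np.empty((n - 1, 4))
    for k in range(n - 1):
        x, y, m = _argmin_tiebreak(M, ids, active)
        h = float(np.sqrt(max(m, 0.0)))
        ida, idb = sorted((ids[x], ids[y]))
        Z[k] = (ida, idb, h, size[x] + size[y])
        others = np.flatnonzero(active)
        others = others[(others != x) & (others != y)]
        if others.size:
            new = _lw_update(scheme, M[x, others], M[y, others], m,
                             size[x], size[y], size[others])
            M[x, others] = M[others, x] = new
        size[x] += size[y]
        ids[x] = n + k
        active[y] = False
    return Z


def linkage(dist: DistanceMatrix, scheme: str = "ward") -> Dendrogram:
    """Agglomerative merge tree of ``dist`` under a linkage scheme.

    Uses the nearest-neighbor-chain algorithm for the five reducible schemes
    (merges re-sorted by height afterwards, which is valid because their
    heights are monotone) and the generic global-minimum algorithm for
    centroid and median.
    """
    _validate(dist, scheme)
    if scheme in _NN_CHAIN_SCHEMES:
        raw = _nn_chain(dist, scheme)
        Z = _label_sorted(raw, dist.n)
    else:
        Z = _generic_linkage(dist, scheme)
    return Dendrogram(n_leaves=dist.n, merges=Z)


# -- first-principles oracle -------------------------------------------------


def naive_linkage(dist: DistanceMatrix, scheme: str = "ward") -> Dendrogram:
    """O(n^3) reference agglomeration computing cluster distances from scratch.

    Each step scans the full current inter-cluster matrix for the global
    minimum (same tie-break as :func:`linkage`) and derives the new cluster's
    distances directly from the original pairwise distances:

    * single/complete/average: min / max / mean over cross pairs;
    * weighted and median: bilinear forms with dyadic (2^-depth) leaf weights;
    * ward and centroid: centroid separation recovered from quadratic forms
      of the squared-distance matrix, ward scaled by 2*na*nb/(na+nb).

    No Lance-Williams recurrence is used anywhere.
    """
    _validate(dist, scheme)
    n = dist.n
    Dfull = dist.as_square()
    D2 = Dfull**2

    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    # leaf-weight vector of each cluster's representative point:
    # uniform 1/size for centroid/ward, dyadic for median/weighted
    w: list[np.ndarray] = [np.eye(n)[i] for i in range(n)]
    size = np.ones(n, dtype=np.intp)
    ids = np.arange(n, dtype=np.intp)
    active = np.ones(n, dtype=bool)
    u2 = [D2 @ w[i] for i in range(n)]  # cached D2 @ w
    uplain = [Dfull @ w[i] for i in range(n)]
    s2 = [0.0] * n  # w^T D2 w (self term)
    squared = scheme in _SQUARED_SCHEMES
    dyadic = scheme in ("weighted", "median")

    def centroid_sq(a: int, b: int) -> float:
        return float(w[b] @ u2[a] - 0.5 * s2[a] - 0.5 * s2[b])

    def cluster_distance(a: int, b: int) -> float:
        if scheme == "single":
            return float(Dfull[np.ix_(members[a], members[b])].min())
        if scheme == "complete":
            return float(Dfull[np.ix_(members[a], members[b])].max())
        if scheme == "average":
            return float(Dfull[np.ix_(members[a], members[b])].mean())
        if scheme == "weighted":
            return float(w[b] @ uplain[a])
        if scheme == "centroid":
            return centroid_sq(a, b)
        if scheme == "median":
            return centroid_sq(a, b)
        if scheme == "ward":
            na, nb = size[a], size[b]
            return 2.0 * na * nb / (na + nb) * centroid_sq(a, b)
        raise AssertionError(scheme)

    M = Dfull**2 if squared else Dfull.copy()
    np.fill_diagonal(M, np.inf)
    Z = np.empty((n - 1, 4))
    for k in range(n - 1):
        x, y, m = _argmin_tiebreak(M, ids, active)
        h = float(np.sqrt(max(m, 0.0))) if squared else m
        ida, idb = sorted((ids[x], ids[y]))
        Z[k] = (ida, idb, h, size[x] + size[y])
        # merge y into x, recompute x's row from first principles
        members[x] = np.concatenate([members[x], members[y]])
        if dyadic:
            w[x] = 0.5 * (w[x] + w[y])
        else:
            w[x] = (size[x] * w[x] + size[y] * w[y]) / (size[x] + size[y])
        u2[x] = D2 @ w[x]
        uplain[x] = Dfull @ w[x]
        s2[x] = float(w[x] @ u2[x])
        size[x] += size[y]
        ids[x] = n + k
        active[y] = False
        for other in np.flatnonzero(active):
            if other == x:
                continue
            M[x, other] = M[other, x] = cluster_distance(x, int(other))
    return Dendrogram(n_leaves=n, merges=Z)


# -- flat cuts and merge-table I/O -------------------------------------------


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat partition obtained by undoing the last ``k - 1`` merges.

    Returns one integer label per leaf; labels 0..k-1 are assigned in order
    of first occurrence over leaf indices.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = np.arange(2 * n - 1, dtype=np.intp)
    for i, row in enumerate(dendrogram.merges[: n - k]):
        parent[int(row[0])] = parent[int(row[1])] = n + i

    def find(x: int) -> int:
        while parent[x] != x:
            x = parent[x]
        return x

    labels = np.empty(n, dtype=np.intp)
    remap: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        labels[leaf] = remap.setdefault(root, len(remap))
    return labels


def write_merges(dendrogram: Dendrogram, path) -> None:
    """Write the merge table as TSV (left, right, height, size)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("left\tright\theight\tsize\n")
        for left, right, height, sz in dendrogram.merges:
            fh.write(f"{int(left)}\t{int(right)}\t{repr(float(height))}\t{int(sz)}\n")


def read_merges(path) -> Dendrogram:
    """Read a merge table written by :func:`write_merges`."""
    with open(path, encoding="ascii") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != ["left", "right", "height", "size"]:
        raise ValueError(f"{path}:1: malformed merge-table header")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        try:
            rows.append([int(cells[0]), int(cells[1]), float(cells[2]), int(cells[3])])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad cell ({exc})") from None
    return Dendrogram(n_leaves=len(rows) + 1, merges=np.array(rows, dtype=np.float64))
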