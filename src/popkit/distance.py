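"""Genetic distances between band profiles and UPGMA dendrograms.

Two binary-profile coefficients are provided, both over pairwise-complete
positions with shared-absence (0,0) pairs ignored:

* Jaccard distance  d = 1 - a/(a+b+c)       (used for AMOVA)
* Nei-Li distance   d = 1 - 2a/(2a+b+c)     (Dice complement, used for
  clustering; the field convention for "Nei's genetic distance" on
  individual band data)

where a = #(1,1), b = #(1,0), c = #(0,1).

UPGMA builds an ultrametric rooted tree by iteratively merging the closest
pair of clusters, with the new cluster's distance to others the size-weighted
arithmetic mean, merge height d_min/2, and ties broken on the
lexicographically smallest pair of cluster representatives (each cluster is
represented by its smallest leaf label), so results are platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, BandMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "jaccard_distance",
    "nei_li_distance",
    "pairwise_distance_matrix",
    "upgma",
    "cut_tree",
]


def _abc(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    ok = (x != MISSING) & (y != MISSING)
    a = int(np.sum((x == 1) & (y == 1) & ok))
    b = int(np.sum((x == 1) & (y == 0) & ok))
    c = int(np.sum((x == 0) & (y == 1) & ok))
    return a, b, c


def jaccard_distance(x: np.ndarray, y: np.ndarray) -> float:
    a, b, c = _abc(np.asarray(x), np.asarray(y))
    if a + b + c == 0:
        raise ValueError("undefined distance: no informative positions")
    return 1.0 - a / (a + b + c)


def nei_li_distance(x: np.ndarray, y: np.ndarray) -> float:
    a, b, c = _abc(np.asarray(x), np.asarray(y))
    if a + b + c == 0:
        raise ValueError("undefined distance: no informative positions")
    return 1.0 - 2.0 * a / (2.0 * a + b + c)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read(cls, path: str | Path, method: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), method)


def pairwise_distance_matrix(matrix: BandMatrix, method: str = "nei_li") -> DistanceMatrix:
    fn = {"jaccard": jaccard_distance, "nei_li": nei_li_distance}[method]
    vals = matrix.values.to_numpy()
    n = vals.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(vals[i], vals[j])
    return DistanceMatrix(matrix.accession_ids, d, method)


@dataclass
class Dendrogram:
    """UPGMA tree stored as a scipy-style linkage plus leaf labels.

    ``linkage[m] = (i, j, height, size)`` merges clusters i and j (indices
    < n are leaves, >= n earlier merges) at the given ultrametric height
    (half the inter-cluster distance).
    """

    labels: list[str]
    linkage: np.ndarray
    merge_order: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic(self) -> np.ndarray:
        """n x n matrix of tree distances (2 x merge height) between leaves."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for m, (i, j, h, _) in enumerate(self.linkage):
            left, right = members.pop(int(i)), members.pop(int(j))
            for a in left:
                for b in right:
                    out[a, b] = out[b, a] = 2.0 * h
            members[n + m] = left + right
        return out

    def to_newick(self, precision: int = 10) -> str:
        n = self.n_leaves
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for m, (i, j, h, _) in enumerate(self.linkage):
            i, j = int(i), int(j)
            bl_i = h - height[i]
            bl_j = h - height[j]
            rep[n + m] = (
                f"({rep[i]}:{bl_i:.{precision}f},{rep[j]}:{bl_j:.{precision}f})"
            )
            height[n + m] = h
        return rep[n + len(self.linkage) - 1] + ";"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Size-weighted average-linkage (UPGMA) agglomeration."""
    n = len(D.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if np.isnan(D.d).any():
        raise ValueError("NaN in distance matrix")
    dist = {frozenset((i, j)): D.d[i, j] for i in range(n) for j in range(i + 1, n)}
    active: dict[int, dict] = {
        i: {"size": 1, "rep": D.ids[i]} for i in range(n)
    }
    linkage = np.zeros((n - 1, 4))
    merge_order: list[tuple[int, int]] = []
    next_id = n
    for step in range(n - 1):
        # closest pair; ties -> lexicographically smallest (rep_i, rep_j)
        best = None
        for key, val in dist.items():
            i, j = sorted(key)
            reps = tuple(sorted((active[i]["rep"], active[j]["rep"])))
            cand = (val, reps)
            if best is None or cand < best[0]:
                best = (cand, i, j)
        (dmin, _), i, j = best
        si, sj = active[i]["size"], active[j]["size"]
        new = {"size": si + sj, "rep": min(active[i]["rep"], active[j]["rep"])}
        for k in list(active):
            if k in (i, j):
                continue
            dk = (si * dist.pop(frozenset((i, k))) + sj * dist.pop(frozenset((j, k)))) / (
                si + sj
            )
            dist[frozenset((next_id, k))] = dk
        dist.pop(frozenset((i, j)))
        del active[i], active[j]
        active[next_id] = new
        linkage[step] = (i, j, dmin / 2.0, new["size"])
        merge_order.append((i, j))
        next_id += 1
    return Dendrogram(list(D.ids), linkage, merge_order)


def cut_tree(tree: Dendrogram, k: int) -> pd.Series:
    """Group labels from cutting the k-1 highest merges.

    Groups are numbered 0..k-1 in order of first appearance along the leaf
    (input) order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # keep the n-k lowest merges (linkage rows are produced in height order
    # only up to ties; sort explicitly by height)
    order = np.argsort(tree.linkage[:, 2], kind="stable")
    for m in order[: n - k]:
        i, j = int(tree.linkage[m, 0]), int(tree.linkage[m, 1])
        root = n + int(m)
        parent[find(i)] = root
        parent[find(j)] = root
    labels: dict[int, int] = {}
    out = []
    for leaf in range(n):
        r = find(leaf)
        if r not in labels:
            labels[r] = len(labels)
        out.append(labels[r])
    return pd.Series(out, index=tree.labels, name="group")
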