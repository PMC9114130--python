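"""Agglomerative hierarchical clustering with minimax linkage and prototypes.

Minimax linkage defines the distance between two clusters G and H as the
smallest radius of a ball, centred on a *member* point, that covers G ∪ H:

    d(G, H) = min_{c in G∪H}  max_{x in G∪H}  dist(c, x)

The minimising centre is the merged cluster's *prototype* — an actual data
point (here: a colony, hence an image series) that best represents the
cluster.  Unlike centroid linkage the representative always exists in the
data, and unlike average linkage the merge heights are monotone (no
dendrogram inversions), so horizontal cuts are interpretable.

Cuts can be taken at a height or at a cluster count k; the number of
clusters is chosen by maximising the Calinski–Harabasz (CH) index — the
ratio of between- to within-cluster dispersion of the flattened trajectory
vectors, normalised by degrees of freedom.

Everything is deterministic: ties in merge order are broken by the smallest
(node-index) pair, ties in the prototype by the smallest leaf index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import CondensedDistances

__all__ = [
    "Merge",
    "Dendrogram",
    "CutResult",
    "CH_DEGENERATE",
    "minimax_radius",
    "minimax_linkage",
    "cut_at",
    "ch_index",
    "select_cut",
    "ch_curve",
]

#: Sentinel CH score for a degenerate partition with zero within-cluster
#: scatter; finite, deterministic, and larger than any realistic score.
CH_DEGENERATE = 1e300


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    size: int
    prototype: int


@dataclass
class Dendrogram:
    """Merge tree: leaves 0..n-1, internal nodes n..2n-2 in merge order."""

    n_leaves: int
    merges: list[Merge]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a full dendrogram has n-1 merges")

    @property
    def root_prototype(self) -> int:
        return self.merges[-1].prototype

    def node_members(self) -> list[np.ndarray]:
        """Leaf sets of every node, indexed 0..2n-2."""
        members = [np.array([i]) for i in range(self.n_leaves)]
        for m in self.merges:
            members.append(np.sort(np.concatenate([members[m.left], members[m.right]])))
        return members

    def to_linkage_matrix(self) -> np.ndarray:
        """The common (n-1, 4) linkage-matrix layout: left, right, height, size."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )


@dataclass
class CutResult:
    """A partition of the leaves with one prototype per cluster."""

    labels: np.ndarray
    prototypes: dict[int, int]
    k: int
    ch: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k != len(set(self.labels.tolist())):
            raise ValueError("k must equal the number of distinct labels")
        for cid, proto in self.prototypes.items():
            if self.labels[proto] != cid:
                raise ValueError("each prototype must belong to its own cluster")


def minimax_radius(
    members: Sequence[int] | np.ndarray, dist: np.ndarray
) -> tuple[float, int]:
    """Smallest member-centred covering radius of a leaf set, and its centre.

    Ties on the radius go to the smallest leaf index.
    """
    m = np.asarray(sorted(members), dtype=int)
    if m.size == 0:
        raise ValueError("member set must be nonempty")
    sub = dist[np.ix_(m, m)]
    maxd = sub.max(axis=1)
    i = int(np.argmin(maxd))  # first minimum = smallest leaf (m is sorted)
    return float(maxd[i]), int(m[i])


def minimax_linkage(cd: CondensedDistances | np.ndarray) -> Dendrogram:
    """Full agglomerative clustering under minimax linkage.

    At each step the pair of active clusters with the smallest minimax
    radius of their union is merged (ties: smallest node-index pair); the
    merge height is that radius and the union's minimax centre is recorded
    as the new node's prototype.
    """
    D = cd.to_square() if isinstance(cd, CondensedDistances) else np.asarray(cd, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two leaves")

    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    # linkage[(a, b)] for active node ids a < b
    linkage: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n - 1) for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    for step in range(n - 1):
        (a, b), _h = min(linkage.items(), key=lambda kv: (kv[1], kv[0]))
        union = np.sort(np.concatenate([members[a], members[b]]))
        height, proto = minimax_radius(union, D)
        new_id = n + step
        merges.append(
            Merge(left=a, right=b, height=height, size=union.size, prototype=proto)
        )
        for key in [k for k in linkage if a in k or b in k]:
            del linkage[key]
        del members[a], members[b]
        for other, om in members.items():
            u = np.concatenate([om, union])
            sub = D[np.ix_(u, u)]
            linkage[(min(other, new_id), max(other, new_id))] = float(
                sub.max(axis=1).min()
            )
        members[new_id] = union
    return Dendrogram(n_leaves=n, merges=merges)


def cut_at(
    dendro: Dendrogram, height: float | None = None, k: int | None = None
) -> CutResult:
    """Partition the leaves at a height or into k clusters.

    Clusters are the subtrees directly below the cut; ids are assigned in
    order of each cluster's smallest leaf index, and prototypes are carried
    from the subtree roots.  A negative height puts every leaf in its own
    cluster.
    """
    n = dendro.n_leaves
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    if height is not None:
        n_merges = sum(1 for m in dendro.merges if m.height <= height)
    else:
        if not (1 <= k <= n):
            raise ValueError(f"k must lie in [1, {n}]")
        n_merges = n - k

    active: dict[int, tuple[np.ndarray, int]] = {
        i: (np.array([i]), i) for i in range(n)
    }
    for step in range(n_merges):
        m = dendro.merges[step]
        union = np.sort(np.concatenate([active[m.left][0], active[m.right][0]]))
        del active[m.left], active[m.right]
        active[n + step] = (union, m.prototype)

    clusters = sorted(active.values(), key=lambda mp: mp[0][0])
    labels = np.empty(n, dtype=int)
    prototypes: dict[int, int] = {}
    for cid, (mem, proto) in enumerate(clusters):
        labels[mem] = cid
        prototypes[cid] = proto
    return CutResult(labels=labels, prototypes=prototypes, k=len(clusters))


def ch_index(labels: np.ndarray, feature_vectors: np.ndarray) -> float:
    """Calinski–Harabasz score of a partition of the feature vectors.

    CH = [B/(k-1)] / [W/(n-k)] with B the between-cluster and W the
    within-cluster sum of squares.  Defined for 2 <= k <= n-1; a partition
    with W = 0 returns the :data:`CH_DEGENERATE` sentinel.
    """
    X = np.asarray(feature_vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels and feature_vectors disagree in length")
    ks = np.unique(labels)
    k = ks.size
    if not (2 <= k <= n - 1):
        raise ValueError(f"CH index undefined for k={k} with n={n}")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in ks:
        Xc = X[labels == c]
        cen = Xc.mean(axis=0)
        B += Xc.shape[0] * float(((cen - grand) ** 2).sum())
        W += float(((Xc - cen) ** 2).sum())
    if W == 0.0:
        return CH_DEGENERATE
    return (B / (k - 1)) / (W / (n - k))


def select_cut(
    dendro: Dendrogram,
    feature_vectors: np.ndarray,
    k_range: tuple[int, int] | None = None,
) -> CutResult:
    """Scan cuts over a k range and return the CH-maximising partition.

    The default range is (2, min(50, ceil(sqrt(n)))).  CH is an F-ratio-like
    statistic: it is only comparable across k while clusters keep several
    members each, and as k approaches n the within-cluster scatter collapses
    toward zero and CH diverges for *any* data, so the scan must stay well
    below n.  The sqrt(n) ceiling is the usual rule of thumb; the cap of 50
    keeps large-ensemble scans tractable.  Ties go to the smallest k.
    """
    n = dendro.n_leaves
    if k_range is None:
        k_range = (2, max(2, min(50, int(np.ceil(np.sqrt(n))))))
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= n):
        raise ValueError(f"invalid k_range {k_range} for n={n}")
    best: CutResult | None = None
    for k in range(k_min, k_max + 1):
        cut = cut_at(dendro, k=k)
        if not (2 <= cut.k <= n - 1):
            continue
        cut.ch = ch_index(cut.labels, feature_vectors)
        if best is None or cut.ch > best.ch:
            best = cut
    if best is None:
        raise ValueError("no valid cut in the requested range")
    return best


def ch_curve(
    dendro: Dendrogram, feature_vectors: np.ndarray, k_range: tuple[int, int]
) -> list[tuple[int, float]]:
    """CH score for each k in the range (for diagnostics and CSV output)."""
    out = []
    for k in range(k_range[0], k_range[1] + 1):
        cut = cut_at(dendro, k=k)
        out.append((k, ch_index(cut.labels, feature_vectors)))
    return out
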