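"""Cluster-proposal generation: mode seeking on the L field plus
topographic-prominence merging, swept over an (r, T) grid.

A single radius r fixes the L3D(r) field and the CSR eligibility mask; the
eligible points and their r-neighbour graph (toroidal metric) form a
discrete landscape in which each point climbs to a local maximum (mode) of
L.  Modes are then pruned by topographic prominence: a mode whose height
above the highest saddle connecting it to a higher mode is below the
threshold T (nm, in L units) is merged into that higher mode's basin —
the persistence-based formalisation of prominence on a neighbour graph
(ToMATo-style).  Each (r, T) pair yields one cluster proposal; the sweep
deduplicates proposals by their labelling so the Bayesian model scores each
distinct partition once.

Total order on points: point a is "higher" than b iff
(L[a], a) > (L[b], b) lexicographically — ties in L are broken towards the
larger point index, which makes climbing and merging fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .locio import ROI, LocalizationTable
from .ripley3d import csr_eligibility_threshold, eligible_mask, l3d_all

#: Smallest admissible cluster.  Under the default radius prior, chance
#: aggregates of up to ~4 background points gain posterior score when
#: labelled as a cluster, so smaller basins are returned to background;
#: 5 is the smallest size at which proposals stay model-identifiable.
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True)
class SweepGrid:
    """Radii r (nm) and prominence thresholds T (nm) to sweep, ascending.

    Radii span the plausible cluster scales (20-200 nm).  Prominence
    thresholds are on the L scale — local L values reach several hundred
    nm in clustered data — so the default T grid spans 0-200 nm in order
    to reach the prominence of marginal density peaks, not just the
    cluster-radius scale.
    """

    r_values: tuple = tuple(range(20, 201, 10))
    t_values: tuple = tuple(range(0, 201, 10))

    def __post_init__(self):
        r = tuple(sorted(set(float(v) for v in self.r_values)))
        t = tuple(sorted(set(float(v) for v in self.t_values)))
        if not r or not t:
            raise ValueError("sweep grid must be non-empty")
        if min(r) <= 0 or min(t) < 0:
            raise ValueError("radii must be positive and thresholds non-negative")
        object.__setattr__(self, "r_values", r)
        object.__setattr__(self, "t_values", t)


@dataclass
class ClusterProposal:
    """An integer labelling of all points: 0 = background, 1..K = clusters."""

    labels: np.ndarray
    r: float
    T: float

    @property
    def K(self) -> int:
        return int(self.labels.max(initial=0))

    def signature(self) -> tuple:
        """Canonical form of the partition, invariant to cluster-id permutation."""
        remap: dict[int, int] = {}
        out = []
        for lab in self.labels:
            lab = int(lab)
            if lab == 0:
                out.append(0)
            else:
                out.append(remap.setdefault(lab, len(remap) + 1))
        return tuple(out)


def _higher(L: np.ndarray, a: int, b: int) -> bool:
    """True iff point a is higher than point b in the (L, index) total order."""
    return (L[a], a) > (L[b], b)


def neighbour_graph(xyz: np.ndarray, indices: np.ndarray, roi: ROI, r: float) -> dict:
    """Adjacency lists (toroidal distance < r) among the given point indices."""
    adj: dict[int, list[int]] = {int(i): [] for i in indices}
    if len(indices) < 2:
        return adj
    sub = np.mod(xyz[indices], roi.lengths)
    tree = cKDTree(sub, boxsize=roi.lengths)
    for a, b in tree.query_pairs(r, output_type="ndarray"):
        d = np.abs(sub[a] - sub[b])
        d = np.minimum(d, roi.lengths - d)
        if (d * d).sum() < r * r:
            ia, ib = int(indices[a]), int(indices[b])
            adj[ia].append(ib)
            adj[ib].append(ia)
    return adj


def climb_to_modes(eligible_idx: np.ndarray, L: np.ndarray, adj: dict):
    """Assign every eligible point to the mode reached by steepest ascent.

    Each point repeatedly moves to its highest neighbour that is strictly
    higher than itself (in the (L, index) order); a point with no higher
    neighbour is a mode.  Returns ``(mode_of, modes)`` where ``mode_of``
    maps point index -> mode index and ``modes`` is sorted by index.
    """
    parent: dict[int, int] = {}
    for i in eligible_idx:
        i = int(i)
        best = i
        for j in adj.get(i, ()):
            if _higher(L, j, best):
                best = j
        parent[i] = best  # best == i marks a mode

    mode_of: dict[int, int] = {}

    def find_mode(i: int) -> int:
        path = []
        while parent[i] != i:
            if i in mode_of:
                break
            path.append(i)
            i = parent[i]
        m = mode_of.get(i, i)
        for p in path:
            mode_of[p] = m
        mode_of[i] = m
        return m

    for i in eligible_idx:
        find_mode(int(i))
    modes = sorted({mode_of[int(i)] for i in eligible_idx})
    return mode_of, modes


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, child, root):
        self.parent[self.find(child)] = self.find(root)


def prominence_merge(mode_of: dict, modes: list, L: np.ndarray, adj: dict,
                     T: float, n_points: int,
                     min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                     r: float = np.nan, l_star: float = 0.0) -> ClusterProposal:
    """Prune low-prominence modes and emit a cluster proposal.

    Eligible points are processed in descending (L, index) order.  When an
    edge first connects the basin of a lower mode m to a higher basin, the
    saddle level is the current point's L and the prominence of m is
    L(m) - L_saddle; if that prominence is below T the basin of m merges
    into the higher basin, otherwise m survives permanently.  A mode whose
    basin never meets a higher basin is an *island*: its prominence is its
    height above the CSR eligibility level, L(m) - ``l_star`` (the
    geographic convention of measuring an isolated summit from sea level),
    and below T its points return to background.  Surviving basins with at
    least ``min_cluster_size`` points become clusters 1..K (numbered by
    ascending mode index); smaller ones go to background.
    """
    uf = _UnionFind(modes)
    prominence_fixed: set[int] = set()
    order = sorted(mode_of.keys(), key=lambda i: (L[i], i), reverse=True)
    for i in order:
        for j in adj.get(i, ()):
            if not _higher(L, j, i):
                continue
            rj = uf.find(mode_of[j])
            ri = uf.find(mode_of[i])
            if ri == rj:
                continue
            low, high = (ri, rj) if _higher(L, rj, ri) else (rj, ri)
            if low in prominence_fixed:
                continue
            prom = L[low] - L[i]
            if prom < T:
                uf.union(low, high)
            else:
                prominence_fixed.add(low)

    labels = np.zeros(n_points, dtype=np.int64)
    root_of = {i: uf.find(m) for i, m in mode_of.items()}
    roots = sorted(set(root_of.values()))
    sizes = {rt: 0 for rt in roots}
    for i, rt in root_of.items():
        sizes[rt] += 1
    cluster_id = {}
    next_id = 1
    for rt in roots:
        island = rt not in prominence_fixed
        if island and L[rt] - l_star < T:
            continue  # summit not significantly above sea level
        if sizes[rt] >= min_cluster_size:
            cluster_id[rt] = next_id
            next_id += 1
    for i, rt in root_of.items():
        labels[i] = cluster_id.get(rt, 0)
    return ClusterProposal(labels=labels, r=float(r), T=float(T))


def propose_at(table: LocalizationTable, roi: ROI, r: float, t_values,
               min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE):
    """All proposals for one radius: shared L field, eligibility, graph, modes."""
    lvals = l3d_all(table, roi, r)
    mask = eligible_mask(lvals, table.n, roi)
    eligible_idx = np.flatnonzero(mask)
    out = []
    if len(eligible_idx) == 0:
        for T in t_values:
            out.append(ClusterProposal(np.zeros(table.n, dtype=np.int64), float(r), float(T)))
        return out, lvals
    adj = neighbour_graph(table.xyz, eligible_idx, roi, r)
    mode_of, modes = climb_to_modes(eligible_idx, lvals.L, adj)
    _, l_star = csr_eligibility_threshold(table.n, roi, r)
    for T in t_values:
        out.append(prominence_merge(mode_of, modes, lvals.L, adj, float(T),
                                    table.n, min_cluster_size, r=r, l_star=l_star))
    return out, lvals


def sweep(table: LocalizationTable, roi: ROI, grid: SweepGrid | None = None,
          min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE):
    """Distinct cluster proposals over the full (r, T) grid.

    Proposals are deduplicated as partitions (cluster-id permutations and
    generating (r, T) tags are ignored); the all-background proposal is
    always present.  Returns the list in deterministic order: the trivial
    proposal first, then by ascending (r, T) of first occurrence.
    """
    grid = grid or SweepGrid()
    if table.n < 2:
        raise ValueError("sweep requires at least 2 points")
    seen: dict[tuple, ClusterProposal] = {}
    trivial = ClusterProposal(np.zeros(table.n, dtype=np.int64), 0.0, 0.0)
    seen[trivial.signature()] = trivial
    for r in grid.r_values:
        proposals, _ = propose_at(table, roi, r, grid.t_values, min_cluster_size)
        for prop in proposals:
            sig = prop.signature()
            if sig not in seen:
                seen[sig] = prop
    return list(seen.values())
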