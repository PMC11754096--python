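"""Nearest-neighbour and cluster statistics for particle fields.

A *cluster* is a group of >= 2 particles, inside one tomogram, connected
under a centre-to-centre distance rule: with a plain cut-off ``t`` an edge
joins any two particles at distance <= t, with a sweep window ``w`` the edge
requires the distance to fall in the closed interval [t - w, t + w]. Cluster
membership is the single-linkage connected component of that graph (an
order-independent partition); the traced member *ordering* within a cluster
follows greedy closest-unvisited chaining from the lowest-id member, the
way a chain of particles would be walked.

Defaults follow the analysis they implement: cut-off 20 nm for membership,
sweep grid 15-40 nm with a +/-0.5 nm window, pair statistics restricted to
15-20 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .particles import EmptySelectionError, ParticleSet

__all__ = [
    "Cluster",
    "ClusterSummary",
    "SweepResult",
    "ClusterModel",
    "ClusterResults",
    "nearest_neighbors",
    "trace_clusters",
    "threshold_sweep",
    "cluster_summary",
    "topology_classify",
    "proximity_fraction",
]


@dataclass
class Cluster:
    """An ordered group of >= 2 particles connected under the distance rule."""

    member_ids: list[str]  # in traced chain order
    tomogram_id: str
    positions: np.ndarray  # (k, 3) nm, aligned with member_ids
    link_distances: np.ndarray  # (k - 1,) consecutive distances in traced order
    threshold: float
    window: float | None = None

    @property
    def length(self) -> int:
        return len(self.member_ids)

    @property
    def topology(self) -> str:
        return topology_classify(self)


def _edge_mask(d: np.ndarray, threshold: float, window: float | None) -> np.ndarray:
    if window is None:
        return d <= threshold
    return (d >= threshold - window) & (d <= threshold + window)


def nearest_neighbors(ps: ParticleSet, state_filter=None) -> pd.DataFrame:
    """Per-particle nearest neighbour within the same tomogram.

    Returns a DataFrame with columns particle_id, tomogram_id, nn_id,
    nn_dist (nm). Particles alone in their tomogram keep nn_id = None and
    nn_dist = NaN rather than being dropped.
    """
    sub = ps.select_states(state_filter)
    rows = []
    for tid, grp in sub.by_tomogram():
        ids = grp["particle_id"].to_numpy()
        pos = grp[["x", "y", "z"]].to_numpy()
        if len(grp) < 2:
            for pid in ids:
                rows.append((pid, tid, None, np.nan))
            continue
        tree = cKDTree(pos)
        dist, idx = tree.query(pos, k=2)
        for i, pid in enumerate(ids):
            rows.append((pid, tid, ids[idx[i, 1]], float(dist[i, 1])))
    return pd.DataFrame(rows, columns=["particle_id", "tomogram_id", "nn_id", "nn_dist"])


def _chain_order(ids: np.ndarray, pos: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Greedy closest-unvisited ordering starting from the lowest-id member."""
    start = int(np.argmin(ids))
    order = [start]
    remaining = set(range(len(ids))) - {start}
    links = []
    while remaining:
        cur = order[-1]
        rem = np.fromiter(remaining, dtype=int)
        d = np.linalg.norm(pos[rem] - pos[cur], axis=1)
        j = rem[int(np.argmin(d))]
        links.append(float(d.min()))
        order.append(int(j))
        remaining.remove(int(j))
    return order, np.asarray(links)


def trace_clusters(
    ps: ParticleSet,
    threshold: float = 20.0,
    window: float | None = None,
    state_filter=None,
) -> list[Cluster]:
    """Trace particle clusters under the centre-to-centre distance rule.

    Membership is the connected component of the distance graph (edges at
    distance <= threshold, or in [threshold - window, threshold + window]
    when a window is given), restricted to components of size >= 2; clusters
    never span tomograms.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if window is not None and window <= 0:
        raise ValueError("window must be positive when given")
    sub = ps.select_states(state_filter)
    r_max = threshold if window is None else threshold + window
    clusters: list[Cluster] = []
    for tid, grp in sub.by_tomogram():
        ids = grp["particle_id"].to_numpy()
        pos = grp[["x", "y", "z"]].to_numpy()
        n = len(grp)
        if n < 2:
            continue
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=r_max, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
            pairs = pairs[_edge_mask(d, threshold, window)]
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        adj = csr_matrix(
            (np.ones(2 * len(pairs)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = np.flatnonzero(labels == c)
            if len(members) < 2:
                continue
            order, links = _chain_order(ids[members], pos[members])
            clusters.append(
                Cluster(
                    member_ids=[str(ids[members][k]) for k in order],
                    tomogram_id=tid,
                    positions=pos[members][order],
                    link_distances=links,
                    threshold=threshold,
                    window=window,
                )
            )
    return clusters


@dataclass
class SweepResult:
    """Cluster counts over a grid of distance thresholds."""

    table: pd.DataFrame  # threshold, n_clusters, n_clustered_particles, frac_clustered
    length_hists: dict[float, dict[int, int]]
    window: float | None
    n_total: int


def threshold_sweep(
    ps: ParticleSet,
    t_min: float = 15.0,
    t_max: float = 40.0,
    step: float = 1.0,
    window: float | None = 0.5,
    state_filter=None,
) -> SweepResult:
    """Cluster counts at each threshold on a grid, each with the +/- window rule.

    With the default window of 0.5 nm the permissible distance at grid value
    t is the closed interval [t - 0.5, t + 0.5]; a distance landing exactly
    on a boundary belongs to both adjacent bins. ``window=None`` gives the
    cumulative (<= t) rule instead.
    """
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    if step <= 0:
        raise ValueError("step must be positive")
    try:
        sub = ps.select_states(state_filter)
        n_total = len(sub)
    except EmptySelectionError:
        sub, n_total = None, 0
    grid = np.arange(t_min, t_max + 0.5 * step, step)
    rows, hists = [], {}
    for t in grid:
        if sub is None:
            clusters = []
        else:
            clusters = trace_clusters(sub, threshold=float(t), window=window)
        n_part = sum(c.length for c in clusters)
        hist: dict[int, int] = {}
        for c in clusters:
            hist[c.length] = hist.get(c.length, 0) + 1
        rows.append(
            (float(t), len(clusters), n_part, n_part / n_total if n_total else 0.0)
        )
        hists[float(t)] = hist
    table = pd.DataFrame(
        rows, columns=["threshold", "n_clusters", "n_clustered_particles", "frac_clustered"]
    )
    return SweepResult(table=table, length_hists=hists, window=window, n_total=n_total)


@dataclass
class ClusterSummary:
    """Per-cluster-length link-distance statistics plus the clustered fraction."""

    per_length: pd.DataFrame  # length, n_clusters, n_links, mean_nm, sd_nm, single_link
    clustered_fraction: float | None
    d_min: float
    d_max: float


def cluster_summary(
    clusters: list[Cluster],
    d_min: float = 15.0,
    d_max: float = 20.0,
    n_total: int | None = None,
) -> ClusterSummary:
    """Summarise link distances per cluster length.

    Only link distances inside [d_min, d_max] contribute to the mean and the
    sample (n-1) standard deviation; a length whose links all fall outside
    the band is dropped rather than reported as NaN. A single qualifying
    link reports sd 0.0 with the single_link flag set.
    """
    by_len: dict[int, list[float]] = {}
    n_clusters_by_len: dict[int, int] = {}
    clustered = 0
    for c in clusters:
        clustered += c.length
        n_clusters_by_len[c.length] = n_clusters_by_len.get(c.length, 0) + 1
        keep = c.link_distances[(c.link_distances >= d_min) & (c.link_distances <= d_max)]
        by_len.setdefault(c.length, []).extend(keep.tolist())
    rows = []
    for k in sorted(by_len):
        links = np.asarray(by_len[k])
        if len(links) == 0:
            continue
        sd = float(np.std(links, ddof=1)) if len(links) > 1 else 0.0
        rows.append(
            (k, n_clusters_by_len[k], len(links), float(links.mean()), sd, len(links) == 1)
        )
    per_length = pd.DataFrame(
        rows, columns=["length", "n_clusters", "n_links", "mean_nm", "sd_nm", "single_link"]
    )
    frac = clustered / n_total if n_total else None
    return ClusterSummary(per_length=per_length, clustered_fraction=frac, d_min=d_min, d_max=d_max)


def topology_classify(c: Cluster) -> str:
    """Label a cluster's arrangement: linear, circular or other.

    Pairs are linear by convention. For k >= 3 the cluster is circular when
    the two chain endpoints lie within the active distance rule of each
    other (a closing link exists); otherwise linear when the straightness
    ratio end-to-end distance / summed link lengths is >= 0.8; else other.
    """
    if c.length == 2:
        return "linear"
    closing = float(np.linalg.norm(c.positions[0] - c.positions[-1]))
    if _edge_mask(np.array([closing]), c.threshold, c.window)[0]:
        return "circular"
    end_to_end = float(np.linalg.norm(c.positions[-1] - c.positions[0]))
    ratio = end_to_end / float(c.link_distances.sum())
    return "linear" if ratio >= 0.8 else "other"


def proximity_fraction(
    clusters: list[Cluster], tracks: ParticleSet, cutoff: float = 20.0
) -> float:
    """Fraction of clusters with any member within ``cutoff`` of a track point.

    Track points (e.g. filament segment centres) are matched within the same
    tomogram only.
    """
    if not clusters:
        raise EmptySelectionError("no clusters to test for proximity")
    trees = {
        tid: cKDTree(grp[["x", "y", "z"]].to_numpy()) for tid, grp in tracks.by_tomogram()
    }
    proximal = 0
    for c in clusters:
        tree = trees.get(c.tomogram_id)
        if tree is None:
            continue
        d, _ = tree.query(c.positions, k=1)
        if np.min(d) <= cutoff:
            proximal += 1
    return proximal / len(clusters)


class ClusterModel:
    """Spatial cluster analysis of one particle state in a set of tomograms.

    Parameters
    ----------
    particles : ParticleSet holding every state; the model filters to `state`.
    state : label(s) analysed, default "closed" (the clustering state of
        interest; other states run through the identical code path).
    threshold : membership cut-off in nm (centre-to-centre), default 20.
    window : optional +/- window in nm making the edge rule an interval.
    """

    def __init__(self, particles: ParticleSet, state="closed", threshold: float = 20.0,
                 window: float | None = None):
        self.particles = particles
        self.state = state
        self.threshold = threshold
        self.window = window

    def fit(self, d_min: float = 15.0, d_max: float = 20.0) -> "ClusterResults":
        sub = self.particles.select_states(self.state)
        clusters = trace_clusters(sub, self.threshold, self.window)
        summary = cluster_summary(clusters, d_min=d_min, d_max=d_max, n_total=len(sub))
        nn = nearest_neighbors(sub)
        return ClusterResults(self, clusters, summary, nn, len(sub))


class ClusterResults:
    """Clusters, their per-length spacing statistics and the clustered fraction."""

    def __init__(self, model: ClusterModel, clusters, summary: ClusterSummary,
                 neighbor_table: pd.DataFrame, n_total: int):
        self.model = model
        self.clusters = clusters
        self.per_length = summary.per_length
        self.clustered_fraction = summary.clustered_fraction
        self.neighbor_table = neighbor_table
        self.n_total = n_total

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def topology_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clusters:
            out[c.topology] = out.get(c.topology, 0) + 1
        return out

    def sweep(self, t_min: float = 15.0, t_max: float = 40.0, step: float = 1.0,
              window: float | None = 0.5) -> SweepResult:
        sub = self.model.particles.select_states(self.model.state)
        return threshold_sweep(sub, t_min, t_max, step, window)

    def proximity_to(self, tracks: ParticleSet, cutoff: float = 20.0) -> float:
        return proximity_fraction(self.clusters, tracks, cutoff)

    def to_frame(self) -> pd.DataFrame:
        """One row per cluster (members semicolon-joined in traced order)."""
        rows = [
            {
                "tomogram_id": c.tomogram_id,
                "length": c.length,
                "topology": c.topology,
                "members": ";".join(c.member_ids),
                "mean_link_nm": float(c.link_distances.mean()),
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["tomogram_id", "length", "topology", "members", "mean_link_nm"]
        )

    def summary(self) -> str:
        lines = [
            "Cluster analysis",
            f"  state filter        : {self.model.state}",
            f"  threshold (nm)      : {self.model.threshold}"
            + (f" +/- {self.model.window}" if self.model.window else ""),
            f"  particles analysed  : {self.n_total}",
            f"  clusters (>=2)      : {self.n_clusters}",
            f"  clustered fraction  : {self.clustered_fraction:.3f}"
            if self.clustered_fraction is not None
            else "  clustered fraction  : n/a",
            f"  topologies          : {self.topology_counts}",
            "",
            self.per_length.to_string(index=False),
        ]
        return "\n".join(lines)
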