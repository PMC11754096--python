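"""Relative-orientation analysis of clustered particles.

Each cluster member is compared against its nearest in-cluster neighbour:
the neighbour's rotation is expressed in the member's frame, the reference
vector (0, 0, 1) is rotated by that relative rotation, and the result is
mapped to a planar disc by two-sided stereographic projection. Identically
oriented neighbours land on the north pole; a uniform scatter over both
hemisphere discs is the signature of no preferred contact interface.

Uniformity is tested with a Rayleigh-type statistic — the length of the
resultant (mean) pole vector — calibrated by Monte-Carlo draws from the
uniform-on-the-sphere null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import HemispherePoint, eulers_to_matrices
from .particles import ParticleSet

__all__ = [
    "OrientationSample",
    "UniformityResult",
    "OrientationModel",
    "OrientationResults",
    "neighbor_orientation_map",
    "uniformity_test",
    "hemisphere_histogram",
]


@dataclass(frozen=True)
class OrientationSample:
    """One member-to-nearest-neighbour relative rotation and its disc image."""

    particle_id: str
    neighbor_id: str
    rotation: np.ndarray  # (3, 3) relative rotation, reference frame -> neighbour
    pole: np.ndarray  # (3,) image of (0, 0, 1)
    point: HemispherePoint


class InsufficientDataError(ValueError):
    """Too few orientation samples for a meaningful test."""


def neighbor_orientation_map(
    ps: ParticleSet, clusters, dedup: bool = False
) -> list[OrientationSample]:
    """Relative orientation of every cluster member to its nearest in-cluster neighbour.

    One sample per member by default, so each unordered pair contributes
    twice (once per direction); ``dedup=True`` keeps only the direction with
    the lexicographically smaller reference id.
    """
    if not clusters:
        raise ValueError("no clusters given")
    euler_by_id = {
        pid: e for pid, e in zip(ps.df["particle_id"], ps.eulers)
    }
    ref_ids, nb_ids = [], []
    for c in clusters:
        for m, pid in enumerate(c.member_ids):
            if pid not in euler_by_id:
                raise KeyError(f"particle {pid!r} has no orientation in the ParticleSet")
            d = np.linalg.norm(c.positions - c.positions[m], axis=1)
            d[m] = np.inf
            nb = c.member_ids[int(np.argmin(d))]
            if dedup and pid > nb:
                continue
            ref_ids.append(pid)
            nb_ids.append(nb)
    R_ref = eulers_to_matrices(np.array([euler_by_id[p] for p in ref_ids]))
    R_nb = eulers_to_matrices(np.array([euler_by_id[p] for p in nb_ids]))
    R_rel = np.einsum("nji,njk->nik", R_ref, R_nb)  # R_ref^T @ R_nb
    poles = R_rel[:, :, 2]
    samples = []
    for pid, nb, R, v in zip(ref_ids, nb_ids, R_rel, poles):
        x, y, z = v
        if z > 0:
            pt = HemispherePoint(x / (1 + z), y / (1 + z), "north")
        else:
            pt = HemispherePoint(x / (1 - z), y / (1 - z), "south")
        samples.append(OrientationSample(pid, nb, R, v, pt))
    return samples


@dataclass
class UniformityResult:
    """Rayleigh-type uniformity test of pole directions on the sphere."""

    statistic: float  # resultant length of the mean pole vector, in [0, 1]
    p_value: float  # Monte-Carlo under the uniform null
    n: int
    n_boot: int
    seed: int | None

    @property
    def reject_at_05(self) -> bool:
        return self.p_value <= 0.05


def _resultant(poles: np.ndarray) -> float:
    return float(np.linalg.norm(poles.mean(axis=0)))


def uniformity_test(
    samples, n_boot: int = 1000, seed: int | None = None
) -> UniformityResult:
    """Test pole directions against the uniform-on-the-sphere null.

    The statistic is the length of the mean pole vector (0 for perfectly
    balanced directions, 1 for total concentration); its null distribution
    is simulated with ``n_boot`` Monte-Carlo draws of the same sample size,
    so the test is deterministic given ``seed``. Requires >= 10 samples.
    """
    if len(samples) and isinstance(samples[0], OrientationSample):
        poles = np.asarray([s.pole for s in samples], dtype=float)
    else:
        poles = np.asarray(samples, dtype=float)
    if len(poles) < 10:
        raise InsufficientDataError(f"need >= 10 samples, got {len(poles)}")
    obs = _resultant(poles)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_boot, len(poles), 3))
    null /= np.linalg.norm(null, axis=2, keepdims=True)
    null_stats = np.linalg.norm(null.mean(axis=1), axis=1)
    p = (1 + int(np.sum(null_stats >= obs))) / (n_boot + 1)
    return UniformityResult(obs, p, len(poles), n_boot, seed)


def hemisphere_histogram(samples, n_bins: int = 48) -> pd.DataFrame:
    """Equal-area binning of the disc points, one histogram per hemisphere.

    The unit disc is divided into rings of equal area (radii sqrt(k / K))
    and each ring into equal angular sectors, giving ~n_bins equal-area
    cells per hemisphere; the density column normalises counts per cell so
    a uniform orientation field has flat density.
    """
    n_rings = max(1, int(round(np.sqrt(n_bins / 3))))
    n_sectors = max(1, int(round(n_bins / n_rings)))
    ring_edges = np.sqrt(np.arange(n_rings + 1) / n_rings)
    rows = []
    pts = [(s.point.u, s.point.v, s.point.hemisphere) for s in samples]
    arr = pd.DataFrame(pts, columns=["u", "v", "hemi"])
    arr["r"] = np.hypot(arr["u"], arr["v"]).clip(upper=1.0)
    arr["ang"] = np.mod(np.arctan2(arr["v"], arr["u"]), 2 * np.pi)
    arr["ring"] = np.clip(np.searchsorted(ring_edges, arr["r"], side="right") - 1, 0, n_rings - 1)
    arr["sector"] = np.minimum((arr["ang"] / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    cell_area = np.pi / (n_rings * n_sectors)
    for hemi in ("north", "south"):
        sub = arr[arr["hemi"] == hemi]
        counts = (
            sub.groupby(["ring", "sector"]).size()
            .reindex(pd.MultiIndex.from_product([range(n_rings), range(n_sectors)],
                                                names=["ring", "sector"]), fill_value=0)
        )
        for (ring, sector), cnt in counts.items():
            rows.append((hemi, ring, sector, int(cnt), cnt / cell_area / max(1, len(arr))))
    return pd.DataFrame(rows, columns=["hemisphere", "ring", "sector", "count", "density"])


class OrientationModel:
    """Relative-orientation analysis of cluster members against nearest neighbours."""

    def __init__(self, particles: ParticleSet, clusters, dedup: bool = False):
        self.particles = particles
        self.clusters = clusters
        self.dedup = dedup

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> "OrientationResults":
        samples = neighbor_orientation_map(self.particles, self.clusters, dedup=self.dedup)
        test = uniformity_test(samples, n_boot=n_boot, seed=seed)
        return OrientationResults(self, samples, test)


class OrientationResults:
    def __init__(self, model: OrientationModel, samples, test: UniformityResult):
        self.model = model
        self.samples = samples
        self.test = test

    @property
    def resultant_length(self) -> float:
        return self.test.statistic

    @property
    def p_value(self) -> float:
        return self.test.p_value

    def histogram(self, n_bins: int = 48) -> pd.DataFrame:
        return hemisphere_histogram(self.samples, n_bins=n_bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "particle_id": s.particle_id,
                    "neighbor_id": s.neighbor_id,
                    "pole_x": s.pole[0],
                    "pole_y": s.pole[1],
                    "pole_z": s.pole[2],
                    "u": s.point.u,
                    "v": s.point.v,
                    "hemisphere": s.point.hemisphere,
                }
                for s in self.samples
            ]
        )

    def plot(self, ax_pair=None):
        """Scatter of the hemisphere disc points (north left, south right)."""
        import matplotlib.pyplot as plt

        if ax_pair is None:
            _, ax_pair = plt.subplots(1, 2, figsize=(8, 4), subplot_kw={"aspect": "equal"})
        df = self.to_frame()
        for ax, hemi in zip(ax_pair, ("north", "south")):
            sub = df[df["hemisphere"] == hemi]
            ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="0.4"))
            ax.scatter(sub["u"], sub["v"], s=6, alpha=0.5)
            ax.set_xlim(-1.05, 1.05)
            ax.set_ylim(-1.05, 1.05)
            ax.set_title(f"{hemi} (n={len(sub)})")
        return ax_pair

    def summary(self) -> str:
        return "\n".join(
            [
                "Relative-orientation analysis",
                f"  samples             : {self.test.n}"
                + (" (deduplicated pairs)" if self.model.dedup else ""),
                f"  resultant length    : {self.test.statistic:.4f}",
                f"  Monte-Carlo p-value : {self.test.p_value:.4f} "
                f"({self.test.n_boot} null draws, seed={self.test.seed})",
                "  interpretation      : "
                + (
                    "orientations deviate from uniform"
                    if self.test.reject_at_05
                    else "no evidence against random relative orientation"
                ),
            ]
        )
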