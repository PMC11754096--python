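"""Core particle containers.

A :class:`ParticleSet` is the currency between all analysis stages: one row
per detected macromolecule with a tomogram identifier, a 3D centre position
in nanometres, a ZYZ Euler orientation in degrees, and a categorical state
label (e.g. ``closed``, ``open_noPFD``, ``ribosome``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the underlying DataFrame.
COLUMNS = [
    "particle_id",
    "tomogram_id",
    "x",
    "y",
    "z",
    "phi",
    "theta",
    "psi",
    "state",
]


def wrap_angle(a):
    """Wrap angles (degrees) to the half-open interval [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class ParticleRecord:
    """One detected particle: centre position (nm) and ZYZ Euler orientation (deg)."""

    particle_id: str
    tomogram_id: str
    position: np.ndarray  # shape (3,), nm
    orientation: tuple[float, float, float]  # (phi, theta, psi), degrees
    state: str = "unknown"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        phi, theta, psi = (float(v) for v in self.orientation)
        if not (0.0 <= theta <= 180.0):
            raise ValueError(f"theta must lie in [0, 180] degrees, got {theta}")
        object.__setattr__(
            self, "orientation", (float(wrap_angle(phi)), theta, float(wrap_angle(psi)))
        )


class ParticleSet:
    """Ordered collection of particles backed by a pandas DataFrame (unit: nm).

    Parameters
    ----------
    df : DataFrame with the columns in :data:`COLUMNS`. Extra columns are
        carried along untouched (opaque extras from the source table).
    provenance : free text describing where the table came from and what
        conversions were applied on ingest.
    """

    unit = "nm"

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ParticleSet is missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["particle_id"] = df["particle_id"].astype(str)
        df["tomogram_id"] = df["tomogram_id"].astype(str)
        df["state"] = df["state"].astype(str)
        for c in ("x", "y", "z", "phi", "theta", "psi"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        if df["particle_id"].duplicated().any():
            dup = df.loc[df["particle_id"].duplicated(), "particle_id"].iloc[0]
            raise ValueError(f"duplicate particle_id {dup!r} within a ParticleSet")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in ParticleSet")
        bad = ~df["theta"].between(0.0, 180.0)
        if bad.any():
            raise ValueError(
                f"theta outside [0, 180] at row {int(np.flatnonzero(bad)[0])}"
            )
        df["phi"] = wrap_angle(df["phi"])
        df["psi"] = wrap_angle(df["psi"])
        self.df = df
        self.provenance = provenance

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ParticleRecord], provenance: str = "") -> "ParticleSet":
        rows = [
            {
                "particle_id": r.particle_id,
                "tomogram_id": r.tomogram_id,
                "x": r.position[0],
                "y": r.position[1],
                "z": r.position[2],
                "phi": r.orientation[0],
                "theta": r.orientation[1],
                "psi": r.orientation[2],
                "state": r.state,
            }
            for r in records
        ]
        if not rows:
            raise ValueError("cannot build a ParticleSet from zero records")
        return cls(pd.DataFrame(rows, columns=COLUMNS), provenance)

    # -- access --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[ParticleRecord]:
        for row in self.df.itertuples(index=False):
            yield ParticleRecord(
                particle_id=row.particle_id,
                tomogram_id=row.tomogram_id,
                position=np.array([row.x, row.y, row.z]),
                orientation=(row.phi, row.theta, row.psi),
                state=row.state,
            )

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy()

    @property
    def eulers(self) -> np.ndarray:
        return self.df[["phi", "theta", "psi"]].to_numpy()

    @property
    def states(self) -> pd.Series:
        return self.df["state"]

    @property
    def tomogram_ids(self) -> list[str]:
        return sorted(self.df["tomogram_id"].unique())

    def select_states(self, states: Sequence[str] | str | None) -> "ParticleSet":
        """Subset to the given state labels (None keeps everything)."""
        if states is None:
            return self
        if isinstance(states, str):
            states = [states]
        sub = self.df[self.df["state"].isin(states)]
        if sub.empty:
            raise EmptySelectionError(f"no particles with state in {list(states)}")
        return ParticleSet(sub, self.provenance)

    def by_tomogram(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for tid, grp in self.df.groupby("tomogram_id", sort=True):
            yield tid, grp

    def state_counts(self) -> dict[str, int]:
        return self.df["state"].value_counts().to_dict()


class EmptySelectionError(ValueError):
    """A state/tomogram filter matched no particles."""
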