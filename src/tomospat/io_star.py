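"""Particle table I/O: RELION STAR dialect and plain delimited tables.

The STAR support here is deliberately narrow — a single data block with one
``loop_`` of labelled columns, the shape RELION-3 particle tables take.
Coordinates may arrive in voxels (``rlnCoordinateX/Y/Z``); they are converted
to nanometres exactly once, on ingest, when a pixel size is supplied.
Unrecognised STAR columns are preserved as opaque extras and re-emitted on
write.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import pandas as pd

from .particles import COLUMNS, ParticleSet

# RELION-3 label -> internal column
STAR_COLUMN_MAP = {
    "rlnCoordinateX": "x",
    "rlnCoordinateY": "y",
    "rlnCoordinateZ": "z",
    "rlnAngleRot": "phi",
    "rlnAngleTilt": "theta",
    "rlnAnglePsi": "psi",
    "rlnMicrographName": "tomogram_id",
    "rlnTomoName": "tomogram_id",
    "rlnImageName": "particle_id",
    "rlnParticleName": "particle_id",
    "rlnClassNumber": "state",
    "rlnParticleState": "state",
}
INTERNAL_TO_STAR = {
    "x": "rlnCoordinateX",
    "y": "rlnCoordinateY",
    "z": "rlnCoordinateZ",
    "phi": "rlnAngleRot",
    "theta": "rlnAngleTilt",
    "psi": "rlnAnglePsi",
    "tomogram_id": "rlnMicrographName",
    "particle_id": "rlnParticleName",
    "state": "rlnParticleState",
}

DELIMITED_ALIASES = {
    "x_nm": "x",
    "y_nm": "y",
    "z_nm": "z",
    "tomo": "tomogram_id",
    "tomo_id": "tomogram_id",
    "id": "particle_id",
}


class TableFormatError(ValueError):
    """The file lacks required columns or is not parseable as a particle table."""


def _read_star_loop(path: Path) -> pd.DataFrame:
    """Parse the first ``loop_`` of the first data block into a DataFrame."""
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    in_header = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                if in_loop and rows and not stripped:
                    break  # blank line terminates the loop body
                continue
            if stripped.startswith("data_"):
                if rows:
                    break  # second data block: out of scope
                continue
            if stripped == "loop_":
                in_loop, in_header = True, True
                continue
            if in_header and stripped.startswith("_"):
                labels.append(stripped.split()[0].lstrip("_"))
                continue
            if in_loop:
                in_header = False
                fields = stripped.split()
                if len(fields) != len(labels):
                    raise TableFormatError(
                        f"{path}: row has {len(fields)} fields, expected {len(labels)}"
                    )
                rows.append(fields)
    if not labels:
        raise TableFormatError(f"{path}: no loop_ data block found")
    return pd.DataFrame(rows, columns=labels)


def read_particle_table(
    path: str | os.PathLike,
    dialect: str = "star",
    pixel_size: float | None = None,
) -> ParticleSet:
    """Read a particle table into a :class:`ParticleSet` with positions in nm.

    Parameters
    ----------
    path : STAR file (single data block with a loop) or delimited text table.
    dialect : ``"star"`` or ``"delimited"``.
    pixel_size : nm per voxel. Required if and only if the coordinates are
        stored in voxels; when given, positions are multiplied by it on
        ingest. Leave ``None`` for tables already in nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "star":
        raw = _read_star_loop(path)
        df = raw.rename(columns={k: v for k, v in STAR_COLUMN_MAP.items() if k in raw.columns})
    elif dialect == "delimited":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
        df = df.rename(columns={k: v for k, v in DELIMITED_ALIASES.items() if k in df.columns})
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'star' or 'delimited')")

    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing coordinate column {col!r}")
    for col in ("phi", "theta", "psi"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing angle column {col!r}")

    for col in ("x", "y", "z", "phi", "theta", "psi"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna()][0])
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            ) from exc

    if "tomogram_id" not in df.columns:
        df["tomogram_id"] = "tomo_1"
    if "particle_id" not in df.columns:
        df["particle_id"] = [f"p{i:06d}" for i in range(len(df))]
    if "state" not in df.columns:
        df["state"] = "unknown"

    conversion = "none (assumed nm)"
    if pixel_size is not None:
        df[["x", "y", "z"]] = df[["x", "y", "z"]] * float(pixel_size)
        conversion = f"voxel -> nm at {pixel_size} nm/voxel"
    extras = [c for c in df.columns if c not in COLUMNS]
    return ParticleSet(
        df[COLUMNS + extras],
        provenance=f"read {dialect} table {path.name}; unit conversion: {conversion}",
    )


def write_particle_table(ps: ParticleSet, path: str | os.PathLike, dialect: str = "star") -> None:
    """Write a ParticleSet losslessly (positions nm, angles deg).

    STAR output is a single ``data_particles`` block with one loop; the
    delimited dialect is TSV/CSV chosen by extension.
    """
    if len(ps) == 0:
        raise ValueError("refusing to write an empty ParticleSet")
    path = Path(path)
    df = ps.df
    if dialect == "star":
        star_cols = {c: INTERNAL_TO_STAR.get(c, c) for c in df.columns}
        out = df.rename(columns=star_cols)
        buf = io.StringIO()
        buf.write("data_particles\n\nloop_\n")
        for i, col in enumerate(out.columns, start=1):
            buf.write(f"_{col} #{i}\n")
        out.to_csv(buf, sep="\t", header=False, index=False, float_format="%.10g")
        path.write_text(buf.getvalue())
    elif dialect == "delimited":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
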