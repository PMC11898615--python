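"""Readers and writers for the package's plain-text interchange formats.

Tracks and localizations: CSV (``track_id, frame, x_um, y_um, cell_id,
...``); cell outlines: JSON polygon records; profiles: CSV
(``position_um, phase, membrane, dna``); image stacks: multi-frame TIFF via
tifffile; matrices (heatmaps, demographs): TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .profiling import CellProfile
from .tracking import CellOutline

__all__ = [
    "read_localizations",
    "write_tracks",
    "read_tracks",
    "write_outlines",
    "read_outlines",
    "write_profile",
    "read_profile",
    "read_stack",
    "write_stack",
    "write_matrix",
]


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"localization CSV must contain {sorted(required)}")
    return df


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"track CSV must contain {sorted(required)}")
    return df


def write_outlines(outlines: list[CellOutline], path) -> None:
    records = []
    for o in outlines:
        records.append(
            {
                "cell_id": o.cell_id,
                "vertices_um": np.asarray(o.vertices).tolist(),
                "poles_um": np.asarray(o.poles).tolist(),
                "length_um": o.length,
                "septum": bool(o.septum),
                "septum_x_um": o.septum_x,
                "width_um": o.width,
                "center_um": None if o.center is None else np.asarray(o.center).tolist(),
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def read_outlines(path) -> list[CellOutline]:
    records = json.loads(Path(path).read_text())
    outlines = []
    for r in records:
        outlines.append(
            CellOutline(
                cell_id=r["cell_id"],
                vertices=np.asarray(r["vertices_um"]),
                poles=np.asarray(r["poles_um"]),
                length=r["length_um"],
                septum=r.get("septum", False),
                septum_x=r.get("septum_x_um"),
                width=r.get("width_um"),
                center=None if r.get("center_um") is None else np.asarray(r["center_um"]),
            )
        )
    return outlines


def write_profile(profile: CellProfile, path) -> None:
    pd.DataFrame(
        {
            "position_um": profile.position,
            "phase": profile.phase,
            "membrane": profile.membrane,
            "dna": profile.dna,
        }
    ).to_csv(path, index=False)


def read_profile(path) -> CellProfile:
    df = pd.read_csv(path)
    return CellProfile(
        position=df["position_um"].to_numpy(),
        phase=df["phase"].to_numpy(),
        membrane=df["membrane"].to_numpy(),
        dna=df["dna"].to_numpy(),
    )


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t")
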