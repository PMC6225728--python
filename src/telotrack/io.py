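"""CSV/TIFF readers and writers shared by the CLI stages.

Every CSV written by the pipeline starts with ``#``-prefixed provenance
comment lines (tool version, config hash, seed); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .models import GroundTruth, NucleusFoci, SpotRecord, Trajectory

FLOAT_FORMAT = "%.6f"


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: Optional[int] = None,
                     config: Optional[dict] = None) -> list[str]:
    lines = [f"# telotrack {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    return lines


def write_csv(df: pd.DataFrame, path: Path | str, seed: Optional[int] = None,
              config: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_csv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_movie(movie: np.ndarray, path: Path | str) -> None:
    """Multi-page TIFF, one page per frame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32),
                     photometric="minisblack")


def read_movie(path: Path | str) -> np.ndarray:
    return tifffile.imread(path)


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Ground truth as traj_id / frame / x_nm / y_nm / z_nm rows."""
    n_traj, n_frames, ndim = truth.positions.shape
    rows = {
        "traj_id": np.repeat(np.arange(n_traj), n_frames),
        "frame": np.tile(np.arange(n_frames), n_traj),
        "x_nm": truth.positions[..., 0].ravel(),
        "y_nm": truth.positions[..., 1].ravel(),
        "z_nm": truth.positions[..., 2].ravel() if ndim > 2
                else np.full(n_traj * n_frames, np.nan),
    }
    return pd.DataFrame(rows)


def spots_to_frame(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "nucleus_id": [s.nucleus_id for s in spots],
        "frame": [s.frame for s in spots],
        "z_um": [s.z if s.z is not None else np.nan for s in spots],
        "x_nm": [s.x for s in spots],
        "y_nm": [s.y for s in spots],
        "intensity": [s.intensity for s in spots],
        "sigma_nm": [s.sigma for s in spots],
    })


def frame_to_spots(df: pd.DataFrame) -> list[SpotRecord]:
    out = []
    for row in df.itertuples(index=False):
        z = getattr(row, "z_um", np.nan)
        out.append(SpotRecord(
            frame=int(row.frame), x=float(row.x_nm), y=float(row.y_nm),
            intensity=float(getattr(row, "intensity", 1.0)),
            sigma=float(getattr(row, "sigma_nm", 0.0) or 1.0),
            z=None if (z is None or (isinstance(z, float) and np.isnan(z))) else float(z),
            nucleus_id=int(getattr(row, "nucleus_id", 0)),
        ))
    return out


def trajectories_to_frame(trajectories: Sequence[Trajectory],
                          corrected: bool = False) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for f, (x, y) in zip(t.frames, t.positions):
            rows.append((t.traj_id, t.nucleus_id, int(f), x, y, int(corrected),
                         t.n_total_frames, t.dt))
    return pd.DataFrame(rows, columns=[
        "traj_id", "nucleus_id", "frame", "x_nm", "y_nm", "corrected",
        "n_total_frames", "dt_s",
    ])


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for tid, grp in df.groupby("traj_id"):
        grp = grp.sort_values("frame")
        out.append(Trajectory(
            traj_id=int(tid),
            frames=grp["frame"].to_numpy(dtype=int),
            positions=grp[["x_nm", "y_nm"]].to_numpy(dtype=float),
            n_total_frames=int(grp["n_total_frames"].iloc[0]),
            dt=float(grp["dt_s"].iloc[0]),
            nucleus_id=int(grp["nucleus_id"].iloc[0]),
        ))
    return out


def foci_to_frame(foci_sets: Iterable[NucleusFoci]) -> pd.DataFrame:
    rows = []
    for nf in foci_sets:
        for i, pos in enumerate(nf.positions):
            inten = nf.intensities[i] if nf.intensities is not None else np.nan
            rows.append((nf.nucleus_id, nf.channel, pos[0], pos[1], pos[2], inten))
    return pd.DataFrame(rows, columns=[
        "nucleus_id", "channel", "x_nm", "y_nm", "z_nm", "intensity"])


def frame_to_foci(df: pd.DataFrame) -> list[NucleusFoci]:
    out = []
    if "channel" not in df:
        df = df.assign(channel="A")
    for (nid, ch), grp in df.groupby(["nucleus_id", "channel"]):
        out.append(NucleusFoci(
            int(nid), grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
            grp["intensity"].to_numpy(dtype=float) if "intensity" in grp else None,
            channel=str(ch),
        ))
    return out
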