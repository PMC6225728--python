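"""Nearest-neighbour trajectory linking, trajectory/cell filters and nucleus
drift correction.

Linking rule: per frame, candidate (open trajectory, new spot) pairs within
the allowed radius are accepted greedily in ascending distance order, each
trajectory and each spot used at most once.  A trajectory missing from a
frame stays open for up to ``max_gap_frames`` frames; the allowed radius
grows linearly with the elapsed frames, capped at twice the one-frame radius.
Gap frames are recorded as absent — no interpolation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .models import SpotRecord, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["LinkingParams", "link_spots", "filter_trajectories", "drift_correct"]


@dataclass(frozen=True)
class LinkingParams:
    """Linking and filtering parameters (distances in nm).

    Defaults: link radius 198.9 nm (three 66.3 nm pixels), gaps up to
    5 frames, keep trajectories present in at least half of all frames, keep
    only nuclei retaining at least 5 trajectories.
    """

    max_link_dist: float = 198.9
    max_gap_frames: int = 5
    min_present_fraction: float = 0.5
    min_foci_per_cell: int = 5

    def __post_init__(self) -> None:
        if self.max_link_dist <= 0:
            raise ValueError("max_link_dist must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not (0.0 <= self.min_present_fraction <= 1.0):
            raise ValueError("min_present_fraction must lie in [0, 1]")


class _OpenTrack:
    __slots__ = ("traj_id", "frames", "positions", "last_frame")

    def __init__(self, traj_id: int, frame: int, pos: np.ndarray):
        self.traj_id = traj_id
        self.frames = [frame]
        self.positions = [pos]
        self.last_frame = frame

    def append(self, frame: int, pos: np.ndarray) -> None:
        self.frames.append(frame)
        self.positions.append(pos)
        self.last_frame = frame


def _dedup(spots: Sequence[SpotRecord]) -> list[SpotRecord]:
    seen: set[tuple[int, float, float]] = set()
    out = []
    dropped = 0
    for s in spots:
        key = (s.frame, s.x, s.y)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(s)
    if dropped:
        warnings.warn(f"dropped {dropped} duplicate (frame, position) spots",
                      stacklevel=3)
    return out


def _link_one_nucleus(spots: list[SpotRecord], params: LinkingParams,
                      n_total_frames: int, dt: float, nucleus_id: int,
                      id_start: int, keep_singletons: bool) -> list[Trajectory]:
    by_frame: dict[int, list[SpotRecord]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = id_start
    for frame in range(n_total_frames):
        still_open = []
        for t in open_tracks:
            if frame - t.last_frame - 1 > params.max_gap_frames:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open
        frame_spots = by_frame.get(frame, [])
        if not frame_spots:
            continue
        pos = np.array([[s.x, s.y] for s in frame_spots])
        candidates = []
        for t in open_tracks:
            elapsed = frame - t.last_frame
            allowed = min(elapsed * params.max_link_dist, 2.0 * params.max_link_dist)
            d = np.linalg.norm(pos - t.positions[-1], axis=1)
            for si in np.flatnonzero(d <= allowed):
                candidates.append((d[si], t.traj_id, int(si), t))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        for dist, tid, si, t in candidates:
            if tid in used_tracks or si in used_spots:
                continue
            used_tracks.add(tid)
            used_spots.add(si)
            t.append(frame, pos[si])
        for si in range(len(frame_spots)):
            if si not in used_spots:
                open_tracks.append(_OpenTrack(next_id, frame, pos[si]))
                next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda t: t.traj_id)
    out = []
    for t in closed:
        if not keep_singletons and len(t.frames) < 2:
            continue
        out.append(Trajectory(
            traj_id=t.traj_id,
            frames=np.asarray(t.frames),
            positions=np.asarray(t.positions),
            n_total_frames=n_total_frames,
            dt=dt,
            nucleus_id=nucleus_id,
        ))
    return out


def link_spots(spots: Sequence[SpotRecord], params: LinkingParams | None = None,
               n_total_frames: int | None = None, dt: float = 0.25,
               keep_singletons: bool = False) -> list[Trajectory]:
    """Link per-frame detections into trajectories, per nucleus.

    Every spot ends up in exactly one trajectory; single-spot trajectories
    are discarded unless ``keep_singletons`` is set.  Distance ties are
    broken by lower trajectory id, then lower spot index within the frame,
    making the assignment invariant to spot ordering up to that rule.
    """
    params = params or LinkingParams()
    spots = _dedup(list(spots))
    if not spots:
        return []
    if n_total_frames is None:
        n_total_frames = max(s.frame for s in spots) + 1
    by_nucleus: dict[int, list[SpotRecord]] = {}
    for s in spots:
        by_nucleus.setdefault(s.nucleus_id, []).append(s)
    out: list[Trajectory] = []
    id_start = 0
    for nid in sorted(by_nucleus):
        trajs = _link_one_nucleus(by_nucleus[nid], params, n_total_frames, dt,
                                  nid, id_start, keep_singletons)
        if trajs:
            id_start = max(t.traj_id for t in trajs) + 1
        out.extend(trajs)
    return out


def filter_trajectories(trajectories: Sequence[Trajectory],
                        params: LinkingParams | None = None) -> list[Trajectory]:
    """Apply the presence filter, then the per-nucleus foci-count filter.

    A trajectory is kept iff it is present in at least
    ceil(N * min_present_fraction) frames — i.e. one that lost more than
    (1 - min_present_fraction) of the movie is discarded, and exactly half
    present is kept.  Then every trajectory of a nucleus whose surviving
    count is below ``min_foci_per_cell`` is removed.  Idempotent.
    """
    params = params or LinkingParams()
    kept = [
        t for t in trajectories
        if t.n_present >= math.ceil(t.n_total_frames * params.min_present_fraction)
    ]
    counts: dict[int, int] = {}
    for t in kept:
        counts[t.nucleus_id] = counts.get(t.nucleus_id, 0) + 1
    return [t for t in kept if counts[t.nucleus_id] >= params.min_foci_per_cell]


def _nucleus_center(trajs: list[Trajectory], n_frames: int) -> np.ndarray:
    """Per-frame unweighted centroid of all present spots; empty frames are
    linearly interpolated from neighbouring frames (logged)."""
    sums = np.zeros((n_frames, 2))
    counts = np.zeros(n_frames)
    for t in trajs:
        sums[t.frames] += t.positions
        counts[t.frames] += 1
    have = counts > 0
    if not have.any():
        raise ValueError("nucleus has no spots in any frame")
    center = np.full((n_frames, 2), np.nan)
    center[have] = sums[have] / counts[have, None]
    if not have.all():
        logger.info("interpolating nucleus center over %d empty frames",
                    int((~have).sum()))
        idx = np.arange(n_frames)
        for ax in range(2):
            center[~have, ax] = np.interp(idx[~have], idx[have], center[have, ax])
    return center


def drift_correct(trajectories: Sequence[Trajectory]) -> list[Trajectory]:
    """Subtract the nucleus-centre motion from every trajectory.

    Per nucleus, the cell centre at each frame is the unweighted centroid of
    all spots present in that frame; the corrected position is
    ``raw - (center(frame) - center(f0))`` where ``f0`` is the first frame at
    which the nucleus has at least one spot.  Absent frames stay absent.
    """
    by_nucleus: dict[int, list[Trajectory]] = {}
    for t in trajectories:
        by_nucleus.setdefault(t.nucleus_id, []).append(t)
    out: list[Trajectory] = []
    for nid in sorted(by_nucleus):
        trajs = by_nucleus[nid]
        n_frames = trajs[0].n_total_frames
        center = _nucleus_center(trajs, n_frames)
        first = int(min(t.frames[0] for t in trajs))
        offset = center - center[first]
        for t in trajs:
            out.append(Trajectory(
                traj_id=t.traj_id,
                frames=t.frames.copy(),
                positions=t.positions - offset[t.frames],
                n_total_frames=t.n_total_frames,
                dt=t.dt,
                nucleus_id=t.nucleus_id,
            ))
    out.sort(key=lambda t: t.traj_id)
    return out
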