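"""Link per-frame detections into single-cell trajectories.

Cells are sheath-focused on the channel axis and strictly advected, so
crossings are impossible and a greedy frame-to-frame nearest-neighbor
assignment with a forward-motion constraint suffices.  Trajectories
that first appear past the channel entrance, or that do not cover the
alignment window, are physically impossible or unusable and are
rejected with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelGeometry
from .data import Detection

# tolerated backward motion (µm); detections never truly move upstream
BACKWARD_TOLERANCE = 1.0
# a track is closed after this many consecutive frames without a match
MAX_MISSED_FRAMES = 3


@dataclass
class Trajectory:
    """Ordered detections attributed to one cell."""

    cell_id: int
    detections: list[Detection] = field(default_factory=list)
    phenotype: str | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])

    @property
    def x(self) -> np.ndarray:
        return np.array([d.centroid[0] for d in self.detections])

    @property
    def first_x(self) -> float:
        return self.detections[0].centroid[0]

    @property
    def last_x(self) -> float:
        return self.detections[-1].centroid[0]

    def __len__(self) -> int:
        return len(self.detections)


def link_detections(detections: list[Detection],
                    max_displacement: float = 15.0) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of detections into trajectories.

    Frame by frame, each open track is matched to the nearest unclaimed
    detection satisfying ``Δx >= -BACKWARD_TOLERANCE`` and Euclidean
    displacement ``<= max_displacement``.  Ties are broken by smallest
    Δx, then lowest y.  Unmatched detections open new tracks; tracks
    unmatched for more than MAX_MISSED_FRAMES frames are closed.
    """
    if not detections:
        return []
    frames: dict[int, list[Detection]] = {}
    for det in detections:
        frames.setdefault(det.frame_index, []).append(det)

    next_id = 0
    open_tracks: list[dict] = []   # {traj, last_det, last_frame}
    done: list[Trajectory] = []

    for frame_index in sorted(frames):
        dets = frames[frame_index]
        # close stale tracks
        still_open = []
        for tr in open_tracks:
            if frame_index - tr["last_frame"] > MAX_MISSED_FRAMES:
                done.append(tr["traj"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        # candidate matches: (dx, y, track_idx, det_idx)
        candidates = []
        for ti, tr in enumerate(open_tracks):
            x0, y0 = tr["last_det"].centroid
            for di, det in enumerate(dets):
                x1, y1 = det.centroid
                dx = x1 - x0
                dist = float(np.hypot(dx, y1 - y0))
                if dx >= -BACKWARD_TOLERANCE and dist <= max_displacement:
                    candidates.append((dx, y1, ti, di))
        candidates.sort(key=lambda c: (c[0], c[1]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dx, y, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            tr = open_tracks[ti]
            tr["traj"].detections.append(dets[di])
            tr["last_det"] = dets[di]
            tr["last_frame"] = frame_index

        for di, det in enumerate(dets):
            if di not in used_dets:
                traj = Trajectory(cell_id=next_id, detections=[det])
                next_id += 1
                open_tracks.append({"traj": traj, "last_det": det,
                                    "last_frame": frame_index})

    done.extend(tr["traj"] for tr in open_tracks)
    done.sort(key=lambda t: t.detections[0].frame_index)
    return done


@dataclass(frozen=True)
class ValidationResult:
    keep: bool
    reason: str | None = None


def validate_trajectory(traj: Trajectory, geometry: ChannelGeometry,
                        entry_threshold: float = 0.0) -> ValidationResult:
    """Reject physically impossible or window-incomplete trajectories.

    A trajectory whose first detection lies past ``entry_threshold``
    cannot be a real transit (no event begins in the middle of the
    channel).  A trajectory that does not span the alignment window
    cannot be aligned with the rest of the population.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    lo, hi = geometry.alignment_window
    if traj.first_x > entry_threshold:
        return ValidationResult(False, "impossible start")
    if traj.first_x > lo or traj.last_x < hi:
        return ValidationResult(False, "incomplete span")
    return ValidationResult(True, None)


def track_dataset(detections: list[Detection], geometry: ChannelGeometry,
                  max_displacement: float = 15.0,
                  entry_threshold: float = 0.0,
                  exit_margin: float = 3.0
                  ) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Link and validate in one pass; returns (kept, discarded+reason).

    Detections past the alignment window (plus ``exit_margin``) are
    ignored: cells bunch up and drop out of the camera field near the
    outlet, and linking there could hand a track over to a trailing
    cell.  The margin exceeds the largest per-frame advance, so every
    surviving trajectory still reaches the window end.
    """
    cutoff = geometry.alignment_window[1] + exit_margin
    detections = [d for d in detections if d.centroid[0] <= cutoff]
    trajectories = link_detections(detections, max_displacement)
    kept: list[Trajectory] = []
    discarded: list[tuple[Trajectory, str]] = []
    for traj in trajectories:
        res = validate_trajectory(traj, geometry, entry_threshold)
        if res.keep:
            if traj.detections[0].truth is not None:
                traj.phenotype = traj.detections[0].truth.get("phenotype")
            kept.append(traj)
        else:
            traj.qc_flags.append(res.reason)
            discarded.append((traj, res.reason))
    return kept, discarded
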