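"""Greedy nearest-neighbor frame-to-frame linking with gap closing.

Shared by the actin-foci and vesicle trackers. Assignment is greedy by
ascending distance under a per-frame displacement cap; a track whose
nearest available detection was claimed by another track terminates with a
``merge`` event, and an unassigned detection appearing next to an already
continued track starts a new track with a ``split`` event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LinkedTrack:
    id: int
    points: list[tuple[int, int]] = field(default_factory=list)  # (frame, det idx)
    merges: list[tuple[int, int]] = field(default_factory=list)  # (frame, partner)
    splits: list[tuple[int, int]] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]


def link_positions(
    positions_per_frame: list[np.ndarray],
    max_disp: float,
    gap_frames: int = 1,
) -> list[LinkedTrack]:
    """Link per-frame detection positions into trajectories.

    Parameters
    ----------
    positions_per_frame
        One (N_t, 2) array of (x, y) positions per frame (may be empty).
    max_disp
        Maximum displacement per frame step, in the same units as the
        positions. A link across a gap of g missed frames is allowed up to
        ``max_disp * (g + 1)``.
    gap_frames
        Number of consecutive missed frames a track may survive (default 1).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if gap_frames < 0:
        raise ValueError("gap_frames must be >= 0")

    tracks: list[LinkedTrack] = []
    # active: track index -> (last position, last frame)
    active: dict[int, tuple[np.ndarray, int]] = {}

    for t, pos in enumerate(positions_per_frame):
        pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        n_det = len(pos)
        candidates = {
            k: v for k, v in active.items() if t - v[1] <= gap_frames + 1
        }
        pairs = []
        for k, (p, last_t) in candidates.items():
            if n_det == 0:
                continue
            d = np.hypot(*(pos - p).T)
            limit = max_disp * (t - last_t)
            for j in np.nonzero(d <= limit)[0]:
                pairs.append((float(d[j]), k, int(j)))
        pairs.sort()
        det_owner: dict[int, int] = {}
        track_assigned: set[int] = set()
        lost_to: dict[int, int] = {}  # track -> winning track (merge candidate)
        for dist, k, j in pairs:
            if k in track_assigned:
                continue
            if j in det_owner:
                lost_to.setdefault(k, det_owner[j])
                continue
            det_owner[j] = k
            track_assigned.add(k)
            tracks[k].points.append((t, j))
            active[k] = (pos[j], t)
            lost_to.pop(k, None)
        # tracks that contended for a taken detection and found nothing else
        for k, winner in lost_to.items():
            if k in track_assigned:
                continue
            tracks[k].merges.append((t, winner))
            tracks[winner].merges.append((t, k))
            active.pop(k, None)
        # expire tracks beyond the gap allowance
        for k in list(active):
            if t - active[k][1] > gap_frames:
                active.pop(k)
        # unassigned detections start new tracks (split if born near a track)
        for j in range(n_det):
            if j in det_owner:
                continue
            nid = len(tracks)
            tr = LinkedTrack(id=nid, points=[(t, j)])
            for k in track_assigned:
                if np.hypot(*(active[k][0] - pos[j])) <= max_disp:
                    tr.splits.append((t, k))
                    tracks[k].splits.append((t, nid))
                    break
            tracks.append(tr)
            active[nid] = (pos[j], t)
    return tracks
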