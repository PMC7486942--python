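"""Frame-to-frame nucleus linking by distance-minimizing assignment.

Consecutive frames are linked by solving the optimal bipartite assignment
that minimizes total centroid displacement (Hungarian algorithm), with a
hard gate on the allowed per-frame displacement.  Unmatched labels in the
old frame terminate their tracks; unmatched labels in the new frame start
new tracks.  A greedy nearest-first fallback is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from locreset.segmentation import LabelMap

__all__ = ["CellTrack", "link", "link_centroids", "tracks_to_dataframe"]


@dataclass
class CellTrack:
    """One tracked nucleus: per-frame label references and centroids."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    flagged: bool = False

    def append(self, frame: int, label: int, centroid: np.ndarray) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.labels.append(label)
        self.centroids.append(np.asarray(centroid, dtype=float))

    def __len__(self) -> int:
        return len(self.frames)


def _match(prev: np.ndarray, cur: np.ndarray, gate: float,
           method: str) -> list[tuple[int, int]]:
    """Pairs (i_prev, j_cur) with distance <= gate."""
    if len(prev) == 0 or len(cur) == 0:
        return []
    d = cdist(prev, cur)
    if method == "greedy":
        pairs = []
        used_i: set[int] = set()
        used_j: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > gate:
                break
            if i in used_i or j in used_j:
                continue
            pairs.append((int(i), int(j)))
            used_i.add(int(i))
            used_j.add(int(j))
        return pairs
    big = gate * 1e6 + 1.0
    cost = np.where(d <= gate, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= gate]


def link_centroids(frames: list[np.ndarray], gate: float,
                   labels_per_frame: list[np.ndarray] | None = None,
                   method: str = "optimal") -> list[CellTrack]:
    """Link per-frame centroid arrays ``(n_i, ndim)`` into tracks.

    ``labels_per_frame`` optionally carries the label id of each centroid;
    when omitted, the row index + 1 is used.  Empty frames are allowed.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if labels_per_frame is None:
        labels_per_frame = [np.arange(1, len(f) + 1) for f in frames]
    tracks: list[CellTrack] = []
    next_id = 1
    # active[j] = track currently owning centroid j of the previous frame
    active: dict[int, CellTrack] = {}
    for j, c in enumerate(np.asarray(frames[0], dtype=float)):
        tr = CellTrack(next_id)
        tr.append(0, int(labels_per_frame[0][j]), c)
        tracks.append(tr)
        active[j] = tr
        next_id += 1
    for t in range(1, len(frames)):
        prev = np.atleast_2d(np.asarray(frames[t - 1], dtype=float))
        cur = np.atleast_2d(np.asarray(frames[t], dtype=float))
        if prev.size == 0:
            prev = prev.reshape(0, 2)
        if cur.size == 0:
            cur = cur.reshape(0, 2)
        pairs = _match(prev, cur, gate, method)
        new_active: dict[int, CellTrack] = {}
        matched_j = set()
        for i, j in pairs:
            if i in active:
                tr = active[i]
                tr.append(t, int(labels_per_frame[t][j]), cur[j])
                new_active[j] = tr
                matched_j.add(j)
        for j in range(len(cur)):
            if j not in matched_j:
                tr = CellTrack(next_id)
                tr.append(t, int(labels_per_frame[t][j]), cur[j])
                tracks.append(tr)
                new_active[j] = tr
                next_id += 1
        active = new_active
    return tracks


def link(label_maps: list[LabelMap], gate: float,
         method: str = "optimal") -> list[CellTrack]:
    """Link a sequence of :class:`LabelMap` frames into tracks."""
    frames = [lm.centroids() for lm in label_maps]
    labels = [lm.table["label"].to_numpy(dtype=int) if len(lm.table)
              else np.empty(0, dtype=int) for lm in label_maps]
    return link_centroids(frames, gate, labels_per_frame=labels, method=method)


def tracks_to_dataframe(tracks: list[CellTrack],
                        pixel_size_um: float | None = None) -> pd.DataFrame:
    """Long-format track table (track_id, frame, label, coordinates, flagged)."""
    rows = []
    for tr in tracks:
        for f, lab, c in zip(tr.frames, tr.labels, tr.centroids):
            row = {"track_id": tr.track_id, "frame": f, "label": lab,
                   "flagged": tr.flagged}
            names = ["z", "y", "x"][-len(c):]
            row.update(dict(zip(names, c)))
            if pixel_size_um is not None:
                for n_, v in zip(names, c):
                    if n_ in ("y", "x"):
                        row[f"{n_}_um"] = v * pixel_size_um
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["track_id", "frame"]).reset_index(drop=True)
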