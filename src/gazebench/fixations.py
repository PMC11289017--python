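"""Dispersion-based fixation detection and offset-fixation selection.

A fixation is an interval in which gaze stays within a small spatial
region.  The detector is a single left-to-right pass with no lookahead
(it mirrors what a real-time system can do):

1. *Open* a candidate when ``min_points`` consecutive valid samples have
   dispersion at or below the threshold.
2. *Extend* while adding the next sample keeps the dispersion below the
   threshold and the relative dispersion increase below
   ``max_relative_change``.
3. If only the relative-change test fails, attempt a *slide*: add the new
   sample and evict the oldest window sample, accepted only if that does
   not increase the dispersion.  Evicted samples remain members of the
   fixation being built, so every valid sample belongs to at most one
   fixation.
4. Otherwise *close* the fixation (centroid = mean of members) and resume
   scanning at the first sample after the last member.  An invalid sample
   always terminates an open candidate, so blinks are never bridged.

Dispersion is the maximum pairwise Euclidean distance in degree space —
rotation-invariant, unlike the classic I-DT box measure
(``(max x - min x) + (max y - min y)``) which is available as an
alternative for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import ScreenGeometry, px_to_deg
from .streams import GazeStream

__all__ = [
    "DispersionParams",
    "Fixation",
    "dispersion",
    "detect_fixations",
    "detect_fixations_stream",
    "select_offset_fixations",
]

#: Offset-related fixations require a confirming press shorter than this.
MAX_PRESS_DURATION_MS = 500.0


@dataclass(frozen=True)
class DispersionParams:
    """Tunables of the dispersion detector.

    ``dispersion_threshold_deg`` and ``max_relative_change`` govern the
    open/extend tests; ``min_points`` (at least 3) sets the smallest
    window that can open a fixation; ``min_duration_ms`` optionally
    drops brief fixations after detection; ``slide_enabled`` toggles the
    evict-oldest step; ``metric`` selects the dispersion functional.
    """

    dispersion_threshold_deg: float = 1.0
    min_points: int = 3
    max_relative_change: float = 0.5
    min_duration_ms: float | None = 100.0
    slide_enabled: bool = True
    metric: str = "max_pairwise"  # or "bbox"

    def __post_init__(self) -> None:
        if self.dispersion_threshold_deg <= 0:
            raise ValueError("dispersion_threshold_deg must be > 0")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.metric not in ("max_pairwise", "bbox"):
            raise ValueError(f"unknown dispersion metric {self.metric!r}")


@dataclass(frozen=True)
class Fixation:
    """A detected fixation event."""

    start_ms: float
    end_ms: float
    cx_deg: float
    cy_deg: float
    dispersion_deg: float
    n_samples: int
    trial_id: int | None = None

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def contains(self, t_ms: float) -> bool:
        return self.start_ms <= t_ms <= self.end_ms


def dispersion(points: np.ndarray, metric: str = "max_pairwise") -> float:
    """Spatial spread of a point set in degrees.

    ``max_pairwise``: maximum pairwise Euclidean distance (0 for a single
    point).  ``bbox``: the I-DT box measure, x-range plus y-range.
    """
    p = np.atleast_2d(np.asarray(points, float))
    if p.shape[0] == 0:
        raise ValueError("dispersion of an empty point set")
    if p.shape[0] == 1:
        return 0.0
    if metric == "bbox":
        return float(np.ptp(p[:, 0]) + np.ptp(p[:, 1]))
    return float(pdist(p).max())


class _Window:
    """Active dispersion window with O(n) incremental max-pairwise update."""

    def __init__(self, pts: np.ndarray, metric: str):
        self.metric = metric
        self.pts: list[np.ndarray] = [np.asarray(q, float) for q in pts]
        self.d = dispersion(np.array(self.pts), metric)

    def dispersion_with(self, q: np.ndarray) -> float:
        if self.metric == "bbox":
            return dispersion(np.vstack([self.pts, q]), "bbox")
        arr = np.asarray(self.pts)
        d_new = float(np.sqrt(((arr - q) ** 2).sum(axis=1)).max())
        return max(self.d, d_new)

    def add(self, q: np.ndarray, d_new: float) -> None:
        self.pts.append(np.asarray(q, float))
        self.d = d_new

    def slide(self, q: np.ndarray) -> float:
        """Dispersion after adding q and evicting the oldest point."""
        return dispersion(np.vstack([self.pts[1:], q]), self.metric)

    def apply_slide(self, q: np.ndarray, d_new: float) -> None:
        self.pts = self.pts[1:] + [np.asarray(q, float)]
        self.d = d_new


def detect_fixations(t_ms: np.ndarray, xy_deg: np.ndarray,
                     valid: np.ndarray | None = None,
                     params: DispersionParams = DispersionParams()
                     ) -> list[Fixation]:
    """Run the dispersion detector over a time-sorted gaze signal.

    ``xy_deg`` is ``(n, 2)`` in degrees; samples flagged invalid (or with
    non-finite position) terminate any open candidate and never join a
    fixation.  Returns disjoint, time-ordered fixations.
    """
    t = np.asarray(t_ms, float)
    p = np.asarray(xy_deg, float)
    if valid is None:
        valid = np.ones(len(t), bool)
    valid = np.asarray(valid, bool) & np.isfinite(p).all(axis=1)
    thr = params.dispersion_threshold_deg
    m = params.min_points
    out: list[Fixation] = []

    def close(members: list[int]) -> None:
        pts = p[members]
        out.append(Fixation(
            start_ms=float(t[members[0]]),
            end_ms=float(t[members[-1]]),
            cx_deg=float(pts[:, 0].mean()),
            cy_deg=float(pts[:, 1].mean()),
            dispersion_deg=dispersion(pts, params.metric),
            n_samples=len(members),
        ))

    i = 0
    n = len(t)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # need min_points consecutive valid samples from i
        j = i
        while j < n and valid[j] and j - i < m:
            j += 1
        if j - i < m:
            i = j + 1 if j < n and not valid[j] else j
            continue
        window_idx = list(range(i, j))
        if dispersion(p[window_idx], params.metric) > thr:
            i += 1
            continue
        # candidate opened
        win = _Window(p[window_idx], params.metric)
        members = list(window_idx)
        k = j
        while k < n:
            if not valid[k]:
                break
            q = p[k]
            d_new = win.dispersion_with(q)
            if d_new > thr:
                break
            rel_ok = (win.d == 0.0) or \
                ((d_new - win.d) / win.d <= params.max_relative_change)
            if rel_ok:
                win.add(q, d_new)
                members.append(k)
                k += 1
                continue
            if params.slide_enabled:
                d_slide = win.slide(q)
                if d_slide <= win.d:
                    win.apply_slide(q, d_slide)
                    members.append(k)
                    k += 1
                    continue
            break
        close(members)
        i = members[-1] + 1

    if params.min_duration_ms is not None:
        out = [f for f in out if f.duration_ms >= params.min_duration_ms]
    return out


def detect_fixations_stream(stream: GazeStream, geom: ScreenGeometry,
                            params: DispersionParams = DispersionParams()
                            ) -> list[Fixation]:
    """Convenience wrapper: convert a pixel stream to degrees and detect."""
    deg = px_to_deg(stream.xy_px, geom)
    return detect_fixations(stream.t_ms, deg, stream.valid, params)


def select_offset_fixations(fixations: list[Fixation], trials, presses,
                            max_press_dur_ms: float = MAX_PRESS_DURATION_MS
                            ) -> dict[int, Fixation | None]:
    """Pick the offset-related fixation for each trial, if any.

    A fixation qualifies when the trial's confirmation press falls inside
    the fixation interval and the press lasted less than
    ``max_press_dur_ms`` (default 500 ms); both criteria are evaluated
    per tracker.  Among multiple qualifying fixations the one overlapping
    the trial interval longest wins.  Unmatched trials map to ``None``.
    """
    result: dict[int, Fixation | None] = {}
    for _, tr in trials.iterrows():
        tid = int(tr["trial_id"])
        onset, offset = float(tr["onset_ms"]), float(tr["offset_ms"])
        trial_presses = presses[presses["trial_id"] == tid]
        best: Fixation | None = None
        best_overlap = -np.inf  # overlap ranks candidates, never filters
        for _, pr in trial_presses.iterrows():
            if float(pr["press_dur_ms"]) >= max_press_dur_ms:
                continue
            pt = float(pr["press_t_ms"])
            for fx in fixations:
                if not fx.contains(pt):
                    continue
                overlap = min(fx.end_ms, offset) - max(fx.start_ms, onset)
                if overlap > best_overlap:
                    best_overlap = overlap
                    best = fx
        result[tid] = best
    return result
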