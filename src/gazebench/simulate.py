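"""Synthetic dual-tracker gaze simulator and test-battery stimuli.

Generates (1) stimulus schedules for the five battery tasks — target
grid, smooth pursuit, free viewing, and the two head-movement tasks —
(2) a ground-truth scanpath of a compliant observer performing them, and
(3) noisy observations of that scanpath by parametric tracker models, so
the whole comparison pipeline is testable without any recordings.

The tracker model captures the phenomenology that matters downstream:
sampling rate and timing jitter, processing latency, a constant accuracy
bias, per-sample precision noise (both in degrees), dropouts and blinks,
a constant clock offset between trackers, and whether loss shows up as
confidence-0 rows (webcam style) or absent samples (lab style).

Everything is driven by ``numpy.random.default_rng`` seeds; identical
seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DEFAULT_SCREEN, ScreenGeometry, deg_to_px, px_to_deg
from .streams import GazeStream

__all__ = [
    "StimulusSchedule",
    "TrackerModel",
    "GroundTruthGaze",
    "OculomotorParams",
    "TRACKER_PRESETS",
    "gen_large_grid",
    "gen_pursuit_target",
    "gen_pursuit_schedule",
    "gen_free_view",
    "gen_head_task",
    "gen_ground_truth_gaze",
    "observe_tracker",
    "tracker_from_preset",
]

#: Head-roll line orientations in degrees, presented once each.
ROLL_ANGLES_DEG = (-15, -10, -5, 0, 5, 10, 15)


@dataclass
class StimulusSchedule:
    """Trial table for one battery task.

    ``trials`` columns: ``trial_id, task, onset_ms, offset_ms,
    target_x_px, target_y_px, meta`` plus, for grid tasks, ``grid_row``
    and ``grid_col``.  Trials are non-overlapping and sorted by onset.
    ``target_paths`` maps a trial_id to a moving-target path
    (``t_ms, x_px, y_px``) for pursuit trials.
    """

    task: str
    trials: pd.DataFrame = field(repr=False)
    target_paths: dict[int, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        t = self.trials
        if len(t):
            on = t["onset_ms"].to_numpy(float)
            off = t["offset_ms"].to_numpy(float)
            if np.any(off <= on):
                raise ValueError("trial offset must exceed onset")
            if np.any(on[1:] < off[:-1]):
                raise ValueError("trials overlap in time")

    def end_ms(self) -> float:
        return float(self.trials["offset_ms"].max()) if len(self.trials) else 0.0


@dataclass(frozen=True)
class TrackerModel:
    """Parametric observation model for one eye tracker."""

    name: str
    rate_hz: float
    timing_jitter_sd_ms: float = 0.0
    latency_ms: float = 0.0
    bias_deg: tuple[float, float] = (0.0, 0.0)
    noise_sd_deg: tuple[float, float] = (0.0, 0.0)
    dropout_prob: float = 0.0
    blink_rate_hz: float = 0.0
    blink_dur_range_ms: tuple[float, float] = (100.0, 300.0)
    confidence_mode: str = "confidence_column"  # or "missing_samples"
    clock_offset_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if min(self.noise_sd_deg) < 0 or self.timing_jitter_sd_ms < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.confidence_mode not in ("confidence_column", "missing_samples"):
            raise ValueError(f"unknown confidence_mode {self.confidence_mode!r}")


#: Presets bracketing the magnitudes of a lab-grade 500-Hz tracker and a
#: 30-Hz webcam tracker.  These are working defaults, not measurements:
#: the lab preset has bias norm 0.5 deg / noise 0.3 deg and reports loss by
#: omitting samples; the webcam preset has bias norm 1.0 deg / noise 0.7 deg,
#: reports a confidence column, and runs on an offset clock.
TRACKER_PRESETS: dict[str, TrackerModel] = {
    "lab": TrackerModel(
        name="lab", rate_hz=500.0, timing_jitter_sd_ms=0.05,
        bias_deg=(0.3, 0.4), noise_sd_deg=(0.3, 0.3),
        dropout_prob=0.005, blink_rate_hz=0.0,
        confidence_mode="missing_samples", clock_offset_ms=0.0,
    ),
    "webcam": TrackerModel(
        name="webcam", rate_hz=30.0, timing_jitter_sd_ms=1.0,
        latency_ms=10.0, bias_deg=(0.6, 0.8), noise_sd_deg=(0.7, 0.7),
        dropout_prob=0.01, blink_rate_hz=0.0,
        confidence_mode="confidence_column", clock_offset_ms=230.0,
    ),
}


def tracker_from_preset(preset: str, **overrides) -> TrackerModel:
    """Copy a named preset with field overrides."""
    model = TRACKER_PRESETS[preset]
    if overrides:
        for key in ("bias_deg", "noise_sd_deg", "blink_dur_range_ms"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        model = replace(model, **overrides)
    return model


@dataclass
class GroundTruthGaze:
    """Fine-resolution ground-truth scanpath standing in for a participant.

    ``state`` labels each sample as fixation / saccade / pursuit / blink;
    ``presses`` lists the spacebar confirmations (trial_id, press_t_ms,
    press_dur_ms).
    """

    t_ms: np.ndarray
    gaze_px: np.ndarray
    state: np.ndarray
    presses: pd.DataFrame
    rate_hz: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("ground-truth timestamps must strictly increase")


@dataclass(frozen=True)
class OculomotorParams:
    """Behavioral parameters of the simulated observer.

    Tremor is white positional noise around the fixated point (a coarse
    stand-in for fixational drift/tremor/microsaccades).  Saccades are
    constant-duration linear ramps — the battery never analyses saccade
    dynamics.  Pursuit follows the target scaled by ``pursuit_gain``
    about the screen center and delayed by ``pursuit_lag_ms``.  Press
    durations are lognormal with the stated median; the tail past 500 ms
    exercises the offset-fixation rejection rule.
    """

    fixation_tremor_sd_deg: float = 0.1
    saccade_dur_ms: float = 40.0
    pursuit_gain: float = 0.95
    pursuit_lag_ms: float = 100.0
    blink_rate_hz: float = 0.1
    blink_dur_range_ms: tuple[float, float] = (100.0, 250.0)
    press_reaction_mean_ms: float = 300.0
    press_reaction_sd_ms: float = 60.0
    press_dur_median_ms: float = 250.0
    press_dur_sigma: float = 0.45
    rate_hz: float = 500.0


# ---------------------------------------------------------------------------
# Stimulus schedules
# ---------------------------------------------------------------------------

def _schedule_frame(task: str, onsets, offsets, xs, ys, metas,
                    grid_rows=None, grid_cols=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "trial_id": np.arange(len(onsets), dtype=int),
        "task": task,
        "onset_ms": np.asarray(onsets, float),
        "offset_ms": np.asarray(offsets, float),
        "target_x_px": np.asarray(xs, float),
        "target_y_px": np.asarray(ys, float),
        "meta": list(metas),
    })
    if grid_rows is not None:
        df["grid_row"] = np.asarray(grid_rows, int)
        df["grid_col"] = np.asarray(grid_cols, int)
    return df


def _grid_positions(rows: int, cols: int, margin_px: float,
                    geom: ScreenGeometry) -> tuple[np.ndarray, np.ndarray]:
    if rows < 2 or cols < 2:
        raise ValueError("grid needs rows >= 2 and cols >= 2")
    if 2 * margin_px >= geom.width_px or 2 * margin_px >= geom.height_px:
        raise ValueError("grid margins exceed the screen")
    xs = margin_px + np.arange(cols) * (geom.width_px - 2 * margin_px) / (cols - 1)
    ys = margin_px + np.arange(rows) * (geom.height_px - 2 * margin_px) / (rows - 1)
    return xs, ys


def gen_large_grid(rows: int = 7, cols: int = 8, margin_px: float = 60.0,
                   seed: int = 0, geom: ScreenGeometry = DEFAULT_SCREEN,
                   trial_duration_ms: float = 1500.0,
                   gap_ms: float = 500.0) -> StimulusSchedule:
    """Fixation-target grid task: one target per trial, order randomized.

    The default 7 x 8 grid yields 56 unique equidistant positions.  The
    observer fixates the target until it disappears and confirms with a
    spacebar press (presses are produced by the ground-truth generator).
    """
    xs, ys = _grid_positions(rows, cols, margin_px, geom)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    order = np.random.default_rng(seed).permutation(rows * cols)
    r, c = rr.ravel()[order], cc.ravel()[order]
    n = rows * cols
    onsets = np.arange(n) * (trial_duration_ms + gap_ms)
    return StimulusSchedule("large_grid", _schedule_frame(
        "large_grid", onsets, onsets + trial_duration_ms,
        xs[c], ys[r], [f"r{i}c{j}" for i, j in zip(r, c)],
        grid_rows=r, grid_cols=c,
    ))


def gen_pursuit_target(duration_s: float, dt_s: float, speed_px_s: float,
                       direction_var_deg2_s: float = 887.0,
                       bounds: tuple[float, float, float, float] | None = None,
                       seed: int = 0,
                       start_xy: tuple[float, float] | None = None,
                       start_theta_deg: float | None = None) -> pd.DataFrame:
    """Brownian-direction pursuit target bouncing off the screen edges.

    The direction angle performs a random walk,
    ``theta(t + dt) = theta(t) + eps`` with
    ``eps ~ N(0, direction_var_deg2_s * dt)``, while the target advances
    at constant speed along ``theta`` and reflects specularly at the
    bounds.  The default diffusion of 887 deg^2/s makes the motion hard
    to anticipate while staying smooth at frame rate.

    Returns a DataFrame ``t_ms, x_px, y_px, theta_deg, reflected`` where
    ``reflected`` marks steps whose direction angle was altered by a
    bounce (excluded when estimating the diffusion from increments).
    """
    if dt_s <= 0 or duration_s < dt_s or speed_px_s <= 0:
        raise ValueError("need dt_s > 0, duration_s >= dt_s, speed > 0")
    if bounds is None:
        bounds = (0.0, 0.0, float(DEFAULT_SCREEN.width_px),
                  float(DEFAULT_SCREEN.height_px))
    xmin, ymin, xmax, ymax = bounds
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    if start_xy is None:
        x, y = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    else:
        x, y = float(start_xy[0]), float(start_xy[1])
    theta = (rng.uniform(0.0, 360.0) if start_theta_deg is None
             else float(start_theta_deg))
    eps = rng.normal(0.0, math.sqrt(direction_var_deg2_s * dt_s), size=n)
    step = speed_px_s * dt_s
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    thetas = np.empty(n + 1)
    refl = np.zeros(n + 1, bool)
    xs[0], ys[0], thetas[0] = x, y, theta
    for i in range(n):
        theta += eps[i]
        x += step * math.cos(math.radians(theta))
        y += step * math.sin(math.radians(theta))
        bounced = False
        # specular reflection; loop handles corner double-bounces
        for _ in range(4):
            if x < xmin:
                x = 2 * xmin - x
                theta = 180.0 - theta
                bounced = True
            elif x > xmax:
                x = 2 * xmax - x
                theta = 180.0 - theta
                bounced = True
            elif y < ymin:
                y = 2 * ymin - y
                theta = -theta
                bounced = True
            elif y > ymax:
                y = 2 * ymax - y
                theta = -theta
                bounced = True
            else:
                break
        xs[i + 1], ys[i + 1], thetas[i + 1] = x, y, theta
        refl[i + 1] = bounced
    return pd.DataFrame({
        "t_ms": np.arange(n + 1) * (dt_s * 1000.0),
        "x_px": xs, "y_px": ys,
        "theta_deg": thetas, "reflected": refl,
    })


def gen_pursuit_schedule(n_trials: int = 4, trial_duration_s: float = 20.0,
                         dt_s: float = 1.0 / 60.0,
                         speed_range_px_s: tuple[float, float] = (100.0, 400.0),
                         direction_var_deg2_s: float = 887.0,
                         margin_px: float = 30.0,
                         gap_ms: float = 1000.0, seed: int = 0,
                         geom: ScreenGeometry = DEFAULT_SCREEN
                         ) -> StimulusSchedule:
    """Smooth-pursuit task: per trial one bouncing target path.

    The per-trial speed is drawn uniformly from ``speed_range_px_s``
    (constant within a trial); direction evolves by the Brownian walk of
    :func:`gen_pursuit_target`.
    """
    rng = np.random.default_rng(seed)
    bounds = (margin_px, margin_px, geom.width_px - margin_px,
              geom.height_px - margin_px)
    onsets, offsets, xs, ys, metas = [], [], [], [], []
    paths: dict[int, pd.DataFrame] = {}
    t = 0.0
    for k in range(n_trials):
        speed = rng.uniform(*speed_range_px_s)
        path = gen_pursuit_target(
            trial_duration_s, dt_s, speed, direction_var_deg2_s,
            bounds, seed=int(rng.integers(2 ** 31)),
        )
        path = path.assign(t_ms=path["t_ms"] + t)
        paths[k] = path
        onsets.append(t)
        offsets.append(t + trial_duration_s * 1000.0)
        xs.append(path["x_px"].iloc[0])
        ys.append(path["y_px"].iloc[0])
        metas.append(f"speed={speed:.1f}")
        t = offsets[-1] + gap_ms
    return StimulusSchedule("smooth_pursuit", _schedule_frame(
        "smooth_pursuit", onsets, offsets, xs, ys, metas), target_paths=paths)


def gen_free_view(n_images: int = 18, duration_s: float = 6.0,
                  gap_ms: float = 500.0, seed: int = 0,
                  geom: ScreenGeometry = DEFAULT_SCREEN) -> StimulusSchedule:
    """Free-viewing task: one image per trial, no instructed target.

    The nominal target is the screen center (unused by the analysis —
    free viewing feeds only the correlation and KDE stages)."""
    del seed  # schedule itself is deterministic; exploration is seeded later
    onsets = np.arange(n_images) * (duration_s * 1000.0 + gap_ms)
    cx, cy = geom.center_px
    return StimulusSchedule("free_view", _schedule_frame(
        "free_view", onsets, onsets + duration_s * 1000.0,
        np.full(n_images, cx), np.full(n_images, cy),
        [f"image_{k}" for k in range(n_images)],
    ))


def gen_head_task(kind: str, seed: int = 0,
                  geom: ScreenGeometry = DEFAULT_SCREEN,
                  margin_px: float = 150.0,
                  trial_duration_ms: float = 3000.0,
                  gap_ms: float = 500.0) -> StimulusSchedule:
    """Head-movement tasks probing robustness (data loss) to head pose.

    ``roll``: a central line rotated by -15..15 deg in 5-deg steps, one
    angle per trial, randomized order; the observer rolls the head to
    match while fixating the line.  ``yaw``: 15 targets on a 3 x 5 grid,
    randomized, fixated while the head is rotated toward each.  Each
    trial ends with a confirmation press (from the ground-truth stage).
    """
    rng = np.random.default_rng(seed)
    cx, cy = geom.center_px
    if kind == "roll":
        angles = rng.permutation(np.array(ROLL_ANGLES_DEG, float))
        n = angles.size
        onsets = np.arange(n) * (trial_duration_ms + gap_ms)
        return StimulusSchedule("head_roll", _schedule_frame(
            "head_roll", onsets, onsets + trial_duration_ms,
            np.full(n, cx), np.full(n, cy),
            [f"roll={a:.0f}" for a in angles],
        ))
    if kind == "yaw":
        xs, ys = _grid_positions(3, 5, margin_px, geom)
        rr, cc = np.meshgrid(np.arange(3), np.arange(5), indexing="ij")
        order = rng.permutation(15)
        r, c = rr.ravel()[order], cc.ravel()[order]
        onsets = np.arange(15) * (trial_duration_ms + gap_ms)
        return StimulusSchedule("head_yaw", _schedule_frame(
            "head_yaw", onsets, onsets + trial_duration_ms,
            xs[c], ys[r], [f"r{i}c{j}" for i, j in zip(r, c)],
            grid_rows=r, grid_cols=c,
        ))
    raise ValueError(f"unknown head task kind {kind!r}")


# ---------------------------------------------------------------------------
# Ground-truth scanpath
# ---------------------------------------------------------------------------

def _free_view_path(onset: float, offset: float, rng: np.random.Generator,
                    geom: ScreenGeometry) -> tuple[np.ndarray, np.ndarray]:
    """A few fixation clusters per image (saliency-free exploration)."""
    n_fix = int(rng.integers(4, 9))
    dwell = rng.dirichlet(np.ones(n_fix)) * (offset - onset)
    times = onset + np.concatenate([[0.0], np.cumsum(dwell)])[:-1]
    pts = np.column_stack([
        rng.uniform(0.15 * geom.width_px, 0.85 * geom.width_px, n_fix),
        rng.uniform(0.15 * geom.height_px, 0.85 * geom.height_px, n_fix),
    ])
    return times, pts


def gen_ground_truth_gaze(schedule: StimulusSchedule,
                          ocm: OculomotorParams = OculomotorParams(),
                          seed: int = 0,
                          geom: ScreenGeometry = DEFAULT_SCREEN
                          ) -> GroundTruthGaze:
    """Simulate a compliant observer performing one task schedule.

    During fixation trials gaze sits on the target plus tremor; target
    changes trigger saccade-labelled linear ramps of fixed duration;
    pursuit trials follow the target path scaled by the pursuit gain and
    delayed by the pursuit lag; blinks are inserted as a Poisson process;
    grid and head trials end with a spacebar press shortly after target
    offset.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / ocm.rate_hz
    end = schedule.end_ms() + 500.0
    t = np.arange(0.0, end, dt)
    n = t.size
    cx, cy = geom.center_px

    # piecewise target signal + per-sample state
    fix_t: list[float] = [0.0]
    fix_p: list[tuple[float, float]] = []
    state = np.full(n, "fixation", dtype="<U8")
    trials = schedule.trials
    first = (float(trials["target_x_px"].iloc[0]),
             float(trials["target_y_px"].iloc[0])) if len(trials) else (cx, cy)
    fix_p.append(first)
    pursuit_ranges: list[tuple[float, float, pd.DataFrame]] = []
    for _, tr in trials.iterrows():
        onset, offset = float(tr["onset_ms"]), float(tr["offset_ms"])
        if schedule.target_paths and int(tr["trial_id"]) in schedule.target_paths:
            pursuit_ranges.append(
                (onset, offset, schedule.target_paths[int(tr["trial_id"])]))
            continue
        if schedule.task == "free_view":
            times, pts = _free_view_path(onset, offset, rng, geom)
            for tt, pp in zip(times, pts):
                fix_t.append(float(tt))
                fix_p.append((float(pp[0]), float(pp[1])))
            continue
        fix_t.append(onset)
        fix_p.append((float(tr["target_x_px"]), float(tr["target_y_px"])))

    gaze = np.empty((n, 2))
    fix_t_arr = np.asarray(fix_t)
    fix_p_arr = np.asarray(fix_p)
    seg = np.clip(np.searchsorted(fix_t_arr, t, side="right") - 1, 0, None)
    gaze[:, 0] = fix_p_arr[seg, 0]
    gaze[:, 1] = fix_p_arr[seg, 1]

    # saccade ramps at every target change
    for k in range(1, fix_t_arr.size):
        t0 = fix_t_arr[k]
        i0 = int(np.searchsorted(t, t0))
        i1 = min(int(np.searchsorted(t, t0 + ocm.saccade_dur_ms)), n)
        if i0 >= n or i1 <= i0:
            continue
        frac = (t[i0:i1] - t0) / ocm.saccade_dur_ms
        prev = fix_p_arr[k - 1]
        new = fix_p_arr[k]
        gaze[i0:i1] = prev + frac[:, None] * (new - prev)
        state[i0:i1] = "saccade"

    # pursuit segments follow the path (gain about center, delayed);
    # after the trial the gaze holds the final path position until the
    # next scheduled fixation instead of snapping back
    for onset, offset, path in pursuit_ranges:
        i0, i1 = np.searchsorted(t, [onset, offset])
        tt = t[i0:i1] - ocm.pursuit_lag_ms
        px = np.interp(tt, path["t_ms"], path["x_px"])
        py = np.interp(tt, path["t_ms"], path["y_px"])
        gaze[i0:i1, 0] = cx + ocm.pursuit_gain * (px - cx)
        gaze[i0:i1, 1] = cy + ocm.pursuit_gain * (py - cy)
        state[i0:i1] = "pursuit"
        if i1 > i0:
            later = fix_t_arr[fix_t_arr > offset]
            i2 = int(np.searchsorted(t, later.min())) if later.size else n
            gaze[i1:i2] = gaze[i1 - 1]

    # fixational tremor (degree space), only while fixating
    if ocm.fixation_tremor_sd_deg > 0:
        fixing = state == "fixation"
        gdeg = px_to_deg(gaze[fixing], geom)
        gdeg += rng.normal(0.0, ocm.fixation_tremor_sd_deg,
                           size=gdeg.shape)
        gaze[fixing] = deg_to_px(gdeg, geom)

    # blinks: Poisson starts, uniform durations; gaze held, state=blink
    if ocm.blink_rate_hz > 0:
        n_blinks = rng.poisson(ocm.blink_rate_hz * end / 1000.0)
        starts = np.sort(rng.uniform(0.0, end, n_blinks))
        durs = rng.uniform(*ocm.blink_dur_range_ms, n_blinks)
        for b0, d in zip(starts, durs):
            i0, i1 = np.searchsorted(t, [b0, b0 + d])
            state[i0:i1] = "blink"

    # spacebar confirmations after target offset (grid and head tasks)
    press_rows = []
    if schedule.task in ("large_grid", "head_roll", "head_yaw"):
        for _, tr in trials.iterrows():
            rt = max(50.0, rng.normal(ocm.press_reaction_mean_ms,
                                      ocm.press_reaction_sd_ms))
            dur = float(rng.lognormal(math.log(ocm.press_dur_median_ms),
                                      ocm.press_dur_sigma))
            press_rows.append((int(tr["trial_id"]),
                               float(tr["offset_ms"]) + rt, dur))
    presses = pd.DataFrame(press_rows,
                           columns=["trial_id", "press_t_ms", "press_dur_ms"])
    return GroundTruthGaze(t_ms=t, gaze_px=gaze, state=state,
                           presses=presses, rate_hz=ocm.rate_hz)


# ---------------------------------------------------------------------------
# Tracker observation
# ---------------------------------------------------------------------------

def observe_tracker(truth: GroundTruthGaze, model: TrackerModel,
                    geom: ScreenGeometry = DEFAULT_SCREEN,
                    seed: int | None = None) -> GazeStream:
    """Observe a ground-truth scanpath through a tracker model.

    Sampling happens at ``model.rate_hz`` with Gaussian timestamp jitter
    (clipped to keep timestamps monotone); each sample reads the truth at
    ``t - latency_ms`` by linear interpolation, then bias and per-sample
    Gaussian noise are applied in degree space and mapped back to pixels.
    Truth blinks, Bernoulli dropouts, and tracker-model blink episodes
    all produce loss; ``confidence_column`` mode keeps lost rows with
    confidence 0 and missing position, ``missing_samples`` mode drops
    them.  Output timestamps carry the model's clock offset.
    """
    if model.rate_hz > truth.rate_hz + 1e-9:
        raise ValueError(
            f"tracker rate {model.rate_hz} Hz exceeds ground-truth "
            f"resolution {truth.rate_hz} Hz"
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    period = 1000.0 / model.rate_hz
    t0, t1 = float(truth.t_ms[0]), float(truth.t_ms[-1])
    n = int((t1 - t0) / period) + 1
    t_nom = t0 + period * np.arange(n)
    if model.timing_jitter_sd_ms > 0:
        jitter = rng.normal(0.0, model.timing_jitter_sd_ms, n)
        np.clip(jitter, -0.45 * period, 0.45 * period, out=jitter)
        t_s = t_nom + jitter
    else:
        t_s = t_nom

    t_read = np.clip(t_s - model.latency_ms, t0, t1)
    xy = np.column_stack([
        np.interp(t_read, truth.t_ms, truth.gaze_px[:, 0]),
        np.interp(t_read, truth.t_ms, truth.gaze_px[:, 1]),
    ])
    deg = px_to_deg(xy, geom)
    deg[:, 0] += model.bias_deg[0]
    deg[:, 1] += model.bias_deg[1]
    if max(model.noise_sd_deg) > 0:
        deg += rng.normal(0.0, model.noise_sd_deg, size=deg.shape)
    xy = deg_to_px(deg, geom)

    # loss: eye closed (truth blink), tracker blink episodes, dropouts
    idx = np.clip(np.searchsorted(truth.t_ms, t_read), 0, truth.t_ms.size - 1)
    lost = truth.state[idx] == "blink"
    if model.blink_rate_hz > 0:
        n_blinks = rng.poisson(model.blink_rate_hz * (t1 - t0) / 1000.0)
        starts = rng.uniform(t0, t1, n_blinks)
        durs = rng.uniform(*model.blink_dur_range_ms, n_blinks)
        for b0, d in zip(starts, durs):
            lost |= (t_s >= b0) & (t_s < b0 + d)
    if model.dropout_prob > 0:
        lost |= rng.random(n) < model.dropout_prob

    t_out = t_s + model.clock_offset_ms
    if model.confidence_mode == "confidence_column":
        df = pd.DataFrame({
            "t_ms": t_out,
            "x_px": np.where(lost, np.nan, xy[:, 0]),
            "y_px": np.where(lost, np.nan, xy[:, 1]),
            "confidence": np.where(lost, 0.0, 1.0),
            "validity": ~lost,
        })
    else:
        keep = ~lost
        df = pd.DataFrame({
            "t_ms": t_out[keep],
            "x_px": xy[keep, 0],
            "y_px": xy[keep, 1],
            "confidence": np.nan,
            "validity": True,
        })
    return GazeStream(source=model.name, nominal_rate_hz=model.rate_hz,
                      data=df.reset_index(drop=True))
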