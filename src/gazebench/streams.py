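"""Gaze-stream containers, CSV dialects, and two-stream synchronization.

Two trackers watching the same eyes produce streams on different clocks
and at different rates (nominally 500 Hz lab vs 30 Hz webcam here).
Comparing them requires (1) estimating and removing the constant
inter-stream clock lag by time-lag cross-correlation and (2) resampling
the high-rate stream onto the low-rate stream's timestamps.  Clock *rate*
mismatch (linear drift) is deliberately not modelled: the lag is treated
as a single constant per recording.

Timestamps are epoch-style milliseconds; all durations are in ms.

CSV dialects
------------
* Gaze stream: header ``t_ms,x_px,y_px,confidence,validity``; UTF-8;
  missing position = empty fields; validity written as 0/1.
* Schedule:    ``trial_id,task,onset_ms,offset_ms,target_x_px,target_y_px,meta``
* Presses:     ``trial_id,press_t_ms,press_dur_ms``
* Merged series: ``t_ms`` plus per-tracker prefixed degree columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .geometry import ScreenGeometry, px_to_deg

__all__ = [
    "GazeStream",
    "MergedSeries",
    "StreamFormatError",
    "InsufficientOverlapError",
    "read_stream",
    "write_stream",
    "read_schedule",
    "write_schedule",
    "read_presses",
    "write_presses",
    "estimate_lag",
    "align_and_resample",
    "merge_streams",
    "write_merged",
]

STREAM_COLUMNS = ["t_ms", "x_px", "y_px", "confidence", "validity"]
SCHEDULE_COLUMNS = ["trial_id", "task", "onset_ms", "offset_ms",
                    "target_x_px", "target_y_px", "meta"]
PRESS_COLUMNS = ["trial_id", "press_t_ms", "press_dur_ms"]


class StreamFormatError(ValueError):
    """A gaze-stream file violates the dialect (bad column, row, or value)."""


class InsufficientOverlapError(ValueError):
    """Too few jointly valid samples to estimate the inter-stream lag."""


@dataclass
class GazeStream:
    """Time-sorted gaze samples from one tracker.

    ``data`` holds columns ``t_ms, x_px, y_px, confidence, validity``.
    Confidence is NaN where the tracker reports none.  A missing position
    implies ``validity == False``; both are enforced at construction.
    """

    source: str
    nominal_rate_hz: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in STREAM_COLUMNS if c not in df.columns]
        if missing:
            raise StreamFormatError(f"stream missing columns {missing}")
        t = df["t_ms"].to_numpy(float)
        if len(t) > 1:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                k = int(bad[0]) + 1
                raise StreamFormatError(
                    f"non-monotone timestamp at row {k}: "
                    f"t_ms={t[k]} after {t[k - 1]}"
                )
        conf = df["confidence"].to_numpy(float)
        out_of_range = np.nonzero((conf < 0) | (conf > 1))[0]
        if out_of_range.size:
            k = int(out_of_range[0])
            raise StreamFormatError(
                f"confidence out of [0, 1] at row {k}: {conf[k]}"
            )
        pos_missing = df["x_px"].isna() | df["y_px"].isna()
        if bool((pos_missing & df["validity"].astype(bool)).any()):
            k = int(np.nonzero((pos_missing & df["validity"].astype(bool))
                               .to_numpy())[0][0])
            raise StreamFormatError(
                f"row {k} has missing position but validity=1"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t_ms(self) -> np.ndarray:
        return self.data["t_ms"].to_numpy(float)

    @property
    def xy_px(self) -> np.ndarray:
        return self.data[["x_px", "y_px"]].to_numpy(float)

    @property
    def valid(self) -> np.ndarray:
        return self.data["validity"].to_numpy(bool)

    def span_ms(self) -> tuple[float, float]:
        t = self.t_ms
        return float(t[0]), float(t[-1])


@dataclass
class MergedSeries:
    """Two streams on one common timebase (the low-rate stream's clock).

    ``data`` columns: ``t_ms``, ``a_x_deg, a_y_deg, a_valid`` for the
    low-rate (timebase-owning) tracker, ``b_x_deg, b_y_deg, b_valid`` for
    the resampled high-rate tracker, and ``valid`` = both.
    """

    data: pd.DataFrame = field(repr=False)
    estimated_lag_ms: float = 0.0
    a_source: str = "a"
    b_source: str = "b"

    def __len__(self) -> int:
        return len(self.data)

    def joint_valid(self) -> np.ndarray:
        return self.data["valid"].to_numpy(bool)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_stream(path, source: str | None = None,
                nominal_rate_hz: float | None = None) -> GazeStream:
    """Read a gaze-stream CSV; raises :class:`StreamFormatError` on a
    missing column, non-monotone time, duplicate timestamp, or a
    confidence outside [0, 1], naming the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing required columns {missing}")
    df = df[STREAM_COLUMNS].copy()
    df["t_ms"] = pd.to_numeric(df["t_ms"], errors="raise")
    for c in ("x_px", "y_px", "confidence"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["validity"] = df["validity"].astype(float).astype(bool)
    if nominal_rate_hz is None:
        t = df["t_ms"].to_numpy(float)
        if len(t) > 1 and t[-1] > t[0]:
            nominal_rate_hz = 1000.0 * (len(t) - 1) / (t[-1] - t[0])
        else:
            nominal_rate_hz = 0.0
    try:
        return GazeStream(source=source or str(path),
                          nominal_rate_hz=float(nominal_rate_hz), data=df)
    except StreamFormatError as e:
        raise StreamFormatError(f"{path}: {e}") from None


def write_stream(stream: GazeStream, path) -> None:
    df = stream.data.copy()
    df["validity"] = df["validity"].astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing schedule columns {missing}")
    return df


def write_schedule(trials: pd.DataFrame, path) -> None:
    trials.reindex(columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def read_presses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PRESS_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing press columns {missing}")
    return df


def write_presses(presses: pd.DataFrame, path) -> None:
    presses.reindex(columns=PRESS_COLUMNS).to_csv(path, index=False)


def write_merged(merged: MergedSeries, path) -> None:
    df = merged.data.copy()
    for c in ("a_valid", "b_valid", "valid"):
        df[c] = df[c].astype(int)
    df = df.rename(columns={
        f"a_{s}": f"{merged.a_source}_{s}" for s in ("x_deg", "y_deg", "valid")
    } | {
        f"b_{s}": f"{merged.b_source}_{s}" for s in ("x_deg", "y_deg", "valid")
    })
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def align_and_resample(target_times: np.ndarray, stream: GazeStream,
                       max_gap_ms: float = 100.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate the stream at ``target_times``.

    Interpolation uses only valid samples.  An output is flagged invalid
    when the query time falls outside the stream, or when the two valid
    samples bracketing it are more than ``max_gap_ms`` apart (so blinks
    and dropouts are never bridged; the default 100 ms is shorter than a
    typical blink).

    Returns ``(xy, valid)`` with ``xy`` of shape ``(n, 2)``.
    """
    tq = np.asarray(target_times, float)
    if tq.size > 1 and np.any(np.diff(tq) <= 0):
        raise ValueError("target_times must be strictly increasing")
    m = stream.valid
    tv = stream.t_ms[m]
    xy = np.full((tq.size, 2), np.nan)
    ok = np.zeros(tq.size, bool)
    if tv.size < 2:
        if tv.size == 1:
            hit = tq == tv[0]
            xy[hit] = stream.xy_px[m][0]
            ok |= hit
        return xy, ok
    pv = stream.xy_px[m]
    right = np.searchsorted(tv, tq, side="left")
    inside = (right > 0) & (right < tv.size)
    exact = (right < tv.size) & (np.take(tv, right, mode="clip") == tq)
    left = np.clip(right - 1, 0, tv.size - 1)
    span = np.take(tv, np.clip(right, 0, tv.size - 1)) - np.take(tv, left)
    ok = exact | (inside & (span <= max_gap_ms))
    xy[:, 0] = np.interp(tq, tv, pv[:, 0])
    xy[:, 1] = np.interp(tq, tv, pv[:, 1])
    xy[~ok] = np.nan
    return xy, ok


# ---------------------------------------------------------------------------
# Lag estimation
# ---------------------------------------------------------------------------

def _lagged_sums(u: np.ndarray, v: np.ndarray, kmax: int) -> np.ndarray:
    """s[k] = sum_i u[i] * v[i + k] for k in [-kmax, kmax], via FFT."""
    c = correlate(v, u, mode="full", method="fft")
    mid = u.size - 1
    return c[mid - kmax: mid + kmax + 1]


def estimate_lag(ref: GazeStream, other: GazeStream,
                 max_lag_ms: float = 2000.0,
                 grid_rate_hz: float | None = None,
                 max_gap_ms: float = 100.0,
                 min_overlap: int = 100,
                 whiten: bool = False) -> float:
    """Estimate the clock lag of ``other`` relative to ``ref``.

    Both streams are resampled onto a uniform auxiliary grid at the
    higher of the two nominal rates; the returned lag is the integer
    grid shift maximizing the mean of the x- and y-axis Pearson
    correlations over jointly valid grid points, converted to ms.  A
    positive lag means ``other``'s clock runs ahead: subtracting the lag
    from its timestamps aligns the streams.  Ties break toward smaller
    absolute lag.

    ``whiten=True`` computes the correlation on first differences of
    the resampled signals instead.  That sharpens the objective for
    streams with fast structure (e.g. two high-rate streams with
    saccade landmarks) but discards information when one stream is a
    low-rate interpolation, whose differences degenerate into a
    staircase; it is therefore off by default.

    Raises
    ------
    InsufficientOverlapError
        If no candidate shift has at least ``min_overlap`` jointly valid
        grid samples.
    """
    if max_lag_ms <= 0:
        raise ValueError("max_lag_ms must be > 0")
    rate = grid_rate_hz or max(ref.nominal_rate_hz, other.nominal_rate_hz)
    if rate <= 0:
        raise ValueError("cannot infer a grid rate from the streams")
    step = 1000.0 / rate
    kmax = max(1, int(round(max_lag_ms / step)))
    t0 = min(ref.t_ms[0], other.t_ms[0])
    t1 = max(ref.t_ms[-1], other.t_ms[-1])
    grid = t0 + step * np.arange(int((t1 - t0) / step) + 1)
    a_xy, a_ok = align_and_resample(grid, ref, max_gap_ms)
    b_xy, b_ok = align_and_resample(grid, other, max_gap_ms)
    if whiten:
        a_xy = np.diff(a_xy, axis=0)
        b_xy = np.diff(b_xy, axis=0)
        a_ok = a_ok[1:] & a_ok[:-1]
        b_ok = b_ok[1:] & b_ok[:-1]
        a_xy[~a_ok] = 0.0
        b_xy[~b_ok] = 0.0

    ma = a_ok.astype(float)
    mb = b_ok.astype(float)
    n_k = _lagged_sums(ma, mb, kmax)
    score = np.zeros(2 * kmax + 1)
    n_axes = np.zeros(2 * kmax + 1)
    for axis in (0, 1):
        a = np.where(a_ok, a_xy[:, axis], 0.0)
        b = np.where(b_ok, b_xy[:, axis], 0.0)
        s_a = _lagged_sums(a, mb, kmax)
        s_b = _lagged_sums(ma, b, kmax)
        s_ab = _lagged_sums(a, b, kmax)
        s_aa = _lagged_sums(a * a, mb, kmax)
        s_bb = _lagged_sums(ma, b * b, kmax)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = s_ab - s_a * s_b / n_k
            var_a = s_aa - s_a ** 2 / n_k
            var_b = s_bb - s_b ** 2 / n_k
            r = cov / np.sqrt(var_a * var_b)
        good = (n_k >= min_overlap) & np.isfinite(r)
        score += np.where(good, r, 0.0)
        n_axes += good
    usable = n_axes > 0
    if not usable.any():
        raise InsufficientOverlapError(
            f"fewer than {min_overlap} jointly valid samples at every "
            f"candidate lag within +/-{max_lag_ms} ms"
        )
    score = np.where(usable, score / np.maximum(n_axes, 1), -np.inf)
    ks = np.arange(-kmax, kmax + 1)
    order = np.argsort(np.abs(ks), kind="stable")  # ties -> smaller |lag|
    best = order[int(np.argmax(score[order]))]
    return float(ks[best] * step)


def merge_streams(low_rate: GazeStream, high_rate: GazeStream,
                  geom: ScreenGeometry,
                  max_lag_ms: float = 2000.0,
                  max_gap_ms: float = 100.0,
                  known_lag_ms: float | None = None) -> MergedSeries:
    """Synchronize two streams and put them on the low-rate timebase.

    The lag of ``high_rate`` relative to ``low_rate`` is estimated (or
    supplied via ``known_lag_ms``) and removed, the high-rate stream is
    linearly resampled at the low-rate timestamps, and both are converted
    to degrees.  A merged row is valid only where both sources are.
    """
    if len(low_rate) == 0 or len(high_rate) == 0:
        raise ValueError("cannot merge an empty stream")
    if known_lag_ms is None:
        lag = estimate_lag(low_rate, high_rate, max_lag_ms=max_lag_ms,
                           max_gap_ms=max_gap_ms)
    else:
        lag = float(known_lag_ms)
    shifted = GazeStream(
        source=high_rate.source,
        nominal_rate_hz=high_rate.nominal_rate_hz,
        data=high_rate.data.assign(t_ms=high_rate.data["t_ms"] - lag),
    )
    tq = low_rate.t_ms
    b_xy, b_ok = align_and_resample(tq, shifted, max_gap_ms)
    a_deg = px_to_deg(low_rate.xy_px, geom)
    b_deg = px_to_deg(b_xy, geom)
    a_ok = low_rate.valid
    df = pd.DataFrame({
        "t_ms": tq,
        "a_x_deg": a_deg[:, 0], "a_y_deg": a_deg[:, 1], "a_valid": a_ok,
        "b_x_deg": b_deg[:, 0], "b_y_deg": b_deg[:, 1], "b_valid": b_ok,
        "valid": a_ok & b_ok,
    })
    return MergedSeries(data=df, estimated_lag_ms=lag,
                        a_source=low_rate.source, b_source=high_rate.source)
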