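"""Data-quality metrics: accuracy, precision, RMS-S2S, loss, correlations,
and drift correction.

Definitions (all angles in degrees of visual angle):

* **Accuracy** — Euclidean distance between a selected fixation centroid
  and its instructed target.
* **Precision (across subjects)** — per-axis SD of fixation centroids
  pooled over subjects at the same grid location (the grid shows each
  location once per subject, so within-subject repetition is
  unavailable), summarized as the grand mean/SD across locations.
* **RMS-S2S** — root mean square of successive sample-to-sample
  displacements per axis; for i.i.d. noise of SD sigma it converges to
  sigma * sqrt(2).
* **Data loss** — percentage of expected samples that are missing
  (sample-omitting trackers) or flagged confidence 0 (confidence-column
  trackers).
* **Axis correlations** — per-subject Pearson r of the two trackers' x
  (and y) signals over jointly valid rows of a merged series; the cohort
  value is the plain mean of per-subject r (Fisher-z averaging
  available).
* **Drift correction** — leave-one-out cross-validated constant offset
  estimated from a 7-point recalibration grid and subtracted from
  subsequent samples; the held-out residual is a running reliability
  measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixations import Fixation
from .geometry import ScreenGeometry, px_to_deg
from .streams import GazeStream, MergedSeries

__all__ = [
    "fixation_accuracy",
    "classify_eccentricity",
    "large_grid_accuracy_records",
    "precision_across_subjects",
    "rms_s2s",
    "data_loss_fraction",
    "axis_correlations",
    "cohort_correlations",
    "drift_correct",
    "AxisCorrelation",
]


def fixation_accuracy(centroid_deg, target_deg) -> float:
    """Angular error: Euclidean norm of centroid minus target, degrees."""
    c = np.asarray(centroid_deg, float)
    g = np.asarray(target_deg, float)
    if not (np.isfinite(c).all() and np.isfinite(g).all()):
        raise ValueError("centroid and target must be finite")
    return float(np.linalg.norm(c - g, axis=-1))


def classify_eccentricity(row_index: int, col_index: int,
                          rows: int, cols: int) -> str:
    """``outer`` iff the target sits on the boundary ring of the grid."""
    if not (0 <= row_index < rows and 0 <= col_index < cols):
        raise ValueError("grid index out of range")
    on_ring = (row_index in (0, rows - 1)) or (col_index in (0, cols - 1))
    return "outer" if on_ring else "inner"


def large_grid_accuracy_records(selected: dict[int, Fixation | None],
                                trials: pd.DataFrame, geom: ScreenGeometry,
                                rows: int, cols: int,
                                subject: str, tracker: str) -> pd.DataFrame:
    """Per-trial accuracy rows for the factorial analysis.

    ``selected`` maps trial_id to the chosen offset fixation (or None).
    Trials are split into first/second half by presentation order; each
    row carries the angular error, eccentricity class, and half.
    """
    recs = []
    n_trials = len(trials)
    for order, (_, tr) in enumerate(trials.iterrows()):
        fx = selected.get(int(tr["trial_id"]))
        if fx is None:
            continue
        tgt = px_to_deg(
            np.array([tr["target_x_px"], tr["target_y_px"]], float), geom)
        err = fixation_accuracy((fx.cx_deg, fx.cy_deg), tgt)
        recs.append({
            "subject": subject,
            "tracker": tracker,
            "trial_id": int(tr["trial_id"]),
            "location": str(tr["meta"]),
            "target_x_deg": float(tgt[0]),
            "target_y_deg": float(tgt[1]),
            "cx_deg": fx.cx_deg,
            "cy_deg": fx.cy_deg,
            "error_deg": err,
            "eccentricity": classify_eccentricity(
                int(tr["grid_row"]), int(tr["grid_col"]), rows, cols),
            "half": "first" if order < n_trials / 2 else "second",
        })
    return pd.DataFrame(recs)


def precision_across_subjects(centroids: pd.DataFrame
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-subject precision at shared grid locations.

    ``centroids`` needs columns ``subject, tracker, location, cx_deg,
    cy_deg`` and optionally ``eccentricity``.  Returns
    ``(per_location, summary)``: per-location n-1 SDs per axis (locations
    with a single contributing subject are excluded and reported with
    ``included=False``), and per-tracker grand mean/SD across included
    locations.
    """
    rows = []
    group_cols = ["tracker", "location"]
    for (tracker, loc), g in centroids.groupby(group_cols, sort=True):
        n = g["subject"].nunique()
        row = {"tracker": tracker, "location": loc, "n_subjects": n,
               "included": n >= 2}
        if "eccentricity" in g.columns:
            row["eccentricity"] = g["eccentricity"].iloc[0]
        if n >= 2:
            row["sd_x_deg"] = float(g["cx_deg"].std(ddof=1))
            row["sd_y_deg"] = float(g["cy_deg"].std(ddof=1))
        else:
            row["sd_x_deg"] = np.nan
            row["sd_y_deg"] = np.nan
        rows.append(row)
    per_location = pd.DataFrame(rows)
    summaries = []
    for tracker, g in per_location[per_location["included"]].groupby("tracker"):
        summaries.append({
            "tracker": tracker,
            "n_locations": len(g),
            "mean_sd_x_deg": float(g["sd_x_deg"].mean()),
            "sd_sd_x_deg": float(g["sd_x_deg"].std(ddof=1)),
            "mean_sd_y_deg": float(g["sd_y_deg"].mean()),
            "sd_sd_y_deg": float(g["sd_y_deg"].std(ddof=1)),
        })
    return per_location, pd.DataFrame(summaries)


def rms_s2s(values: np.ndarray, valid: np.ndarray | None = None) -> float:
    """RMS of successive displacements along one axis.

    Only index-consecutive pairs with both samples valid contribute;
    pairs spanning an invalid sample are excluded.  Requires at least one
    such pair.
    """
    x = np.asarray(values, float)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(x)
    pair_ok = valid[:-1] & valid[1:]
    if not pair_ok.any():
        raise ValueError("rms_s2s needs at least two consecutive valid samples")
    d = np.diff(x)[pair_ok]
    return float(np.sqrt(np.mean(d ** 2)))


def data_loss_fraction(stream: GazeStream,
                       interval_ms: tuple[float, float] | None = None,
                       mode: str | None = None) -> float:
    """Percentage of lost data in an interval.

    ``confidence`` mode counts the share of samples flagged confidence 0;
    ``missing`` mode compares the observed sample count with the count
    expected from the nominal rate (floor of interval x rate), clipped to
    [0, 100] %.  When ``mode`` is None it is inferred from whether the
    stream carries any confidence values.
    """
    if mode is None:
        mode = ("confidence"
                if stream.data["confidence"].notna().any() else "missing")
    t = stream.t_ms
    if interval_ms is None:
        interval_ms = (float(t[0]), float(t[-1]))
    t0, t1 = interval_ms
    sel = (t >= t0) & (t <= t1)
    if mode == "confidence":
        conf = stream.data["confidence"].to_numpy(float)[sel]
        if conf.size == 0:
            return 0.0
        return float(100.0 * np.mean(conf == 0.0))
    if mode == "missing":
        expected = int((t1 - t0) / 1000.0 * stream.nominal_rate_hz)
        if expected <= 0:
            return 0.0
        observed = int(sel.sum())
        return float(np.clip(100.0 * (1.0 - observed / expected), 0.0, 100.0))
    raise ValueError(f"unknown data-loss mode {mode!r}")


@dataclass(frozen=True)
class AxisCorrelation:
    """Per-subject Pearson correlations between the two trackers."""

    r_x: float
    r_y: float
    n: int


def axis_correlations(merged: MergedSeries,
                      min_valid: int = 30) -> AxisCorrelation:
    """Pearson r per axis over jointly valid rows of a merged series.

    Raises ``ValueError`` when fewer than ``min_valid`` jointly valid
    rows remain (such subjects are excluded from cohort means).
    """
    m = merged.joint_valid()
    n = int(m.sum())
    if n < min_valid:
        raise ValueError(
            f"only {n} jointly valid rows (< {min_valid}); subject excluded"
        )
    d = merged.data.loc[m]
    r_x = float(np.corrcoef(d["a_x_deg"], d["b_x_deg"])[0, 1])
    r_y = float(np.corrcoef(d["a_y_deg"], d["b_y_deg"])[0, 1])
    return AxisCorrelation(r_x=r_x, r_y=r_y, n=n)


def cohort_correlations(per_subject: list[AxisCorrelation],
                        fisher: bool = False) -> tuple[float, float]:
    """Average per-subject correlations across the cohort.

    The default is the arithmetic mean of r; ``fisher=True`` averages in
    Fisher-z space instead (statistically cleaner, optional).
    """
    if not per_subject:
        raise ValueError("no subjects with computable correlations")
    rx = np.array([c.r_x for c in per_subject])
    ry = np.array([c.r_y for c in per_subject])
    if fisher:
        return (float(np.tanh(np.arctanh(rx).mean())),
                float(np.tanh(np.arctanh(ry).mean())))
    return float(rx.mean()), float(ry.mean())


def drift_correct(samples_deg: np.ndarray,
                  recal_centroids_deg: np.ndarray,
                  recal_targets_deg: np.ndarray,
                  stat: str = "median") -> tuple[np.ndarray, np.ndarray, float]:
    """Constant-offset drift correction from a recalibration grid.

    The systematic offset is the per-axis median (or mean) of
    ``centroid - target`` over the recalibration points; it is estimated
    leave-one-out to yield a cross-validated residual, then the all-point
    offset is subtracted from ``samples_deg``.

    Returns ``(corrected_samples, correction_xy, residual_deg)`` where
    ``residual_deg`` is the mean held-out offset error.
    """
    cen = np.atleast_2d(np.asarray(recal_centroids_deg, float))
    tgt = np.atleast_2d(np.asarray(recal_targets_deg, float))
    if cen.shape != tgt.shape or cen.shape[0] < 3:
        raise ValueError("need at least 3 matched recalibration pairs")
    reduce = np.median if stat == "median" else np.mean
    offsets = cen - tgt
    k = offsets.shape[0]
    held_out = np.empty(k)
    for i in range(k):
        rest = np.delete(offsets, i, axis=0)
        corr_i = reduce(rest, axis=0)
        held_out[i] = np.linalg.norm(offsets[i] - corr_i)
    correction = reduce(offsets, axis=0)
    corrected = np.asarray(samples_deg, float) - correction
    return corrected, correction, float(held_out.mean())
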