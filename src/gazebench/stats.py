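"""Statistical summary stage and end-to-end battery runner.

Covers the factorial ANOVAs over the accuracy/precision records, paired
t tests on data loss, the calibration-table summary, Gaussian-KDE gaze
heatmaps, and ``run_battery``, which chains simulate -> sync -> detect ->
metrics -> stats for all five tasks and emits a battery-summary table.

No multiple-testing correction is applied anywhere; the tables report
uncorrected p values alongside eta-squared effect sizes.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import quality, simulate
from .fixations import DispersionParams, detect_fixations, select_offset_fixations
from .geometry import ScreenGeometry, px_to_deg, screen_from_diagonal
from .streams import GazeStream, MergedSeries, estimate_lag, merge_streams

__all__ = [
    "factorial_anova",
    "paired_ttest",
    "load_calibration_table",
    "summarize_calibration",
    "kde_heatmap",
    "default_scenario",
    "smoke_scenario",
    "run_battery",
    "BatteryResult",
]

#: Table-5-style metric row names used in the battery summary.
SUMMARY_METRICS = [
    "mean_loss_pct", "sd_loss_pct",
    "corr_x", "corr_y",
    "n_fixations", "n_offset_fixations",
    "mean_accuracy_deg", "sd_accuracy_deg",
    "mean_precision_deg", "sd_precision_deg",
]


# ---------------------------------------------------------------------------
# ANOVA and t tests
# ---------------------------------------------------------------------------

def factorial_anova(records: pd.DataFrame, factors: list[str],
                    response: str) -> pd.DataFrame:
    """Full-factorial ANOVA with Type-II sums of squares.

    All main effects and interactions up to the full order are fitted by
    OLS; Type-II SS keep the decomposition invariant to factor order
    under the mild imbalance left by excluded trials.  Returns a table
    with ``sum_sq, df, mean_sq, F, p_unc, eta_sq`` per effect plus a
    Residual row; ``eta_sq`` is effect SS over total SS.

    Raises ``ValueError`` on a factor with fewer than two observed
    levels or on an empty design cell (which makes Type-II SS
    inestimable), naming the offending cell.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = records[factors + [response]].dropna().copy()
    levels = {}
    for f in factors:
        levels[f] = sorted(df[f].astype(str).unique())
        if len(levels[f]) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    observed = set(map(tuple, df[factors].astype(str).itertuples(index=False)))
    for cell in itertools.product(*(levels[f] for f in factors)):
        if cell not in observed:
            name = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise ValueError(f"empty design cell ({name}); Type-II SS "
                             "inestimable")
    # fit under safe internal names so user columns (e.g. a factor
    # called "C") cannot shadow formula builtins
    safe = {f: f"factor_{i}_" for i, f in enumerate(factors)}
    fit_df = df.rename(columns={**safe, response: "response_"})
    formula = "response_ ~ " + " * ".join(f"C({safe[f]})" for f in factors)
    model = ols(formula, data=fit_df).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        table = anova_lm(model, typ=2)
    back = {v: k for k, v in safe.items()}

    def _rename(term: str) -> str:
        term = re.sub(r"C\(([^)]+)\)", r"\1", term)
        return ":".join(back.get(p, p) for p in term.split(":"))

    table = table.rename(index=_rename)
    table = table.rename(columns={"PR(>F)": "p_unc"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    ss_total = float(table["sum_sq"].sum())
    table["eta_sq"] = table["sum_sq"] / ss_total if ss_total > 0 else 0.0
    return table[["sum_sq", "df", "mean_sq", "F", "p_unc", "eta_sq"]]


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Classic paired t test; returns ``(t, df, p_two_sided)``.

    Identical inputs give ``(0, n-1, 1)``.  A nonzero constant
    difference (zero variance) raises rather than returning infinities —
    that situation signals a degenerate simulation, not a finding.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_ttest needs two equal-length vectors, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


# ---------------------------------------------------------------------------
# Calibration summary
# ---------------------------------------------------------------------------

def load_calibration_table() -> pd.DataFrame:
    """Packaged per-participant calibration-error table (degrees)."""
    path = resources.files("gazebench").joinpath(
        "fixtures/calibration_table1.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def summarize_calibration(table: pd.DataFrame) -> pd.Series:
    """Column means of a calibration table, rounded to 2 decimals.

    Any numeric column except a participant identifier is averaged, so
    the result carries the mean of per-subject mean errors and (where
    available) the mean of per-subject maximum errors, per tracker.
    """
    if len(table) < 1:
        raise ValueError("empty calibration table")
    cols = [c for c in table.columns
            if c.lower() not in ("participant", "subject")
            and pd.api.types.is_numeric_dtype(table[c])]
    if not cols:
        raise ValueError("no numeric error columns found")
    return table[cols].mean().round(2)


# ---------------------------------------------------------------------------
# KDE heatmap
# ---------------------------------------------------------------------------

def kde_heatmap(points: np.ndarray, grid_shape: tuple[int, int] = (90, 144),
                extent: tuple[float, float, float, float] | None = None,
                bandwidth: float | None = None,
                normalize: bool = True) -> np.ndarray:
    """Gaussian kernel-density raster of gaze positions.

    ``grid_shape`` is ``(ny, nx)``; ``extent`` is
    ``(xmin, xmax, ymin, ymax)`` (defaults to the point bounding box
    padded by 10 %).  Bandwidth defaults to Scott's rule; degenerate
    inputs (a single point or zero variance) fall back to an isotropic
    Gaussian whose sigma is ``bandwidth`` or 1/20 of the extent span.
    With ``normalize=True`` the raster is divided by its maximum so the
    peak is exactly 1.
    """
    p = np.atleast_2d(np.asarray(points, float))
    if p.shape[0] < 1:
        raise ValueError("kde_heatmap needs at least one point")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    ny, nx = grid_shape
    if extent is None:
        pad_x = 0.1 * max(np.ptp(p[:, 0]), 1.0)
        pad_y = 0.1 * max(np.ptp(p[:, 1]), 1.0)
        extent = (p[:, 0].min() - pad_x, p[:, 0].max() + pad_x,
                  p[:, 1].min() - pad_y, p[:, 1].max() + pad_y)
    xs = np.linspace(extent[0], extent[1], nx)
    ys = np.linspace(extent[2], extent[3], ny)
    gx, gy = np.meshgrid(xs, ys)
    try:
        kde = sps.gaussian_kde(p.T, bw_method=bandwidth)
        z = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(ny, nx)
    except (np.linalg.LinAlgError, ValueError):
        sigma = bandwidth or max(extent[1] - extent[0],
                                 extent[3] - extent[2]) / 20.0
        z = np.zeros((ny, nx))
        for q in p:
            z += np.exp(-((gx - q[0]) ** 2 + (gy - q[1]) ** 2)
                        / (2.0 * sigma ** 2))
        z /= 2.0 * np.pi * sigma ** 2 * p.shape[0]
    if normalize:
        peak = z.max()
        if peak > 0:
            z = z / peak
    return z


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

def default_scenario() -> dict:
    """Study-scale scenario: 19 subjects, full five-task battery.

    Mirrors the bench's reference study conditions: a 15-inch 1440x900
    display at 600 mm, a 500-Hz lab tracker vs a 30-Hz webcam tracker,
    a 7x8 fixation grid, Brownian-direction pursuit at 887 deg^2/s, 18
    free-viewing images of 6 s, and the two head-movement tasks.
    """
    return {
        "screen": {"diagonal_mm": 381.0, "width_px": 1440,
                   "height_px": 900, "distance_mm": 600.0},
        "n_subjects": 19,
        "trackers": {"lab": {"preset": "lab"},
                     "webcam": {"preset": "webcam"}},
        "oculomotor": {},
        # dispersion thresholds track each tracker's per-sample noise:
        # the max-pairwise spread of a stationary fixation grows with
        # noise SD and sample count, so a noisier (or faster) stream
        # needs a proportionally larger threshold to hold fixations
        # together.  Roughly 5x the 2-D per-sample noise SD works well.
        "detector": {"min_points": 3, "max_relative_change": 0.5,
                     "min_duration_ms": 100.0,
                     "per_tracker": {
                         "lab": {"dispersion_threshold_deg": 2.0},
                         "webcam": {"dispersion_threshold_deg": 3.0},
                     }},
        "sync": {"max_lag_ms": 2000.0, "max_gap_ms": 100.0},
        "tasks": {
            "large_grid": {"rows": 7, "cols": 8, "margin_px": 60.0,
                           "trial_duration_ms": 1500.0, "gap_ms": 500.0},
            "smooth_pursuit": {"n_trials": 4, "trial_duration_s": 20.0,
                               "direction_var_deg2_s": 887.0,
                               "speed_range_px_s": [100.0, 400.0]},
            "free_view": {"n_images": 18, "duration_s": 6.0},
            "head_roll": {},
            "head_yaw": {},
        },
    }


def smoke_scenario() -> dict:
    """Scaled-down scenario for fast end-to-end runs and tests."""
    sc = default_scenario()
    sc["n_subjects"] = 3
    sc["tasks"]["large_grid"].update(rows=4, cols=4,
                                     trial_duration_ms=900.0)
    sc["tasks"]["smooth_pursuit"].update(n_trials=1, trial_duration_s=12.0)
    sc["tasks"]["free_view"].update(n_images=3, duration_s=4.0)
    sc["tasks"]["head_roll"].update(trial_duration_ms=1500.0, gap_ms=300.0)
    sc["tasks"]["head_yaw"].update(trial_duration_ms=1500.0, gap_ms=300.0)
    return sc


def _merge_config(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_config(out[k], v)
        else:
            out[k] = v
    return out


def _scenario_geometry(scenario: dict) -> ScreenGeometry:
    s = scenario["screen"]
    return screen_from_diagonal(s["diagonal_mm"], s["width_px"],
                                s["height_px"], s["distance_mm"])


def _scenario_tracker(cfg: dict, name: str) -> simulate.TrackerModel:
    cfg = dict(cfg)
    preset = cfg.pop("preset", name)
    return simulate.tracker_from_preset(preset, name=name, **cfg)


# ---------------------------------------------------------------------------
# Battery runner
# ---------------------------------------------------------------------------

@dataclass
class BatteryResult:
    """Everything the battery computed, ready to be written as CSVs."""

    scenario: dict
    seed: int
    config_hash: str
    summary: pd.DataFrame
    anova_accuracy: pd.DataFrame | None
    anova_precision_x: pd.DataFrame | None
    anova_precision_y: pd.DataFrame | None
    ttest_loss: pd.DataFrame
    accuracy_records: pd.DataFrame = field(repr=False)
    precision_per_location: pd.DataFrame = field(repr=False)
    precision_summary: pd.DataFrame = field(repr=False)
    correlations: pd.DataFrame = field(repr=False)
    lags: pd.DataFrame = field(repr=False)
    free_view_points: dict[str, np.ndarray] = field(repr=False,
                                                    default_factory=dict)

    def write(self, out_dir, heatmaps: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary_table5.csv")
        for name, tbl in (("anova_accuracy", self.anova_accuracy),
                          ("anova_precision_x", self.anova_precision_x),
                          ("anova_precision_y", self.anova_precision_y)):
            if tbl is not None:
                tbl.to_csv(out / f"{name}.csv")
        self.ttest_loss.to_csv(out / "ttest_loss.csv", index=False)
        self.accuracy_records.to_csv(out / "accuracy_records.csv", index=False)
        self.precision_per_location.to_csv(out / "precision_locations.csv",
                                           index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.lags.to_csv(out / "lags.csv", index=False)
        (out / "run.log").write_text(
            f"seed={self.seed}\nconfig_sha256={self.config_hash}\n")
        if heatmaps:
            self._write_heatmaps(out)

    def _write_heatmaps(self, out: Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for tracker, pts in self.free_view_points.items():
            if len(pts) < 2:
                continue
            z = kde_heatmap(pts)
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.imshow(z, origin="upper", cmap="magma")
            ax.set_title(f"Free-view gaze density ({tracker})")
            ax.set_axis_off()
            fig.savefig(out / f"heatmap_free_view_{tracker}.png", dpi=110)
            plt.close(fig)


def _make_schedule(task: str, cfg: dict, seed: int,
                   geom: ScreenGeometry) -> simulate.StimulusSchedule:
    if task == "large_grid":
        return simulate.gen_large_grid(seed=seed, geom=geom, **cfg)
    if task == "smooth_pursuit":
        cfg = dict(cfg)
        if "speed_range_px_s" in cfg:
            cfg["speed_range_px_s"] = tuple(cfg["speed_range_px_s"])
        return simulate.gen_pursuit_schedule(seed=seed, geom=geom, **cfg)
    if task == "free_view":
        return simulate.gen_free_view(seed=seed, geom=geom, **cfg)
    if task == "head_roll":
        return simulate.gen_head_task("roll", seed=seed, geom=geom, **cfg)
    if task == "head_yaw":
        return simulate.gen_head_task("yaw", seed=seed, geom=geom, **cfg)
    raise ValueError(f"unknown task {task!r}")


def _fixation_rms(stream_deg: np.ndarray, valid: np.ndarray,
                  t: np.ndarray, fixations) -> tuple[float, float] | None:
    """RMS-S2S per axis restricted to samples inside detected fixations."""
    in_fix = np.zeros(len(t), bool)
    for fx in fixations:
        in_fix |= (t >= fx.start_ms) & (t <= fx.end_ms)
    mask = valid & in_fix
    try:
        return (quality.rms_s2s(stream_deg[:, 0], mask),
                quality.rms_s2s(stream_deg[:, 1], mask))
    except ValueError:
        return None


def run_battery(scenario: dict | None = None, seed: int = 0,
                out_dir=None, heatmaps: bool = False) -> BatteryResult:
    """Run the full five-task comparison on simulated subjects.

    Per subject and task: generate the stimulus schedule and a
    ground-truth scanpath, observe it through both tracker models,
    estimate and remove the inter-tracker lag, merge onto the low-rate
    timebase, detect fixations per tracker, and accumulate loss,
    correlation, accuracy, and precision records.  Afterwards the
    factorial ANOVAs and the paired loss t tests are computed and a
    battery-summary table (metric x task per tracker) is assembled.

    Fully deterministic for a fixed scenario and seed.
    """
    scenario = _merge_config(default_scenario(), scenario)
    geom = _scenario_geometry(scenario)
    ocm = simulate.OculomotorParams(**scenario.get("oculomotor", {}))
    det_cfg = dict(scenario.get("detector", {}))
    det_per_tracker = det_cfg.pop("per_tracker", {})
    detectors = {
        name: DispersionParams(**{**det_cfg,
                                  **det_per_tracker.get(name, {})})
        for name in scenario["trackers"]
    }
    sync_cfg = scenario.get("sync", {})
    trackers = {name: _scenario_tracker(cfg, name)
                for name, cfg in scenario["trackers"].items()}
    lab_name, web_name = list(trackers)[:2] if "lab" not in trackers else \
        ("lab", [n for n in trackers if n != "lab"][0])
    tasks = scenario["tasks"]
    n_subjects = int(scenario["n_subjects"])
    root_ss = np.random.SeedSequence(seed)
    subject_seeds = root_ss.spawn(n_subjects)

    grid_cfg = tasks.get("large_grid", {})
    grid_rows = int(grid_cfg.get("rows", 7))
    grid_cols = int(grid_cfg.get("cols", 8))

    loss_rows, corr_rows, lag_rows, acc_frames = [], [], [], []
    fix_counts: dict[tuple[str, str], int] = {}
    offset_counts: dict[str, int] = {}
    rms_rows = []
    fv_points: dict[str, list[np.ndarray]] = {n: [] for n in trackers}

    for s_idx, s_ss in enumerate(subject_seeds):
        subject = f"S{s_idx + 1:02d}"
        task_seeds = s_ss.spawn(len(tasks) * 4)
        for t_idx, (task, cfg) in enumerate(tasks.items()):
            sched_seed, truth_seed, lab_seed, web_seed = (
                int(ss.generate_state(1)[0] % (2 ** 31))
                for ss in task_seeds[t_idx * 4:(t_idx + 1) * 4])
            schedule = _make_schedule(task, cfg, sched_seed, geom)
            truth = simulate.gen_ground_truth_gaze(schedule, ocm,
                                                   truth_seed, geom)
            streams = {
                lab_name: simulate.observe_tracker(
                    truth, trackers[lab_name], geom, seed=lab_seed),
                web_name: simulate.observe_tracker(
                    truth, trackers[web_name], geom, seed=web_seed),
            }
            for name, st in streams.items():
                loss_rows.append({
                    "subject": subject, "task": task, "tracker": name,
                    "loss_pct": quality.data_loss_fraction(st),
                })
            # synchronize: bring the webcam stream onto the lab clock,
            # which is also the clock the press events live on
            lag = estimate_lag(streams[lab_name], streams[web_name],
                               **sync_cfg)
            lag_rows.append({"subject": subject, "task": task,
                             "lag_ms": lag})
            web_sync = GazeStream(
                source=streams[web_name].source,
                nominal_rate_hz=streams[web_name].nominal_rate_hz,
                data=streams[web_name].data.assign(
                    t_ms=streams[web_name].data["t_ms"] - lag),
            )
            merged = merge_streams(web_sync, streams[lab_name], geom,
                                   known_lag_ms=0.0,
                                   max_gap_ms=sync_cfg.get("max_gap_ms", 100.0))
            merged.estimated_lag_ms = lag
            try:
                ac = quality.axis_correlations(merged)
                corr_rows.append({"subject": subject, "task": task,
                                  "r_x": ac.r_x, "r_y": ac.r_y, "n": ac.n})
            except ValueError:
                pass

            synced = {lab_name: streams[lab_name], web_name: web_sync}
            fixations = {}
            for name, st in synced.items():
                deg = px_to_deg(st.xy_px, geom)
                fixations[name] = detect_fixations(st.t_ms, deg,
                                                   st.valid, detectors[name])
                fix_counts[(name, task)] = (
                    fix_counts.get((name, task), 0) + len(fixations[name]))
                if task == "free_view":
                    fv_points[name].append(deg[st.valid])

            if task == "large_grid":
                for name, st in synced.items():
                    sel = select_offset_fixations(
                        fixations[name], schedule.trials, truth.presses)
                    offset_counts[name] = (offset_counts.get(name, 0)
                                           + sum(v is not None
                                                 for v in sel.values()))
                    acc_frames.append(quality.large_grid_accuracy_records(
                        sel, schedule.trials, geom, grid_rows, grid_cols,
                        subject, name))
                    deg = px_to_deg(st.xy_px, geom)
                    rms = _fixation_rms(deg, st.valid, st.t_ms,
                                        fixations[name])
                    if rms is not None:
                        rms_rows.append({"subject": subject, "tracker": name,
                                         "rms_x_deg": rms[0],
                                         "rms_y_deg": rms[1]})

    accuracy_records = (pd.concat(acc_frames, ignore_index=True)
                        if acc_frames else pd.DataFrame())
    loss = pd.DataFrame(loss_rows)
    corr = pd.DataFrame(corr_rows)
    lags = pd.DataFrame(lag_rows)
    rms = pd.DataFrame(rms_rows)

    # precision across subjects at shared grid locations
    if len(accuracy_records):
        per_loc, prec_summary = quality.precision_across_subjects(
            accuracy_records)
    else:
        per_loc = pd.DataFrame()
        prec_summary = pd.DataFrame()

    # ANOVAs
    anova_acc = anova_px = anova_py = None
    if len(accuracy_records):
        try:
            anova_acc = factorial_anova(
                accuracy_records, ["half", "eccentricity", "tracker"],
                "error_deg")
        except ValueError:
            pass
    if len(per_loc) and "eccentricity" in per_loc.columns:
        inc = per_loc[per_loc["included"]]
        for resp, slot in (("sd_x_deg", "x"), ("sd_y_deg", "y")):
            try:
                tbl = factorial_anova(inc, ["tracker", "eccentricity"], resp)
            except ValueError:
                tbl = None
            if slot == "x":
                anova_px = tbl
            else:
                anova_py = tbl

    # paired loss t tests for the head tasks
    t_rows = []
    for task in ("head_roll", "head_yaw"):
        sub = loss[loss["task"] == task]
        if not len(sub):
            continue
        wide = sub.pivot(index="subject", columns="tracker",
                         values="loss_pct").dropna()
        if len(wide) >= 2 and {lab_name, web_name} <= set(wide.columns):
            try:
                t, dfree, p = paired_ttest(wide[web_name], wide[lab_name])
                t_rows.append({"task": task, "t": t, "df": dfree, "p": p})
            except ValueError:
                pass
    ttest_loss = pd.DataFrame(t_rows)

    # Table-5-shaped summary: (tracker, metric) x task
    task_names = list(tasks)
    index = pd.MultiIndex.from_product([list(trackers), SUMMARY_METRICS],
                                       names=["tracker", "metric"])
    summary = pd.DataFrame(np.nan, index=index, columns=task_names)
    for name in trackers:
        for task in task_names:
            g = loss[(loss["tracker"] == name) & (loss["task"] == task)]
            if len(g):
                summary.loc[(name, "mean_loss_pct"), task] = round(
                    g["loss_pct"].mean(), 2)
                summary.loc[(name, "sd_loss_pct"), task] = round(
                    g["loss_pct"].std(ddof=1) if len(g) > 1 else 0.0, 2)
            if (name, task) in fix_counts:
                summary.loc[(name, "n_fixations"), task] = \
                    fix_counts[(name, task)]
        if name in offset_counts:
            summary.loc[(name, "n_offset_fixations"), "large_grid"] = \
                offset_counts[name]
        if len(accuracy_records):
            g = accuracy_records[accuracy_records["tracker"] == name]
            per_subj = g.groupby("subject")["error_deg"].mean()
            if len(per_subj):
                summary.loc[(name, "mean_accuracy_deg"), "large_grid"] = \
                    round(per_subj.mean(), 2)
                summary.loc[(name, "sd_accuracy_deg"), "large_grid"] = round(
                    per_subj.std(ddof=1) if len(per_subj) > 1 else 0.0, 2)
        if len(per_loc):
            g = per_loc[(per_loc["tracker"] == name) & per_loc["included"]]
            pool = np.concatenate([g["sd_x_deg"].to_numpy(),
                                   g["sd_y_deg"].to_numpy()]) if len(g) else []
            if len(pool):
                summary.loc[(name, "mean_precision_deg"), "large_grid"] = \
                    round(float(np.mean(pool)), 2)
                summary.loc[(name, "sd_precision_deg"), "large_grid"] = \
                    round(float(np.std(pool, ddof=1)), 2)
    if len(corr):
        for task in task_names:
            g = corr[corr["task"] == task]
            if len(g):
                rx, ry = quality.cohort_correlations(
                    [quality.AxisCorrelation(r.r_x, r.r_y, r.n)
                     for r in g.itertuples()])
                # correlations describe the tracker pair; store on both rows
                for name in trackers:
                    summary.loc[(name, "corr_x"), task] = round(rx, 2)
                    summary.loc[(name, "corr_y"), task] = round(ry, 2)

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(scenario, sort_keys=True).encode()).hexdigest()
    result = BatteryResult(
        scenario=scenario, seed=seed, config_hash=cfg_hash,
        summary=summary, anova_accuracy=anova_acc,
        anova_precision_x=anova_px, anova_precision_y=anova_py,
        ttest_loss=ttest_loss, accuracy_records=accuracy_records,
        precision_per_location=per_loc, precision_summary=prec_summary,
        correlations=corr, lags=lags,
        free_view_points={k: (np.vstack(v) if v else np.empty((0, 2)))
                          for k, v in fv_points.items()},
    )
    if out_dir is not None:
        result.write(out_dir, heatmaps=heatmaps)
    return result
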