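import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from gazebench import DispersionParams, detect_fixations, dispersion
from gazebench.fixations import Fixation, select_offset_fixations


def oracle_detect(t, xy, valid, thr, min_pts=3, max_rel=np.inf):
    """Reference detector: exhaustive left-to-right maximal windows.

    Recomputes the dispersion of every candidate window from scratch
    with a brute-force O(n^2) pairwise scan (slide step absent), so it
    shares no code path with the incremental implementation.
    """
    def disp(win):
        if len(win) < 2:
            return 0.0
        return float(pdist(np.asarray(win)).max())

    n = len(t)
    out = []
    i = 0
    while i < n:
        ok_window = (i + min_pts <= n and all(valid[i:i + min_pts])
                     and disp(xy[i:i + min_pts]) <= thr)
        if not ok_window:
            i += 1
            continue
        j = i + min_pts
        while j < n and valid[j]:
            d_old = disp(xy[i:j])
            d_new = disp(xy[i:j + 1])
            if d_new > thr:
                break
            if d_old > 0 and (d_new - d_old) / d_old > max_rel:
                break
            j += 1
        out.append((float(t[i]), float(t[j - 1])))
        i = j
    return out


def random_walk_stream(seed, n=50, step=0.25, jump_prob=0.1, jump=3.0,
                       invalid_prob=0.05):
    """Gaze-like degree signal: slow walk with occasional large jumps."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, step, (n, 2))
    jumps = rng.random(n) < jump_prob
    steps[jumps] += rng.normal(0, jump, (int(jumps.sum()), 2))
    xy = np.cumsum(steps, axis=0)
    valid = rng.random(n) >= invalid_prob
    t = np.arange(n) * 33.0
    return t, xy, valid


class TestDispersion:
    def test_singleton_zero(self):
        assert dispersion(np.array([[0.0, 0.0]])) == 0.0

    def test_3_4_5(self):
        assert dispersion(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pts = rng.normal(0, 1, (10, 2))
            brute = max(np.linalg.norm(a - b)
                        for i, a in enumerate(pts) for b in pts[i + 1:])
            assert dispersion(pts) == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dispersion(np.empty((0, 2)))

    def test_bbox_metric(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [0.5, 0.5]])
        assert dispersion(pts, metric="bbox") == pytest.approx(3.0)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            DispersionParams(dispersion_threshold_deg=0.0)
        with pytest.raises(ValueError):
            DispersionParams(min_points=2)
        with pytest.raises(ValueError):
            DispersionParams(metric="euclid")


class TestDetectFixations:
    def test_constant_input_single_fixation(self):
        t = np.arange(10) * 50.0
        xy = np.tile([5.0, 5.0], (10, 1))
        fx = detect_fixations(t, xy, params=DispersionParams())
        assert len(fx) == 1
        f = fx[0]
        assert (f.cx_deg, f.cy_deg) == (5.0, 5.0)
        assert f.dispersion_deg == 0.0
        assert f.n_samples == 10

    def test_two_noiseless_clusters(self):
        t = np.arange(40) * 25.0
        xy = np.zeros((40, 2))
        xy[20:] = [5.0, 5.0]
        fx = detect_fixations(t, xy, params=DispersionParams(
            dispersion_threshold_deg=1.0))
        assert len(fx) == 2
        assert (fx[0].cx_deg, fx[0].cy_deg) == (0.0, 0.0)
        assert (fx[1].cx_deg, fx[1].cy_deg) == (5.0, 5.0)
        assert fx[0].n_samples == fx[1].n_samples == 20

    def test_too_few_samples_no_fixation(self):
        t = np.array([0.0, 33.0])
        xy = np.zeros((2, 2))
        assert detect_fixations(t, xy, params=DispersionParams()) == []

    def test_invalid_sample_terminates_fixation(self):
        t = np.arange(20) * 50.0
        xy = np.zeros((20, 2))
        valid = np.ones(20, bool)
        valid[10] = False
        fx = detect_fixations(t, xy, valid, DispersionParams())
        assert len(fx) == 2
        assert fx[0].end_ms < t[10] < fx[1].start_ms

    def test_fixations_disjoint_and_ordered(self):
        for seed in range(20):
            t, xy, valid = random_walk_stream(seed, n=200)
            fx = detect_fixations(t, xy, valid, DispersionParams(
                min_duration_ms=None))
            for a, b in zip(fx, fx[1:]):
                assert a.end_ms < b.start_ms

    def test_members_stay_near_centroid(self):
        # every sample inside a fixation interval lies within the
        # dispersion threshold of the centroid (simulated tremor input)
        rng = np.random.default_rng(5)
        t = np.arange(400) * 33.0
        centers = np.repeat(rng.uniform(-5, 5, (4, 2)), 100, axis=0)
        xy = centers + rng.normal(0, 0.25, (400, 2))
        params = DispersionParams(min_duration_ms=None)
        fx = detect_fixations(t, xy, params=params)
        assert fx
        for f in fx:
            sel = (t >= f.start_ms) & (t <= f.end_ms)
            d = np.linalg.norm(xy[sel] - [f.cx_deg, f.cy_deg], axis=1)
            assert np.all(d <= params.dispersion_threshold_deg)

    def test_centroid_recovery_under_tremor(self):
        # parameter recovery: centroid error < 3 sigma / sqrt(n) per axis
        rng = np.random.default_rng(9)
        sigma = 0.2
        t = np.arange(200) * 33.0
        target = np.array([2.0, -1.0])
        xy = target + rng.normal(0, sigma, (200, 2))
        fx = detect_fixations(t, xy, params=DispersionParams(
            dispersion_threshold_deg=2.0, max_relative_change=np.inf))
        assert len(fx) == 1
        n = fx[0].n_samples
        bound = 3 * sigma / np.sqrt(n)
        assert abs(fx[0].cx_deg - target[0]) <= bound
        assert abs(fx[0].cy_deg - target[1]) <= bound

    @pytest.mark.parametrize("max_rel", [np.inf, 0.5])
    def test_matches_exhaustive_oracle(self, max_rel):
        params = DispersionParams(dispersion_threshold_deg=1.0,
                                  max_relative_change=max_rel,
                                  slide_enabled=False,
                                  min_duration_ms=None)
        for seed in range(60):
            t, xy, valid = random_walk_stream(seed)
            got = [(f.start_ms, f.end_ms)
                   for f in detect_fixations(t, xy, valid, params)]
            want = oracle_detect(t, xy, valid, thr=1.0, max_rel=max_rel)
            assert got == want, f"seed {seed}"

    def test_slide_keeps_sample_conservation(self):
        # drifting cluster: slides may fire, but every valid sample
        # belongs to at most one fixation interval
        rng = np.random.default_rng(3)
        t = np.arange(300) * 33.0
        xy = np.cumsum(rng.normal(0, 0.08, (300, 2)), axis=0)
        fx = detect_fixations(t, xy, params=DispersionParams(
            min_duration_ms=None))
        covered = np.zeros(300, int)
        for f in fx:
            covered[(t >= f.start_ms) & (t <= f.end_ms)] += 1
        assert covered.max() <= 1

    def test_min_duration_filter(self):
        t = np.arange(6) * 20.0
        xy = np.zeros((6, 2))
        assert detect_fixations(t, xy, params=DispersionParams(
            min_duration_ms=200.0)) == []
        assert len(detect_fixations(t, xy, params=DispersionParams(
            min_duration_ms=100.0))) == 1


class TestSelectOffsetFixations:
    @staticmethod
    def _trial(trial_id=0, onset=0.0, offset=1200.0):
        return pd.DataFrame([{"trial_id": trial_id, "task": "large_grid",
                              "onset_ms": onset, "offset_ms": offset,
                              "target_x_px": 0.0, "target_y_px": 0.0,
                              "meta": "r0c0"}])

    @staticmethod
    def _press(t, dur, trial_id=0):
        return pd.DataFrame([{"trial_id": trial_id, "press_t_ms": t,
                              "press_dur_ms": dur}])

    @staticmethod
    def _fix(start, end):
        return Fixation(start_ms=start, end_ms=end, cx_deg=0.0, cy_deg=0.0,
                        dispersion_deg=0.1, n_samples=10)

    def test_press_inside_short_press_selected(self):
        sel = select_offset_fixations([self._fix(900, 1400)],
                                      self._trial(), self._press(1000, 300))
        assert sel[0] is not None

    def test_long_press_rejected(self):
        sel = select_offset_fixations([self._fix(900, 1400)],
                                      self._trial(), self._press(1000, 600))
        assert sel[0] is None

    def test_press_outside_fixation_rejected(self):
        sel = select_offset_fixations([self._fix(900, 1400)],
                                      self._trial(), self._press(1500, 300))
        assert sel[0] is None

    def test_fixation_after_target_offset_still_selected(self):
        # the confirming press typically lands after the target has
        # disappeared; a fixation lying wholly past the trial offset
        # must still qualify (overlap only ranks, it never filters)
        sel = select_offset_fixations([self._fix(1250, 1700)],
                                      self._trial(), self._press(1400, 300))
        assert sel[0] is not None

    def test_ambiguity_resolved_by_trial_overlap(self):
        short = self._fix(1190, 1300)   # barely overlaps the trial
        long = self._fix(600, 1250)     # covers most of the trial
        sel = select_offset_fixations([short, long], self._trial(),
                                      self._press(1240, 200))
        assert sel[0] is long
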