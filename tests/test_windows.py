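"""Sliding windows, person-centering, and within-person mixed models."""

import numpy as np
import pandas as pd
import pytest

from hrvbold import (
    BoldRun,
    NNIntervalSeries,
    WindowSpec,
    fit_within_model,
    make_windows,
    per_window_metrics,
    person_center,
    window_validity,
)


class TestMakeWindows:
    def test_three_overlapping_windows(self):
        wins = make_windows(WindowSpec(480.0, 240.0, 0.5))
        assert wins == [(0.0, 240.0), (120.0, 360.0), (240.0, 480.0)]

    def test_single_full_span_window(self):
        assert make_windows(WindowSpec(240.0, 240.0, 0.5)) == [(0.0, 240.0)]

    def test_no_overlap(self):
        assert make_windows(WindowSpec(480.0, 240.0, 0.0)) == [
            (0.0, 240.0),
            (240.0, 480.0),
        ]

    def test_window_longer_than_scan_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(100.0, 240.0, 0.5)


class TestWindowValidity:
    def test_no_artifacts_valid(self):
        assert window_validity([], (0.0, 240.0))

    def test_long_artifact_invalidates(self):
        # 130 s of artifact inside a 240 s window exceeds the 2-minute cap
        assert not window_validity([(50.0, 180.0)], (0.0, 240.0))

    def test_summed_intersections_below_cutoff(self):
        segs = [(10.0, 60.0), (100.0, 160.0)]  # 50 + 60 = 110 s <= 120 s
        assert window_validity(segs, (0.0, 240.0))

    def test_only_intersection_counts(self):
        # 130 s artifact, but only 30 s of it falls inside the window
        assert window_validity([(210.0, 340.0)], (0.0, 240.0))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            window_validity([(0.0, 50.0), (40.0, 80.0)], (0.0, 240.0))


def _run_with_amplitude(amplitudes, tr=2.0, n_volumes=240, seed=0, sd=10.0):
    """64-voxel run whose noise SD follows a per-volume amplitude curve."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((8, 8, 1, n_volumes)) * sd * amplitudes
    return BoldRun(data=1000.0 + noise, tr=tr, mask=np.ones((8, 8, 1), bool))


def _steady_nn(duration=480.0, seed=0):
    rng = np.random.default_rng(seed)
    intervals = rng.normal(900.0, 40.0, int(duration / 0.7))
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    keep = onsets < duration
    return NNIntervalSeries(onsets[keep], intervals[keep])


class TestPerWindowMetrics:
    WINDOWS = [(0.0, 240.0), (120.0, 360.0), (240.0, 480.0)]

    def test_stationary_run_has_equal_window_sd(self):
        run = _run_with_amplitude(np.ones(240), seed=1)
        wt = per_window_metrics(run, _steady_nn(), self.WINDOWS)
        sds = wt["mean_sd_bold"].to_numpy()
        assert wt["valid"].all()
        assert sds.max() / sds.min() < 1.05

    def test_doubled_amplitude_window_detected(self):
        amp = np.ones(240)
        amp[120:] = 2.0  # volumes at t >= 240 s
        run = _run_with_amplitude(amp, seed=2)
        wt = per_window_metrics(run, _steady_nn(), self.WINDOWS)
        sds = wt["mean_sd_bold"].to_numpy()
        assert sds[2] / sds[0] == pytest.approx(2.0, rel=0.1)
        # middle window straddles both regimes: sqrt((1+4)/2) ~ 1.58
        assert sds[0] < sds[1] < sds[2]

    def test_lf_modulation_localized_to_window(self):
        t = np.arange(0, 480, 0.9)
        lf = np.where((t >= 120) & (t < 360), 60.0, 0.0)
        intervals = 900.0 + lf * np.sin(2 * np.pi * 0.1 * t)
        nn = NNIntervalSeries(t, intervals)
        run = _run_with_amplitude(np.ones(240), seed=3)
        wt = per_window_metrics(run, nn, self.WINDOWS)
        assert wt["log_lf"].idxmax() == 1

    def test_artifact_heavy_window_flagged(self):
        run = _run_with_amplitude(np.ones(240), seed=4)
        wt = per_window_metrics(
            run,
            _steady_nn(),
            self.WINDOWS,
            artifact_segments=[(10.0, 140.0)],  # 130 s inside window 1
        )
        assert not wt.loc[0, "valid"]
        assert wt.loc[0, "reason"] == "excess_artifact"
        assert wt.loc[2, "valid"]

    def test_window_without_volumes_marked_invalid(self):
        run = _run_with_amplitude(np.ones(100), n_volumes=100, seed=5)
        wt = per_window_metrics(run, _steady_nn(), self.WINDOWS)
        assert not wt.loc[2, "valid"]  # run ends at 200 s
        assert "sdbold" in wt.loc[2, "reason"]


def _window_table(values_by_subject, valid=None):
    rows = []
    for sid, vals in values_by_subject.items():
        for w, v in enumerate(vals):
            rows.append(
                {
                    "subject_id": sid,
                    "window_index": w,
                    "log_sdnn": v,
                    "mean_sd_bold": 1.0,
                    "valid": True if valid is None else valid[sid][w],
                }
            )
    return pd.DataFrame(rows)


class TestPersonCenter:
    def test_hand_example(self):
        out = person_center(_window_table({"a": [1.0, 2.0, 3.0]}), "log_sdnn")
        np.testing.assert_allclose(out["log_sdnn_pc"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out["log_sdnn_pm"], 2.0)

    def test_constant_subject_dropped(self):
        table = _window_table({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="dropped 1"):
            out = person_center(table, "log_sdnn")
        assert set(out["subject_id"]) == {"b"}

    def test_centering_uses_only_valid_windows(self):
        table = _window_table(
            {"a": [1.0, 99.0, 3.0]}, valid={"a": [True, False, True]}
        )
        out = person_center(table, "log_sdnn")
        assert len(out) == 2
        np.testing.assert_allclose(out["log_sdnn_pm"], 2.0)
        np.testing.assert_allclose(
            sorted(out["log_sdnn_pc"]), [-np.sqrt(0.5), np.sqrt(0.5)]
        )

    def test_within_subject_mean_zero_sd_one(self, rng):
        table = _window_table(
            {f"s{i}": rng.normal(4, 0.3, 3).tolist() for i in range(15)}
        )
        out = person_center(table, "log_sdnn")
        for _, grp in out.groupby("subject_id"):
            assert grp["log_sdnn_pc"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["log_sdnn_pc"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_between_within_orthogonality(self, rng):
        table = _window_table(
            {f"s{i}": rng.normal(4, 0.3, 3).tolist() for i in range(25)}
        )
        out = person_center(table, "log_sdnn")
        cov = np.cov(out["log_sdnn_pc"], out["log_sdnn_pm"])[0, 1]
        assert abs(cov) < 1e-10


def _mixed_table(rng, n_subjects=25, beta_pc=0.0, beta_pm=0.0, noise=0.02):
    rows = []
    for s in range(n_subjects):
        offset = rng.normal(1.0, 0.05)
        pcs = rng.standard_normal(3)
        pcs = (pcs - pcs.mean()) / pcs.std(ddof=1)
        pm = rng.normal(4.0, 0.3)
        age, sex, race = rng.uniform(25, 75), s % 2, (s // 2) % 2
        for w in range(3):
            rows.append(
                {
                    "subject_id": f"s{s}",
                    "window_index": w,
                    "valid": True,
                    "log_sdnn_pc": pcs[w],
                    "log_sdnn_pm": pm,
                    "mean_sd_bold": offset
                    + beta_pc * pcs[w]
                    + beta_pm * pm
                    + (rng.normal(0, noise) if noise else 0.0),
                    "age": age,
                    "sex": sex,
                    "race": race,
                }
            )
    return pd.DataFrame(rows)


class TestFitWithinModel:
    def test_exact_linear_data_recovers_slope(self, rng):
        table = _mixed_table(rng, beta_pc=0.01, noise=0.0)
        fit = fit_within_model(table, "log_sdnn")
        eff = fit.effect("log_sdnn_pc")
        assert eff["beta"] == pytest.approx(0.01, abs=1e-6)
        assert eff["p"] < 0.05

    def test_noisy_data_recovers_slope(self, rng):
        table = _mixed_table(rng, n_subjects=80, beta_pc=0.01, noise=0.005)
        fit = fit_within_model(table, "log_sdnn")
        eff = fit.effect("log_sdnn_pc")
        assert eff["beta"] == pytest.approx(0.01, rel=0.3)

    def test_too_few_subjects_rejected(self, rng):
        table = _mixed_table(rng, n_subjects=5)
        with pytest.raises(ValueError, match="subjects"):
            fit_within_model(table, "log_sdnn")

    def test_missing_centered_columns_rejected(self, rng):
        table = _mixed_table(rng).drop(columns=["log_sdnn_pc"])
        with pytest.raises(ValueError, match="person_center"):
            fit_within_model(table, "log_sdnn")

    def test_null_t_statistics_calibrated(self):
        """Fixed-effect t under a null coupling has empirical SD near 1."""
        ts = []
        for sim in range(200):
            r = np.random.default_rng(3000 + sim)
            table = _mixed_table(r, n_subjects=40, beta_pc=0.0, noise=0.02)
            fit = fit_within_model(table, "log_sdnn")
            ts.append(fit.effect("log_sdnn_pc")["t"])
        assert 0.8 <= np.std(ts) <= 1.25
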