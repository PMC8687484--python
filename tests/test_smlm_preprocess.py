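"""Localization I/O, quality filtering, channel registration, drift."""

import numpy as np
import pandas as pd
import pytest

from perisynmap.smlm_preprocess import (
    apply_calibration,
    drift_correct,
    filter_localizations,
    fit_channel_calibration,
    read_localizations,
    write_localizations,
)
from perisynmap.synthetic_scenes import gen_bead_field, gen_drift_series


def make_table(**cols):
    base = {
        "frame": [0, 1, 2],
        "x_nm": [100.0, 200.0, 300.0],
        "y_nm": [50.0, 60.0, 70.0],
        "sigma_nm": [150.0, 150.0, 150.0],
        "uncertainty_nm": [10.0, 10.0, 10.0],
        "photons": [1000.0, 1000.0, 1000.0],
        "channel": ["CF568"] * 3,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestLocalizationIO:
    def test_round_trip_identity(self, tmp_path):
        table = make_table(x_nm=[100.123456789, 2.5e4, 1 / 3])
        p = tmp_path / "locs.csv"
        write_localizations(table, p)
        back = read_localizations(p)
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_round_trips(self, tmp_path):
        table = make_table().iloc[:0]
        p = tmp_path / "empty.csv"
        write_localizations(table, p)
        back = read_localizations(p)
        assert len(back) == 0
        assert list(back.columns) == list(table.columns)

    def test_thunderstorm_dialect_parses_to_same_table(self, tmp_path):
        a = tmp_path / "plain.csv"
        b = tmp_path / "ts.csv"
        a.write_text("frame,x,y,uncertainty\n1,100.5,200.5,12.0\n")
        b.write_text('frame,"x [nm]","y [nm]","uncertainty [nm]"\n1,100.5,200.5,12.0\n')
        ta, tb = read_localizations(a), read_localizations(b)
        pd.testing.assert_frame_equal(ta, tb)
        assert list(ta.columns) == ["frame", "x_nm", "y_nm", "uncertainty_nm"]

    def test_missing_columns_error_lists_headers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,intensity\n1,5\n")
        with pytest.raises(ValueError, match="x_nm"):
            read_localizations(p)


class TestFilterLocalizations:
    def test_high_uncertainty_removed(self):
        table = make_table(uncertainty_nm=[25.0, 19.9, 20.0])
        out = filter_localizations(table)
        assert list(out["uncertainty_nm"]) == [19.9]

    def test_sigma_window_per_channel(self):
        table = make_table(
            sigma_nm=[150.0, 95.0, 210.0],
            channel=["CF568", "AF647", "CF568"],
        )
        out = filter_localizations(
            table, sigma_range={"CF568": (100, 200), "AF647": (90, 190)}
        )
        # CF568 sigma 150 kept; AF647 sigma 95 kept; CF568 sigma 210 dropped
        assert list(out["sigma_nm"]) == [150.0, 95.0]

    def test_empty_table_passes_through(self):
        out = filter_localizations(make_table().iloc[:0])
        assert len(out) == 0

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        table = make_table(
            uncertainty_nm=rng.uniform(5, 30, 3), sigma_nm=rng.uniform(80, 220, 3)
        )
        once = filter_localizations(table, sigma_range={"CF568": (100, 200)})
        twice = filter_localizations(once, sigma_range={"CF568": (100, 200)})
        assert len(once) <= len(table)
        pd.testing.assert_frame_equal(once, twice)

    def test_unlisted_channel_errors(self):
        with pytest.raises(ValueError, match="CF568"):
            filter_localizations(make_table(), sigma_range={"AF647": (90, 190)})


class TestChannelCalibration:
    def test_identical_points_give_zero_model(self):
        pts = np.random.default_rng(1).uniform(0, 1e4, (20, 2))
        cal = fit_channel_calibration(pts, pts)
        assert cal.control_rms == 0.0
        assert np.allclose(cal.predict(pts), 0.0, atol=1e-9)

    def test_pure_translation_recovered_exactly(self):
        pts = np.random.default_rng(2).uniform(0, 1e4, (30, 2))
        shifted = pts + np.array([50.0, -30.0])
        cal = fit_channel_calibration(shifted, pts, degree=2)
        disp = cal.predict(np.array([[123.0, 456.0], [9e3, 2e3]]))
        assert np.allclose(disp, [50.0, -30.0], atol=1e-9)
        assert cal.control_rms < 1e-9

    def test_quadratic_distortion_exact_in_model_class(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 2.5e4, (60, 2))
        u, v = pts[:, 0] / 1e4, pts[:, 1] / 1e4
        disp = np.column_stack(
            [5 + 2 * u - 3 * v + 0.7 * u * v + 0.2 * u**2, -4 + v**2 - u]
        )
        cal = fit_channel_calibration(pts + disp, pts, degree=2)
        assert cal.control_rms < 1e-8
        probe = rng.uniform(0, 2.5e4, (10, 2))
        pu, pv = probe[:, 0] / 1e4, probe[:, 1] / 1e4
        want = np.column_stack(
            [5 + 2 * pu - 3 * pv + 0.7 * pu * pv + 0.2 * pu**2, -4 + pv**2 - pu]
        )
        assert np.allclose(cal.predict(probe), want, atol=1e-6)

    def test_under_determined_fit_raises(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="at least 6"):
            fit_channel_calibration(pts, pts, degree=2)

    def test_apply_then_invert_translation_is_identity(self):
        table = make_table()
        pts = table[["x_nm", "y_nm"]].to_numpy()
        fwd = fit_channel_calibration(pts + [50.0, -30.0], pts, degree=0)
        shifted = apply_calibration(table, fwd)
        back_cal = fit_channel_calibration(
            pts, shifted[["x_nm", "y_nm"]].to_numpy(), degree=0
        )
        back = apply_calibration(shifted, back_cal)
        assert np.allclose(back[["x_nm", "y_nm"]], table[["x_nm", "y_nm"]], atol=1e-9)

    def test_held_out_rms_under_15nm_with_realistic_distortion(self):
        """Smooth <=100 nm distortion + 5 nm noise: corrected held-out RMS < 15 nm."""
        ref, mov, _ = gen_bead_field(
            n_beads=200, distortion_amplitude=100.0, noise_sd=5.0, seed=4
        )
        rp = ref[["x_nm", "y_nm"]].to_numpy()
        mp = mov[["x_nm", "y_nm"]].to_numpy()
        idx = np.random.default_rng(5).permutation(len(rp))
        tr, te = idx[:100], idx[100:]
        cal = fit_channel_calibration(rp[tr], mp[tr], degree=2)
        resid = rp[te] - (mp[te] + cal.predict(mp[te]))
        rms = np.sqrt((resid**2).sum(axis=1).mean())
        assert rms < 15.0

    def test_locally_weighted_mode_interpolates_displacements(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        disp = np.array([[10.0, 0.0]] * 4)
        cal = fit_channel_calibration(pts + disp, pts, model_kind="locally_weighted", bandwidth=50.0)
        assert np.allclose(cal.predict([[50.0, 50.0]]), [[10.0, 0.0]], atol=1e-9)

    def test_registration_composes_to_identity(self):
        """A->B then B->A displacement fields cancel within 2x control RMS."""
        ref, mov, _ = gen_bead_field(n_beads=120, noise_sd=3.0, seed=6)
        rp = ref[["x_nm", "y_nm"]].to_numpy()
        mp = mov[["x_nm", "y_nm"]].to_numpy()
        ab = fit_channel_calibration(rp, mp)
        ba = fit_channel_calibration(mp, rp)
        probe = np.random.default_rng(7).uniform(2e3, 2.3e4, (50, 2))
        roundtrip = probe + ab.predict(probe)
        roundtrip = roundtrip + ba.predict(roundtrip)
        err = np.sqrt(((roundtrip - probe) ** 2).sum(axis=1))
        assert err.max() <= 2 * max(ab.control_rms, ba.control_rms)


class TestDriftCorrect:
    def test_stationary_emitters_give_null_drift(self):
        table, _ = gen_drift_series(
            n_frames=1200, magnitude=0.0, loc_precision=8.0, seed=8
        )
        _, trace = drift_correct(table)
        assert np.abs(trace.segment_displacement).max() <= 10.0

    def test_linear_drift_recovered_within_bin(self):
        table, truth = gen_drift_series(
            n_frames=2000, drift_model="linear", magnitude=100.0,
            loc_precision=10.0, seed=9,
        )
        _, trace = drift_correct(table)
        true_seg = np.array(
            [truth.drift_trace[int(c)] for c in trace.segment_centers]
        )
        true_seg = true_seg - true_seg[0]
        assert np.abs(trace.segment_displacement - true_seg).max() <= 10.0

    def test_correction_restores_emitter_spread_to_precision(self):
        """After correction one emitter's spread is ~precision, not precision+drift."""
        emitters = np.array([[1000.0, 1000.0]])
        table, _ = gen_drift_series(
            n_frames=2000, emitters=emitters, drift_model="linear",
            magnitude=150.0, loc_precision=10.0, seed=10,
        )
        corrected, _ = drift_correct(table)
        raw_sd = table[["x_nm", "y_nm"]].to_numpy().std(axis=0).max()
        corr_sd = corrected[["x_nm", "y_nm"]].to_numpy().std(axis=0).max()
        assert raw_sd > 25.0  # drift dominates before correction
        assert corr_sd < 14.0  # close to the 10 nm localization precision

    def test_offset_equivariance(self):
        """Shifting all frames by a constant changes recovered drift by <= bin."""
        table, _ = gen_drift_series(n_frames=1200, magnitude=80.0, seed=11)
        _, t1 = drift_correct(table)
        shifted = table.copy()
        shifted["x_nm"] += 500.0
        _, t2 = drift_correct(shifted)
        assert np.abs(t1.segment_displacement - t2.segment_displacement).max() <= 10.0

    def test_too_few_segments_raises(self):
        table, _ = gen_drift_series(n_frames=600, magnitude=0.0, seed=12)
        with pytest.raises(ValueError, match="segments"):
            drift_correct(table, segment_len=500)

    def test_step_drift_truth_piecewise_constant(self):
        _, truth = gen_drift_series(
            n_frames=100, drift_model="step", magnitude=50.0, seed=13
        )
        jumps = np.abs(np.diff(truth.drift_trace, axis=0)).sum(axis=1)
        assert (jumps > 0).sum() == 1
        assert np.isclose(np.linalg.norm(truth.drift_trace[-1]), 50.0)
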