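"""Windowing and the 12 features, checked against naive loop oracles."""

import math
import warnings

import numpy as np
import pytest
from scipy.signal import hilbert

import sarcoemg.features as ft
from sarcoemg import (FeatureParams, WindowPlan, build_feature_matrix,
                      segment_windows)
from sarcoemg.core_io import ValidationError

FS = 1000.0


# ---------------------------------------------------------------------------
# independent naive oracles (plain Python loops over the stated formulas)
# ---------------------------------------------------------------------------

def naive_features(x, thr):
    n = len(x)
    iemg = sum(abs(v) for v in x)
    mav = iemg / n
    mav1 = sum((1.0 if 0.25 * n <= i <= 0.75 * n else 0.5) * abs(x[i - 1])
               for i in range(1, n + 1)) / n
    mav2 = 0.0
    for i in range(1, n + 1):
        if i < 0.25 * n:
            k = 4.0 * i / n
        elif i <= 0.75 * n:
            k = 1.0
        else:
            k = 4.0 * (n - i) / n
        mav2 += k * abs(x[i - 1])
    mav2 /= n
    ssi = sum(v * v for v in x)
    rms = math.sqrt(ssi / n)
    var = ssi / (n - 1)
    aac = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    zc = sum(1 for i in range(n - 1)
             if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= thr)
    ssc = sum(1 for i in range(1, n - 1)
              if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= thr)
    wamp = sum(1 for i in range(n - 1) if abs(x[i] - x[i + 1]) >= thr)
    return {"IEMG": iemg, "MAV": mav, "MAV1": mav1, "MAV2": mav2, "RMS": rms,
            "VAR": var, "AAC": aac, "ZC": zc, "SSI": ssi, "SSC": ssc,
            "WAMP": wamp}


def naive_aif(x, fs):
    phase = np.unwrap(np.angle(hilbert(x)))
    freqs = [(phase[i + 1] - phase[i]) * fs / (2 * math.pi)
             for i in range(len(x) - 1)]
    return min(max(sum(freqs) / len(freqs), 0.0), fs / 2)


class TestWindowing:
    @pytest.mark.parametrize("length,expected", [
        (1000, 17),   # floor((1000-200)/50)+1
        (200, 1),
        (249, 1),     # trailing partial discarded
        (250, 2),
    ])
    def test_window_count(self, length, expected):
        plan = WindowPlan(200.0, 50.0, FS)
        assert segment_windows(np.zeros(length), plan).shape == (expected, 200)

    def test_shorter_than_one_window_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            segment_windows(np.zeros(199), WindowPlan(200.0, 50.0, FS))

    def test_window_offsets(self, rng):
        x = rng.normal(size=500)
        w = segment_windows(x, WindowPlan(200.0, 50.0, FS))
        np.testing.assert_array_equal(w[2], x[100:300])


class TestClosedForms:
    def test_constant_window(self):
        x = np.full(200, 0.5)
        got = ft.compute_window_features(x, FS, thr=0.1)
        assert got["IEMG"] == pytest.approx(100.0)
        assert got["MAV"] == pytest.approx(0.5)
        assert got["RMS"] == pytest.approx(0.5)
        assert got["SSI"] == pytest.approx(50.0)
        assert got["VAR"] == pytest.approx(50.0 / 199)
        assert got["AAC"] == 0 and got["ZC"] == 0
        assert got["SSC"] == 0 and got["WAMP"] == 0

    def test_unit_sinusoid_rms(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 50.0 * t)   # 50 integer periods
        assert ft.feature_RMS(x) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_alternating_signal_counts(self):
        n = 200
        x = 0.2 * (-1.0) ** np.arange(n)
        p = FeatureParams(thr=0.1)
        assert ft.feature_WAMP(x, p) == n - 1
        assert ft.feature_ZC(x, p) == n - 1

    def test_mav1_constant_matches_brute_force(self):
        c, n = 0.7, 200
        x = np.full(n, c)
        expected = naive_features(list(x), 0.1)["MAV1"]
        assert ft.feature_MAV1(x) == pytest.approx(expected, rel=1e-12)
        # closed form: half weight on the outer halves of the window
        k_sum = sum(1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
                    for i in range(1, n + 1))
        assert ft.feature_MAV1(x) == pytest.approx(c * k_sum / n)


class TestOracleAgreement:
    def test_all_features_match_naive_loops(self, rng):
        """100 random windows: vectorised features equal the loop oracle to
        1e-9 relative."""
        for _ in range(100):
            n = int(rng.integers(20, 300))
            x = rng.normal(scale=rng.uniform(0.05, 2.0), size=n)
            thr = float(rng.uniform(0.0, 0.3))
            expected = naive_features(list(x), thr)
            got = ft.compute_window_features(x, FS, thr=thr,
                                             features=list(expected))
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name

    def test_aif_matches_loop(self, rng):
        x = rng.normal(size=256)
        assert ft.feature_AIF(x, FS) == pytest.approx(naive_aif(x, FS), rel=1e-9)


class TestInvariants:
    def test_scale_identities(self, rng):
        x = rng.normal(size=200)
        n = len(x)
        assert ft.feature_SSI(x) == pytest.approx(n * ft.feature_RMS(x) ** 2,
                                                  rel=1e-9)
        assert ft.feature_VAR(x) == pytest.approx(ft.feature_SSI(x) / (n - 1),
                                                  rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.0])
    def test_homogeneity(self, rng, c):
        x = rng.normal(size=150)
        thr = 0.1
        p, pc = FeatureParams(thr=thr), FeatureParams(thr=c * thr)
        for f in (ft.feature_IEMG, ft.feature_MAV, ft.feature_MAV1,
                  ft.feature_MAV2, ft.feature_RMS, ft.feature_AAC):
            assert f(c * x) == pytest.approx(c * f(x), rel=1e-9)
        for f in (ft.feature_SSI, ft.feature_VAR):
            assert f(c * x) == pytest.approx(c ** 2 * f(x), rel=1e-9)
        for f in (ft.feature_ZC, ft.feature_WAMP):
            assert f(c * x, pc) == f(x, p)
        # SSC thresholds a product of two differences, so it is invariant
        # when thr scales with c^2
        assert ft.feature_SSC(c * x, FeatureParams(thr=c ** 2 * thr)) == \
            ft.feature_SSC(x, p)


class TestAif:
    @pytest.mark.parametrize("freq", [50.0, 120.0])
    def test_pure_tone_frequency(self, freq):
        t = np.arange(200) / FS
        x = np.sin(2 * np.pi * freq * t)
        assert ft.feature_AIF(x, FS) == pytest.approx(freq, rel=0.02)

    def test_all_zero_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert ft.feature_AIF(np.zeros(100), FS) == 0.0

    def test_band_noise_centre_ordering(self):
        """AIF separates noise centred at 160 Hz from noise centred at 80 Hz
        in at least 95% of paired windows."""
        from sarcoemg.synthetic import generate_semg_channel
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        hi = generate_semg_channel(10.0, FS, np.ones(10_000), 160.0, 40.0,
                                   1.0, 0.0, rng1)
        lo = generate_semg_channel(10.0, FS, np.ones(10_000), 80.0, 40.0,
                                   1.0, 0.0, rng2)
        plan = WindowPlan(200.0, 50.0, FS)
        a = [ft.feature_AIF(w, FS) for w in segment_windows(hi, plan)]
        b = [ft.feature_AIF(w, FS) for w in segment_windows(lo, plan)]
        assert np.mean(np.array(a) > np.array(b)) >= 0.95


class TestFeatureMatrix:
    def test_cohort_matrix_is_32_by_48(self, feature_matrix):
        assert feature_matrix.data.shape == (32, 48)
        assert feature_matrix.class_counts() == {1: 3, 2: 22, 3: 7}

    def test_column_order_is_channel_major(self, feature_matrix):
        cols = feature_matrix.columns
        assert cols[0] == "GL_left:IEMG"
        assert cols[11] == "GL_left:AIF"
        assert cols[12] == "GL_right:IEMG"
        assert len(cols) == 48

    def test_per_window_instances(self, cohort, config):
        from sarcoemg import extract_cohort_features
        import dataclasses
        cfg = dataclasses.replace(config, aggregate="per_window")
        fm = extract_cohort_features([cohort[0]], cfg)
        # 4 s segment minus 2x0.25 s trim: floor((3500-200)/50)+1 windows
        assert fm.data.shape == (67, 48)

    def test_restricted_feature_list(self, cohort, config):
        from sarcoemg import extract_cohort_features
        import dataclasses
        cfg = dataclasses.replace(config, features=("IEMG", "RMS", "AIF"))
        fm = extract_cohort_features([cohort[0]], cfg)
        assert fm.data.shape[1] == 12

    def test_missing_segment_names_subject(self, cohort):
        rec = cohort[0].recording
        stripped = rec.replace_channels(rec.channels)
        del stripped.segments["sit_to_stand"]
        with pytest.raises(ValidationError, match=stripped.subject_id):
            build_feature_matrix([stripped], [1])
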