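"""ABR/DPOAE feature extraction: detection rule, threshold logic,
P1/N1 features, and DP/noise-floor reads."""

import numpy as np
import pytest

from cochleaquant.audiology import (ABRSeries, ABRTrace, DPOAESpectrum,
                                    abr_features, abr_threshold,
                                    detect_response, dp_extract,
                                    dpoae_threshold, DPResult)
from cochleaquant.synthgen import ABRSimParams, gen_abr_series, gen_dpoae_levels


def make_trace(voltage, fs_khz=16.0, onset=2.0, intensity=60.0):
    v = np.asarray(voltage, dtype=float)
    t = np.arange(v.size) / fs_khz
    return ABRTrace(time_ms=t, voltage_uv=v, frequency=12.0,
                    intensity_db=intensity, onset_ms=onset)


def make_series(detect_plan, fs_khz=16.0):
    """Series whose traces carry a clear artificial peak exactly where
    ``detect_plan[intensity]`` is true."""
    traces = {}
    n = int(12 * fs_khz) + 1
    for inten, has_resp in detect_plan.items():
        v = np.zeros(n)
        v[:int(2 * fs_khz)] = 0.01 * np.sin(np.arange(int(2 * fs_khz)))
        if has_resp:
            i0 = int(3.0 * fs_khz)
            v[i0] = 1.0
            v[i0 + 3] = -1.0
        traces[float(inten)] = make_trace(v, fs_khz=fs_khz, intensity=inten)
    return ABRSeries(frequency=12.0, traces=traces)


class TestDetectResponse:
    def test_flat_zero_trace_not_detected(self):
        tr = make_trace(np.zeros(200))
        assert not detect_response(tr, (0, 2), (2, 8))

    def test_rule_application(self):
        # baseline SD 0.1, response peak-to-peak 1.0, k=4 -> 1.0 > 0.4
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 0.1, 32), np.zeros(160)])
        v[32:] = 0.0
        v[50], v[55] = 0.5, -0.5
        tr = make_trace(v)
        base_sd = v[:32].std()
        assert detect_response(tr, (0, 2), (2, 8), k=4) == (1.0 > 4 * base_sd)
        assert detect_response(tr, (0, 2), (2, 8), k=4)

    def test_overlapping_windows_rejected(self):
        tr = make_trace(np.zeros(200))
        with pytest.raises(ValueError, match="disjoint"):
            detect_response(tr, (0, 3), (2, 8))

    def test_zero_length_window_rejected(self):
        tr = make_trace(np.zeros(200))
        with pytest.raises(ValueError):
            detect_response(tr, (2, 2), (2, 8))


class TestAbrThreshold:
    GRID = {i: False for i in range(10, 95, 5)}

    def test_threshold_at_first_sustained_detection(self):
        plan = dict(self.GRID)
        for i in range(35, 95, 5):
            plan[i] = True
        res = abr_threshold(make_series(plan))
        assert res.threshold_db == 35.0
        assert not res.censored

    def test_all_undetected_is_censored(self):
        res = abr_threshold(make_series(dict(self.GRID)))
        assert res.censored
        assert res.threshold_db == 95.0  # grid max + step, flagged

    def test_monotone_rule_skips_isolated_detection(self):
        plan = dict(self.GRID)
        plan[40] = True        # isolated false positive
        for i in range(50, 95, 5):
            plan[i] = True
        res = abr_threshold(make_series(plan))
        assert res.threshold_db == 50.0

    def test_missing_intensities_rejected(self):
        plan = {10: False, 20: False, 25: True}  # non-uniform grid
        with pytest.raises(ValueError, match="uniform|missing"):
            abr_threshold(make_series(plan))

    def test_noiseless_synthetic_series_exact(self):
        series, truth = gen_abr_series(ABRSimParams(
            noise_sd_uv=0.0, frequencies=(12.0,), true_threshold_db=35.0))
        res = abr_threshold(series[12.0])
        assert res.threshold_db == truth[12.0]["threshold_db"] == 35.0


class TestAbrFeatures:
    def test_constructed_peak_and_trough(self):
        # peak 1.2 µV at 1.5 ms post-onset, trough -0.8 µV at 2.3 ms
        fs = 20.0
        n = int(12 * fs) + 1
        t = np.arange(n) / fs
        onset = 2.0
        v = (1.2 * np.exp(-((t - onset - 1.5) ** 2) / (2 * 0.2**2))
             - 0.8 * np.exp(-((t - onset - 2.3) ** 2) / (2 * 0.2**2)))
        tr = ABRTrace(time_ms=t, voltage_uv=v, frequency="click",
                      intensity_db=80.0, onset_ms=onset)
        f = abr_features(tr)
        assert f.detected
        assert f.p1_latency_ms == pytest.approx(1.5, abs=0.1)
        assert f.p1n1_delta_uv == pytest.approx(2.0, abs=0.1)

    def test_flat_trace_flagged(self):
        f = abr_features(make_trace(np.zeros(200)))
        assert not f.detected
        assert f.p1_latency_ms is None

    def test_programmed_slopes_recovered(self):
        # latency decreases and P1-N1 grows linearly with intensity; the
        # fitted slopes match the generator's programmed values within 5%
        p = ABRSimParams(noise_sd_uv=0.0, frequencies=(12.0,),
                         true_threshold_db=30.0)
        series, _ = gen_abr_series(p)
        ints = np.arange(40.0, 95.0, 5.0)
        lats, deltas = [], []
        for i in ints:
            f = abr_features(series[12.0].traces[i])
            assert f.detected
            lats.append(f.p1_latency_ms)
            deltas.append(f.p1n1_delta_uv)
        lat_slope = np.polyfit(ints, lats, 1)[0]
        delta_slope = np.polyfit(ints, deltas, 1)[0]
        assert lat_slope == pytest.approx(-p.latency_shift_per_db, rel=0.05)
        assert delta_slope == pytest.approx(p.amplitude_growth_uv_per_db, rel=0.05)

    def test_n1_follows_p1(self):
        series, _ = gen_abr_series(ABRSimParams(
            noise_sd_uv=0.0, frequencies=(12.0,), true_threshold_db=30.0))
        f = abr_features(series[12.0].traces[60.0])
        assert f.p1n1_delta_uv >= 0
        assert f.p1_amplitude_uv > f.n1_amplitude_uv


class TestDpExtract:
    def make_spectrum(self, dp_db=20.0, background=-10.0, f1=10_000.0,
                      f2=12_000.0, level=60.0):
        freqs = np.arange(6000.0, 14000.0, 50.0)
        amp = np.full(freqs.size, background)
        amp[np.argmin(np.abs(freqs - f1))] = 50.0
        amp[np.argmin(np.abs(freqs - f2))] = 50.0
        amp[np.argmin(np.abs(freqs - (2 * f1 - f2)))] = dp_db
        return DPOAESpectrum(frequency_hz=freqs, amplitude_db=amp,
                             f1_hz=f1, f2_hz=f2, level_db=level)

    def test_dp_read_at_2f1_minus_f2(self):
        res = dp_extract(self.make_spectrum())
        assert res.dp_frequency_hz == pytest.approx(8000.0)

    def test_constructed_dp_and_noise(self):
        res = dp_extract(self.make_spectrum(dp_db=20.0, background=-10.0))
        assert res.dp_amplitude_db == pytest.approx(20.0)
        assert res.noise_floor_db == pytest.approx(-10.0)
        assert res.detected

    def test_primary_collision_rejected(self):
        # ratio so close to 2 that 2f1-f2 lands on the f1 bin
        freqs = np.arange(1000.0, 14000.0, 50.0)
        amp = np.full(freqs.size, -10.0)
        sp = DPOAESpectrum(frequency_hz=freqs, amplitude_db=amp,
                           f1_hz=6000.0, f2_hz=6020.0, level_db=60.0)
        with pytest.raises(ValueError, match="collides"):
            dp_extract(sp)

    def test_false_positive_rate_on_pure_noise(self):
        # no DP injected: detection should be rare at the +6 dB criterion
        fp = 0
        nseeds = 200
        for seed in range(nseeds):
            sp = gen_dpoae_levels(12.0, levels=[40.0], true_threshold_db=999.0,
                                  seed=seed)[0]
            fp += dp_extract(sp).detected
        assert fp / nseeds <= 0.05


class TestDpoaeThreshold:
    def test_threshold_recovered_from_synthetic_levels(self):
        sp = gen_dpoae_levels(12.0, true_threshold_db=40.0, seed=5)
        res = dpoae_threshold([dp_extract(s) for s in sp])
        assert res.threshold_db == 40.0
        assert not res.censored

    def test_never_detected_censored(self):
        results = [DPResult(dp_frequency_hz=8000.0, dp_amplitude_db=-10.0,
                            noise_floor_db=-10.0, detected=False,
                            level_db=float(l)) for l in range(20, 85, 5)]
        res = dpoae_threshold(results)
        assert res.censored
        assert res.threshold_db == 85.0

    def test_recovery_within_one_step_many_seeds(self):
        # DP SNR is 15 dB at threshold: recovery within one 5 dB level step
        hits = 0
        for seed in range(50):
            sp = gen_dpoae_levels(12.0, true_threshold_db=40.0, seed=seed)
            res = dpoae_threshold([dp_extract(s) for s in sp])
            hits += abs(res.threshold_db - 40.0) <= 5.0
        assert hits / 50 >= 0.95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dpoae_threshold([])


class TestAveragingContract:
    def test_sweep_averaging_scales_noise_sd(self):
        # baseline-segment SD ratio between 1- and 512-sweep averages
        # approaches 1/sqrt(512) over many traces
        sds = {}
        for nsw in (1, 512):
            vals = []
            for seed in range(100):
                s, _ = gen_abr_series(ABRSimParams(
                    frequencies=(12.0,), intensities_db=(10, 15),
                    true_threshold_db=90.0, n_sweeps=nsw, seed=seed))
                tr = s[12.0].traces[10.0]
                vals.append(tr.voltage_uv[tr.time_ms < tr.onset_ms].std())
            sds[nsw] = np.mean(vals)
        ratio = sds[512] / sds[1]
        assert ratio == pytest.approx(1 / np.sqrt(512), rel=0.2)

    def test_censored_truth_above_grid(self):
        with pytest.warns(UserWarning, match="censored"):
            _, truth = gen_abr_series(ABRSimParams(
                frequencies=(12.0,), true_threshold_db=95.0))
        assert truth[12.0]["censored"]
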