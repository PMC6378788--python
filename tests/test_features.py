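"""The 11-feature profile and the spatiotemporal index (STI)."""

import math

import numpy as np
import pytest

from nnskit import discrimination as dsc
from nnskit import features as ft
from nnskit import preprocess
from nnskit.discrimination import AnalysisConfig, Burst, PeakClass, PeakEvent
from nnskit.features import STI_RECORD_LENGTH, STI_SD_INTERVAL
from nnskit.preprocess import ProcessedSignal
from nnskit.synthgen import DriftSpec, SynthConfig, generate_assessment

from conftest import pulse_signal


def _peak(t, klass=PeakClass.NNS, amp=8.0, width=250.0):
    return PeakEvent(t, amp, width, t - 0.125, t + 0.125, klass)


def _burst(times, index=0):
    return Burst(peaks=[_peak(t) for t in times], index=index)


def sti_oracle(segments):
    """Independent loop-based STI: explicit z-scoring and SD summation."""
    z = []
    for seg in segments:
        mean = sum(seg) / len(seg)
        var = sum((v - mean) ** 2 for v in seg) / len(seg)
        sd = math.sqrt(var) if var > 0 else 1.0
        z.append([(v - mean) / sd for v in seg])
    total = 0.0
    for i in range(0, STI_RECORD_LENGTH, STI_SD_INTERVAL):
        vals = [zi[i] for zi in z]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        total += math.sqrt(var)
    return total


class TestComputeFeatures:
    def test_rates_and_ratio_arithmetic(self, analysis_cfg):
        # 10 NNS + 2 non-NNS in 2 min: 5/min, 6/min total, 83.33%
        sig = ProcessedSignal.from_pressure(np.zeros(12000), 100.0,
                                            assume_corrected=True)
        peaks = ([_peak(5.0 + i) for i in range(10)] +
                 [_peak(40.0 + 5 * i, PeakClass.NON_NNS, width=900.0)
                  for i in range(2)])
        fv = ft.compute_features(sig, peaks, [], analysis_cfg, (0.0, 120.0))
        assert fv.nns_cycles_per_min == pytest.approx(5.0)
        assert fv.total_compressions_per_min == pytest.approx(6.0)
        assert fv.nns_ratio_pct == pytest.approx(100 * 10 / 12)

    def test_no_peaks_degenerate(self, analysis_cfg):
        sig = ProcessedSignal.from_pressure(np.zeros(12000), 100.0,
                                            assume_corrected=True)
        fv = ft.compute_features(sig, [], [], analysis_cfg, (0.0, 120.0))
        assert fv.n_nns_cycles == 0
        assert fv.nns_cycles_per_min == 0.0
        assert fv.nns_ratio_pct is None
        assert fv.mean_nns_amplitude is None
        assert fv.sti is None

    def test_burst_statistics(self, analysis_cfg):
        sig = ProcessedSignal.from_pressure(np.zeros(12000), 100.0,
                                            assume_corrected=True)
        bursts = [_burst(np.arange(5) * 0.5, 0),
                  _burst(10 + np.arange(3) * 0.5, 1)]
        peaks = [p for b in bursts for p in b.peaks]
        fv = ft.compute_features(sig, peaks, bursts, analysis_cfg, (0.0, 120.0))
        assert fv.mean_cycles_per_burst == pytest.approx(4.0)
        assert fv.max_cycles_per_burst == 5
        assert fv.n_bursts == 2

    def test_ratio_complement_sums_to_100(self, analysis_cfg):
        sig = ProcessedSignal.from_pressure(np.zeros(12000), 100.0,
                                            assume_corrected=True)
        peaks = ([_peak(float(i)) for i in range(7)] +
                 [_peak(50.0 + i, PeakClass.NON_NNS, width=900.0)
                  for i in range(3)])
        fv = ft.compute_features(sig, peaks, [], analysis_cfg, (0.0, 120.0))
        non_ratio = 100.0 * fv.n_non_nns_events / (fv.n_nns_cycles +
                                                   fv.n_non_nns_events)
        assert fv.nns_ratio_pct + non_ratio == pytest.approx(100.0, abs=1e-12)

    def test_zero_length_window_rejected(self, analysis_cfg):
        sig = ProcessedSignal.from_pressure(np.zeros(100), 100.0,
                                            assume_corrected=True)
        with pytest.raises(ValueError):
            ft.compute_features(sig, [], [], analysis_cfg, (5.0, 5.0))


class TestSelectStiBursts:
    def test_filter_then_take_first(self, analysis_cfg):
        sizes = [6, 4, 7, 5, 5, 9, 8]
        bursts = [_burst(10 * i + np.arange(n) * 0.5, i)
                  for i, n in enumerate(sizes)]
        chosen = ft.select_sti_bursts(bursts, analysis_cfg)
        assert [b.index for b in chosen] == [0, 2, 3, 4, 5]

    def test_insufficient_bursts(self, analysis_cfg):
        bursts = [_burst(np.arange(2) * 0.5, i) for i in range(6)]
        assert ft.select_sti_bursts(bursts, analysis_cfg) == []

    def test_exactly_n_qualifying(self, analysis_cfg):
        bursts = [_burst(10 * i + np.arange(5) * 0.5, i) for i in range(5)]
        assert len(ft.select_sti_bursts(bursts, analysis_cfg)) == 5


class TestComputeSti:
    def _bursts_signal(self, jitter=0.0, seed=0, n_bursts=5):
        """A signal of n identical (or jittered) 5-cycle bursts."""
        rng = np.random.default_rng(seed)
        events, bursts = [], []
        t0 = 2.0
        for b in range(n_bursts):
            times = [t0 + i * 0.5 + (rng.uniform(-jitter, jitter) if i else 0.0)
                     for i in range(5)]
            events += [(t, 8.0, 0.25) for t in times]
            bursts.append(_burst(times, b))
            t0 = times[-1] + 3.0
        sig = pulse_signal(events, duration_s=t0 + 2.0)
        return sig, bursts

    def test_identical_bursts_give_zero(self, analysis_cfg):
        sig, bursts = self._bursts_signal(jitter=0.0)
        res = ft.compute_sti(bursts, sig, analysis_cfg)
        assert res.sti == pytest.approx(0.0, abs=1e-9)
        assert res.n_bursts_used == 5

    def test_normalized_segments_are_z_scores(self, analysis_cfg):
        sig, bursts = self._bursts_signal(jitter=0.02, seed=3)
        res = ft.compute_sti(bursts, sig, analysis_cfg)
        assert res.normalized_segments.shape == (5, STI_RECORD_LENGTH)
        np.testing.assert_allclose(res.normalized_segments.mean(axis=1), 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(res.normalized_segments.std(axis=1), 1.0,
                                   atol=1e-9)
        assert res.sti == pytest.approx(res.sd_profile.sum())

    def test_two_segment_closed_form(self, analysis_cfg):
        # sd over {z0, z1} with the n-1 denominator is |z0 - z1| / sqrt(2),
        # i.e. sqrt(2)|z| when the segments are z-score negatives
        sig, bursts = self._bursts_signal(jitter=0.05, seed=1, n_bursts=2)
        res = ft.compute_sti(bursts, sig, analysis_cfg)
        z = res.normalized_segments
        grid = np.arange(0, STI_RECORD_LENGTH, STI_SD_INTERVAL)
        expected = np.abs(z[0, grid] - z[1, grid]) / np.sqrt(2.0)
        np.testing.assert_allclose(res.sd_profile, expected, atol=1e-12)
        neg = np.vstack([z[0], -z[0]])
        profile = neg[:, grid].std(axis=0, ddof=1)
        np.testing.assert_allclose(profile, np.sqrt(2.0) * np.abs(z[0, grid]),
                                   atol=1e-12)

    def test_matches_loop_oracle(self, analysis_cfg):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            segments = rng.normal(size=(n, STI_RECORD_LENGTH))
            mean = segments.mean(axis=1, keepdims=True)
            sd = segments.std(axis=1, keepdims=True)
            z = (segments - mean) / sd
            grid = np.arange(0, STI_RECORD_LENGTH, STI_SD_INTERVAL)
            sti = float(z[:, grid].std(axis=0, ddof=1).sum())
            assert sti == pytest.approx(sti_oracle(segments.tolist()),
                                        abs=1e-9)

    def test_insufficiency_flag(self, analysis_cfg):
        sig, bursts = self._bursts_signal(n_bursts=2)
        res = ft.compute_sti(bursts[:1], sig, analysis_cfg)
        assert res.insufficient
        assert res.sti is None

    def test_scale_and_dilation_invariance(self, analysis_cfg):
        sig, bursts = self._bursts_signal(jitter=0.03, seed=5)
        base = ft.compute_sti(bursts, sig, analysis_cfg).sti
        scaled = ProcessedSignal(pressure=sig.pressure * 7.5,
                                 sample_rate_hz=sig.sample_rate_hz,
                                 provenance=sig.provenance)
        assert ft.compute_sti(bursts, scaled, analysis_cfg).sti == \
            pytest.approx(base, abs=1e-6)

    def test_sti_increases_with_timing_jitter(self, analysis_cfg):
        # controlled perturbation: more cycle-timing jitter, higher STI
        means = []
        for jitter in (0.0, 0.03, 0.08):
            vals = [ft.compute_sti(*reversed(self._bursts_signal(jitter, s)),
                                   analysis_cfg).sti for s in range(8)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestFullRecordSti:
    def test_sti_from_pipeline_is_finite_and_reported(self, clean_record,
                                                      analysis_cfg):
        from nnskit import pipeline

        raw, _ = clean_record
        res = pipeline.analyze_assessment(raw)
        assert res.sti.sti is not None
        assert res.features.sti == res.sti.sti
        assert res.sti.n_bursts_used >= 2


class TestFeatureTrajectory:
    def _fv(self, pma, value):
        return ft.FeatureVector(
            n_nns_cycles=int(value), nns_cycles_per_min=value / 2.0,
            n_non_nns_events=1, total_compressions_per_min=value / 2.0 + 0.5,
            nns_ratio_pct=90.0, n_bursts=5, bursts_per_min=2.5,
            mean_cycles_per_burst=6.0, max_cycles_per_burst=9,
            mean_nns_amplitude=8.0, sti=50.0, window=(0.0, 120.0),
            pma_days=pma)

    def test_linear_trend_has_unit_correlation(self):
        fvs = [self._fv(200 + 5 * i, 10.0 + 2 * i) for i in range(6)]
        table, summary = ft.feature_trajectory(fvs)
        row = summary[summary.feature == "n_nns_cycles"].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.slope == pytest.approx(0.4)

    def test_constant_feature_zero_slope(self):
        fvs = [self._fv(200 + i, 10.0) for i in range(4)]
        _, summary = ft.feature_trajectory(fvs)
        assert (summary[summary.feature == "sti"].slope == 0).all()

    def test_input_order_invariance(self):
        fvs = [self._fv(200 + 5 * i, 10.0 + i) for i in range(5)]
        t1, _ = ft.feature_trajectory(fvs)
        t2, _ = ft.feature_trajectory(list(reversed(fvs)))
        assert t1.equals(t2)

    def test_requires_two_sessions(self):
        with pytest.raises(ValueError):
            ft.feature_trajectory([self._fv(200, 10.0)])
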