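import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meadev as md
from meadev.bursts import BurstConfig, poisson_surprise
from oracles import poisson_tail


class TestMaxIntervalDetection:
    def test_single_burst(self):
        bursts = md.detect_bursts_max_interval(np.array([0.0, 0.05, 0.10, 1.0]))
        assert len(bursts) == 1
        b = bursts[0]
        assert b.n_spikes == 3 and b.t_start == 0.0 and b.t_end == pytest.approx(0.10)

    def test_no_burst_when_isis_large(self):
        assert md.detect_bursts_max_interval(np.array([0.0, 0.5, 1.0, 1.5])) == []

    def test_merge_rule(self):
        t = np.array([0.0, 0.05, 0.10, 0.25, 0.30, 0.35])
        bursts = md.detect_bursts_max_interval(t)
        assert len(bursts) == 1 and bursts[0].n_spikes == 6

    def test_min_spikes_filter(self):
        # 2-spike candidate is discarded
        assert md.detect_bursts_max_interval(np.array([0.0, 0.05, 1.0])) == []

    def test_translation_invariance(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        base = md.detect_bursts_max_interval(t)
        shifted = md.detect_bursts_max_interval(t + 17.0)
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert b.t_start == pytest.approx(a.t_start + 17.0)
            assert b.n_spikes == a.n_spikes

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_burst_invariants_fuzz(self, seed):
        """Every detected burst honors min-spikes, min-duration and max-ISI."""
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 400))
        t = np.unique(np.round(np.sort(r.uniform(0, 60, n)), 5))
        cfg = BurstConfig()
        for b in md.detect_bursts_max_interval(t, cfg):
            assert b.n_spikes >= cfg.min_spikes
            assert b.duration >= cfg.min_burst_dur_s
            assert np.all(np.diff(b.spike_times) <= cfg.max_end_isi_s + 1e-12)


class TestSpikeFeatures:
    def test_single_channel_rate(self):
        rec = md.Recording("A", 7, 300.0, {1: np.linspace(0.05, 299.5, 300)})
        assert md.spike_features(rec)["mfr"] == pytest.approx(1.0)

    def test_mfr_is_channel_mean(self):
        rec = md.Recording(
            "A", 7, 300.0,
            {1: np.linspace(0.05, 299.5, 300), 2: np.linspace(0.05, 299.9, 900)},
        )
        assert md.spike_features(rec)["mfr"] == pytest.approx(2.0)

    def test_isi_mean(self):
        rec = md.Recording("A", 7, 300.0, {1: np.array([0.0, 1.0, 3.0])})
        f = md.spike_features(rec, md.QCConfig(min_rate_spikes_per_min=0.1))
        assert f["isi"] == pytest.approx(1.5)

    def test_no_active_channels_flagged(self):
        rec = md.Recording("A", 7, 300.0, {1: np.array([1.0])})
        f = md.spike_features(rec)
        assert f["ch_spikes"] == 0 and f["mfr"] == 0 and math.isnan(f["isi"])


class TestBurstFeatures:
    qc = md.QCConfig(min_rate_spikes_per_min=0.1)

    def _features(self, spikes):
        rec = md.Recording("A", 7, 300.0, spikes)
        bb = {
            ch: md.detect_bursts_max_interval(t, channel=ch)
            for ch, t in rec.spikes.items()
        }
        return md.burst_features(bb, rec, self.qc)

    def test_all_spikes_in_burst(self):
        f = self._features({1: np.array([0.0, 0.05, 0.10])})
        assert f["burst_pct_spikes"] == pytest.approx(100.0)
        assert f["ch_bursts"] == 1

    def test_peak_frequency(self):
        f = self._features({1: np.array([0.0, 0.05, 0.075])})  # ISIs 0.05, 0.025
        assert f["burst_peakfreq"] == pytest.approx(40.0)

    def test_surprise_against_tail_oracle(self):
        """Burst surprise equals -ln P(Poisson(rate*dur) >= n) exactly."""
        rec = md.Recording(
            "A", 7, 300.0,
            {1: np.unique(np.concatenate([
                np.linspace(10.0, 10.2, 10),  # 10 spikes in 0.2 s
                np.linspace(20, 299, 280),
            ]))},
        )
        bb = {1: md.detect_bursts_max_interval(rec.train(1), channel=1)}
        burst = bb[1][0]
        rate = rec.train(1).size / 300.0
        expected = -math.log(poisson_tail(burst.n_spikes, rate * burst.duration))
        f = md.burst_features(bb, rec, self.qc)
        assert f["burst_surprise"] == pytest.approx(expected, rel=1e-9)
        assert f["burst_surprise"] > 20.0

    def test_surprise_monotone_in_spike_count(self):
        s = [poisson_surprise(n, 0.2, 1.0) for n in (5, 10, 20)]
        assert s[0] < s[1] < s[2] and s[0] > 0

    def test_zero_bursts_missing_flagged(self):
        f = self._features({1: np.array([0.0, 10.0, 20.0])})
        assert f["ch_bursts"] == 0 and math.isnan(f["mbr"])


class TestNetworkEvents:
    def test_silent_recording_zero(self):
        rec = md.Recording("A", 7, 300.0, {})
        assert md.network_spike_rate(rec) == 0.0

    def test_single_network_spike(self):
        qc = md.QCConfig(min_rate_spikes_per_min=0.1)
        spikes = {ch: np.array([5.0 + 0.002 * ch]) for ch in range(1, 11)}
        rec = md.Recording("A", 7, 300.0, spikes)
        assert md.network_spike_rate(rec, qc=qc) == pytest.approx(1.0 / 300.0)

    def test_sparse_independent_channels_near_zero(self, rng):
        qc = md.QCConfig(min_rate_spikes_per_min=0.1)
        rates = []
        for _ in range(10):
            spikes = {
                ch: np.sort(rng.uniform(0, 300, rng.poisson(0.2 * 300)))
                for ch in range(1, 11)
            }
            rec = md.Recording("A", 7, 300.0, spikes)
            rates.append(md.network_spike_rate(rec, qc=qc))
        assert np.mean(rates) < 0.02

    def test_single_network_burst(self):
        spikes = {ch: np.arange(10.0, 10.31, 0.05) for ch in range(1, 9)}
        rec = md.Recording("A", 7, 300.0, spikes)
        bb = {ch: md.detect_bursts_max_interval(t, channel=ch) for ch, t in spikes.items()}
        assert md.network_burst_rate(bb, rec) == pytest.approx(0.2)

    def test_two_network_bursts(self):
        ts = np.concatenate([np.arange(10.0, 10.31, 0.05), np.arange(100.0, 100.31, 0.05)])
        spikes = {ch: ts for ch in range(1, 9)}
        rec = md.Recording("A", 7, 300.0, spikes)
        bb = {ch: md.detect_bursts_max_interval(t, channel=ch) for ch, t in spikes.items()}
        assert md.network_burst_rate(bb, rec) == pytest.approx(0.4)

    def test_no_bursts_zero(self):
        rec = md.Recording("A", 7, 300.0, {1: np.array([1.0, 50.0])})
        assert md.network_burst_rate({1: []}, rec) == 0.0
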