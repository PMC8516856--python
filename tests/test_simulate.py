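import numpy as np
import pandas as pd
import pytest

import meadev as md
from meadev.simulate import ArchetypeParams, _archetype_assignment


def flat_params(lam=0.0, nu=0.0, p=0.0, n_act=60, **kw):
    return ArchetypeParams(
        1, lambda_bg=(lam, lam), nu_nb=(nu, nu), p_part=(p, p), n_active=(n_act, n_act), **kw
    )


class TestSimulateRecording:
    def test_no_sources_no_spikes(self):
        rec = md.simulate_recording(flat_params(), 10, seed=0)
        assert rec.n_spikes() == 0

    def test_background_poisson_expectation(self):
        """Pure 1 Hz background x 300 s: per-channel counts average ~300."""
        means = []
        for seed in range(10):
            rec = md.simulate_recording(flat_params(lam=1.0), 10, seed=seed)
            counts = [rec.train(ch).size for ch in range(1, 61)]
            means.append(np.mean(counts))
        assert abs(np.mean(means) - 300.0) / 300.0 < 0.05

    def test_inactive_channels_silent(self):
        rec = md.simulate_recording(flat_params(lam=2.0, n_act=10), 10, seed=1)
        assert all(ch <= 10 for ch in rec.channel_ids)

    def test_network_events_make_synchrony(self):
        """Dense recruitment at 10 events/min gives mean STTC above 0.5."""
        rec = md.simulate_recording(flat_params(lam=0.1, nu=10.0, p=1.0), 10, seed=2)
        _, _, mean_sttc = md.sttc_matrix(rec)
        assert mean_sttc > 0.5

    def test_deterministic_under_seed(self):
        a = md.simulate_recording(flat_params(lam=1.0, nu=5.0, p=0.5), 10, seed=7)
        b = md.simulate_recording(flat_params(lam=1.0, nu=5.0, p=0.5), 10, seed=7)
        assert a.channel_ids == b.channel_ids
        for ch in a.channel_ids:
            np.testing.assert_array_equal(a.train(ch), b.train(ch))

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            ArchetypeParams(1, lambda_bg=(-1, 0), nu_nb=(0, 0), p_part=(0, 0), n_active=(60, 60))
        with pytest.raises(ValueError):
            ArchetypeParams(1, lambda_bg=(0, 0), nu_nb=(0, 0), p_part=(0, 1.5), n_active=(60, 60))
        with pytest.raises(ValueError):
            md.simulate_recording(flat_params(), 10, duration_s=-5.0)

    def test_times_on_sampling_grid(self):
        rec = md.simulate_recording(flat_params(lam=2.0, nu=10.0, p=0.8), 10, seed=3)
        for ch in rec.channel_ids:
            t = rec.train(ch)
            np.testing.assert_allclose(t, np.round(t / 4e-5) * 4e-5, atol=1e-12)
            assert np.all(np.diff(t) > 0)


class TestSimulateCohort:
    def test_bookkeeping(self):
        cfg = md.CohortConfig(n_dishes=60, seed=7, div_schedule=(7, 10, 14))
        recs, truth = md.simulate_cohort(cfg)
        assert len(recs) == 60 * 3
        counts = truth.drop_duplicates("dish")["archetype"].value_counts()
        assert sorted(counts) == [20, 20, 20]

    def test_deterministic(self):
        cfg = md.CohortConfig(n_dishes=4, seed=11, div_schedule=(7, 14))
        r1, t1 = md.simulate_cohort(cfg)
        r2, t2 = md.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        for a, b in zip(r1, r2):
            assert a.dish_id == b.dish_id and a.div == b.div
            for ch in a.channel_ids:
                np.testing.assert_array_equal(a.train(ch), b.train(ch))

    def test_zero_noise_link_exact_function(self):
        cfg = md.CohortConfig(n_dishes=6, seed=3, noise_link=0.0, div_schedule=(7,))
        _, truth = md.simulate_cohort(cfg)
        per_dish = truth.drop_duplicates("dish")
        np.testing.assert_allclose(per_dish["m_late"], per_dish["m_early"])

    def test_assignment_deterministic_and_proportional(self):
        cfg = md.CohortConfig(n_dishes=10, archetype_mix=(0.5, 0.3, 0.2))
        a = _archetype_assignment(cfg)
        assert a == sorted(a) and len(a) == 10
        assert [a.count(i) for i in range(3)] == [5, 3, 2]

    def test_invalid_mix_raises(self):
        with pytest.raises(ValueError):
            md.CohortConfig(archetype_mix=(0.5, 0.2, 0.2))

    def test_write_cohort_round_trip(self, tmp_path):
        cfg = md.CohortConfig(n_dishes=2, seed=5, div_schedule=(7, 14))
        recs, truth = md.simulate_cohort(cfg)
        md.write_cohort(recs, truth, cfg, tmp_path)
        assert (tmp_path / "truth.csv").exists() and (tmp_path / "config.json").exists()
        back = md.io.read_cohort(tmp_path)
        assert len(back) == 4
        assert {r.dish_id for r in back} == {"D001", "D002"}


class TestGroundTruthRecovery:
    def test_mfr_recovers_background_rate(self):
        """Estimated MFR converges to lambda_bg (< 5% error over 10 seeds)."""
        mfrs = [
            md.spike_features(md.simulate_recording(flat_params(lam=1.0), 10, seed=s))["mfr"]
            for s in range(10)
        ]
        assert abs(np.mean(mfrs) - 1.0) < 0.05

    def test_network_burst_rate_recovers_event_rate(self):
        """Network-burst rate within 15% of nu_nb at near-full recruitment."""
        params = flat_params(lam=0.5, nu=10.0, p=0.9)
        rates = []
        for s in range(10):
            rec = md.simulate_recording(params, 10, seed=100 + s)
            rates.append(md.network_burst_rate(md.detect_bursts(rec), rec))
        assert abs(np.mean(rates) - 10.0) / 10.0 < 0.15

    def test_mbr_recovers_event_rate_at_full_recruitment(self):
        params = flat_params(lam=0.5, nu=10.0, p=1.0)
        mbrs = []
        for s in range(10):
            rec = md.simulate_recording(params, 10, seed=200 + s)
            bb = md.detect_bursts(rec)
            bursting = [bs for bs in bb.values() if bs]
            mbrs.append(np.mean([len(bs) / 5.0 for bs in bursting]))
        assert abs(np.mean(mbrs) - 10.0) / 10.0 < 0.15

    def test_mean_sttc_monotone_in_recruitment(self):
        """Cohort-mean STTC is non-decreasing in the recruitment probability."""
        means = []
        for p in (0.2, 0.5, 0.8, 1.0):
            params = flat_params(lam=0.3, nu=10.0, p=p, n_act=20)
            vals = [
                md.sttc_matrix(md.simulate_recording(params, 10, seed=300 + s))[2]
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))
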