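import numpy as np
import pytest
from scipy.signal import periodogram

from myorsa import (ProtocolConfig, reduced_protocol,
                    generate_activation_profile, derive_affected_profile,
                    generate_recording, generate_cohort, save_session,
                    load_session, segment_phases, ActivationProfile)
from myorsa.simulate import build_schedule


def small_profile(cfg, distinctness=0.5, seed=0, **kw):
    return generate_activation_profile(
        len(cfg.movements), cfg.n_channels_unaffected, distinctness, seed,
        band=cfg.band, **kw)


class TestActivationProfile:
    def test_distinctness_zero_identical_rows(self):
        prof = generate_activation_profile(10, 7, 0.0, 3)
        assert np.all(prof.weights == prof.weights[0])
        assert np.all(prof.spectral_centers == prof.spectral_centers[0])

    def test_deterministic_for_seed(self):
        a = generate_activation_profile(10, 7, 0.6, 11)
        b = generate_activation_profile(10, 7, 0.6, 11)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.spectral_centers, b.spectral_centers)

    def test_row_separation_increases_with_distinctness(self):
        def mean_pairwise(d, seed):
            w = generate_activation_profile(10, 7, d, seed).weights
            dists = [np.linalg.norm(w[i] - w[j])
                     for i in range(10) for j in range(i + 1, 10)]
            return np.mean(dists)
        lo = np.mean([mean_pairwise(0.1, s) for s in range(20)])
        hi = np.mean([mean_pairwise(0.9, s) for s in range(20)])
        assert hi > lo

    def test_bounds_and_band(self):
        prof = generate_activation_profile(6, 5, 0.7, 1, band=(20.0, 200.0))
        assert np.all((prof.weights >= 0) & (prof.weights <= 1))
        assert np.all((prof.spectral_centers > 20)
                      & (prof.spectral_centers < 200))

    @pytest.mark.parametrize("bad", [-0.1, 1.5, np.nan])
    def test_invalid_distinctness_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_activation_profile(5, 4, bad, 0)


class TestDerivedProfile:
    def test_identity_case(self):
        prof = generate_activation_profile(5, 4, 0.6, 2)
        assert derive_affected_profile(prof, 1.0, 1.0, 9) is prof

    def test_pure_attenuation_halves_weights(self):
        prof = generate_activation_profile(5, 4, 0.6, 2)
        out = derive_affected_profile(prof, 1.0, 0.5, 9)
        assert np.allclose(out.weights, 0.5 * prof.weights)

    def test_fidelity_zero_decorrelates(self):
        prof = generate_activation_profile(8, 7, 0.9, 2)
        cors = []
        for s in range(50):
            out = derive_affected_profile(prof, 0.0, 1.0, s)
            for i in range(8):
                cors.append(np.corrcoef(prof.weights[i],
                                        out.weights[i])[0, 1])
        assert abs(np.mean(cors)) < 0.1

    def test_fidelity_out_of_range_rejected(self):
        prof = generate_activation_profile(5, 4, 0.6, 2)
        with pytest.raises(ValueError):
            derive_affected_profile(prof, 1.2, 1.0, 0)


class TestRecording:
    def test_trial_sample_arithmetic_at_full_rate(self):
        cfg = ProtocolConfig(movements=("CW",))
        # 5 cycles x (4 s + 3 s) at 6000 Hz per trial
        assert cfg.samples_per_trial == 210_000
        assert cfg.total_samples == 2 * 210_000

    def test_schedule_covers_all_phases_exactly(self, reduced_cfg):
        sched = build_schedule(reduced_cfg)
        assert len(sched) == (len(reduced_cfg.movements)
                              * reduced_cfg.repetitions * 2)
        # intervals tile the recording without gap or overlap
        assert sched["start_sample"].iloc[0] == 0
        assert np.array_equal(sched["start_sample"].to_numpy()[1:],
                              sched["end_sample"].to_numpy()[:-1])
        assert sched["end_sample"].iloc[-1] == reduced_cfg.total_samples

    def test_gain_zero_contraction_matches_relaxation(self):
        cfg = reduced_protocol(n_movements=2)
        prof = small_profile(cfg, gain=0.0, rep_jitter_sd=0.0)
        ratios = []
        for seed in range(10):
            rec = generate_recording(cfg, prof, "unaffected", seed)
            segs = segment_phases(rec, cfg)
            rms = {"contraction": [], "relaxation": []}
            for s in segs:
                rms[s.phase].append(
                    np.sqrt(np.mean(s.channel_data ** 2)))
            ratios.append(np.mean(rms["contraction"])
                          / np.mean(rms["relaxation"]))
        assert 0.95 <= np.mean(ratios) <= 1.05

    def test_contraction_rms_increases_with_weight(self):
        # 3 single-channel movements with weights 0.2 / 0.5 / 0.9
        cfg = reduced_protocol(n_movements=3, n_channels=1,
                               cycles_per_trial=1)
        means = {w: [] for w in (0.2, 0.5, 0.9)}
        for seed in range(50):
            prof = ActivationProfile(
                weights=np.array([[0.2], [0.5], [0.9]]),
                spectral_centers=np.full((3, 1), 100.0),
                band=cfg.band, rep_jitter_sd=0.2)
            rec = generate_recording(cfg, prof, "unaffected", seed)
            segs = segment_phases(rec, cfg)
            acc = {m: [] for m in cfg.movements}
            for s in segs:
                if s.phase == "contraction":
                    acc[s.movement].append(
                        np.sqrt(np.mean(s.channel_data ** 2)))
            for w, mov in zip((0.2, 0.5, 0.9), cfg.movements):
                means[w].append(np.mean(acc[mov]))
        avg = {w: np.mean(v) for w, v in means.items()}
        assert avg[0.2] < avg[0.5] < avg[0.9]

    def test_contraction_power_confined_to_band(self, reduced_cfg):
        lo, hi = reduced_cfg.band
        for seed in range(10):
            prof = small_profile(reduced_cfg, 0.8, seed)
            rec = generate_recording(reduced_cfg, prof, "unaffected", seed)
            seg = next(s for s in segment_phases(rec, reduced_cfg)
                       if s.phase == "contraction")
            f, p = periodogram(seg.channel_data[0],
                               fs=reduced_cfg.sampling_rate)
            inside = p[(f >= lo) & (f <= hi)].sum()
            assert inside / p.sum() >= 0.95

    def test_signal_within_adc_range(self, reduced_cfg):
        prof = small_profile(reduced_cfg, 0.8, 1, gain=400.0)
        rec = generate_recording(reduced_cfg, prof, "unaffected", 1)
        assert np.all(np.abs(rec.signal) <= reduced_cfg.adc_range)
        assert rec.clipped_fraction > 0

    def test_channel_mismatch_rejected(self, reduced_cfg):
        prof = generate_activation_profile(
            len(reduced_cfg.movements), 3, 0.5, 0, band=reduced_cfg.band)
        with pytest.raises(ValueError):
            generate_recording(reduced_cfg, prof, "unaffected", 0)


class TestCohort:
    def test_byte_identical_for_same_seed(self, reduced_cfg):
        a = generate_cohort(reduced_cfg, 0.8, 0.9, 0.8, 5)
        b = generate_cohort(reduced_cfg, 0.8, 0.9, 0.8, 5)
        for x, y in zip(a, b):
            assert np.array_equal(x.signal, y.signal)

    def test_perfect_fidelity_degenerate_copy(self, reduced_cfg):
        rec_u, rec_a = generate_cohort(reduced_cfg, 0.8, 1.0, 1.0, 5)
        assert np.array_equal(rec_u.signal, rec_a.signal)

    def test_limbs_share_schedule(self, reduced_cfg):
        rec_u, rec_a = generate_cohort(reduced_cfg, 0.8, 0.5, 0.8, 5)
        assert rec_u.schedule.equals(rec_a.schedule)

    def test_default_protocol_gives_ten_contraction_reps(self):
        # protocol arithmetic only: 2 trials x 5 cycles
        cfg = ProtocolConfig()
        sched = build_schedule(cfg)
        counts = sched[sched["phase"] == "contraction"].groupby(
            "movement").size()
        assert len(counts) == 10
        assert (counts == 10).all()

    def test_affected_channel_subset(self):
        cfg = reduced_protocol()
        cfg = cfg.with_(n_channels_affected=3)
        rec_u, rec_a = generate_cohort(cfg, 0.8, 0.9, 0.8, 1)
        assert rec_u.n_channels == 4 and rec_a.n_channels == 3


class TestSessionRoundTrip:
    def test_hdf5_round_trip(self, reduced_cfg, tmp_path):
        rec_u, rec_a = generate_cohort(reduced_cfg, 0.8, 0.9, 0.8, 3)
        path = tmp_path / "session.h5"
        save_session(path, reduced_cfg,
                     {"unaffected": rec_u, "affected": rec_a})
        cfg2, recs = load_session(path)
        assert cfg2 == reduced_cfg
        assert np.array_equal(recs["unaffected"].signal, rec_u.signal)
        assert recs["affected"].schedule.equals(rec_a.schedule)
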