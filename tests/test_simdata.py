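"""Synthetic benchmark generator: hypnogram chain, stage acoustics, domains."""

import numpy as np
import pytest
from scipy.signal import butter, find_peaks, sosfiltfilt
from scipy.stats import kurtosis

from sonosleep.simdata import (
    GenConfig,
    build_benchmark,
    default_transition_matrix,
    load_benchmark,
    sample_breath_intervals,
    sample_profile,
    save_benchmark,
    simulate_hypnogram,
    stationary_distribution,
    synth_epoch,
    synth_noise_clip,
)
from sonosleep.hypnogram import STAGES
from sonosleep.sigproc import MelConfig

from util import spectral_peak_hz

SR = 2000


class TestSimulateHypnogram:
    def test_identity_matrix_freezes_stage(self, rng):
        h = simulate_hypnogram(rng, 50, np.eye(5), np.array([1, 0, 0, 0, 0.0]))
        assert all(s == "W" for s in h.stages)

    def test_requested_length(self, rng):
        assert len(simulate_hypnogram(rng, 960)) == 960

    def test_non_stochastic_matrix_rejected(self, rng):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="stochastic"):
            simulate_hypnogram(rng, 10, bad)

    def test_deterministic_under_seed(self):
        a = simulate_hypnogram(np.random.default_rng(3), 200)
        b = simulate_hypnogram(np.random.default_rng(3), 200)
        assert list(a.stages) == list(b.stages)

    def test_frequencies_approach_stationary_distribution(self):
        """Empirical stage frequencies vs the chain's stationary law.

        The oracle is matrix powering (P^k rows converge to the stationary
        distribution), independent of the eigen-solve in the package.
        """
        P = default_transition_matrix()
        Pk = np.linalg.matrix_power(P, 4096)
        pi_oracle = Pk[0]
        h = simulate_hypnogram(np.random.default_rng(11), 30_000)
        idx = h.indices()
        freq = np.bincount(idx, minlength=5) / len(idx)
        assert np.abs(freq - pi_oracle).max() < 0.02
        # and the package's eigen-solve agrees with the powering oracle
        assert np.abs(stationary_distribution(P) - pi_oracle).max() < 1e-9


class TestBreathingModel:
    def test_rem_more_irregular_than_deep_sleep(self, rng):
        cvs = {}
        for stage in ("REM", "N3"):
            vals = []
            for _ in range(200):
                iv = sample_breath_intervals(stage, sample_profile(rng), rng)
                vals.append(iv.std() / iv.mean())
            cvs[stage] = np.mean(vals)
        assert cvs["REM"] > 2 * cvs["N3"]

    def test_wake_has_movement_bursts_deep_sleep_none(self, rng):
        profile = sample_profile(rng)
        w_bursts = sum(
            synth_epoch("W", profile, "source", rng, SR, return_events=True)[1][
                "n_bursts"
            ]
            for _ in range(30)
        )
        n3_bursts = sum(
            synth_epoch("N3", profile, "source", rng, SR, return_events=True)[1][
                "n_bursts"
            ]
            for _ in range(30)
        )
        assert w_bursts > 20
        assert n3_bursts == 0

    def test_epoch_waveform_deterministic(self):
        profile = sample_profile(np.random.default_rng(0))
        a = synth_epoch("N2", profile, "source", np.random.default_rng(5), SR)
        b = synth_epoch("N2", profile, "source", np.random.default_rng(5), SR)
        assert np.array_equal(a.samples, b.samples)

    def test_breathing_rate_bounds_enforced(self):
        with pytest.raises(ValueError, match="physiologic"):
            sample_profile(np.random.default_rng(0)).__class__(breathing_rate=40.0)


class TestNoiseClips:
    def test_hum_concentrates_on_line_spectrum(self, rng):
        clip = synth_noise_clip("hum", np.random.default_rng(2), SR)
        peak = spectral_peak_hz(clip.samples, SR)
        # fundamental is drawn in [50, 120]; the peak must sit on a harmonic
        assert any(
            abs(peak - k * f0) < 3.0
            for f0 in range(50, 121)
            for k in (1, 2, 3, 4, 5)
        )

    def test_transients_heavier_tailed_than_colored_noise(self):
        kt = kurtosis(synth_noise_clip("transient", np.random.default_rng(4), SR).samples)
        kc = kurtosis(synth_noise_clip("colored", np.random.default_rng(4), SR).samples)
        assert kt > kc + 5

    def test_deterministic_under_seed(self):
        a = synth_noise_clip("fan", np.random.default_rng(8), SR)
        b = synth_noise_clip("fan", np.random.default_rng(8), SR)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown noise kind"):
            synth_noise_clip("spaceship", rng, SR)


def oracle_stage3(x: np.ndarray) -> str:
    """3-stage classification from the generator's own waveform features.

    Movement bursts are broadband (high-band energy), breathing is
    band-limited; REM breathing is irregular (high interval CV).
    """
    sos_hi = butter(4, 700.0, btype="high", fs=SR, output="sos")
    sos_env = butter(2, 2.0, btype="low", fs=SR, output="sos")
    hi = sosfiltfilt(sos_hi, x)
    if np.sum(hi**2) / np.sum(x**2) > 0.10:
        return "W"
    env = sosfiltfilt(sos_env, np.abs(x))
    peaks, _ = find_peaks(env, distance=int(1.6 * SR), prominence=0.3 * env.std())
    iv = np.diff(peaks) / SR
    cv = iv.std() / iv.mean() if len(iv) >= 3 else 1.0
    return "REM" if cv > 0.17 else "NREM"


class TestBenchmark:
    def test_label_fidelity_oracle_classifier(self):
        """Clean source epochs are >80% 3-stage classifiable by construction."""
        rng = np.random.default_rng(0)
        correct = total = 0
        for _ in range(6):
            profile = sample_profile(rng)
            hyp = simulate_hypnogram(rng, 40)
            for stage in hyp.stages:
                x = synth_epoch(stage, profile, "source", rng, SR).samples
                true3 = "W" if stage == "W" else ("REM" if stage == "REM" else "NREM")
                correct += oracle_stage3(x) == true3
                total += 1
        assert correct / total > 0.80

    def test_split_sizes_and_label_placement(self, small_benchmark):
        cfg = small_benchmark.gen_config
        per_night = (cfg.epochs_per_night - 40) // cfg.stride + 1
        assert len(small_benchmark.source_train) == cfg.n_source_nights * per_night
        assert len(small_benchmark.target_train) == cfg.n_target_nights * per_night
        assert len(small_benchmark.target_test) == cfg.n_test_nights * per_night
        assert all(w.labels is not None for w in small_benchmark.source_train)
        assert all(w.labels is None for w in small_benchmark.target_train)
        assert all(w.labels is not None for w in small_benchmark.target_test)
        assert all(w.domain == "source" for w in small_benchmark.source_train)
        assert all(w.domain == "target" for w in small_benchmark.target_train)
        assert len(small_benchmark.test_nights) == cfg.n_test_nights

    def test_target_noise_floor_is_elevated(self, small_benchmark):
        """The injected household noise raises the low-band mel floor."""
        def low_band_floor(windows):
            return np.median(
                np.stack([w.mel[:, :8, :] for w in windows]), axis=None
            )

        src = low_band_floor(small_benchmark.source_train)
        tgt = low_band_floor(small_benchmark.target_train)
        assert tgt > 3.0 * src

    def test_domain_gap_is_real(self, small_benchmark):
        """Raw-mel summaries separate the domains almost perfectly."""
        from sonosleep.trainer import input_domain_separability

        acc = input_domain_separability(
            small_benchmark.source_train, small_benchmark.target_train
        )
        assert acc > 0.9

    def test_rebuild_same_seed_identical(self):
        cfg = GenConfig(n_source_nights=1, n_target_nights=1, n_test_nights=1,
                        epochs_per_night=40, noise_bank_clips=4)
        a = build_benchmark(cfg, 99)
        b = build_benchmark(cfg, 99)
        assert np.array_equal(a.source_train[0].mel, b.source_train[0].mel)
        assert np.array_equal(a.target_train[0].mel, b.target_train[0].mel)
        assert np.array_equal(a.bank.clips, b.bank.clips)
        assert list(a.test_nights[0].hypnogram.stages) == list(
            b.test_nights[0].hypnogram.stages
        )

    def test_subject_splits_disjoint_by_construction(self, small_benchmark):
        ids = {n.night_id for n in small_benchmark.test_nights}
        assert all(i.startswith("H") for i in ids)
        assert len(ids) == small_benchmark.gen_config.n_test_nights

    def test_persistence_round_trip(self, tmp_path):
        cfg = GenConfig(n_source_nights=1, n_target_nights=1, n_test_nights=1,
                        epochs_per_night=40, noise_bank_clips=4)
        bench = build_benchmark(cfg, 5)
        save_benchmark(bench, tmp_path / "bench")
        back = load_benchmark(tmp_path / "bench")
        assert back.gen_config == cfg
        assert np.array_equal(back.source_train[0].mel, bench.source_train[0].mel)
        assert list(back.source_train[0].labels) == list(
            bench.source_train[0].labels
        )
        assert back.target_train[0].labels is None
        assert np.array_equal(back.bank.clips, bench.bank.clips)
        assert np.array_equal(back.test_nights[0].mel, bench.test_nights[0].mel)
        assert list(back.test_nights[0].hypnogram.stages) == list(
            bench.test_nights[0].hypnogram.stages
        )
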