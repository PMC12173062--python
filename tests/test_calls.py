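"""Synthetic call and soundscape generator tests.

Oracles: dominant-frequency trajectories are measured from STFT ridges of
clean rendered calls; minute durations are cross-checked against a
brute-force fine-grid overlap integration; Poisson event counts against the
analytic mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from broilervox.calls import (
    DEFAULT_PRESETS,
    FRAME_SECONDS,
    VOCAL_LABELS,
    CallEvent,
    CallType,
    SoundscapeConfig,
    age_pitch_scale,
    constant_profile,
    demo_diurnal_profile,
    events_to_frame_labels,
    events_to_minute_durations,
    read_fixture,
    sample_events,
    synth_call,
    synth_soundscape,
    write_fixture,
)

SR = 16000


def ridge_trajectory(wave: np.ndarray, sr: int = SR) -> np.ndarray:
    """Dominant-frequency trajectory (Hz) of the voiced part of a call."""
    f, t, S = signal.stft(wave, fs=sr, nperseg=512, noverlap=448)
    mag = np.abs(S)
    energy = mag.sum(axis=0)
    active = energy > 0.1 * energy.max()
    return f[mag[:, active].argmax(axis=0)]


class TestSynthCall:
    def test_ascending_contour_ridge_increases(self):
        ev = CallEvent(CallType.PN, 0.0, 0.15, 3000.0, 3600.0, "ascending")
        traj = ridge_trajectory(synth_call(ev, SR))
        assert traj[-1] > traj[0]
        # monotone up to one STFT bin of jitter
        assert np.all(np.diff(traj) >= -sr_bin_width())

    def test_descending_contour_ridge_decreases(self):
        ev = CallEvent(CallType.SP, 0.0, 0.2, 3500.0, 2500.0, "descending")
        traj = ridge_trajectory(synth_call(ev, SR))
        assert traj[0] > traj[-1]
        assert np.all(np.diff(traj) <= sr_bin_width())

    def test_bow_contour_rises_then_falls(self):
        ev = CallEvent(CallType.W, 0.0, 0.5, 1200.0, 1200.0, "bow")
        traj = ridge_trajectory(synth_call(ev, SR))
        peak = traj.argmax()
        assert 0 < peak < traj.size - 1
        assert traj[peak] > traj[0] + 100 and traj[peak] > traj[-1] + 100

    def test_dc_syllable_count(self):
        ev = CallEvent(CallType.DC, 0.0, 4 * 0.3 + 3 * 0.05, 3800.0, 3000.0,
                       "descending", n_syllables=4, level_db=10.0)
        w = synth_call(ev, SR)
        env = np.convolve(np.abs(w), np.ones(80) / 80, mode="same")
        bursts = np.diff((env > 0.05 * env.max()).astype(int))
        assert (bursts == 1).sum() == 4

    def test_rendering_is_deterministic(self):
        ev = CallEvent(CallType.SP, 0.0, 0.2, 3500.0, 2500.0, "descending")
        assert np.array_equal(synth_call(ev, SR), synth_call(ev, SR))

    def test_level_db_scales_rms(self):
        lo = CallEvent(CallType.SP, 0.0, 0.2, 3500.0, 2500.0, "descending", level_db=0.0)
        hi = CallEvent(CallType.SP, 0.0, 0.2, 3500.0, 2500.0, "descending", level_db=10.0)
        r = np.sqrt(np.mean(synth_call(hi, SR) ** 2) / np.mean(synth_call(lo, SR) ** 2))
        assert r == pytest.approx(10 ** 0.5, rel=0.01)

    def test_nyquist_violation_rejected(self):
        ev = CallEvent(CallType.SP, 0.0, 0.2, 3500.0, 2500.0, "descending")
        with pytest.raises(ValueError, match="Nyquist"):
            synth_call(ev, 4000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration=-0.1),
            dict(f0_start=100.0),
            dict(f0_end=9000.0),
            dict(contour="wiggle"),
            dict(n_syllables=0),
        ],
    )
    def test_invalid_events_rejected(self, kwargs):
        base = dict(type=CallType.SP, onset=0.0, duration=0.2, f0_start=3500.0,
                    f0_end=2500.0, contour="descending")
        with pytest.raises(ValueError):
            CallEvent(**{**base, **kwargs})

    def test_multi_syllable_only_for_repetitive_types(self):
        with pytest.raises(ValueError, match="repetitive"):
            CallEvent(CallType.PN, 0.0, 0.5, 3000.0, 3600.0, "ascending", n_syllables=2)


def sr_bin_width() -> float:
    return SR / 512 + 1.0


class TestAgePitch:
    def test_anchors_and_monotonicity(self):
        assert age_pitch_scale(1) == 1.0
        assert age_pitch_scale(42) == pytest.approx(0.6)
        scales = [age_pitch_scale(a) for a in range(0, 43)]
        assert all(s0 >= s1 for s0, s1 in zip(scales, scales[1:]))
        with pytest.raises(ValueError):
            age_pitch_scale(-1)

    def test_generated_f0_tracks_age_scale(self):
        """Median measured F0 at age 42 = scale(42) x age-1 median within 5%."""
        meds = {}
        for age in (1.0, 42.0):
            cfg = SoundscapeConfig(
                total_duration=60.0, profile=constant_profile({CallType.SP: 10.0}),
                sample_rate=SR, age_days=age, seed=5,
            )
            f0s = []
            for ev in sample_events(cfg)[:25]:
                f0s.append(np.median(ridge_trajectory(synth_call(ev, SR))))
            meds[age] = np.median(f0s)
        assert meds[42.0] / meds[1.0] == pytest.approx(0.6, rel=0.05)


class TestSampleEvents:
    def test_zero_rate_gives_no_events(self):
        cfg = SoundscapeConfig(
            total_duration=120.0,
            profile=constant_profile({ct: 0.0 for ct in CallType}),
            sample_rate=SR, seed=3,
        )
        assert sample_events(cfg) == []

    def test_poisson_event_count_mean(self):
        """Mean event count over 100 seeds within 3 MC SD of the analytic
        rate / mean-duration prediction."""
        rate = 6.0
        mean_dur = DEFAULT_PRESETS[CallType.SP].mean_duration()
        expected = 3600.0 * rate / 60.0 / mean_dur  # T * r/60 / E[dur]
        counts = []
        for seed in range(100):
            cfg = SoundscapeConfig(
                total_duration=3600.0, profile=constant_profile({CallType.SP: rate}),
                sample_rate=SR, seed=seed,
            )
            counts.append(len(sample_events(cfg)))
        counts = np.asarray(counts)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) <= 3 * se + 3.0

    def test_seed_changes_events(self):
        prof = constant_profile({CallType.SP: 6.0})
        mk = lambda s: sample_events(
            SoundscapeConfig(total_duration=60.0, profile=prof, sample_rate=SR, seed=s)
        )
        assert mk(1) != mk(2)
        assert mk(1) == mk(1)

    def test_diurnal_profile_modulates_hourly_rates(self):
        prof = demo_diurnal_profile()
        cfg = SoundscapeConfig(
            total_duration=24 * 3600.0, profile=prof, sample_rate=SR, seed=4,
        )
        events = [e for e in sample_events(cfg) if e.type is CallType.SP]
        per_hour = np.zeros(24)
        for ev in events:
            per_hour[int(ev.onset // 3600) % 24] += ev.duration
        evening = per_hour[16:22].mean() / 60.0
        night = (per_hour[22:].sum() + per_hour[:4].sum()) / 6.0 / 60.0
        assert evening > 2.5 * night  # configured 24 vs 6 s/min

    def test_non_overlap_mode(self):
        cfg = SoundscapeConfig(
            total_duration=300.0, profile=demo_diurnal_profile(), sample_rate=SR,
            seed=8, allow_overlap=False, start_hour=17.0,
        )
        evs = sample_events(cfg)
        assert evs, "expected events at evening rates"
        for a, b in zip(evs, evs[1:]):
            assert b.onset >= a.offset


def brute_force_minutes(events, total) -> pd.DataFrame:
    """Independent oracle: fine-grid indicator integration (1 ms grid)."""
    dt = 2e-4
    grid = np.arange(0.0, total, dt)
    n_min = int(np.ceil(total / 60.0))
    out = pd.DataFrame(0.0, index=pd.RangeIndex(n_min, name="minute"),
                       columns=list(VOCAL_LABELS))
    for ev in events:
        mask = (grid >= ev.onset) & (grid < ev.offset)
        for m in range(n_min):
            sel = mask & (grid >= 60 * m) & (grid < 60 * (m + 1))
            out.loc[m, ev.type.value] += sel.sum() * dt
    return out


class TestGroundTruth:
    def test_minute_durations_match_brute_force(self):
        cfg = SoundscapeConfig(
            total_duration=180.0, profile=demo_diurnal_profile(), sample_rate=SR,
            seed=21, start_hour=16.0,
        )
        events = sample_events(cfg)
        exact = events_to_minute_durations(events, 180.0)
        brute = brute_force_minutes(events, 180.0)
        assert np.allclose(exact.to_numpy(), brute.to_numpy(), atol=0.08)

    def test_frame_labels_for_aligned_call(self):
        ev = CallEvent(CallType.SP, 0.0, 0.48, 3500.0, 2500.0, "descending")
        labels = events_to_frame_labels([ev], 1.2)
        assert list(labels) == ["SP", "SP", "background", "background", "background"]

    def test_frame_label_count(self):
        assert events_to_frame_labels([], 60.0).shape == (250,)
        assert events_to_frame_labels([], 60.1).shape == (int(np.ceil(60.1 / FRAME_SECONDS)),)

    def test_conservation_without_overlap(self):
        cfg = SoundscapeConfig(
            total_duration=600.0, profile=demo_diurnal_profile(2.0), sample_rate=SR,
            seed=2, allow_overlap=False, start_hour=16.0,
        )
        _, truth = synth_soundscape(cfg)
        assert (truth.minute_durations.sum(axis=1) <= 60.0 + 1e-9).all()

    def test_rate_fidelity_over_an_hour(self):
        """Ground-truth s/min at constant rate r within 3 SE of r."""
        r = 6.0
        cfg = SoundscapeConfig(
            total_duration=3600.0, profile=constant_profile({CallType.SP: r}),
            sample_rate=SR, seed=17,
        )
        events = sample_events(cfg)
        md = events_to_minute_durations(events, 3600.0)["SP"]
        se = md.std(ddof=1) / np.sqrt(len(md))
        assert abs(md.mean() - r) <= 3 * se


class TestSoundscape:
    def test_determinism(self):
        cfg = SoundscapeConfig(
            total_duration=30.0, profile=constant_profile({CallType.DC: 4.0}),
            sample_rate=SR, seed=12,
        )
        w1, t1 = synth_soundscape(cfg)
        w2, t2 = synth_soundscape(cfg)
        assert np.array_equal(w1, w2)
        assert t1.events == t2.events
        assert np.array_equal(t1.frame_labels, t2.frame_labels)

    def test_empty_profile_gives_pure_background(self):
        cfg = SoundscapeConfig(
            total_duration=10.0, profile=constant_profile({}), sample_rate=SR, seed=12,
        )
        w, truth = synth_soundscape(cfg)
        assert truth.events == []
        assert (truth.minute_durations.to_numpy() == 0).all()
        assert w.std() > 0  # background present

    def test_snr_controls_call_level(self):
        prof = constant_profile({CallType.SP: 10.0})
        waves = {}
        for snr in (0.0, 20.0):
            cfg = SoundscapeConfig(total_duration=20.0, profile=prof,
                                   sample_rate=SR, seed=5, snr_db=snr)
            w, truth = synth_soundscape(cfg)
            active = np.zeros(w.size, bool)
            for ev in truth.events:
                active[int(ev.onset * SR): int(ev.offset * SR)] = True
            waves[snr] = w[active].std() / w[~active].std()
        assert waves[20.0] > 3.0 * waves[0.0]

    @pytest.mark.parametrize("background", ["white", "pink", "fan"])
    def test_background_kinds(self, background):
        cfg = SoundscapeConfig(
            total_duration=5.0, profile=constant_profile({}), sample_rate=SR,
            seed=1, background=background,
        )
        w, _ = synth_soundscape(cfg)
        assert np.all(np.isfinite(w)) and w.std() > 0


class TestFixtureRoundTrip:
    @pytest.mark.parametrize("rates", [{}, {CallType.SP: 2.0}, None])
    def test_labels_round_trip(self, rates, tmp_path):
        profile = demo_diurnal_profile() if rates is None else constant_profile(rates)
        cfg = SoundscapeConfig(total_duration=60.0, profile=profile,
                               sample_rate=SR, seed=3, start_hour=18.0)
        wave, truth = synth_soundscape(cfg)
        write_fixture(wave, SR, truth, tmp_path / "fx")
        wave2, sr2, truth2 = read_fixture(tmp_path / "fx")
        assert sr2 == SR and wave2.size == wave.size
        assert truth2.events == truth.events
        assert np.array_equal(truth2.frame_labels, truth.frame_labels)
        assert np.allclose(
            truth2.minute_durations.to_numpy(), truth.minute_durations.to_numpy()
        )
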