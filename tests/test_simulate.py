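"""Generator fidelity: schedule structure, signal shape, artifacts, cohort."""

import numpy as np
import pytest

from painmon.simulate import (
    ARTIFACT_CODES,
    BASELINE,
    SAMPLING_RATE_HZ,
    GeneratorConfig,
    SubjectProfile,
    generate_cohort,
    generate_schedule,
    generate_session,
    inject_artifacts,
    labels_from_schedule,
    read_session,
    scr_kernel_peak_time,
    session_duration_s,
    session_to_frame,
    stimulus_code,
    synthesize_eda,
    synthesize_facial,
    write_session,
)


def _quiet_profile(**over):
    base = dict(subject_id="S1", expressiveness_category=3, eda_gain=0.6,
                facial_gain=0.8, scr_latency_s=2.0, noise_sd=0.0)
    base.update(over)
    return SubjectProfile(**base)


class TestSchedule:
    def test_default_counts(self):
        sched = generate_schedule(GeneratorConfig(), np.random.default_rng(0))
        phasic = [e for e in sched if e.stim_type == "phasic"]
        tonic = [e for e in sched if e.stim_type == "tonic"]
        assert len(phasic) == 180
        assert len(tonic) == 6
        for q in ("heat", "electrical"):
            for i in (1, 2, 3):
                assert sum(e.quality == q and e.intensity == i for e in phasic) == 30
                assert sum(e.quality == q and e.intensity == i for e in tonic) == 1
        assert all(e.duration_s == 60.0 for e in tonic)
        assert all(e.duration_s == 5.0 for e in phasic)

    def test_empty_schedule(self):
        cfg = GeneratorConfig(phasic_reps=0, tonic_reps=0)
        assert generate_schedule(cfg, np.random.default_rng(0)) == []

    def test_fixed_pause_span_arithmetic(self):
        cfg = GeneratorConfig(phasic_reps=2, tonic_reps=0, qualities=("heat",),
                              intensities=(1,), phasic_pause_range_s=(10.0, 10.0))
        sched = generate_schedule(cfg, np.random.default_rng(0))
        assert len(sched) == 2
        span = sched[-1].offset_s - sched[0].onset_s
        assert span == pytest.approx(2 * 5 + 10)

    def test_events_ordered_nonoverlapping_pauses_in_range(self):
        cfg = GeneratorConfig()
        sched = generate_schedule(cfg, np.random.default_rng(1))
        for a, b in zip(sched, sched[1:]):
            gap = b.onset_s - a.offset_s
            assert gap > 0
            if a.stim_type == "phasic":
                assert 8.0 <= gap <= 12.0
            else:
                assert gap == pytest.approx(300.0)

    def test_session_length_about_81_minutes(self):
        cfg = GeneratorConfig()
        sched = generate_schedule(cfg, np.random.default_rng(2))
        dur = session_duration_s(sched, cfg)
        assert 4700 <= dur <= 5100        # 81 min +/- pause sampling

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(split_fractions=(0.5, 0.2, 0.2)).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(artifact_fraction=1.5).validate()


class TestEda:
    def test_zero_gain_zero_noise_constant(self):
        cfg = GeneratorConfig(eda_drift_amplitude=0.0)
        sched = generate_schedule(cfg, np.random.default_rng(0))
        prof = _quiet_profile(eda_gain=0.0)
        eda = synthesize_eda(sched, prof, cfg, np.random.default_rng(0))
        assert np.ptp(eda) == 0.0

    def test_single_scr_peak_location(self):
        cfg = GeneratorConfig(phasic_reps=1, tonic_reps=0, qualities=("heat",),
                              intensities=(2,), eda_drift_amplitude=0.0)
        sched = generate_schedule(cfg, np.random.default_rng(0))
        prof = _quiet_profile(scr_latency_s=2.0)
        eda = synthesize_eda(sched, prof, cfg, np.random.default_rng(0))
        expected = sched[0].onset_s + 2.0 + scr_kernel_peak_time(
            cfg.scr_rise_s, cfg.scr_decay_s)
        assert np.argmax(eda) / SAMPLING_RATE_HZ == pytest.approx(expected, abs=0.05)

    def test_peak_amplitude_increases_with_intensity(self):
        cfg = GeneratorConfig(tonic_reps=0, qualities=("heat",),
                              eda_drift_amplitude=0.0)
        rng = np.random.default_rng(5)
        sched = generate_schedule(cfg, rng)
        prof = _quiet_profile(noise_sd=0.0)
        eda = synthesize_eda(sched, prof, cfg, rng)
        means = {}
        for i in (1, 2, 3):
            peaks = []
            for ev in sched:
                if ev.intensity != i:
                    continue
                i0 = int(ev.onset_s * 25)
                i1 = int((ev.offset_s + 4) * 25)
                peaks.append(eda[i0:i1].max() - cfg.eda_baseline_us)
            means[i] = np.mean(peaks)
        assert means[1] < means[2] < means[3]


class TestFacial:
    def test_21_channels(self, small_cohort):
        _, recordings, _ = small_cohort
        assert recordings[0].facial.shape[0] == 21

    def test_category1_flat_responsive_channels(self):
        cfg = GeneratorConfig(phasic_reps=2, tonic_reps=0)
        sched = generate_schedule(cfg, np.random.default_rng(0))
        prof = _quiet_profile(expressiveness_category=1, facial_gain=0.0)
        facial = synthesize_facial(sched, prof, cfg, np.random.default_rng(0))
        assert np.ptp(facial) == 0.0

    def test_response_monotone_in_category(self):
        from painmon.simulate import PAIN_RESPONSIVE_CHANNELS, sample_profile

        cfg = GeneratorConfig(phasic_reps=5, tonic_reps=0, qualities=("heat",),
                              intensities=(2,))
        amp = {}
        for cat in (1, 2, 3, 4):
            rng = np.random.default_rng(cat)
            sched = generate_schedule(cfg, rng)
            prof = sample_profile("S", cat, np.random.default_rng(99))
            prof.noise_sd = 0.0
            facial = synthesize_facial(sched, prof, cfg, rng)
            amp[cat] = facial[list(PAIN_RESPONSIVE_CHANNELS)].max()
        assert amp[1] < amp[2] < amp[3] < amp[4]

    def test_category1_profile_invariant(self):
        with pytest.raises(ValueError):
            SubjectProfile("S", 1, 0.5, 0.5, 2.0, 0.05)


class TestArtifacts:
    def _rec(self, artifact_fraction):
        cfg = GeneratorConfig(n_subjects=3, phasic_reps=2,
                              artifact_fraction=artifact_fraction, seed=3)
        prof = _quiet_profile()
        rng = np.random.default_rng(3)
        return cfg, generate_session(prof, cfg, rng)

    def test_zero_fraction_identity(self):
        cfg, rec = self._rec(0.0)
        assert not np.isin(rec.labels, ARTIFACT_CODES).any()

    def test_fraction_near_target_and_signal_unchanged(self):
        cfg = GeneratorConfig(phasic_reps=2, artifact_fraction=0.05)
        prof = _quiet_profile()
        rng = np.random.default_rng(4)
        sched = generate_schedule(cfg, rng)
        n = int(np.ceil(session_duration_s(sched, cfg) * 25))
        eda = synthesize_eda(sched, prof, cfg, rng, n)
        from painmon.simulate import SessionRecording

        rec = SessionRecording(eda=eda.copy(), facial=np.zeros((21, n)),
                               labels=labels_from_schedule(sched, n),
                               schedule=sched, profile=prof)
        rec2 = inject_artifacts(rec, cfg, np.random.default_rng(5))
        frac = np.isin(rec2.labels, ARTIFACT_CODES).mean()
        assert 0.03 <= frac <= 0.07
        assert np.array_equal(rec2.eda, eda)
        # artifact spans only ever replace labels, never invent pain codes
        changed = rec2.labels != labels_from_schedule(sched, n)
        assert set(np.unique(rec2.labels[changed])) <= set(ARTIFACT_CODES)


class TestCohort:
    def test_split_sizes_8_1_1(self):
        _, assignment = generate_cohort(GeneratorConfig(n_subjects=10, phasic_reps=1, seed=0))
        sizes = {s: sum(v == s for v in assignment.values())
                 for s in ("train", "val", "test")}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_subjects=3, phasic_reps=1, seed=11)
        recs1, a1 = generate_cohort(cfg)
        recs2, a2 = generate_cohort(cfg)
        assert a1 == a2
        assert np.array_equal(recs1[0].eda, recs2[0].eda)
        assert np.array_equal(recs1[-1].labels, recs2[-1].labels)

    def test_every_split_has_all_intensities(self, small_cohort):
        _, recordings, assignment = small_cohort
        for split in ("train", "val", "test"):
            codes = np.concatenate([r.labels for r in recordings
                                    if assignment[r.profile.subject_id] == split])
            intensities = {(c - 1) % 3 + 1 for c in np.unique(codes) if 1 <= c <= 12}
            assert intensities == {1, 2, 3}

    def test_train_split_covers_all_categories(self):
        recs, assignment = generate_cohort(GeneratorConfig(n_subjects=10, phasic_reps=1, seed=0))
        cats = {r.profile.expressiveness_category for r in recs
                if assignment[r.profile.subject_id] == "train"}
        assert cats == {1, 2, 3, 4}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(GeneratorConfig(n_subjects=2))

    def test_label_stream_conserves_schedule(self):
        cfg = GeneratorConfig(phasic_reps=2, artifact_fraction=0.0)
        rng = np.random.default_rng(6)
        sched = generate_schedule(cfg, rng)
        n = int(np.ceil(session_duration_s(sched, cfg) * 25))
        labels = labels_from_schedule(sched, n)
        for code in np.unique(labels):
            if code == BASELINE:
                continue
            expect = sum(round(e.duration_s * 25) for e in sched if e.code == code)
            assert abs(int((labels == code).sum()) - expect) <= len(sched)


class TestSessionIO:
    def test_roundtrip(self, tmp_path, small_cohort):
        _, recordings, _ = small_cohort
        rec = recordings[0]
        path = tmp_path / "s.csv"
        write_session(rec, path)
        back = read_session(path)
        assert np.allclose(back.eda, rec.eda, atol=1e-5)
        assert np.array_equal(back.labels, rec.labels)
        df = session_to_frame(rec)
        assert list(df.columns) == (["time_s", "eda"]
                                    + [f"f{i:02d}" for i in range(1, 22)] + ["label"])
        assert np.all(np.diff(df["time_s"]) > 0)

    def test_stimulus_code_layout(self):
        assert stimulus_code("phasic", "heat", 2) == 2
        assert stimulus_code("phasic", "electrical", 2) == 5
        assert stimulus_code("tonic", "heat", 1) == 7
        assert stimulus_code("tonic", "electrical", 3) == 12
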