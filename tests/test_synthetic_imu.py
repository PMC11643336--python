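"""Generator contracts: determinism, structure, degradation monotonicity."""

import numpy as np
import pandas as pd
import pytest

import moveprof as mp
from moveprof import synthetic_imu as syn
from moveprof.session_io import GRADES, MOVEMENTS, PLACEMENTS


@pytest.fixture(scope="module")
def archetypes():
    return syn.build_default_archetypes()


@pytest.fixture(scope="module")
def profiles():
    return syn.default_profiles()


class TestArchetypes:
    def test_six_archetypes_with_valid_fundamentals(self, archetypes):
        assert set(archetypes) == set(MOVEMENTS)
        for a in archetypes.values():
            assert 0.1 <= a.fundamental_hz <= 0.5
            assert len(a.sites) == 13

    def test_archetypes_pairwise_distinguishable(self, archetypes):
        """Each pair differs in tempo, coordination, or posture."""
        for m1 in MOVEMENTS:
            for m2 in MOVEMENTS:
                if m1 >= m2:
                    continue
                a, b = archetypes[m1], archetypes[m2]
                tempo = abs(a.fundamental_hz - b.fundamental_hz) > 0.01
                coord = any(abs(a.coordination[p] - b.coordination[p]) > 0.1
                            for p in PLACEMENTS)
                orient = any(abs(a.sites[p].pitch_mean - b.sites[p].pitch_mean) > 2
                             for p in PLACEMENTS)
                assert tempo or coord or orient, f"{m1} vs {m2} indistinguishable"

    def test_confusable_pair_converges_with_overlap(self):
        """GST/WHLC templates converge as overlap -> 1."""
        near = syn.build_default_archetypes(overlap=0.99)
        far = syn.build_default_archetypes(overlap=0.2)

        def gap(archs):
            g, w = archs["GST"], archs["WHLC"]
            return sum(abs(g.sites[p].pitch_mean - w.sites[p].pitch_mean)
                       for p in PLACEMENTS)

        assert gap(near) < gap(far)

    def test_amplitude_range_validation(self, archetypes):
        from dataclasses import replace
        a = archetypes["PUSH"]
        bad_site = replace(a.sites["r_wrist"], gyro_amp=(3000.0, 10.0, 10.0))
        bad = syn.MovementArchetype(
            name="PUSH", fundamental_hz=a.fundamental_hz, harmonic_rel=a.harmonic_rel,
            jerk_scale=a.jerk_scale, sites={**a.sites, "r_wrist": bad_site})
        with pytest.raises(syn.RangeViolationError):
            bad.validate_ranges()


class TestProfiles:
    def test_degradation_strictly_ordered(self, profiles):
        for p in ("jerk_noise_sd", "tempo_jitter_cv", "amplitude_cv",
                  "coordination_error_sd"):
            lo, me, hi = (getattr(profiles[g], p) for g in GRADES)
            assert lo > me > hi > 0

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            syn.ProficiencyProfile("high", jerk_noise_sd=0.0, tempo_jitter_cv=0.1,
                                   amplitude_cv=0.1, coordination_error_sd=0.1)


class TestGenerateSubject:
    def test_repetition_count_forced_by_config(self, archetypes, profiles):
        cfg = mp.CohortConfig(n_subjects=2, movements=("GST",), seed=7)
        s = syn.generate_subject(archetypes, profiles["high"], cfg, seed=7)
        for bi in range(2):  # bilateral: 2 blocks
            assert sum(t["block_index"] == bi for t in s.truth) == 6

    def test_bit_identical_for_same_seed(self, archetypes, profiles):
        cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",), seed=7)
        a = syn.generate_subject(archetypes, profiles["medium"], cfg, seed=7)
        b = syn.generate_subject(archetypes, profiles["medium"], cfg, seed=7)
        for p in PLACEMENTS:
            np.testing.assert_array_equal(a.channels[p].accel, b.channels[p].accel)
            np.testing.assert_array_equal(a.channels[p].gyro, b.channels[p].gyro)
            np.testing.assert_array_equal(a.channels[p].mag, b.channels[p].mag)
        assert a.truth == b.truth

    def test_different_seeds_differ(self, archetypes, profiles):
        cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",), seed=7)
        a = syn.generate_subject(archetypes, profiles["medium"], cfg, seed=7)
        b = syn.generate_subject(archetypes, profiles["medium"], cfg, seed=8)
        assert not np.array_equal(a.channels["chest"].gyro, b.channels["chest"].gyro)

    def test_low_grade_has_larger_period_variance(self, archetypes, profiles):
        cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",),
                              repetitions_per_movement=9, seed=3)

        def period_var(profile):
            s = syn.generate_subject(archetypes, profile, cfg, seed=3)
            t = pd.DataFrame(s.truth)
            durations = t["end_s"] - t["start_s"]
            # interior repetitions only: edge reps carry the block margins
            keep = t["rep_index"].between(1, 7)
            return float(durations[keep].var())

        assert period_var(profiles["low"]) > period_var(profiles["high"])

    def test_gravity_consistent_with_orientation_profile(self, archetypes, profiles):
        """Mean accel during rest approximates 1 g pointing along gravity."""
        cfg = mp.CohortConfig(n_subjects=2, movements=("RTP",), seed=5)
        s = syn.generate_subject(archetypes, profiles["high"], cfg, seed=5)
        lead = s.channels["chest"].accel[:150]  # rest before the first marker
        norm = np.linalg.norm(lead.mean(axis=0))
        assert abs(norm - 1.0) < 0.05

    def test_pause_gyro_floor(self, archetypes, profiles):
        """Within every generated pause the gyro magnitude stays quiet."""
        cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",), seed=9,
                              pause_duration_s=0.6)
        s = syn.generate_subject(archetypes, profiles["low"], cfg, seed=9)
        t = pd.DataFrame(s.truth)
        gyro = s.channels["r_wrist"].gyro
        rate = 100.0
        for b in t["block_index"].unique():
            tb = t[t["block_index"] == b].sort_values("rep_index")
            for _, row in tb.iloc[1:].iterrows():
                mid = row["start_s"]  # boundary = pause midpoint
                i0 = int((mid - 0.1) * rate)
                i1 = int((mid + 0.1) * rate)
                mags = np.linalg.norm(gyro[i0:i1], axis=1)
                assert mags.mean() < syn.PAUSE_FLOOR_DPS

    def test_empty_archetypes_rejected(self, profiles):
        cfg = mp.CohortConfig(n_subjects=2, movements=(), seed=1)
        with pytest.raises(ValueError):
            syn.generate_subject({}, profiles["high"], cfg, seed=1)


class TestSpectralRealism:
    def test_power_concentrated_at_fundamental(self, archetypes, profiles):
        """High-grade band-pass power peaks within 0.2 Hz of the fundamental
        or a harmonic, measured over a whole block."""
        from moveprof import preprocess as pp
        cfg = mp.CohortConfig(n_subjects=2, movements=("PUSH",), seed=2)
        s = syn.generate_subject(archetypes, profiles["high"], cfg, seed=2)
        m = s.markers[0]
        f0 = archetypes["PUSH"].fundamental_hz
        sig = s.channels["r_wrist"].gyro[int(m.start_s * 100):int(m.end_s * 100), 0]
        x = pp.bandpass(pp.resample(sig, 100.0, 32.0), 32.0)
        freqs = np.fft.rfftfreq(len(x), 1 / 32.0)
        power = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
        peak = freqs[np.argmax(power)]
        harmonics = [k * f0 for k in (1, 2, 3)]
        assert min(abs(peak - h) for h in harmonics) < 0.2


class TestGenerateCohort:
    def test_truth_table_arithmetic(self, small_cohort):
        cfg, sessions, truth = small_cohort
        # 5 bilateral x 2 sides x 6 reps + RTP x 6 reps = 66 per subject
        assert len(truth) == cfg.n_subjects * 66
        assert len(sessions) == cfg.n_subjects

    def test_min_subjects_enforced(self):
        with pytest.raises(ValueError, match="n_subjects"):
            mp.CohortConfig(n_subjects=1)

    def test_class_proportions_respected(self):
        cfg = mp.CohortConfig(n_subjects=8, class_proportions=(0.5, 0.25, 0.25), seed=4)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
        alloc = syn._allocate_grades(cfg, rng)
        for m, grades in alloc.items():
            counts = pd.Series(grades).value_counts()
            # stratified allocation: exact up to rounding, trivially inside
            # any binomial interval around the target proportions
            assert counts["low"] == 4 and counts["medium"] == 2 and counts["high"] == 2

    def test_cohort_determinism_and_seed_sensitivity(self):
        cfg = mp.CohortConfig(n_subjects=2, movements=("GR",), seed=21)
        s1, t1 = mp.generate_cohort(cfg)
        s2, t2 = mp.generate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(s1[0].channels["l_thigh"].accel,
                                      s2[0].channels["l_thigh"].accel)
        s3, _ = mp.generate_cohort(mp.CohortConfig(n_subjects=2, movements=("GR",), seed=22))
        assert not np.array_equal(s1[0].channels["l_thigh"].accel,
                                  s3[0].channels["l_thigh"].accel)

    def test_sessions_within_sensor_ranges(self, small_cohort):
        _, sessions, _ = small_cohort
        for s in sessions:
            for p, cs in s.channels.items():
                assert np.abs(cs.accel).max() <= 4.0
                assert np.abs(cs.gyro).max() <= 2000.0
                assert np.abs(cs.mag).max() <= 1.9
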