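"""Synthetic generators: determinism, spectral content, planted effects."""

import numpy as np
import pytest
from scipy import signal as sps

from mieeg.preprocess import RawRecording, notch_filter, preprocess_recording
from mieeg.spectral import band_power_table
from mieeg.synth import (
    CONTROL_EFFECTS,
    EXPERIMENTAL_EFFECTS,
    NULL_EFFECTS,
    CouplingSpec,
    EffectSpec,
    RecordingSpec,
    TABLE1_DEMOGRAPHICS,
    generate_cohort,
    generate_coupled_pair,
    generate_resting_recording,
    generate_task_recording,
    make_background,
    make_band_oscillation,
)


class TestBandOscillation:
    def test_construction(self):
        x = make_band_oscillation(10.0, 1.0, 0.0, 2.0, 500.0)
        assert len(x) == 1000
        freqs, psd = sps.periodogram(x, fs=500.0)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=0.5)

    def test_zero_amplitude_zero_frequency(self):
        assert np.allclose(make_band_oscillation(0.0, 0.0, 0.0, 2.0, 500.0), 0.0)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_band_oscillation(250.0, 1.0, 0.0, 2.0, 500.0)

    def test_notch_kills_line_frequency_tone(self):
        x = make_band_oscillation(50.0, 5.0, 0.0, 4.0, 500.0)
        rec = RawRecording(x[None, :], ["c0"], 500.0)
        out = notch_filter(rec)
        mid = slice(500, -500)  # steady-state, past the filter transient
        assert (out.data[:, mid] ** 2).sum() < 0.01 * (x[mid] ** 2).sum()


class TestBackground:
    @staticmethod
    def _fitted_slope(exponent, n_real=8):
        slopes = []
        for seed in range(n_real):
            x = make_background(exponent, 500.0, 60.0, seed=seed)
            freqs, psd = sps.welch(x, fs=500.0, nperseg=4096)
            m = (freqs >= 1.0) & (freqs <= 45.0)
            slope = np.polyfit(np.log10(freqs[m]), np.log10(psd[m]), 1)[0]
            slopes.append(slope)
        return float(np.mean(slopes))

    def test_flat_spectrum_at_zero_exponent(self):
        assert abs(self._fitted_slope(0.0)) < 0.15

    def test_pink_slope_at_unit_exponent(self):
        assert self._fitted_slope(1.0) == pytest.approx(-1.0, abs=0.2)

    def test_deterministic_by_seed(self):
        a = make_background(1.0, 500.0, 10.0, seed=3)
        b = make_background(1.0, 500.0, 10.0, seed=3)
        assert np.array_equal(a, b)

    def test_unit_rms(self):
        x = make_background(1.0, 500.0, 30.0, seed=0)
        assert np.sqrt((x**2).mean()) == pytest.approx(1.0, rel=1e-9)


class TestSpecValidation:
    def test_artifact_rate_bounds(self):
        with pytest.raises(ValueError):
            RecordingSpec(artifact_epoch_rate=1.5)

    def test_coupling_invariants(self):
        with pytest.raises(ValueError):
            CouplingSpec([("a", "b")], "theta", 4.0, 0.5)  # lag outside (-pi, pi]
        with pytest.raises(ValueError):
            CouplingSpec([("a", "b")], "theta", 0.5, 1.5)

    def test_effect_factors_positive(self):
        with pytest.raises(ValueError):
            EffectSpec(theta_power_shift=0.0)


class TestRestingRecording:
    def test_deterministic(self):
        spec = RecordingSpec(duration=10.0, seed=4)
        a = generate_resting_recording(spec)
        b = generate_resting_recording(spec)
        assert np.array_equal(a.data, b.data)

    def test_planted_artifacts_rejected_at_planted_rate(self):
        spec = RecordingSpec(duration=120.0, artifact_epoch_rate=0.1, seed=6)
        rec = generate_resting_recording(spec)
        ep = preprocess_recording(rec)
        rejected = 1.0 - ep.n_kept / ep.n_epochs
        assert rejected == pytest.approx(0.1, abs=0.05)
        # the rejected epochs are exactly the planted ones
        assert sorted(np.nonzero(~ep.kept)[0].tolist()) == rec.meta["artifact_epochs"]

    def test_alpha_dominant_in_occipital_share(self):
        spec = RecordingSpec(duration=30.0, seed=8)
        rec = generate_resting_recording(spec)
        tbl = band_power_table(preprocess_recording(rec))
        occ = tbl[tbl.region == "occipital"].set_index("band")["relative_power"]
        assert occ.idxmax() == "alpha"

    def test_thirty_channels_with_ocular(self):
        rec = generate_resting_recording(RecordingSpec(duration=6.0, seed=1))
        assert rec.n_channels == 30
        assert "HEOL" in rec.ch_names and "HEOR" in rec.ch_names


class TestCoupledPair:
    def test_requires_two_epochs(self):
        with pytest.raises(ValueError):
            generate_coupled_pair(n_epochs=1)

    def test_deterministic(self):
        a = generate_coupled_pair(seed=9)
        b = generate_coupled_pair(seed=9)
        assert np.array_equal(a.epochs, b.epochs)


class TestTaskRecording:
    def test_target_engagement_recovered(self):
        from mieeg.engagement_tf import engagement_index

        for target in (30.0, 70.0):
            rec = generate_task_recording(target, duration=40.0, seed=2)
            ep = preprocess_recording(rec, to_regions=False)
            assert engagement_index(ep) == pytest.approx(target, abs=8.0)

    def test_engagement_bounds_enforced(self):
        with pytest.raises(ValueError):
            generate_task_recording(0.0)


class TestCohort:
    def test_manifest_shape_and_groups(self):
        coh = generate_cohort(n_per_group=3, seed=1)
        assert len(coh.manifest) == 6
        assert set(coh.manifest.group) == {"control", "experimental"}
        assert coh.manifest.kviq.between(55, 100).all()
        assert coh.manifest.bbs_pre.between(0, 56).all()
        assert coh.manifest.fac_post.between(0, 5).all()

    def test_printed_demographics_fixture(self):
        coh = generate_cohort(n_per_group=5, seed=1, use_printed_demographics=True)
        ctrl = coh.manifest[coh.manifest.group == "control"]
        assert ctrl.kviq.tolist() == [k for _, _, _, k, _ in TABLE1_DEMOGRAPHICS["control"]]

    def test_experimental_effects_larger_than_control(self):
        assert EXPERIMENTAL_EFFECTS.theta_power_shift > CONTROL_EFFECTS.theta_power_shift
        assert EXPERIMENTAL_EFFECTS.beta_power_shift < CONTROL_EFFECTS.beta_power_shift
        assert (EXPERIMENTAL_EFFECTS.delta_theta_coupling_shift
                > CONTROL_EFFECTS.delta_theta_coupling_shift)

    def test_positive_slope_raises_final_engagement(self):
        coh = generate_cohort(n_per_group=4, seed=3)
        first = [coh.engagement_target(s, 1) for s in coh.subjects]
        last = [coh.engagement_target(s, 20) for s in coh.subjects]
        assert np.mean(last) > np.mean(first)

    def test_null_effects_flat_engagement(self):
        coh = generate_cohort(
            n_per_group=4, seed=3,
            effects={"control": NULL_EFFECTS,
                     "experimental": EffectSpec(group="experimental")},
        )
        first = [coh.engagement_target(s, 1) for s in coh.subjects]
        last = [coh.engagement_target(s, 20) for s in coh.subjects]
        assert abs(np.mean(last) - np.mean(first)) < 8.0

    def test_recordings_deterministic_per_subject(self):
        coh = generate_cohort(n_per_group=2, seed=5, resting_duration=6.0)
        a = coh.resting_recording("cont01", "pre")
        b = coh.resting_recording("cont01", "pre")
        assert np.array_equal(a.data, b.data)

    def test_adding_subjects_preserves_existing_streams(self):
        small = generate_cohort(n_per_group=2, seed=5, resting_duration=6.0)
        large = generate_cohort(n_per_group=4, seed=5, resting_duration=6.0)
        a = small.resting_recording("cont01", "pre")
        b = large.resting_recording("cont01", "pre")
        assert np.array_equal(a.data, b.data)
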