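"""Generator contracts: determinism, invariants, and recoverable truth."""

import numpy as np
import pytest

from mspilot.backfit import backfit
from mspilot.recording import run_lengths, spatial_correlation
from mspilot.synth import (
    ProtocolSpec,
    generate_template_maps,
    rectified_sine_envelope,
    render_eeg,
    sample_correlated_pm1,
    sample_label_sequence,
    simulate_protocol,
    uniform_sequence_model,
)


class TestTemplateMaps:
    def test_unit_norm_zero_mean(self, template_maps):
        norms = np.linalg.norm(template_maps.maps, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        np.testing.assert_allclose(template_maps.maps.sum(axis=1), 0.0, atol=1e-9)

    def test_deterministic(self):
        a = generate_template_maps(7, 64, 0.7, seed=1)
        b = generate_template_maps(7, 64, 0.7, seed=1)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_pairwise_similarity_bound_brute_force(self, template_maps):
        # exhaustive check over all 21 pairs
        M = template_maps.maps
        for i in range(7):
            for j in range(i + 1, 7):
                assert abs(spatial_correlation(M[i], M[j])) <= 0.7

    def test_infeasible_similarity_raises(self):
        with pytest.raises(ValueError):
            generate_template_maps(6, 8, 0.01, seed=0, max_tries=50)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_template_maps(64, 64, 0.7, seed=0)
        with pytest.raises(ValueError):
            generate_template_maps(7, 64, 1.5, seed=0)


class TestLabelSequences:
    def test_degenerate_single_class(self):
        model = uniform_sequence_model(1, mean_dwell=5)
        seq = sample_label_sequence(model, 1000, seed=0)
        vals, lens = run_lengths(seq.labels)
        assert len(vals) == 1 and lens[0] == 1000

    def test_mean_dwell_matches_model(self):
        model = uniform_sequence_model(7, mean_dwell=20)
        seq = sample_label_sequence(model, 100_000, seed=3)
        _, lens = run_lengths(seq.labels)
        # drop the truncated final run
        assert abs(lens[:-1].mean() - 20) / 20 < 0.05

    def test_uniform_coverage(self):
        model = uniform_sequence_model(7, mean_dwell=20)
        seq = sample_label_sequence(model, 200_000, seed=4)
        cov = np.bincount(seq.labels, minlength=7) / seq.n_samples
        assert np.all(np.abs(cov - 1 / 7) < 0.01)

    def test_coverage_sums_to_one(self):
        model = uniform_sequence_model(5, mean_dwell=7)
        seq = sample_label_sequence(model, 12_345, seed=9)
        cov = np.bincount(seq.labels, minlength=5) / seq.n_samples
        assert abs(cov.sum() - 1.0) < 1e-12

    def test_fixed_dwell(self):
        model = uniform_sequence_model(3, mean_dwell=10, dwell_distribution="fixed")
        seq = sample_label_sequence(model, 1000, seed=1)
        _, lens = run_lengths(seq.labels)
        assert set(lens[:-1]) == {10}

    def test_invalid_transition_matrix(self):
        from mspilot.synth import SequenceModel

        with pytest.raises(ValueError):
            SequenceModel(
                n_classes=2,
                transition_matrix=np.array([[0.0, 0.5], [1.0, 0.0]]),
                mean_dwell=np.array([5.0, 5.0]),
            )


class TestRenderEeg:
    def test_noiseless_backfit_recovers_labels(
        self, template_maps, planted_sequence, clean_recording
    ):
        seq = backfit(clean_recording, template_maps.maps)
        gfp_positive = clean_recording.data.std(axis=0) > 0
        assert np.array_equal(
            seq.labels[gfp_positive], planted_sequence.labels[gfp_positive]
        )

    def test_zero_envelope_is_silent(self, template_maps, planted_sequence):
        env = np.zeros(planted_sequence.n_samples)
        rec = render_eeg(template_maps, planted_sequence, env, snr_db=10, seed=0)
        assert np.all(rec.data == 0)

    def test_snr_within_half_db(self, template_maps, planted_sequence):
        env = rectified_sine_envelope(planted_sequence.n_samples, 250.0)
        signal = render_eeg(
            template_maps, planted_sequence, env, snr_db=np.inf, seed=7
        ).data
        noisy = render_eeg(
            template_maps, planted_sequence, env, snr_db=10.0, seed=7
        ).data
        noise = noisy - signal
        measured = 10 * np.log10(np.mean(signal**2) / np.mean(noise**2))
        assert abs(measured - 10.0) < 0.5

    def test_rendered_gfp_equals_envelope(self, clean_recording, planted_sequence):
        env = rectified_sine_envelope(planted_sequence.n_samples, 250.0)
        gfp = clean_recording.data.std(axis=0, ddof=0)
        np.testing.assert_allclose(gfp, env, atol=1e-9)

    def test_average_referenced(self, noisy_recording):
        np.testing.assert_allclose(
            noisy_recording.data.sum(axis=0), 0.0, atol=1e-6
        )

    def test_mismatched_lengths_raise(self, template_maps, planted_sequence):
        with pytest.raises(ValueError):
            render_eeg(template_maps, planted_sequence, np.ones(10), seed=0)


class TestProtocol:
    def test_default_protocol_yields_44_tasks(self, template_maps):
        spec = ProtocolSpec(baseline_duration=2.0, trial_duration=3.0)
        model = uniform_sequence_model(7, 20)
        items = simulate_protocol(spec, template_maps, model, model, seed=0)
        assert len(items) == 44
        assert sum(1 for i in items if i.task_type == "Baseline") == 22
        assert sum(1 for i in items if i.task_type == "Trial") == 22

    def test_stage_session_counts(self, template_maps):
        spec = ProtocolSpec(baseline_duration=2.0, trial_duration=3.0)
        model = uniform_sequence_model(7, 20)
        items = simulate_protocol(spec, template_maps, model, model, seed=0)
        counts = {}
        for i in items:
            if i.task_type == "Baseline":
                counts[i.stage] = counts.get(i.stage, 0) + 1
        assert counts == {"Training": 7, "PracticeA": 8, "PracticeB": 7}

    def test_task_durations(self, template_maps):
        spec = ProtocolSpec(stages=(("Training", 1),))
        model = uniform_sequence_model(7, 20)
        items = simulate_protocol(spec, template_maps, model, model, seed=0)
        assert len(items) == 2
        assert items[0].recording.duration == pytest.approx(30.0)
        assert items[1].recording.duration == pytest.approx(90.0)

    def test_deterministic(self, template_maps):
        spec = ProtocolSpec(stages=(("Training", 1),), baseline_duration=2.0,
                            trial_duration=2.0)
        model = uniform_sequence_model(7, 20)
        a = simulate_protocol(spec, template_maps, model, model, seed=11)
        b = simulate_protocol(spec, template_maps, model, model, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.recording.data, y.recording.data)
            np.testing.assert_array_equal(x.labels.labels, y.labels.labels)


class TestCorrelatedPm1:
    def test_values_are_pm1(self):
        x = sample_correlated_pm1(0.7, 1000, seed=0)
        assert set(np.unique(x)) <= {-1, 1}

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sample_correlated_pm1(0.5, 100, seed=0)

    def test_invalid_hurst_raises(self):
        with pytest.raises(ValueError):
            sample_correlated_pm1(1.2, 1000, seed=0)
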