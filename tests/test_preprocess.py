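import numpy as np
import pytest
from dataclasses import replace

from capnoshape import (
    CapnogramRecord,
    cohort_preset,
    denoise,
    process_record,
    qc_breath,
    qc_capnogram,
    segment_phases,
    separate_breaths,
    simulate_capnogram,
)
from capnoshape.preprocess import (
    BreathSpan,
    PreprocessConfig,
    QCReason,
    QCResult,
    SegmentationError,
)
from capnoshape.simulate import ArtefactSpec, CohortPreset

from conftest import match_annotation


def rec_from(p, fs=10.0):
    return CapnogramRecord("t", "other", "", fs, np.asarray(p, float))


class TestDenoise:
    def test_constant_preserved(self):
        d = denoise(rec_from(np.full(100, 3.0)))
        np.testing.assert_allclose(d.pco2_kpa, 3.0, atol=1e-9)

    def test_single_sample_spike_suppressed_tenfold(self):
        p = np.full(200, 3.0)
        p[100] += 2.0
        d = denoise(rec_from(p))
        assert np.max(np.abs(d.pco2_kpa - 3.0)) < 0.2

    def test_4hz_tone_attenuated_below_10pct(self):
        t = np.arange(400) / 10.0
        s = 3 + np.sin(2 * np.pi * 4.0 * t)
        d = denoise(rec_from(s))
        assert np.sqrt(np.mean((d.pco2_kpa - 3) ** 2)) < 0.1

    def test_idempotent_on_clean_recording(self):
        # baseline raised so the non-negativity clip never engages
        pr = cohort_preset("healthy")
        raised = CohortPreset(
            "healthy", replace(pr.params, p_base=0.3), pr.target_alpha_deg)
        rec = simulate_capnogram(raised, seed=3, breath_variability=0.05)
        d1 = denoise(rec)
        d2 = denoise(d1)
        assert np.max(np.abs(d2.pco2_kpa - d1.pco2_kpa)) < 1e-6

    def test_length_preserved(self, healthy_record):
        assert len(denoise(healthy_record).pco2_kpa) == \
            len(healthy_record.pco2_kpa)

    def test_sampling_rate_too_low_for_cutoff(self):
        cfg = PreprocessConfig(lowpass_cutoff_hz=6.0)
        with pytest.raises(ValueError, match="cutoff"):
            denoise(rec_from(np.ones(50)), cfg)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            denoise(rec_from(np.ones(5)))


class TestBreathSeparation:
    def test_constant_signal_yields_nothing(self):
        assert separate_breaths(rec_from(np.full(300, 3.0))) == []

    def test_clean_record_spans_match_truth(self, healthy_clean_record):
        den = denoise(healthy_clean_record)
        spans = separate_breaths(den)
        complete = [s for s in spans if s.complete]
        assert len(complete) == 18
        assert not spans[0].complete and not spans[-1].complete
        for span in complete:
            _, err = match_annotation(healthy_clean_record, span)
            assert err <= 2

    def test_one_breath_flanked_by_partials(self):
        rec = simulate_capnogram(cohort_preset("healthy"), duration_s=8.0,
                                 breath_variability=0.0, seed=2)
        spans = separate_breaths(denoise(rec))
        assert sum(s.complete for s in spans) == 1
        assert sum(not s.complete for s in spans) == 2

    def test_spans_ordered_and_non_overlapping(self, processed_healthy):
        spans = processed_healthy.spans
        for a, b in zip(spans[:-1], spans[1:]):
            assert a.end_idx == b.start_idx


class TestPhaseSegmentation:
    def test_boundaries_within_two_samples_of_truth(self, healthy_clean_record):
        res = process_record(healthy_clean_record)
        fs = healthy_clean_record.sampling_rate_hz
        checked = 0
        for span, seg in zip(res.spans, res.segmentations):
            if seg is None:
                continue
            ann, _ = match_annotation(healthy_clean_record, span)
            L = span.end_idx - span.start_idx
            for k in (1, 2, 3):
                truth_idx = span.start_idx + ann["bounds_frac"][k] * L
                assert abs(seg.boundaries[k] - truth_idx) <= 2
            checked += 1
        assert checked >= 16

    def test_each_phase_keeps_two_samples(self, processed_healthy):
        for seg in processed_healthy.segmentations:
            if seg is None:
                continue
            b = seg.boundaries
            assert all(y - x >= 2 for x, y in zip(b[:-1], b[1:]))

    def test_square_wave_collapses_transitions(self):
        p = np.concatenate([
            np.zeros(10), np.full(20, 5.0), np.zeros(10)])
        seg = segment_phases(rec_from(p), BreathSpan(0, 40))
        b = seg.boundaries
        assert b[2] - b[1] <= 3          # phase II is a 2-sample jump
        assert abs(seg.tangents[2].slope) < 0.05  # flat plateau tangent

    def test_flat_span_fails_loudly(self):
        with pytest.raises(SegmentationError):
            segment_phases(rec_from(np.full(40, 3.0)), BreathSpan(0, 40))

    def test_swallow_never_yields_silent_nonsense(self):
        rec = simulate_capnogram(
            cohort_preset("healthy"), seed=21,
            artefacts=ArtefactSpec(swallow_rate_per_min=10.0),
            breath_variability=0.05,
        )
        res = process_record(rec)
        labelled = rejected = 0
        for span, qc in zip(res.spans, res.qc_results):
            if not span.complete:
                continue
            ann, _ = match_annotation(rec, span)
            if "swallow" in ann["artefacts"]:
                labelled += 1
                rejected += (not qc.valid)
        assert labelled >= 5
        assert rejected / labelled >= 0.8


class TestBreathQC:
    def test_clean_breaths_pass(self, processed_healthy):
        valid = [q for s, q in zip(processed_healthy.spans,
                                   processed_healthy.qc_results)
                 if s.complete and q.valid]
        assert len(valid) >= 16

    def test_low_amplitude_flagged(self):
        params = replace(
            cohort_preset("healthy").params,
            etco2=0.8, p_base=0.1, plateau_slope=0.1, noise_sd_kpa=0.01,
            plateau_ripple_kpa=0.0,
        )
        rec = simulate_capnogram(
            CohortPreset("faint", params, 100.0), seed=3)
        res = process_record(rec)
        reasons = [r for q in res.qc_results for r in q.reasons]
        assert QCReason.amplitude_too_low in reasons

    def test_overlong_breath_flagged(self):
        params = replace(cohort_preset("healthy").params,
                         breath_duration_s=16.0)
        rec = simulate_capnogram(CohortPreset("slow", params, 100.0),
                                 duration_s=48.0, seed=4)
        res = process_record(rec)
        reasons = [r for q in res.qc_results for r in q.reasons]
        assert QCReason.duration_out_of_range in reasons

    def test_cough_flagged_with_cause(self):
        hits = total = 0
        for seed in range(6):
            rec = simulate_capnogram(
                cohort_preset("healthy"), seed=100 + seed,
                artefacts=ArtefactSpec(cough_rate_per_min=8.0),
                breath_variability=0.05,
            )
            res = process_record(rec)
            for span, qc in zip(res.spans, res.qc_results):
                if not span.complete:
                    continue
                ann, _ = match_annotation(rec, span)
                if "cough" in ann["artefacts"]:
                    total += 1
                    hits += any(r == QCReason.cough for r in qc.reasons)
        assert total >= 20
        assert hits / total >= 0.9

    def test_cardiogenic_ripple_flagged(self):
        rec = simulate_capnogram(
            cohort_preset("healthy"), seed=31,
            artefacts=ArtefactSpec(cardiogenic_amplitude_kpa=0.15,
                                   cardiogenic_freq_hz=1.2),
            breath_variability=0.05,
        )
        res = process_record(rec)
        flagged = sum(QCReason.cardiogenic in q.reasons
                      for s, q in zip(res.spans, res.qc_results)
                      if s.complete)
        assert flagged >= 0.7 * res.qc_report.n_breaths_total


class TestRecordingQC:
    def test_perfect_quality_is_100pct(self, healthy_clean_record):
        report = process_record(healthy_clean_record).qc_report
        assert report.breath_quality_pct == 100.0
        assert report.recording_valid

    def test_condensation_drift_rejects_recording(self):
        rec = simulate_capnogram(
            cohort_preset("healthy"), seed=8,
            artefacts=ArtefactSpec(condensation_drift_kpa_per_min=0.3),
            breath_variability=0.05,
        )
        report = process_record(rec).qc_report
        assert not report.recording_valid
        assert QCReason.condensation in report.recording_reasons

    def test_too_few_valid_breaths_rejects_recording(self, healthy_record):
        den = denoise(healthy_record)
        spans = separate_breaths(den)
        # force most breaths invalid
        results = [
            QCResult((QCReason.cough,)) if i % 3 else QCResult()
            for i in range(len(spans))
        ]
        report = qc_capnogram(den, spans, results)
        assert report.n_breaths_valid < 8
        assert not report.recording_valid
        assert QCReason.too_few_valid_breaths in report.recording_reasons

    def test_quality_pct_arithmetic(self, healthy_record):
        den = denoise(healthy_record)
        spans = separate_breaths(den)
        results = [QCResult() for _ in spans]
        report = qc_capnogram(den, spans, results)
        assert report.breath_quality_pct == 100.0
        assert report.n_breaths_total == sum(s.complete for s in spans)
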