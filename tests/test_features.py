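import math

import numpy as np
import pytest
from dataclasses import replace

from capnoshape import (
    CapnogramRecord,
    aggregate,
    angles_from_slopes,
    cohort_preset,
    compute_angles,
    normalize_breath,
    whole_capnogram_features,
)
from capnoshape.features import (
    BreathFeatureSet,
    normalized_features,
    segment_normalized,
)
from capnoshape.preprocess import BreathSpan, QCReport, segment_phases
from capnoshape.simulate import COHORT_PRESETS, simulate_breath


def rec_from(p, fs=10.0):
    return CapnogramRecord("t", "other", "", fs, np.asarray(p, float))


class TestAngles:
    def test_square_wave_limits(self):
        a, b, _, _ = angles_from_slopes(0.0, 1e15, 0.0, -1e15)
        assert a == pytest.approx(90.0, abs=1e-6)
        assert b == pytest.approx(90.0, abs=1e-6)

    def test_arctangent_formula_fixture(self):
        # m2 = 16, m3 = 0.15 -> alpha = 180 - (86.42 - 8.53)
        a, _, _, _ = angles_from_slopes(0.0, 16.0, 0.15, -10.0)
        assert a == pytest.approx(
            180.0 - (math.degrees(math.atan(16.0))
                     - math.degrees(math.atan(0.15))), abs=1e-12)
        assert a == pytest.approx(102.1, abs=0.05)

    def test_gamma_uses_next_baseline_with_fallback(self):
        a1 = angles_from_slopes(0.05, 12.0, 0.2, -9.0, m1_next=0.10)
        a2 = angles_from_slopes(0.05, 12.0, 0.2, -9.0)
        assert a1[2] != a2[2]
        assert a2[2] == pytest.approx(
            180.0 - (math.degrees(math.atan(0.05))
                     - math.degrees(math.atan(-9.0))), abs=1e-12)

    @pytest.mark.parametrize("name", sorted(COHORT_PRESETS))
    def test_extractor_matches_analytic_truth_noise_free(self, name):
        """Oracle equivalence: extracted angles within 1 degree of the
        dense-grid analytic truth for every preset."""
        params = replace(cohort_preset(name).params,
                         noise_sd_kpa=0.0, plateau_ripple_kpa=0.0)
        samples, truth = simulate_breath(params, 25.0)
        seg = segment_phases(rec_from(samples, 25.0),
                             BreathSpan(0, len(samples)))
        measured = compute_angles(seg)
        for got, key in zip(measured, ("alpha_deg", "beta_deg",
                                       "gamma_deg", "delta_deg")):
            assert got == pytest.approx(truth[key], abs=1.0)


@pytest.fixture(scope="module")
def flat_breath():
    """Ideal trapezoid: baseline 0, sharp shoulders, plateau flat at 5."""
    p = np.concatenate([
        np.zeros(10), np.linspace(0, 5, 6)[1:-1], np.full(20, 5.0),
        np.linspace(5, 0, 6)[1:-1], np.zeros(10),
    ])
    rec = rec_from(p, 10.0)
    span = BreathSpan(0, len(p))
    from capnoshape.features import per_breath_features

    seg = segment_phases(rec, span)
    return per_breath_features(rec, span, seg)


class TestPerBreathFeatures:

    def test_flat_plateau_etco2_and_flatness(self, flat_breath):
        v = flat_breath.values
        assert v["etco2_kpa"] == pytest.approx(5.0, abs=0.02)
        assert v["plateau_flatness"] == pytest.approx(1.0, abs=0.02)

    def test_flat_plateau_chord_area_vanishes(self, flat_breath):
        assert flat_breath.values["area_above_chord"] == \
            pytest.approx(0.0, abs=0.01)

    def test_exactly_87_features(self, flat_breath):
        assert len(flat_breath.values) == 87

    def test_feature_set_size_enforced(self):
        with pytest.raises(ValueError, match="87"):
            BreathFeatureSet({"only": 1.0})


class TestNormalization:
    def test_breath_on_grid_is_identity(self):
        p = np.linspace(0, 5, 50)
        wave = normalize_breath(rec_from(p), BreathSpan(0, 50), grid_size=50)
        np.testing.assert_allclose(wave, p, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        p = np.linspace(1.0, 4.0, 30)
        wave = normalize_breath(rec_from(p), BreathSpan(0, 30), grid_size=100)
        np.testing.assert_allclose(np.diff(wave, 2), 0.0, atol=1e-12)

    def test_grid_of_two_keeps_endpoints(self):
        p = np.array([1.0, 2.0, 7.0])
        wave = normalize_breath(rec_from(p), BreathSpan(0, 3), grid_size=2)
        np.testing.assert_allclose(wave, [1.0, 7.0])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_breath(rec_from([1.0]), BreathSpan(0, 1))
        with pytest.raises(ValueError):
            normalize_breath(rec_from([1.0, 2.0, 3.0]), BreathSpan(0, 3),
                             grid_size=1)

    def test_breath_duration_absent_from_normalized_set(self):
        samples, _ = simulate_breath(
            replace(cohort_preset("healthy").params, noise_sd_kpa=0.0), 10.0)
        wave = normalize_breath(rec_from(samples),
                                BreathSpan(0, len(samples)))
        feats = normalized_features(wave)
        assert "norm_breath_duration_s" not in feats
        assert len(feats) == 43

    def test_amplitude_features_survive_normalization(self):
        samples, _ = simulate_breath(
            replace(cohort_preset("healthy").params, noise_sd_kpa=0.0), 10.0)
        rec = rec_from(samples)
        span = BreathSpan(0, len(samples))
        seg = segment_phases(rec, span)
        from capnoshape.features import per_breath_features

        fs = per_breath_features(rec, span, seg,
                                 grid_size=len(samples)).values
        assert fs["norm_etco2_kpa"] == pytest.approx(
            fs["etco2_kpa"], abs=1e-3)
        assert fs["norm_baseline_kpa"] == pytest.approx(
            fs["baseline_kpa"], abs=2e-3)

    def test_time_dilation_invariance(self):
        """Two breaths identical up to a uniform time dilation produce
        identical normalized feature sets."""
        base = replace(cohort_preset("asthma").params,
                       noise_sd_kpa=0.0, plateau_ripple_kpa=0.0)
        s1, _ = simulate_breath(base, 10.0)                    # 4.2 s at 10 Hz
        dilated = replace(base, breath_duration_s=2 * base.breath_duration_s)
        s2, _ = simulate_breath(dilated, 5.0)                  # 8.4 s at 5 Hz
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        w1 = normalize_breath(rec_from(s1, 10.0), BreathSpan(0, len(s1)))
        w2 = normalize_breath(rec_from(s2, 5.0), BreathSpan(0, len(s2)))
        f1 = normalized_features(w1)
        f2 = normalized_features(w2)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-3), name


def make_feature_sets(registry, n, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n):
        vals = {
            name: 1.0 + (jitter * rng.normal() if jitter else 0.0)
            for name in registry.per_breath_names
        }
        vals["breath_duration_s"] = 4.0
        vals["etco2_kpa"] = 5.0
        sets.append(BreathFeatureSet(vals, registry_version=registry.version))
    return sets


class TestWholeAndAggregate:
    def test_respiratory_rate_arithmetic(self, registry, healthy_record):
        # 18 valid breaths spanning 72 s of breathing -> 15 / min
        sets = make_feature_sets(registry, 18)
        spans = [BreathSpan(40 * i, 40 * (i + 1)) for i in range(18)]
        report = QCReport(18, 18, 100.0, True)
        whole = whole_capnogram_features(healthy_record, spans, report, sets)
        assert whole["resp_rate_per_min"] == pytest.approx(15.0)
        assert whole["ibi_cv"] == pytest.approx(0.0, abs=1e-12)
        assert whole["etco2_trend_kpa_min"] == pytest.approx(0.0, abs=1e-9)
        assert whole["n_valid_breaths"] == 18

    def test_too_few_breaths_is_an_error(self, registry, healthy_record):
        sets = make_feature_sets(registry, 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            whole_capnogram_features(
                healthy_record, [BreathSpan(0, 40)],
                QCReport(1, 1, 100.0, True), sets)

    def test_identical_breaths_zero_sd(self, registry, healthy_record):
        sets = make_feature_sets(registry, 10)
        whole = {n: 1.0 for n in registry.whole_names}
        vec = aggregate(sets, whole, registry, record=healthy_record)
        assert len(vec.features) == 159
        for name in registry.sd_names:
            assert vec.features[f"sd_{name}"] == 0.0

    def test_median_invariant_to_duplication(self, registry, healthy_record):
        sets = make_feature_sets(registry, 9, jitter=0.3, seed=5)
        whole = {n: 1.0 for n in registry.whole_names}
        v1 = aggregate(sets, whole, registry, record=healthy_record)
        v2 = aggregate(sets + sets, whole, registry, record=healthy_record)
        for name in registry.per_breath_names:
            assert v1.features[f"median_{name}"] == pytest.approx(
                v2.features[f"median_{name}"], abs=1e-12)

    def test_below_minimum_breaths_rejected(self, registry, healthy_record):
        sets = make_feature_sets(registry, 5)
        whole = {n: 1.0 for n in registry.whole_names}
        with pytest.raises(ValueError, match="minimum"):
            aggregate(sets, whole, registry, record=healthy_record)
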