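import numpy as np
import pytest

from capnoshape import cohort_preset, default_registry, process_record, simulate_capnogram

PRESET_NAMES = (
    "healthy",
    "asthma",
    "chf",
    "pneumonia_acute",
    "pneumonia_recovered",
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def healthy_record():
    """One 75 s healthy recording with mild breath-to-breath variability."""
    return simulate_capnogram(
        cohort_preset("healthy"), seed=42, breath_variability=0.05
    )


@pytest.fixture(scope="session")
def healthy_clean_record():
    """Noise-free, zero-variability healthy recording (oracle fixture)."""
    from dataclasses import replace

    from capnoshape.simulate import CohortPreset

    pr = cohort_preset("healthy")
    quiet = CohortPreset(
        pr.name,
        replace(pr.params, noise_sd_kpa=0.0, plateau_ripple_kpa=0.0),
        pr.target_alpha_deg,
    )
    return simulate_capnogram(quiet, seed=7, breath_variability=0.0)


@pytest.fixture(scope="session")
def processed_healthy(healthy_record):
    return process_record(healthy_record)


def annotation_by_span(record):
    """Map annotated breath truth by span start index."""
    return {b["span_start_idx"]: b for b in record.annotations["breaths"]}


def match_annotation(record, span):
    ann = annotation_by_span(record)
    key = min(ann, key=lambda k: abs(k - span.start_idx))
    return ann[key], abs(key - span.start_idx)
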