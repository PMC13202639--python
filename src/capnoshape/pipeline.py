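"""End-to-end processing of one or many capnogram recordings.

``process_record`` runs denoise -> breath separation -> phase segmentation
-> breath QC -> recording QC -> per-breath feature extraction -> median/SD
aggregation, returning the intermediate artefacts alongside the final
159-entry feature vector (``None`` when the recording fails QC or has too
few valid breaths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import (
    BreathFeatureSet,
    CapnogramFeatureVector,
    aggregate,
    normalize_breath,
    per_breath_features,
    segment_normalized,
    whole_capnogram_features,
)
from .io import CapnogramRecord
from .preprocess import (
    DEFAULT_CONFIG,
    BreathSpan,
    PhaseSegmentation,
    PreprocessConfig,
    QCReport,
    QCResult,
    SegmentationError,
    denoise,
    qc_breath,
    qc_capnogram,
    segment_phases,
    separate_breaths,
)
from .registry import FeatureRegistry, default_registry

__all__ = ["ProcessResult", "process_record", "extract_feature_table"]


@dataclass
class ProcessResult:
    record: CapnogramRecord                      # denoised
    spans: list[BreathSpan]
    segmentations: list[PhaseSegmentation | None]
    qc_results: list[QCResult]
    qc_report: QCReport
    feature_sets: list[BreathFeatureSet | None] = field(repr=False)
    normalized_waveforms: list = field(repr=False)
    vector: CapnogramFeatureVector | None = None

    @property
    def valid_normalized_waveforms(self) -> list:
        return [w for w in self.normalized_waveforms if w is not None]


def process_record(
    record: CapnogramRecord,
    registry: FeatureRegistry | None = None,
    config: PreprocessConfig = DEFAULT_CONFIG,
    grid_size: int = 100,
) -> ProcessResult:
    """Run the full single-recording pipeline."""
    registry = registry or default_registry()
    den = denoise(record, config)
    spans = separate_breaths(den, config)

    segs: list[PhaseSegmentation | None] = []
    for span in spans:
        if not span.complete:
            segs.append(None)
            continue
        try:
            segs.append(segment_phases(den, span, config))
        except SegmentationError:
            segs.append(None)

    qc_results = [
        qc_breath(den, span, seg, config) for span, seg in zip(spans, segs)
    ]
    report = qc_capnogram(den, spans, qc_results, segs, config)

    # normalized waveforms and their segmentations for QC-valid breaths
    waves: list = [None] * len(spans)
    norm_segs: list = [None] * len(spans)
    for i, (span, seg, qc) in enumerate(zip(spans, segs, qc_results)):
        if not span.complete or seg is None or not qc.valid:
            continue
        wave = normalize_breath(den, span, grid_size)
        try:
            norm_segs[i] = segment_normalized(wave, config)
            waves[i] = wave
        except SegmentationError:
            pass

    feature_sets: list[BreathFeatureSet | None] = [None] * len(spans)
    for i, (span, seg, qc) in enumerate(zip(spans, segs, qc_results)):
        if seg is None or not qc.valid or waves[i] is None:
            continue
        nxt = next(
            (segs[j] for j in range(i + 1, len(spans)) if segs[j] is not None),
            None,
        )
        nxt_norm = next(
            (norm_segs[j] for j in range(i + 1, len(spans))
             if norm_segs[j] is not None),
            None,
        )
        try:
            feature_sets[i] = per_breath_features(
                den, span, seg,
                next_phase1=nxt.tangents[0] if nxt else None,
                config=config, grid_size=grid_size,
                next_phase1_norm=nxt_norm.tangents[0] if nxt_norm else None,
                registry=registry,
            )
        except SegmentationError:
            pass

    vector = None
    valid_sets = [f for f in feature_sets if f is not None]
    if report.recording_valid and len(valid_sets) >= config.min_valid_breaths:
        whole = whole_capnogram_features(den, spans, report, feature_sets)
        vector = aggregate(
            valid_sets, whole, registry, record=record,
            min_breaths=config.min_valid_breaths,
        )
    return ProcessResult(
        record=den,
        spans=spans,
        segmentations=segs,
        qc_results=qc_results,
        qc_report=report,
        feature_sets=feature_sets,
        normalized_waveforms=waves,
        vector=vector,
    )


def extract_feature_table(
    records: list[CapnogramRecord],
    registry: FeatureRegistry | None = None,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Process many recordings into one feature table (rows that fail QC
    are dropped)."""
    registry = registry or default_registry()
    rows = []
    for rec in records:
        res = process_record(rec, registry, config)
        if res.vector is None:
            continue
        row = {
            "subject_id": res.vector.subject_id,
            "cohort": res.vector.cohort,
            "recorded_at": res.vector.recorded_at,
            "n_valid_breaths": res.vector.n_valid_breaths,
        }
        row.update(res.vector.features)
        rows.append(row)
    columns = ["subject_id", "cohort", "recorded_at", "n_valid_breaths"]
    columns += registry.vector_names
    return pd.DataFrame(rows, columns=columns)
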