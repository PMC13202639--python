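"""Per-breath geometric features, time normalization, and aggregation.

Angle coordinate frame
----------------------
Capnogram corner angles (alpha, beta, gamma, delta) depend on the aspect
ratio of the axes they are drawn in, so the package fixes a frame: each
breath's time axis is rescaled to [0, 1] and pCO2 is divided by a reference
pressure P_ref = 5 kPa.  In this frame an ideal square wave has vertical
transitions and the alpha and beta corners are exactly 90 degrees; typical
healthy tidal breaths land near 100-105 degrees.

With ``m_i`` the fitted tangent slope of phase *i* in that frame and
``theta_i = atan(m_i)`` in degrees:

* ``alpha = 180 - (theta_2 - theta_3)`` — upstroke-to-plateau corner; widens
  with airway obstruction,
* ``beta  = 180 - (theta_3 - theta_4)`` — plateau-to-downstroke corner,
* ``delta = 180 - (theta_2 - theta_1)`` — baseline-to-upstroke corner,
* ``gamma = 180 - (theta_1' - theta_4)`` — downstroke to the *following*
  baseline (falling back to the current baseline tangent for the last
  breath of a recording).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CapnogramRecord
from .preprocess import (
    DEFAULT_CONFIG,
    BreathSpan,
    P_REF_KPA,
    PhaseSegmentation,
    PreprocessConfig,
    QCReport,
    Tangent,
    _detrended,
    band_power_fraction,
    segment_phases,
)
from .registry import FeatureRegistry, default_registry

__all__ = [
    "BreathFeatureSet",
    "CapnogramFeatureVector",
    "angles_from_slopes",
    "compute_angles",
    "per_breath_features",
    "normalize_breath",
    "normalized_features",
    "whole_capnogram_features",
    "aggregate",
]

#: periodogram band for plateau oscillation power: Hz in the raw domain,
#: cycles-per-breath in the normalized domain (2-12 cycles/breath matches
#: 0.5-3 Hz at a typical 4 s breath and keeps the normalized feature
#: invariant under uniform time dilation).
RAW_OSC_BAND_HZ = (0.5, 3.0)
NORM_OSC_BAND = (2.0, 12.0)

_SAMPEN_CAP = 5.0


def angles_from_slopes(
    m1: float,
    m2: float,
    m3: float,
    m4: float,
    m1_next: float | None = None,
) -> tuple[float, float, float, float]:
    """(alpha, beta, gamma, delta) in degrees from angle-frame tangent slopes.

    Infinite slopes are taken in the limit (theta -> +/-90 deg), so the
    square-wave limit ``m2 -> inf, m3 = 0`` gives alpha = 90 exactly.
    """
    th1, th2, th3, th4 = (math.degrees(math.atan(m)) for m in (m1, m2, m3, m4))
    th1n = math.degrees(math.atan(m1_next)) if m1_next is not None else th1
    alpha = 180.0 - (th2 - th3)
    beta = 180.0 - (th3 - th4)
    delta = 180.0 - (th2 - th1)
    gamma = 180.0 - (th1n - th4)
    return alpha, beta, gamma, delta


def compute_angles(
    seg: PhaseSegmentation, next_phase1: Tangent | None = None
) -> tuple[float, float, float, float]:
    """Corner angles of one segmented breath; ``next_phase1`` is the
    following breath's baseline tangent (used by gamma)."""
    m = [t.slope for t in seg.tangents]
    mn = next_phase1.slope if next_phase1 is not None else None
    return angles_from_slopes(m[0], m[1], m[2], m[3], mn)


# ---------------------------------------------------------------------------
# per-breath features
# ---------------------------------------------------------------------------

def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy of a short series; capped where undefined."""
    x = np.asarray(x, float)
    n = len(x)
    sd = float(np.std(x))
    if n < m + 2 or sd == 0:
        return 0.0
    r = r_frac * sd

    def count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        return int((np.sum(d <= r) - len(templ)) // 2)

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return _SAMPEN_CAP
    return float(min(_SAMPEN_CAP, -np.log(a / b)))


def _osc_power_fraction(
    plate: np.ndarray, t: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    if len(plate) < 8:
        return 0.0
    resid = _detrended(t, plate)
    if np.var(resid) == 0:
        return 0.0
    return band_power_fraction(resid, fs, band)[0]


def _crossing_time(
    p: np.ndarray, t: np.ndarray, start: int, level: float, rising: bool
) -> float | None:
    """Time after ``t[start]`` at which p first crosses ``level``
    (sub-sample linear interpolation)."""
    seg = p[start:]
    hit = np.nonzero(seg >= level if rising else seg <= level)[0]
    if len(hit) == 0:
        return None
    j = int(hit[0])
    if j == 0:
        return 0.0
    p0, p1 = seg[j - 1], seg[j]
    frac = 0.0 if p1 == p0 else (level - p0) / (p1 - p0)
    return t[start + j - 1] + frac * (t[start + j] - t[start + j - 1]) - t[start]


def _raw_feature_dict(
    p: np.ndarray,
    fs: float,
    seg_bounds: tuple[int, ...],
    tangents: tuple[Tangent, ...],
    angles: tuple[float, float, float, float],
    osc_band: tuple[float, float],
) -> dict[str, float]:
    """The 44 raw-domain features for one breath (local indices)."""
    b = seg_bounds
    L = len(p)
    t = np.arange(L) / fs
    duration = L / fs
    alpha, beta, gamma, delta = angles

    dur = [(b[k + 1] - b[k]) / fs for k in range(4)]
    # baseline over the central 60% of phase I (avoids the downstroke tail
    # that the span convention leaves at the start of the phase)
    n1 = b[1] - b[0]
    k = int(round(0.2 * n1))
    ph1 = p[b[0] + k: b[1] - k] if n1 - 2 * k >= 1 else p[b[0]:b[1]]
    baseline = float(np.mean(ph1))
    ph3 = p[b[2]:b[3]]
    etco2 = float(np.max(ph3))
    amplitude = etco2 - baseline
    plateau_mean = float(np.mean(ph3))

    area_total = float(np.trapezoid(p - baseline, t))
    area2 = float(np.trapezoid(p[b[1]:b[2]] - baseline, t[b[1]:b[2]]))
    area3 = float(np.trapezoid(ph3 - baseline, t[b[2]:b[3]]))
    chord = np.linspace(ph3[0], ph3[-1], len(ph3))
    area_chord = float(np.trapezoid(ph3 - chord, t[b[2]:b[3]]))

    def up_time(q: float) -> float:
        v = _crossing_time(p, t, b[1], baseline + q * amplitude, rising=True)
        return v if v is not None else dur[1] + dur[2]

    def down_time(q: float) -> float:
        v = _crossing_time(p, t, b[3], baseline + q * amplitude, rising=False)
        return v if v is not None else dur[3]

    deriv = np.gradient(p) * fs
    d2 = np.gradient(deriv) * fs
    span_frac = max(L - 1, 1)
    pos_etco2 = (b[2] + int(np.argmax(ph3))) / span_frac
    pos_up = (b[1] + int(np.argmax(deriv[b[1]:b[2]]))) / span_frac
    pos_down = (b[3] + int(np.argmin(deriv[b[3]:b[4]]))) / span_frac

    ph2_d = deriv[b[1]:b[2]]
    half = max(1, len(ph2_d) // 2)
    mean_second = float(np.mean(ph2_d[half:]))
    asym = float(np.mean(ph2_d[:half])) / max(mean_second, 1e-9)

    t3 = t[b[2]:b[3]]
    return {
        "alpha_deg": alpha,
        "beta_deg": beta,
        "gamma_deg": gamma,
        "delta_deg": delta,
        "grad_phase1": tangents[0].slope,
        "grad_phase2": tangents[1].slope,
        "grad_phase3": tangents[2].slope,
        "grad_phase4": tangents[3].slope,
        "dur_phase1_s": dur[0],
        "dur_phase2_s": dur[1],
        "dur_phase3_s": dur[2],
        "dur_phase4_s": dur[3],
        "breath_duration_s": duration,
        "expiratory_time_s": dur[1] + dur[2],
        "inspiratory_time_s": dur[3] + dur[0],
        "ei_ratio": (dur[1] + dur[2]) / max(dur[3] + dur[0], 1e-9),
        "etco2_kpa": etco2,
        "baseline_kpa": baseline,
        "amplitude_kpa": amplitude,
        "plateau_mean_kpa": plateau_mean,
        "area_total": area_total,
        "area_phase2": area2,
        "area_phase3": area3,
        "area_above_chord": area_chord,
        "t_up_25": up_time(0.25),
        "t_up_50": up_time(0.50),
        "t_up_75": up_time(0.75),
        "t_down_75": down_time(0.75),
        "t_down_50": down_time(0.50),
        "t_down_25": down_time(0.25),
        "pos_etco2": pos_etco2,
        "pos_max_upslope": pos_up,
        "pos_max_downslope": pos_down,
        "ratio_dur_2_3": dur[1] / max(dur[2], 1e-9),
        "area_per_s": area_total / duration,
        "amplitude_per_s": amplitude / duration,
        "max_upslope": float(np.max(ph2_d)),
        "upslope_asymmetry": float(np.clip(asym, -1e3, 1e3)),
        "plateau_d2_mean": float(np.mean(d2[b[2]:b[3]])),
        "plateau_flatness": 1.0 - (float(np.ptp(ph3)) / amplitude
                                   if amplitude > 0 else 0.0),
        "resid_rms_phase2": tangents[1].resid_rms,
        "resid_rms_phase3": tangents[2].resid_rms,
        "plateau_sampen": _sample_entropy(_detrended(t3, ph3)),
        "plateau_osc_power": _osc_power_fraction(ph3, t3, fs, osc_band),
    }


@dataclass
class BreathFeatureSet:
    """87 named per-breath feature values (44 raw + 43 normalized)."""

    values: dict[str, float]
    valid: bool = True
    registry_version: str = "default_v1"

    def __post_init__(self) -> None:
        if len(self.values) != 87:
            raise ValueError(
                f"expected 87 per-breath features, got {len(self.values)}"
            )


def per_breath_features(
    record: CapnogramRecord,
    span: BreathSpan,
    seg: PhaseSegmentation,
    next_phase1: Tangent | None = None,
    config: PreprocessConfig = DEFAULT_CONFIG,
    grid_size: int = 100,
    next_phase1_norm: Tangent | None = None,
    registry: FeatureRegistry | None = None,
) -> BreathFeatureSet:
    """Evaluate the full 87-feature per-breath registry for one valid breath.

    Raises :class:`~capnoshape.preprocess.SegmentationError` if the
    time-normalized waveform cannot be re-segmented on the grid.
    """
    registry = registry or default_registry()
    p = record.pco2_kpa[span.start_idx:span.end_idx]
    fs = record.sampling_rate_hz
    local = tuple(i - span.start_idx for i in seg.boundaries)
    angles = compute_angles(seg, next_phase1)
    raw = _raw_feature_dict(p, fs, local, seg.tangents, angles, RAW_OSC_BAND_HZ)

    wave = normalize_breath(record, span, grid_size)
    norm = normalized_features(
        wave, config=config, next_phase1=next_phase1_norm
    )
    values = {**raw, **norm}
    missing = set(registry.per_breath_names) - set(values)
    if missing:
        raise RuntimeError(f"features missing from evaluation: {missing}")
    return BreathFeatureSet(
        {n: float(values[n]) for n in registry.per_breath_names},
        registry_version=registry.version,
    )


def normalize_breath(
    record: CapnogramRecord, span: BreathSpan, grid_size: int = 100
) -> np.ndarray:
    """Linear interpolation of one breath onto ``grid_size`` points equally
    spaced over [breath start, breath end]; pCO2 values unchanged."""
    p = record.pco2_kpa[span.start_idx:span.end_idx]
    if len(p) < 2:
        raise ValueError("breath span shorter than 2 samples")
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    x_old = np.arange(len(p)) / (len(p) - 1)
    grid = np.linspace(0.0, 1.0, grid_size)
    return np.interp(grid, x_old, p)


def segment_normalized(
    wave: np.ndarray, config: PreprocessConfig = DEFAULT_CONFIG
) -> PhaseSegmentation:
    """Re-run phase segmentation on a time-normalized waveform."""
    rec = CapnogramRecord(
        subject_id="_norm",
        cohort="other",
        recorded_at="",
        sampling_rate_hz=float(len(wave) - 1),
        pco2_kpa=np.asarray(wave, float),
    )
    return segment_phases(rec, BreathSpan(0, len(wave)), config)


def normalized_features(
    wave: np.ndarray,
    config: PreprocessConfig = DEFAULT_CONFIG,
    next_phase1: Tangent | None = None,
) -> dict[str, float]:
    """The 43 normalized-domain features (raw set minus breath duration),
    re-evaluated on the unit-time grid after re-segmentation."""
    seg = segment_normalized(wave, config)
    fs = float(len(wave) - 1)  # unit total duration
    angles = compute_angles(seg, next_phase1)
    raw = _raw_feature_dict(
        np.asarray(wave, float), fs, seg.boundaries, seg.tangents, angles,
        NORM_OSC_BAND,
    )
    del raw["breath_duration_s"]
    return {f"norm_{k}": v for k, v in raw.items()}


# ---------------------------------------------------------------------------
# whole-capnogram features and aggregation
# ---------------------------------------------------------------------------

def whole_capnogram_features(
    record: CapnogramRecord,
    spans: list[BreathSpan],
    qc_report: QCReport,
    feature_sets: list[BreathFeatureSet | None],
) -> dict[str, float]:
    """Respiratory rate, inter-breath-interval CV, ETCO2 trend, valid-breath
    count and breath quality for one recording."""
    fs = record.sampling_rate_hz
    durations, etco2s, mids = [], [], []
    for span, fset in zip(spans, feature_sets):
        if fset is None or not span.complete:
            continue
        durations.append(fset.values["breath_duration_s"])
        etco2s.append(fset.values["etco2_kpa"])
        mids.append(0.5 * (span.start_idx + span.end_idx) / fs)
    n_valid = len(durations)
    if n_valid < 2:
        raise ValueError("fewer than 2 valid breaths: recording should "
                         "have failed QC")
    total_t = float(np.sum(durations))
    rr = 60.0 * n_valid / total_t
    mean_d = float(np.mean(durations))
    ibi_cv = float(np.std(durations, ddof=1) / mean_d) if mean_d > 0 else 0.0
    trend = 60.0 * float(np.polyfit(mids, etco2s, 1)[0])
    return {
        "resp_rate_per_min": rr,
        "ibi_cv": ibi_cv,
        "etco2_trend_kpa_min": trend,
        "n_valid_breaths": float(n_valid),
        "breath_quality_pct": qc_report.breath_quality_pct,
    }


@dataclass
class CapnogramFeatureVector:
    """The 159 aggregated features of one capnogram (87 medians, 67 SDs,
    5 whole-capnogram metrics)."""

    subject_id: str
    cohort: str
    recorded_at: str
    n_valid_breaths: int
    features: dict[str, float] = field(repr=False)
    registry_version: str = "default_v1"

    def __post_init__(self) -> None:
        if len(self.features) != 159:
            raise ValueError(
                f"expected 159 aggregated features, got {len(self.features)}"
            )


def aggregate(
    feature_sets: list[BreathFeatureSet],
    whole: dict[str, float],
    registry: FeatureRegistry | None = None,
    record: CapnogramRecord | None = None,
    min_breaths: int = 8,
) -> CapnogramFeatureVector:
    """Median over valid breaths for all 87 per-breath features, sample SD
    (n-1 denominator) for the 67 SD-aggregated ones, plus the 5 whole-
    capnogram values: a 159-entry vector."""
    sets = [f for f in feature_sets if f is not None and f.valid]
    if len(sets) < min_breaths:
        raise ValueError(
            f"{len(sets)} valid breaths < required minimum {min_breaths}"
        )
    registry = registry or default_registry()
    versions = {f.registry_version for f in sets}
    if versions != {registry.version}:
        raise ValueError(f"registry version mismatch: {versions}")
    mat = {
        name: np.array([f.values[name] for f in sets])
        for name in registry.per_breath_names
    }
    features: dict[str, float] = {}
    for name in registry.per_breath_names:
        features[f"median_{name}"] = float(np.median(mat[name]))
    for name in registry.sd_names:
        features[f"sd_{name}"] = float(np.std(mat[name], ddof=1))
    for name in registry.whole_names:
        features[name] = float(whole[name])
    return CapnogramFeatureVector(
        subject_id=record.subject_id if record else "",
        cohort=record.cohort if record else "other",
        recorded_at=record.recorded_at if record else "",
        n_valid_breaths=len(sets),
        features=features,
        registry_version=registry.version,
    )
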