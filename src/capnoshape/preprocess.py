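"""Pipeline front end: denoising, breath separation, phase segmentation, QC.

The stages mirror how tidal-breathing capnograms are prepared for geometric
analysis:

1. :func:`denoise` — despike (Hampel) then zero-phase low-pass.
2. :func:`separate_breaths` — hysteresis threshold crossings of a rolling
   mid-amplitude envelope split the trace into breath spans.
3. :func:`segment_phases` — derivative rules locate phase I (inspiratory
   baseline), II (expiratory upstroke), III (alveolar plateau) and IV
   (inspiratory downstroke) inside each span and fit a least-squares tangent
   to each phase in the angle coordinate frame.
4. :func:`qc_breath` / :func:`qc_capnogram` — deterministic signal-quality
   rules flag coughs, swallows, cardiogenic oscillations, condensation
   drift, low amplitude and implausible durations.

All indices are 0-based and spans are half-open.  Every numeric threshold is
a field of :class:`PreprocessConfig`; the defaults define the package's
operating point (the artefact rule *classes* are standard, the numbers are
this package's own calibration).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import CapnogramRecord

__all__ = [
    "PreprocessConfig",
    "BreathSpan",
    "PhaseSegmentation",
    "SegmentationError",
    "QCReason",
    "QCResult",
    "QCReport",
    "denoise",
    "separate_breaths",
    "segment_phases",
    "qc_breath",
    "qc_capnogram",
]

#: reference pCO2 for the angle coordinate frame (kPa); breath time is
#: rescaled to [0, 1] and pressure divided by P_REF before tangents/angles
#: are computed, so an ideal square wave has 90-degree alpha/beta corners.
P_REF_KPA = 5.0


@dataclass(frozen=True)
class PreprocessConfig:
    # denoise
    despike_window: int = 5
    despike_nsigma: float = 3.0
    despike_floor_kpa: float = 0.3
    lowpass_cutoff_scale: float = 0.3   # cutoff = scale * fs (3 Hz at 10 Hz)
    lowpass_cutoff_hz: float | None = None
    # breath separation
    envelope_window_s: float = 15.0
    min_envelope_kpa: float = 0.5
    hysteresis_frac: float = 0.10       # total hysteresis band, as amplitude
    min_low_s: float = 1.2              # debounce: sustained low to accept a boundary
    min_high_s: float = 0.3
    # phase segmentation (fractions of extreme smoothed derivative)
    upstroke_start_frac: float = 0.20
    plateau_start_frac: float = 0.10
    downstroke_start_frac: float = 0.20
    tangent_central_frac: float = 0.60
    # breath QC
    min_amplitude_kpa: float = 1.0
    duration_range_s: tuple[float, float] = (1.0, 15.0)
    cough_depth_kpa: float = 0.5
    cough_max_s: float = 1.0
    swallow_baseline_frac: float = 0.20
    swallow_min_s: float = 0.5
    cardiogenic_band_hz: tuple[float, float] = (0.5, 3.0)
    cardiogenic_power_frac: float = 0.25
    cardiogenic_min_rms_kpa: float = 0.07
    # recording QC
    condensation_slope_kpa_min: float = 0.1
    min_valid_breaths: int = 8


DEFAULT_CONFIG = PreprocessConfig()


@dataclass(frozen=True)
class BreathSpan:
    """Half-open sample-index span of one breath; partial edge breaths are
    flagged ``complete=False`` and excluded downstream."""

    start_idx: int
    end_idx: int
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ValueError("empty breath span")

    def duration_s(self, fs: float) -> float:
        return (self.end_idx - self.start_idx) / fs


@dataclass(frozen=True)
class Tangent:
    slope: float       # angle-frame units (d(p/P_ref) / d(tau))
    intercept: float
    resid_rms: float   # RMS fit residual, angle-frame units


@dataclass(frozen=True)
class PhaseSegmentation:
    """Phase boundaries i0 <= i1 <= i2 <= i3 <= i4 (absolute sample indices)
    delimiting phases I-IV within a breath span, plus per-phase tangents
    fitted in the angle frame."""

    boundaries: tuple[int, int, int, int, int]
    tangents: tuple[Tangent, Tangent, Tangent, Tangent]

    def phase_slice(self, phase: int) -> slice:
        """1-based phase number -> slice of absolute sample indices."""
        b = self.boundaries
        return slice(b[phase - 1], b[phase])


class SegmentationError(RuntimeError):
    """A breath whose phases cannot be delimited (e.g. fewer than two
    samples in a phase, or no expiratory upstroke found)."""


class QCReason(str, Enum):
    cough = "cough"
    swallow = "swallow"
    cardiogenic = "cardiogenic"
    condensation = "condensation"
    amplitude_too_low = "amplitude_too_low"
    duration_out_of_range = "duration_out_of_range"
    segmentation_failed = "segmentation_failed"
    # recording-level only
    too_few_valid_breaths = "too_few_valid_breaths"


@dataclass(frozen=True)
class QCResult:
    reasons: tuple[QCReason, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class QCReport:
    n_breaths_total: int
    n_breaths_valid: int
    breath_quality_pct: float
    recording_valid: bool
    rejection_reasons: dict[str, int] = field(default_factory=dict)
    recording_reasons: tuple[QCReason, ...] = ()


# ---------------------------------------------------------------------------
# small numeric helpers shared across the pipeline
# ---------------------------------------------------------------------------

def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least-squares line fit -> (slope, intercept)."""
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    slope = float(dx @ (y - ym)) / denom if denom > 0 else 0.0
    return slope, ym - slope * xm


def _detrended(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    slope, icpt = _linfit(x, y)
    return y - (slope * x + icpt)


def band_power_fraction(
    resid: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[float, float]:
    """(fraction of spectral power in band, band power) of a detrended
    series, from its one-sided periodogram."""
    n = len(resid)
    spec = np.abs(np.fft.rfft(resid)) ** 2 / (n * fs)
    spec[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    total = float(np.trapezoid(spec, freqs))
    if total <= 0:
        return 0.0, 0.0
    sel = (freqs >= band[0]) & (freqs <= band[1])
    bp = float(np.trapezoid(spec[sel], freqs[sel]))
    return bp / total, bp


# ---------------------------------------------------------------------------
# denoise
# ---------------------------------------------------------------------------

def _hampel(p: np.ndarray, window: int, nsigma: float, floor: float) -> np.ndarray:
    """Replace isolated outliers by the rolling median (MAD test with an
    absolute floor so smooth clean signals pass through untouched)."""
    s = pd.Series(p)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    mad = (
        (s - med).abs().rolling(window, center=True, min_periods=1).median()
    ).to_numpy()
    thresh = np.maximum(nsigma * 1.4826 * mad, floor)
    out = p.copy()
    mask = np.abs(p - med) > thresh
    half = window // 2
    mask[:half] = False          # truncated edge windows are unreliable
    if half:
        mask[-half:] = False
    out[mask] = med[mask]
    return out


def _spectral_lowpass(p: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass by spectral truncation above ``cutoff_hz``.

    The signal is reflect-extended before the FFT (equivalently, truncation
    happens in a DCT basis), so there is no wrap-around discontinuity and
    the operation remains an exact projection: applied twice it equals
    itself, keeping the whole denoise stage idempotent on clean signals.
    """
    n = len(p)
    z = np.concatenate([p, p[::-1]])
    spec = np.fft.rfft(z)
    freqs = np.fft.rfftfreq(2 * n, d=1.0 / fs)
    spec[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=2 * n)[:n]


def denoise(
    record: CapnogramRecord, config: PreprocessConfig = DEFAULT_CONFIG
) -> CapnogramRecord:
    """Despike then low-pass a recording; output length equals input length."""
    if len(record.pco2_kpa) < 10:
        raise ValueError("denoise requires at least 10 samples")
    fs = record.sampling_rate_hz
    cutoff = (
        config.lowpass_cutoff_hz
        if config.lowpass_cutoff_hz is not None
        else config.lowpass_cutoff_scale * fs
    )
    if fs <= 2.0 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz too low for low-pass cutoff {cutoff} Hz"
        )
    p = _hampel(
        record.pco2_kpa,
        config.despike_window,
        config.despike_nsigma,
        config.despike_floor_kpa,
    )
    p = _spectral_lowpass(p, fs, cutoff)
    return record.replace_samples(np.clip(p, 0.0, None))


# ---------------------------------------------------------------------------
# breath separation
# ---------------------------------------------------------------------------

def _rolling_envelope(
    p: np.ndarray, fs: float, window_s: float
) -> tuple[np.ndarray, np.ndarray]:
    w = max(3, int(round(window_s * fs)) | 1)
    s = pd.Series(p)
    p10 = s.rolling(w, center=True, min_periods=1).quantile(0.10).to_numpy()
    p90 = s.rolling(w, center=True, min_periods=1).quantile(0.90).to_numpy()
    return p10, p90


def separate_breaths(
    record: CapnogramRecord, config: PreprocessConfig = DEFAULT_CONFIG
) -> list[BreathSpan]:
    """Split a (denoised) recording into breath spans.

    Boundaries sit at downward crossings of the mid-amplitude threshold of a
    rolling 10th/90th-percentile envelope, with hysteresis and a debounce:
    an excursion across the band must persist (default 1 s below / 0.3 s
    above) to count, so plateau interruptions such as swallows do not split
    a breath.  Returns an empty list for flat or occluded recordings.
    """
    p = record.pco2_kpa
    fs = record.sampling_rate_hz
    n = len(p)
    if n < 4:
        return []
    p10, p90 = _rolling_envelope(p, fs, config.envelope_window_s)
    amp = p90 - p10
    if np.all(amp < config.min_envelope_kpa):
        return []
    mid = 0.5 * (p10 + p90)
    half_band = 0.5 * config.hysteresis_frac * amp
    below = p < (mid - half_band)
    above = p > (mid + half_band)
    min_low_n = max(1, int(round(config.min_low_s * fs)))
    min_high_n = max(1, int(round(config.min_high_s * fs)))

    downs: list[int] = []
    state = None
    i = 0
    while i < n:
        if state is None:
            if above[i]:
                state = "high"
            elif below[i]:
                state = "low"
            i += 1
        elif state == "high" and below[i]:
            j = i + 1
            while j < n and not above[j]:
                j += 1
            if (j - i) >= min_low_n or j == n:
                downs.append(i)
                state = "low"
                i += 1
            else:
                i = j  # short dip (artefact): remain in the high state
        elif state == "low" and above[i]:
            j = i + 1
            while j < n and not below[j]:
                j += 1
            if (j - i) >= min_high_n or j == n:
                state = "high"
                i += 1
            else:
                i = j
        else:
            i += 1

    if not downs:
        return []
    spans: list[BreathSpan] = []
    if downs[0] > 0:
        spans.append(BreathSpan(0, downs[0], complete=False))
    for a, b in zip(downs[:-1], downs[1:]):
        spans.append(BreathSpan(a, b, complete=True))
    if downs[-1] < n:
        spans.append(BreathSpan(downs[-1], n, complete=False))
    return spans


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def _fit_tangent_window(
    tau: np.ndarray, y: np.ndarray, a: int, b: int, central_frac: float
) -> Tangent:
    """LS tangent over the central fraction of fine-grid window [a, b)."""
    n = b - a
    k = int(round(0.5 * (1.0 - central_frac) * n))
    lo, hi = a + k, b - k
    if hi - lo < 2:
        lo, hi = a, b
    slope, icpt = _linfit(tau[lo:hi], y[lo:hi])
    resid = y[lo:hi] - (slope * tau[lo:hi] + icpt)
    return Tangent(slope, icpt, float(np.sqrt(np.mean(resid ** 2))))


def segment_phases(
    record: CapnogramRecord,
    span: BreathSpan,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> PhaseSegmentation:
    """Locate phase boundaries in one breath span and fit phase tangents.

    Rules (on the derivative of the denoised signal within the span):
    phase II starts at the first sample whose derivative exceeds 20% of the
    span's maximum positive derivative; phase III where it falls back below
    10% of that maximum; phase IV at the first later sample below -20% of
    the maximum-magnitude negative derivative.  Raises
    :class:`SegmentationError` when any phase would hold < 2 samples.
    """
    p = record.pco2_kpa[span.start_idx:span.end_idx]
    fs = record.sampling_rate_hz
    L = len(p)
    if L < 8:
        raise SegmentationError("span too short to segment")
    # Monotone-cubic (PCHIP) reconstruction of the denoised samples: the
    # derivative rules and tangent fits run on a fine grid of the
    # interpolant, so boundary placement is not quantized to the coarse
    # sample grid and matches what the same rules give on a densely
    # sampled version of the underlying waveform.
    interp = PchipInterpolator(np.arange(L), p)
    upsample = max(1, int(np.ceil(200 / L)) * 4)
    nf = (L - 1) * upsample + 1
    x = np.linspace(0.0, L - 1, nf)
    deriv = interp(x, 1) * fs
    dmax = float(deriv.max())
    dmin = float(-deriv.min())
    if dmax <= 0 or dmin <= 0:
        raise SegmentationError("no expiratory upstroke / downstroke found")

    def first_idx(cond: np.ndarray, start: int) -> int:
        hits = np.nonzero(cond[start:])[0]
        if len(hits) == 0:
            raise SegmentationError("phase boundary rule found no crossing")
        return start + int(hits[0])

    j1 = first_idx(deriv > config.upstroke_start_frac * dmax, 0)
    j2 = first_idx(deriv < config.plateau_start_frac * dmax, j1 + 1)
    j3 = first_idx(deriv < -config.downstroke_start_frac * dmin, j2 + 1)
    # a step-like transition collapses to the minimal 2-sample phase
    min_gap = 2 * upsample
    j1 = max(j1, min_gap)
    j2 = max(j2, j1 + min_gap)
    j3 = max(j3, j2 + min_gap)
    jbounds = (0, j1, j2, j3, nf)
    bounds = tuple(
        int(round(x[j])) if j < nf else L for j in jbounds
    )
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            raise SegmentationError(
                f"phase with fewer than 2 samples (boundaries {bounds})"
            )
    tau = x / (L - 1)
    y = interp(x) / P_REF_KPA
    tangents = tuple(
        _fit_tangent_window(tau, y, a, b, config.tangent_central_frac)
        for a, b in zip(jbounds[:-1], jbounds[1:])
    )
    s0 = span.start_idx
    return PhaseSegmentation(
        boundaries=tuple(s0 + b for b in bounds),  # type: ignore[arg-type]
        tangents=tangents,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# breath QC
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _amplitude_landmarks(
    p: np.ndarray, seg: PhaseSegmentation | None, start_idx: int
) -> tuple[float, float]:
    """(baseline, etco2) for a span; percentile fallback when unsegmented."""
    if seg is not None:
        b = [i - start_idx for i in seg.boundaries]
        baseline = float(np.mean(p[b[0]:b[1]]))
        etco2 = float(np.max(p[b[2]:b[3]]))
    else:
        baseline = float(np.quantile(p, 0.10))
        etco2 = float(np.quantile(p, 0.95))
    return baseline, etco2


def qc_breath(
    record: CapnogramRecord,
    span: BreathSpan,
    seg: PhaseSegmentation | None,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> QCResult:
    """Evaluate all breath-level signal-quality rules independently.

    Artefact rules run on the expiratory high region found by thresholding,
    so a breath whose phase segmentation failed (e.g. because a swallow tore
    the plateau apart) is still attributed a cause.
    """
    p = record.pco2_kpa[span.start_idx:span.end_idx]
    fs = record.sampling_rate_hz
    reasons: list[QCReason] = []
    if seg is None:
        reasons.append(QCReason.segmentation_failed)

    baseline, etco2 = _amplitude_landmarks(p, seg, span.start_idx)
    amplitude = etco2 - baseline
    if amplitude < config.min_amplitude_kpa:
        reasons.append(QCReason.amplitude_too_low)
    lo_s, hi_s = config.duration_range_s
    if not (lo_s <= span.duration_s(fs) <= hi_s):
        reasons.append(QCReason.duration_out_of_range)

    if amplitude > 0:
        hi_level = baseline + 0.6 * amplitude
        idx_hi = np.nonzero(p > hi_level)[0]
        if len(idx_hi) >= 4:
            w0, w1 = int(idx_hi[0]), int(idx_hi[-1]) + 1
            window = p[w0:w1]
            t = np.arange(len(window)) / fs
            on_plateau = window > hi_level
            if on_plateau.sum() >= 2:
                slope, icpt = _linfit(t[on_plateau], window[on_plateau])
                level = slope * t + icpt
            else:
                level = np.full_like(window, float(np.median(window)))

            # cough: deep short negative transient within the plateau
            dips = _runs(window < level - config.cough_depth_kpa)
            for a, b in dips:
                if 0 < a and b < len(window) and (b - a) / fs <= config.cough_max_s:
                    reasons.append(QCReason.cough)
                    break
            # swallow: sustained interruption down to near baseline
            near_base = window <= baseline + config.swallow_baseline_frac * amplitude
            for a, b in _runs(near_base):
                if (b - a) / fs >= config.swallow_min_s:
                    reasons.append(QCReason.swallow)
                    break
            # cardiogenic oscillations: band-limited ripple on the central
            # plateau (edges and the alpha-corner rounding are excluded so
            # their broadband fit residual cannot masquerade as ripple)
            if seg is not None:
                b2 = seg.boundaries[2] - span.start_idx
                b3 = seg.boundaries[3] - span.start_idx
                trim = int(round(0.2 * (b3 - b2)))
                sel = np.arange(b2 + trim, b3 - trim)
            else:
                hi_idx = np.nonzero(p > baseline + 0.75 * amplitude)[0]
                trim = int(round(0.2 * len(hi_idx)))
                sel = hi_idx[trim: len(hi_idx) - trim]
            plate = p[sel]
            if len(plate) >= 8:
                resid = _detrended(sel / fs, plate)
                if np.var(resid) > 0:
                    frac, band_power = band_power_fraction(
                        resid, fs, config.cardiogenic_band_hz)
                    if (
                        frac > config.cardiogenic_power_frac
                        and np.sqrt(band_power) > config.cardiogenic_min_rms_kpa
                    ):
                        reasons.append(QCReason.cardiogenic)
    return QCResult(tuple(reasons))


# ---------------------------------------------------------------------------
# recording QC
# ---------------------------------------------------------------------------

def qc_capnogram(
    record: CapnogramRecord,
    spans: list[BreathSpan],
    qc_results: list[QCResult],
    segs: list[PhaseSegmentation | None] | None = None,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> QCReport:
    """Aggregate breath QC and run whole-recording rules.

    The recording is rejected when the per-breath inspiratory baseline
    drifts upward faster than the condensation threshold (default 0.1
    kPa/min), or when fewer than ``min_valid_breaths`` breaths survive.
    """
    complete = [s for s in spans if s.complete]
    if segs is None:
        segs = [None] * len(spans)
    fs = record.sampling_rate_hz
    n_total = len(complete)
    valid_flags = [
        r.valid for s, r in zip(spans, qc_results) if s.complete
    ]
    n_valid = int(sum(valid_flags))
    pct = 100.0 * n_valid / n_total if n_total else 0.0

    histogram: Counter[str] = Counter()
    for s, r in zip(spans, qc_results):
        if s.complete:
            for reason in r.reasons:
                histogram[reason.value] += 1

    recording_reasons: list[QCReason] = []
    # condensation: linear trend of per-breath baselines
    baselines, times = [], []
    for s, seg in zip(spans, segs):
        if not s.complete:
            continue
        p = record.pco2_kpa[s.start_idx:s.end_idx]
        b, _ = _amplitude_landmarks(p, seg, s.start_idx)
        baselines.append(b)
        times.append(0.5 * (s.start_idx + s.end_idx) / fs)
    if len(baselines) >= 3:
        slope_per_min = 60.0 * _linfit(np.asarray(times),
                                       np.asarray(baselines))[0]
        if slope_per_min > config.condensation_slope_kpa_min:
            recording_reasons.append(QCReason.condensation)
    if n_valid < config.min_valid_breaths:
        recording_reasons.append(QCReason.too_few_valid_breaths)
    return QCReport(
        n_breaths_total=n_total,
        n_breaths_valid=n_valid,
        breath_quality_pct=pct,
        recording_valid=not recording_reasons,
        rejection_reasons=dict(histogram),
        recording_reasons=tuple(recording_reasons),
    )
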