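"""Synthetic capnogram generator with analytic ground truth.

The breath model is phenomenological, not a gas-exchange simulation: each
phase of the cycle is a simple parametric curve chosen so that every
geometric feature downstream has an independent knob.

* phase I  — constant inspiratory baseline ``p_base``;
* phase II — normalized logistic rise (rate ``upstroke_steepness``);
* phase III — a line of slope ``plateau_slope`` (kPa per unit normalized
  breath time) approached from below through an exponential term (rate
  ``plateau_curvature``) that rounds the alpha corner; the plateau ends
  exactly at ``etco2``;
* phase IV — normalized logistic fall back to baseline.

Continuous recordings concatenate cycles in expiration-first order
(II, III, IV, I), so a recording starts at the foot of an upstroke and
breath-detector spans (mid-amplitude downward crossings) line up with whole
cycles.  Ground truth — span boundaries, derivative-rule phase boundaries,
angle-frame tangent slopes and the alpha/beta/gamma/delta angles — is
computed on a densely sampled noise-free version of the same signal, using
the published rule definitions but independently of the extraction code
path, and stored in the record's annotations.

Artefacts (cough and swallow transients, condensation drift, cardiogenic
plateau oscillations) are injected after truth computation and logged with
sample-index intervals, giving labelled benchmarks for the QC rules.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import angles_from_slopes
from .io import CapnogramRecord
from .preprocess import DEFAULT_CONFIG, P_REF_KPA, PreprocessConfig, _linfit

__all__ = [
    "BreathModelParams",
    "ArtefactSpec",
    "CohortPreset",
    "COHORT_PRESETS",
    "cohort_preset",
    "simulate_breath",
    "breath_truth",
    "tune_plateau_slope",
    "simulate_capnogram",
    "simulate_study",
    "simulate_etco2_recovery",
    "StudyDataset",
]

#: fraction of the plateau line's total rise consumed by the exponential
#: rounding of the alpha corner (depth of the approach term)
_ROUNDING_DEPTH_FRAC = 0.5

_DENSE_FACTOR = 25  # dense truth grid oversampling vs the output rate


@dataclass(frozen=True)
class BreathModelParams:
    p_base: float = 0.04            # inspired baseline pCO2, kPa
    etco2: float = 5.0              # end-tidal pCO2, kPa
    breath_duration_s: float = 4.0
    frac_I: float = 0.30
    frac_II: float = 0.15
    frac_III: float = 0.40
    frac_IV: float = 0.15
    upstroke_steepness: float = 14.0    # logistic rate of phase II
    plateau_slope: float = 0.55         # kPa per unit normalized breath time
    plateau_curvature: float = 9.0      # exponential-approach rate
    downstroke_steepness: float = 14.0
    noise_sd_kpa: float = 0.03
    plateau_ripple_kpa: float = 0.0     # RMS-scale stochastic plateau texture
    baseline_tilt_kpa: float = 0.0      # phase-I drift, kPa per unit breath time

    def __post_init__(self) -> None:
        if not 0 <= self.p_base < self.etco2:
            raise ValueError("require 0 <= p_base < etco2")
        fr = (self.frac_I, self.frac_II, self.frac_III, self.frac_IV)
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("phase fractions must be positive and sum to 1")
        if self.plateau_slope < 0:
            raise ValueError("plateau_slope must be >= 0")
        if self.breath_duration_s <= 0 or self.noise_sd_kpa < 0 \
                or self.plateau_ripple_kpa < 0:
            raise ValueError("invalid duration, noise SD or ripple")
        rise = (1 + _ROUNDING_DEPTH_FRAC) * self.plateau_slope * self.frac_III
        if self.etco2 - rise <= self.p_base:
            raise ValueError("plateau rise exceeds breath amplitude")
        if self.p_base - self.baseline_tilt_kpa * self.frac_I < 0:
            raise ValueError("baseline tilt drives phase I below 0 kPa")


@dataclass(frozen=True)
class ArtefactSpec:
    cough_rate_per_min: float = 0.0
    swallow_rate_per_min: float = 0.0
    condensation_drift_kpa_per_min: float = 0.0
    cardiogenic_amplitude_kpa: float = 0.0
    cardiogenic_freq_hz: float = 1.2

    def __post_init__(self) -> None:
        if min(self.cough_rate_per_min, self.swallow_rate_per_min,
               self.condensation_drift_kpa_per_min,
               self.cardiogenic_amplitude_kpa) < 0:
            raise ValueError("artefact rates/amplitudes must be >= 0")
        if self.cardiogenic_amplitude_kpa > 0 and not (
            0.5 <= self.cardiogenic_freq_hz <= 3.0
        ):
            raise ValueError("cardiogenic frequency must be in [0.5, 3] Hz")

    @property
    def any_active(self) -> bool:
        return (self.cough_rate_per_min > 0 or self.swallow_rate_per_min > 0
                or self.condensation_drift_kpa_per_min > 0
                or self.cardiogenic_amplitude_kpa > 0)


NO_ARTEFACTS = ArtefactSpec()


@dataclass(frozen=True)
class CohortPreset:
    name: str
    params: BreathModelParams
    target_alpha_deg: float

    def __post_init__(self) -> None:
        if not 90.0 < self.target_alpha_deg < 180.0:
            raise ValueError("target alpha must lie in (90, 180) degrees")


# ---------------------------------------------------------------------------
# waveform evaluation
# ---------------------------------------------------------------------------

def _logistic01(u: np.ndarray, k: float) -> np.ndarray:
    """Normalized logistic: 0 at u=0, 1 at u=1, rate k."""
    lo, hi = expit(-0.5 * k), expit(0.5 * k)
    return (expit(k * (u - 0.5)) - lo) / (hi - lo)


def _cycle_segments(p: BreathModelParams):
    """(fraction, func(u in [0,1]) -> kPa) segments in II,III,IV,I order."""
    rise = p.plateau_slope * p.frac_III
    depth = _ROUNDING_DEPTH_FRAC * rise
    p_join = p.etco2 - rise - depth  # value where phase II hands over to III

    def phase2(u):
        return p.p_base + (p_join - p.p_base) * _logistic01(
            u, p.upstroke_steepness)

    def phase3(u):
        line = p.etco2 - rise * (1.0 - u)
        c = p.plateau_curvature
        if depth == 0.0:
            return line
        if c < 1e-9:
            r = 1.0 - u
        else:
            r = (np.exp(-c * u) - math.exp(-c)) / (1.0 - math.exp(-c))
        return line - depth * r

    p_i0 = p.p_base - p.baseline_tilt_kpa * p.frac_I  # phase-I start level

    def phase4(u):
        return p_i0 + (p.etco2 - p_i0) * (
            1.0 - _logistic01(u, p.downstroke_steepness))

    def phase1(u):
        return p_i0 + p.baseline_tilt_kpa * p.frac_I * np.asarray(u, float)

    return [
        (p.frac_II, phase2),
        (p.frac_III, phase3),
        (p.frac_IV, phase4),
        (p.frac_I, phase1),
    ]


def _eval_segments(x: np.ndarray, segments) -> np.ndarray:
    """Evaluate piecewise segments over normalized cycle time x in [0, 1)."""
    out = np.empty_like(x, dtype=float)
    start = 0.0
    for frac, func in segments:
        stop = start + frac
        m = (x >= start) & (x < stop) if stop < 1.0 - 1e-12 else (x >= start)
        if m.any():
            out[m] = func((x[m] - start) / frac)
        start = stop
    return out


def eval_breath(
    params: BreathModelParams, x: np.ndarray, order: str = "span"
) -> np.ndarray:
    """Noise-free breath waveform at normalized times x in [0, 1).

    ``order="span"`` lays the phases out I,II,III,IV (a standalone breath
    starting and ending at baseline); ``order="cycle"`` uses the
    expiration-first II,III,IV,I layout used inside continuous recordings.
    """
    segs = _cycle_segments(params)
    if order == "span":
        segs = [segs[3]] + segs[:3]
    elif order != "cycle":
        raise ValueError("order must be 'span' or 'cycle'")
    return _eval_segments(np.asarray(x, float), segs)


# ---------------------------------------------------------------------------
# dense-grid ground truth (independent oracle for the extraction pipeline)
# ---------------------------------------------------------------------------

def _dense_rule_truth(
    p: np.ndarray,
    tau: np.ndarray,
    config: PreprocessConfig,
) -> dict:
    """Apply the phase-boundary and tangent-fit rule definitions on a dense
    noise-free span; tau is the span-normalized time in [0, 1]."""
    d = np.gradient(p, tau)
    dmax, dmin = float(d.max()), float(-d.min())
    if dmax <= 0 or dmin <= 0:
        raise ValueError("degenerate breath: no upstroke or downstroke")
    n = len(p)
    i1 = int(np.argmax(d > config.upstroke_start_frac * dmax))
    i2 = i1 + 1 + int(np.argmax(d[i1 + 1:] < config.plateau_start_frac * dmax))
    i3 = i2 + 1 + int(np.argmax(d[i2 + 1:] < -config.downstroke_start_frac * dmin))
    bounds = (0, i1, i2, i3, n)
    y = p / P_REF_KPA
    slopes, intercepts = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        b = max(b, a + 2)  # degenerate (step-like) phases keep two points
        m = b - a
        k = int(round(0.5 * (1 - config.tangent_central_frac) * m))
        lo, hi = a + k, b - k
        if hi - lo < 2:
            lo, hi = a, b
        slope, icpt = _linfit(tau[lo:hi], y[lo:hi])
        slopes.append(slope)
        intercepts.append(icpt)
    return {
        "bounds_frac": tuple(float(tau[i]) if i < n else 1.0 for i in bounds),
        "tangent_slopes": slopes,
        "tangent_intercepts": intercepts,
    }


def breath_truth(
    params: BreathModelParams,
    order: str = "span",
    config: PreprocessConfig = DEFAULT_CONFIG,
    n_dense: int = 4000,
) -> dict:
    """Analytic (dense, noise-free) ground truth for a single breath:
    rule-based phase boundaries (as fractions of the breath), angle-frame
    tangent slopes, the four corner angles, and the end-tidal point."""
    tau = np.linspace(0.0, 1.0, n_dense, endpoint=False)
    p = eval_breath(params, tau, order=order)
    info = _dense_rule_truth(p, tau, config)
    m1, m2, m3, m4 = _slopes_in_phase_order(info["tangent_slopes"], order)
    alpha, beta, gamma, delta = angles_from_slopes(m1, m2, m3, m4)
    return {
        "alpha_deg": alpha,
        "beta_deg": beta,
        "gamma_deg": gamma,
        "delta_deg": delta,
        "tangent_slopes": [m1, m2, m3, m4],
        "bounds_frac": info["bounds_frac"],
        "etco2_kpa": params.etco2,
        "baseline_kpa": params.p_base,
    }


def _slopes_in_phase_order(slopes: list, order: str) -> tuple:
    """Map fitted segment slopes to (phase I, II, III, IV) order."""
    if order == "span":
        return tuple(slopes)  # already I,II,III,IV
    m2, m3, m4, m1 = slopes
    return m1, m2, m3, m4


def simulate_breath(
    params: BreathModelParams,
    sampling_rate_hz: float,
    seed: int = 0,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, dict]:
    """One standalone breath (phases I,II,III,IV) plus its ground truth.

    Raises ``ValueError`` if any phase would contain fewer than 4 samples.
    """
    T = params.breath_duration_s
    n = int(round(T * sampling_rate_hz))
    for name, frac in (("I", params.frac_I), ("II", params.frac_II),
                       ("III", params.frac_III), ("IV", params.frac_IV)):
        if frac * T * sampling_rate_hz < 4:
            raise ValueError(
                f"phase {name} would hold < 4 samples at "
                f"{sampling_rate_hz} Hz"
            )
    tau = np.arange(n) / n
    p = eval_breath(params, tau, order="span")
    if params.noise_sd_kpa > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, params.noise_sd_kpa, size=n)
    truth = breath_truth(params, order="span", config=config)
    return np.clip(p, 0.0, None), truth


def tune_plateau_slope(
    params: BreathModelParams,
    target_alpha_deg: float,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> BreathModelParams:
    """Solve for the plateau slope whose analytic alpha equals the target."""
    from scipy.optimize import brentq

    def f(slope: float) -> float:
        p = replace(params, plateau_slope=slope)
        return breath_truth(p, config=config)["alpha_deg"] - target_alpha_deg

    # keep the plateau rise below half the amplitude so the waveform stays
    # plateau-shaped (beyond that the derivative rules see no upstroke)
    hi = 0.5 * (params.etco2 - params.p_base) / (
        (1 + _ROUNDING_DEPTH_FRAC) * params.frac_III
    )
    slope = brentq(f, 1e-4, hi, xtol=1e-6)
    return replace(params, plateau_slope=float(slope))


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------
# plateau_slope values are pre-tuned against breath_truth so the analytic
# alpha of each noise-free preset breath sits on its target (healthy and
# disease targets follow the cohort-median alpha ordering the method is
# meant to resolve: healthy < pneumonia < asthma < CHF).

def _preset_table() -> dict[str, CohortPreset]:
    base = dict(p_base=0.04, noise_sd_kpa=0.03, plateau_ripple_kpa=0.035)
    table = {
        "healthy": CohortPreset(
            "healthy",
            BreathModelParams(
                etco2=5.0, breath_duration_s=4.0,
                frac_I=0.30, frac_II=0.15, frac_III=0.40, frac_IV=0.15,
                upstroke_steepness=14.0, downstroke_steepness=14.0,
                plateau_curvature=9.0, plateau_slope=0.7605, **base,
            ),
            target_alpha_deg=102.9,
        ),
        "asthma": CohortPreset(
            "asthma",
            BreathModelParams(
                etco2=4.95, breath_duration_s=4.2,
                frac_I=0.265, frac_II=0.185, frac_III=0.40, frac_IV=0.15,
                upstroke_steepness=12.5, downstroke_steepness=12.0,
                plateau_curvature=5.0, plateau_slope=1.2620, **base,
            ),
            target_alpha_deg=112.8,
        ),
        "chf": CohortPreset(
            "chf",
            BreathModelParams(
                etco2=4.6, breath_duration_s=3.8,
                frac_I=0.27, frac_II=0.18, frac_III=0.40, frac_IV=0.15,
                upstroke_steepness=8.5, downstroke_steepness=10.0,
                plateau_curvature=6.0, plateau_slope=1.4360, **base,
            ),
            target_alpha_deg=116.5,
        ),
        "pneumonia_acute": CohortPreset(
            "pneumonia_acute",
            BreathModelParams(
                etco2=3.5, breath_duration_s=4.0,
                frac_I=0.29, frac_II=0.16, frac_III=0.40, frac_IV=0.15,
                upstroke_steepness=11.0, downstroke_steepness=12.0,
                plateau_curvature=8.0, plateau_slope=0.9794, **base,
            ),
            target_alpha_deg=109.4,
        ),
        "pneumonia_recovered": CohortPreset(
            "pneumonia_recovered",
            BreathModelParams(
                etco2=3.941, breath_duration_s=4.0,
                frac_I=0.29, frac_II=0.16, frac_III=0.40, frac_IV=0.15,
                upstroke_steepness=11.0, downstroke_steepness=12.0,
                plateau_curvature=8.0, plateau_slope=1.0472, **base,
            ),
            target_alpha_deg=109.4,
        ),
    }
    return table


COHORT_PRESETS = _preset_table()


def cohort_preset(name: str) -> CohortPreset:
    try:
        return COHORT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(COHORT_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal factor with coefficient of
    variation ``cv`` (keeps jittered parameters positive)."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _jittered_fracs(
    base: BreathModelParams, rng: np.random.Generator, cv: float
) -> dict[str, float]:
    """Multiplicative jitter on the phase-duration fractions, renormalized
    to sum to one."""
    f = np.array([base.frac_I, base.frac_II, base.frac_III, base.frac_IV])
    f = f * np.array([_jitter(rng, cv) for _ in range(4)])
    f = f / f.sum()
    return dict(zip(("frac_I", "frac_II", "frac_III", "frac_IV"), f))


def _jittered_params(
    base: BreathModelParams, rng: np.random.Generator, cv: float
) -> BreathModelParams:
    if cv <= 0:
        return base
    return replace(
        base,
        breath_duration_s=base.breath_duration_s * _jitter(rng, cv),
        plateau_slope=base.plateau_slope * _jitter(rng, cv),
        upstroke_steepness=base.upstroke_steepness * _jitter(rng, cv),
        downstroke_steepness=base.downstroke_steepness * _jitter(rng, cv),
        etco2=base.etco2 * _jitter(rng, 0.3 * cv),
        **_jittered_fracs(base, rng, 0.5 * cv),
    )


def simulate_capnogram(
    preset: CohortPreset | BreathModelParams,
    duration_s: float = 75.0,
    sampling_rate_hz: float = 10.0,
    artefacts: ArtefactSpec = NO_ARTEFACTS,
    breath_variability: float = 0.0,
    seed: int = 0,
    subject_id: str = "SIM",
    cohort: str = "other",
    recorded_at: str = "",
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> CapnogramRecord:
    """Simulate a continuous annotated recording (default 75 s).

    Breaths are concatenated cycles with per-breath multiplicative lognormal
    parameter jitter of the given coefficient of variation; artefacts are
    injected per :class:`ArtefactSpec` and logged, with affected breaths
    labelled.  Deterministic under a fixed seed.
    """
    if isinstance(preset, BreathModelParams):
        preset = CohortPreset("custom", preset, target_alpha_deg=100.0)
    base = preset.params
    if duration_s < 2 * base.breath_duration_s:
        raise ValueError("duration must cover at least two breaths")
    ss = np.random.SeedSequence([seed, 0xCA9])
    rng_breath, rng_art, rng_noise, rng_ripple = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    fs = sampling_rate_hz
    n = int(round(duration_s * fs))

    # draw cycles until they cover the recording
    cycles: list[tuple[float, BreathModelParams]] = []  # (start time, params)
    t_cursor = 0.0
    while t_cursor < duration_s:
        cp = _jittered_params(base, rng_breath, breath_variability)
        cycles.append((t_cursor, cp))
        t_cursor += cp.breath_duration_s

    def eval_on(times: np.ndarray) -> np.ndarray:
        out = np.full(times.shape, base.p_base, dtype=float)
        for t0, cp in cycles:
            T = cp.breath_duration_s
            m = (times >= t0) & (times < t0 + T)
            if m.any():
                out[m] = eval_breath(cp, (times[m] - t0) / T, order="cycle")
        return out

    t = np.arange(n) / fs
    clean = eval_on(t)

    # ---- ground truth from a dense noise-free grid --------------------
    nd = n * _DENSE_FACTOR
    td = np.arange(nd) / (fs * _DENSE_FACTOR)
    dense = eval_on(td)
    mid = 0.5 * (base.p_base + np.median([cp.etco2 for _, cp in cycles]))
    downs = np.nonzero((dense[:-1] >= mid) & (dense[1:] < mid))[0] + 1
    breaths: list[dict] = []
    for bi, (a, b) in enumerate(zip(downs[:-1], downs[1:])):
        taus = (td[a:b] - td[a]) / (td[b - 1] - td[a])
        try:
            info = _dense_rule_truth(dense[a:b], taus, config)
        except ValueError:
            continue
        slopes = info["tangent_slopes"]  # span layout: I,II,III,IV
        breaths.append({
            "index": bi,
            "span_start_idx": int(round(td[a] * fs)),
            "span_end_idx": int(round(td[b] * fs)) if b < nd else n,
            "complete": True,
            "bounds_frac": list(info["bounds_frac"]),
            "tangent_slopes": slopes,
            "etco2_kpa": float(dense[a:b].max()),
            "baseline_kpa": base.p_base,
            "duration_s": float(td[b] - td[a]) if b < nd else float(
                td[-1] - td[a]),
            "artefacts": [],
        })
    # corner angles, using the next breath's baseline tangent for gamma
    for j, br in enumerate(breaths):
        m1, m2, m3, m4 = br["tangent_slopes"]
        m1n = breaths[j + 1]["tangent_slopes"][0] if j + 1 < len(breaths) \
            else None
        a_, b_, g_, d_ = angles_from_slopes(m1, m2, m3, m4, m1n)
        br.update(alpha_deg=a_, beta_deg=b_, gamma_deg=g_, delta_deg=d_)

    # ---- artefact injection ------------------------------------------
    p = clean.copy()
    events: list[dict] = []

    def plateau_window(cycle_start: float, cp: BreathModelParams):
        T = cp.breath_duration_s
        t0 = cycle_start + cp.frac_II * T
        return t0, t0 + cp.frac_III * T

    for ci, (t0, cp) in enumerate(cycles):
        pt0, pt1 = plateau_window(t0, cp)
        if pt1 > duration_s:
            continue
        T = cp.breath_duration_s
        has_cough = (artefacts.cough_rate_per_min > 0 and
                     rng_art.random() < artefacts.cough_rate_per_min * T / 60)
        has_swallow = (
            not has_cough and artefacts.swallow_rate_per_min > 0
            and rng_art.random() < artefacts.swallow_rate_per_min * T / 60
        )
        if has_cough:
            width = rng_art.uniform(0.4, 0.8)
            depth = rng_art.uniform(1.2, 2.2)
            tc = rng_art.uniform(pt0 + 0.25 * (pt1 - pt0),
                                 pt1 - 0.25 * (pt1 - pt0))
            sig = width / 4.0
            bump = (-depth * np.exp(-0.5 * ((t - tc) / sig) ** 2)
                    + 0.3 * depth * np.exp(-0.5 * ((t - tc - 2 * sig) / sig) ** 2))
            p += bump
            events.append({
                "label": "cough",
                "start_idx": int(max(0, math.floor((tc - 2 * sig) * fs))),
                "end_idx": int(min(n, math.ceil((tc + 3 * sig) * fs))),
            })
        elif has_swallow:
            w = rng_art.uniform(0.55, 0.85)
            ramp = 0.1
            tc = 0.5 * (pt0 + pt1)
            lvl = cp.p_base + rng_art.uniform(0.05, 0.15) * (
                cp.etco2 - cp.p_base)
            dt_c = np.abs(t - tc)
            wgt = np.clip((w / 2 + ramp - dt_c) / ramp, 0.0, 1.0)
            wgt = 0.5 - 0.5 * np.cos(np.pi * wgt)
            p = (1 - wgt) * p + wgt * lvl
            events.append({
                "label": "swallow",
                "start_idx": int(max(0, math.floor((tc - w / 2 - ramp) * fs))),
                "end_idx": int(min(n, math.ceil((tc + w / 2 + ramp) * fs))),
            })
        if artefacts.cardiogenic_amplitude_kpa > 0:
            m = (t >= pt0) & (t < pt1)
            phase = rng_art.uniform(0, 2 * np.pi)
            p[m] += artefacts.cardiogenic_amplitude_kpa * np.sin(
                2 * np.pi * artefacts.cardiogenic_freq_hz * t[m] + phase)
            events.append({
                "label": "cardiogenic",
                "start_idx": int(round(pt0 * fs)),
                "end_idx": int(round(pt1 * fs)),
            })
    # stochastic plateau texture: irregular low-amplitude two-tone ripple
    # per breath (emulates the fine structure real alveolar plateaus carry;
    # not logged as an artefact because it is part of normal morphology)
    for t0, cp in cycles:
        if cp.plateau_ripple_kpa <= 0:
            continue
        pt0, pt1 = plateau_window(t0, cp)
        if pt1 > duration_s:
            continue
        m = (t >= pt0) & (t < pt1)
        f1_, f2_ = rng_ripple.uniform(0.6, 1.8, 2)
        ph1_, ph2_ = rng_ripple.uniform(0, 2 * np.pi, 2)
        amp = cp.plateau_ripple_kpa * _jitter(rng_ripple, 0.3)
        p[m] += amp * (np.sin(2 * np.pi * f1_ * t[m] + ph1_)
                       + 0.6 * np.sin(2 * np.pi * f2_ * t[m] + ph2_))

    if artefacts.condensation_drift_kpa_per_min > 0:
        p += artefacts.condensation_drift_kpa_per_min * t / 60.0
        events.append({"label": "condensation", "start_idx": 0, "end_idx": n})

    # label affected breaths
    for ev in events:
        for br in breaths:
            if ev["label"] == "condensation":
                continue
            if ev["start_idx"] < br["span_end_idx"] and \
                    ev["end_idx"] > br["span_start_idx"]:
                if ev["label"] not in br["artefacts"]:
                    br["artefacts"].append(ev["label"])

    if base.noise_sd_kpa > 0:
        p = p + rng_noise.normal(0.0, base.noise_sd_kpa, size=n)
    p = np.clip(p, 0.0, None)

    annotations = {
        "seed": seed,
        "preset": preset.name,
        "target_alpha_deg": preset.target_alpha_deg,
        "sampling_rate_hz": fs,
        "breath_variability": breath_variability,
        "params": asdict(base),
        "artefact_spec": asdict(artefacts),
        "breaths": breaths,
        "artefacts": events,
    }
    return CapnogramRecord(
        subject_id=subject_id,
        cohort=cohort,
        recorded_at=recorded_at,
        sampling_rate_hz=fs,
        pco2_kpa=p,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# study-level simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """Records plus per-subject truth and a clinical covariate table."""

    records: list[CapnogramRecord]
    subjects: pd.DataFrame = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)


_STUDY_COHORT_PRESET = {
    "healthy": "healthy",
    "asthma": "asthma",
    "chf": "chf",
    "pneumonia": "pneumonia_acute",
}


def _subject_params(
    base: BreathModelParams, rng: np.random.Generator,
    slope_cv: float = 0.25, up_steep_cv: float = 0.15,
    down_steep_cv: float = 0.45,
    etco2_cv: float = 0.05, dur_cv: float = 0.12, frac_cv: float = 0.18,
) -> BreathModelParams:
    fracs = _jittered_fracs(base, rng, frac_cv)
    # cap the drawn slope below the admissibility limit of the waveform
    slope_max = 0.5 * (base.etco2 - base.p_base) / (
        (1 + _ROUNDING_DEPTH_FRAC) * base.frac_III
    )
    return replace(
        base,
        plateau_slope=min(base.plateau_slope * _jitter(rng, slope_cv),
                          slope_max),
        upstroke_steepness=base.upstroke_steepness * _jitter(rng, up_steep_cv),
        downstroke_steepness=base.downstroke_steepness
        * _jitter(rng, down_steep_cv),
        etco2=base.etco2 * _jitter(rng, etco2_cv),
        breath_duration_s=base.breath_duration_s * _jitter(rng, dur_cv),
        plateau_ripple_kpa=base.plateau_ripple_kpa * _jitter(rng, 0.35),
        baseline_tilt_kpa=float(np.clip(
            base.baseline_tilt_kpa + rng.normal(0.0, 0.10),
            -0.35, 0.9 * base.p_base / fracs["frac_I"])),
        **fracs,
    )


def _coupled(
    rng: np.random.Generator, z: np.ndarray, rho: float, mu: float,
    sd: float, sign: float,
) -> np.ndarray:
    """mu + sd * (sign * rho * z + sqrt(1-rho^2) * eps): a noisy monotone
    function of the standardized driver z with correlation ~ sign*rho."""
    eps = rng.standard_normal(len(z))
    return mu + sd * (sign * rho * z + math.sqrt(1.0 - rho * rho) * eps)


def simulate_study(
    design: dict[str, int] | None = None,
    recordings_per_subject: int = 2,
    seed: int = 0,
    duration_s: float = 75.0,
    sampling_rate_hz: float = 10.0,
    breath_variability: float = 0.05,
    artefacts: ArtefactSpec = NO_ARTEFACTS,
    spiro_coupling: float = 0.72,
    lvef_coupling: float = 0.68,
    etco2_recovery_shift: float = 0.126,
    config: PreprocessConfig = DEFAULT_CONFIG,
) -> StudyDataset:
    """Simulate a multi-cohort observational study.

    ``design`` maps cohort name to subject count (default mirrors the
    10/17/9/14 healthy/asthma/CHF/pneumonia layout).  Clinical covariates
    are generated with the stated couplings: spirometry (FEV1/FVC and %
    predicted FEV1) noisily *decreasing* in each asthma subject's true alpha
    angle, LVEF noisily *increasing* in alpha for CHF, NT-proBNP independent
    of alpha.  Pneumonia subjects record in two windows (days 0-7 acute and
    168-175 recovered) with recovered end-tidal CO2 scaled up by
    ``etco2_recovery_shift``.
    """
    design = design or {"healthy": 10, "asthma": 17, "chf": 9,
                        "pneumonia": 14}
    if any(v < 1 for v in design.values()):
        raise ValueError("subject counts must be >= 1")
    ss = np.random.SeedSequence([seed, 0x57D])
    rng_subj, rng_cov = (np.random.default_rng(s) for s in ss.spawn(2))
    records: list[CapnogramRecord] = []
    subj_rows: list[dict] = []

    sid = 0
    for cohort, n_subj in design.items():
        preset = cohort_preset(_STUDY_COHORT_PRESET[cohort])
        for _ in range(n_subj):
            sid += 1
            subject_id = f"S{sid:03d}"
            sp = _subject_params(preset.params, rng_subj)
            true_alpha = breath_truth(sp, config=config)["alpha_deg"]
            subj_rows.append({
                "subject_id": subject_id,
                "cohort": cohort,
                "true_alpha_deg": true_alpha,
                "true_etco2_kpa": sp.etco2,
            })
            rec_seed = int(rng_subj.integers(0, 2**31 - 1))
            windows = [("start", 0.0, sp)]
            if cohort == "pneumonia":
                recovered = replace(
                    sp, etco2=sp.etco2 * (1.0 + etco2_recovery_shift))
                windows = [("start", 0.0, sp), ("end", 168.0, recovered)]
            for wname, day0, wparams in windows:
                for r in range(recordings_per_subject):
                    day = day0 + 7.0 * r / max(recordings_per_subject, 1)
                    rec = simulate_capnogram(
                        CohortPreset(preset.name, wparams,
                                     preset.target_alpha_deg),
                        duration_s=duration_s,
                        sampling_rate_hz=sampling_rate_hz,
                        artefacts=artefacts,
                        breath_variability=breath_variability,
                        seed=rec_seed + 7919 * r + (99991 if wname == "end"
                                                    else 0),
                        subject_id=subject_id,
                        cohort=cohort,
                        recorded_at=f"day{day:07.2f}",
                        config=config,
                    )
                    records.append(rec)

    subjects = pd.DataFrame(subj_rows)

    # ---- clinical covariates -----------------------------------------
    cov = subjects[["subject_id", "cohort"]].copy()
    cov["fev1_fvc_pct"] = np.nan
    cov["fev1_pct_pred"] = np.nan
    cov["lvef_pct"] = np.nan
    cov["nt_probnp_pg_ml"] = np.nan

    def zscore(a: np.ndarray) -> np.ndarray:
        sd = a.std(ddof=0)
        return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)

    m_asthma = subjects["cohort"] == "asthma"
    if m_asthma.any():
        z = zscore(subjects.loc[m_asthma, "true_alpha_deg"].to_numpy())
        cov.loc[m_asthma, "fev1_fvc_pct"] = np.clip(
            _coupled(rng_cov, z, spiro_coupling, 67.0, 10.0, -1.0), 20, 95)
        cov.loc[m_asthma, "fev1_pct_pred"] = np.clip(
            _coupled(rng_cov, z, spiro_coupling, 80.0, 18.0, -1.0), 15, 140)
    m_healthy = subjects["cohort"] == "healthy"
    if m_healthy.any():
        nh = int(m_healthy.sum())
        cov.loc[m_healthy, "fev1_fvc_pct"] = np.clip(
            81.0 + 4.0 * rng_cov.standard_normal(nh), 60, 95)
        cov.loc[m_healthy, "fev1_pct_pred"] = np.clip(
            107.0 + 9.0 * rng_cov.standard_normal(nh), 70, 140)
    m_chf = subjects["cohort"] == "chf"
    if m_chf.any():
        z = zscore(subjects.loc[m_chf, "true_alpha_deg"].to_numpy())
        # LVEF rises with alpha in this cohort (positive association)
        cov.loc[m_chf, "lvef_pct"] = np.clip(
            _coupled(rng_cov, z, lvef_coupling, 40.0, 8.0, +1.0), 10, 75)
        cov.loc[m_chf, "nt_probnp_pg_ml"] = rng_cov.lognormal(
            math.log(1800.0), 0.9, int(m_chf.sum()))
    return StudyDataset(records=records, subjects=subjects, covariates=cov)


def simulate_etco2_recovery(
    n_subjects: int = 8,
    rel_shift: float = 0.126,
    noise_sd_kpa: float = 0.1,
    recordings_per_window: int = 3,
    base_etco2_kpa: float = 3.5,
    subject_cv: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Measurement-level paired-recovery benchmark: per-recording end-tidal
    CO2 values for ``n_subjects`` subjects in a start window (days 0-7,
    acute) and an end window (days 168-175, end-tidal raised by
    ``rel_shift``), with i.i.d. Gaussian measurement noise.

    Returns a tidy frame with columns subject_id, day, etco2_kpa suitable
    for :func:`capnoshape.summary.etco2_change_analysis`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7C]))
    rows = []
    for i in range(n_subjects):
        level = base_etco2_kpa * _jitter(rng, subject_cv)
        for w, (day0, scale) in enumerate(
            [(0.0, 1.0), (168.0, 1.0 + rel_shift)]
        ):
            for r in range(recordings_per_window):
                rows.append({
                    "subject_id": f"P{i + 1:03d}",
                    "day": day0 + 7.0 * r / max(recordings_per_window, 1),
                    "etco2_kpa": level * scale + rng.normal(0, noise_sd_kpa),
                })
    return pd.DataFrame(rows)
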