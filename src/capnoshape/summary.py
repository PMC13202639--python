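"""Standardized waveform averaging and paired end-tidal CO2 change analysis.

Average standardized waveforms are pointwise means of time-normalized
breaths on a common unit-time grid; they are what cohort-level "average
breath shape" figures are drawn from.  The paired analysis tracks recovery
(e.g. from pneumonia) as the relative change in each subject's median
end-tidal CO2 between a start window and an end window, tested with the
exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StandardizedWaveform",
    "PairedEtco2Change",
    "average_waveform",
    "etco2_change_analysis",
]


@dataclass
class StandardizedWaveform:
    grid: np.ndarray
    mean_pco2: np.ndarray
    n_breaths: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ValueError("need at least one breath")
        if len(self.grid) != len(self.mean_pco2):
            raise ValueError("grid/value length mismatch")
        if not np.all(np.isfinite(self.mean_pco2)):
            raise ValueError("non-finite averaged waveform")


def write_waveform_csv(wave: "StandardizedWaveform", path) -> None:
    """Export a standardized waveform as a two-column (grid, mean) CSV."""
    pd.DataFrame({
        "grid": wave.grid, "mean_pco2_kpa": wave.mean_pco2,
    }).to_csv(path, index=False, float_format="%.6g")


def average_waveform(
    breaths: list[np.ndarray], label: str = ""
) -> StandardizedWaveform:
    """Pointwise arithmetic mean of time-normalized breaths sharing a grid."""
    if not breaths:
        raise ValueError("no breaths to average")
    lengths = {len(b) for b in breaths}
    if len(lengths) != 1:
        raise ValueError(f"mismatched waveform grids: lengths {sorted(lengths)}")
    g = lengths.pop()
    mean = np.mean(np.vstack(breaths), axis=0)
    return StandardizedWaveform(
        grid=np.linspace(0.0, 1.0, g),
        mean_pco2=mean,
        n_breaths=len(breaths),
        label=label,
    )


@dataclass
class PairedEtco2Change:
    """Per-subject start/end median ETCO2 and the cohort-level change."""

    per_subject: pd.DataFrame = field(repr=False)
    median_change_pct: float
    p_value: float
    n_subjects: int
    n_excluded: int
    test: str = "wilcoxon"


def _paired_pvalue(diffs: np.ndarray, method: str) -> float:
    diffs = np.asarray(diffs, float)
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0  # degenerate null: no subject changed
    if method == "sign":
        k = int(np.sum(nz > 0))
        return float(sps.binomtest(k, len(nz), 0.5).pvalue)
    mode = "exact" if len(nz) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.wilcoxon(nz, method=mode).pvalue)


def etco2_change_analysis(
    measurements: pd.DataFrame,
    start_window: tuple[float, float],
    end_window: tuple[float, float],
    time_col: str = "day",
    value_col: str = "etco2_kpa",
    method: str = "wilcoxon",
) -> PairedEtco2Change:
    """Paired start-vs-end end-tidal CO2 change.

    ``measurements`` is tidy: one row per valid recording with columns
    ``subject_id``, a time column, and an ETCO2 column.  Windows are
    half-open ``[lo, hi)`` on the time column.  Each subject's ETCO2 in a
    window is the median over their recordings there; subjects missing
    either window are excluded (and counted).  Significance is the exact
    Wilcoxon signed-rank on (end - start) for n <= 25 (config-switchable to
    a sign test).
    """
    if not (start_window[1] <= end_window[0] or
            end_window[1] <= start_window[0]):
        raise ValueError("start and end windows must not overlap")
    rows, excluded = [], 0
    for sid, grp in measurements.groupby("subject_id"):
        t = grp[time_col]
        start_vals = grp.loc[(t >= start_window[0]) & (t < start_window[1]),
                             value_col]
        end_vals = grp.loc[(t >= end_window[0]) & (t < end_window[1]),
                           value_col]
        if start_vals.empty or end_vals.empty:
            excluded += 1
            continue
        s, e = float(start_vals.median()), float(end_vals.median())
        rows.append({
            "subject_id": sid,
            "start_etco2_kpa": s,
            "end_etco2_kpa": e,
            "rel_change_pct": 100.0 * (e - s) / s,
        })
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "start_etco2_kpa", "end_etco2_kpa",
                       "rel_change_pct"],
    )
    if per_subject.empty:
        raise ValueError("no subject has recordings in both windows")
    diffs = (per_subject["end_etco2_kpa"] -
             per_subject["start_etco2_kpa"]).to_numpy()
    return PairedEtco2Change(
        per_subject=per_subject,
        median_change_pct=float(per_subject["rel_change_pct"].median()),
        p_value=_paired_pvalue(diffs, method),
        n_subjects=len(per_subject),
        n_excluded=excluded,
        test=method,
    )
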