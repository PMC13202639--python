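"""Reading and writing capnogram recordings and feature tables.

On-disk dialect
---------------
A capnogram is a plain CSV file with ``# key=value`` header lines carrying
metadata, followed by two columns ``time_s,pco2_kpa``::

    # subject_id=S001
    # cohort=healthy
    # recorded_at=2017-09-08T09:00:00
    # sampling_rate_hz=10.0
    time_s,pco2_kpa
    0.000000,0.051234
    ...

Ground-truth annotations (present only for simulated data) live in a sibling
JSON file named ``<stem>.annotations.json``.  Feature tables are plain CSV,
one row per capnogram, metadata columns first, then the registry's 159
feature columns in registry order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .registry import FeatureRegistry, default_registry

__all__ = [
    "COHORTS",
    "CapnogramRecord",
    "CapnogramFormatError",
    "read_capnogram",
    "write_capnogram",
    "write_feature_table",
    "read_feature_table",
]

COHORTS = ("healthy", "asthma", "chf", "pneumonia", "other")

_METADATA_COLUMNS = ["subject_id", "cohort", "recorded_at", "n_valid_breaths"]


class CapnogramFormatError(ValueError):
    """Raised when a capnogram file does not conform to the dialect."""


@dataclass
class CapnogramRecord:
    """A single tidal-breathing pCO2 recording.

    pCO2 is in kPa; recordings are nominally 75 s of tidal breathing at a
    fixed sampling rate.  ``annotations`` carries simulator ground truth
    (breath boundaries, artefact intervals, per-breath parameters) and is
    absent for anything that emulates real data.
    """

    subject_id: str
    cohort: str
    recorded_at: str
    sampling_rate_hz: float
    pco2_kpa: np.ndarray
    annotations: dict[str, Any] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        p = np.asarray(self.pco2_kpa, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("pCO2 contains non-finite values")
        if np.any(p < 0):
            warnings.warn(
                "negative pCO2 values clipped to 0 kPa", stacklevel=2
            )
            p = np.clip(p, 0.0, None)
        self.pco2_kpa = p

    @property
    def duration_s(self) -> float:
        return len(self.pco2_kpa) / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.pco2_kpa)) / self.sampling_rate_hz

    def replace_samples(self, pco2_kpa: np.ndarray) -> "CapnogramRecord":
        return CapnogramRecord(
            subject_id=self.subject_id,
            cohort=self.cohort,
            recorded_at=self.recorded_at,
            sampling_rate_hz=self.sampling_rate_hz,
            pco2_kpa=np.asarray(pco2_kpa, dtype=float),
            annotations=self.annotations,
        )


def _annotation_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".annotations.json")


def read_capnogram(path: str | Path) -> CapnogramRecord:
    """Read a capnogram CSV (and sibling annotation JSON, if present)."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_seen = False
    times: list[float] = []
    pco2: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise CapnogramFormatError(
                        f"{path}:{lineno}: metadata line after column header"
                    )
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise CapnogramFormatError(
                        f"{path}:{lineno}: malformed metadata line {line!r}"
                    )
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            elif not header_seen:
                if line.replace(" ", "") != "time_s,pco2_kpa":
                    raise CapnogramFormatError(
                        f"{path}:{lineno}: expected column header "
                        f"'time_s,pco2_kpa', got {line!r}"
                    )
                header_seen = True
            else:
                parts = line.split(",")
                if len(parts) != 2:
                    raise CapnogramFormatError(
                        f"{path}:{lineno}: expected two columns, got {line!r}"
                    )
                try:
                    times.append(float(parts[0]))
                    pco2.append(float(parts[1]))
                except ValueError as exc:
                    raise CapnogramFormatError(
                        f"{path}:{lineno}: non-numeric sample {line!r}"
                    ) from exc
    if not header_seen:
        raise CapnogramFormatError(f"{path}: missing column header")
    for key in ("subject_id", "cohort", "sampling_rate_hz"):
        if key not in meta:
            raise CapnogramFormatError(f"{path}: missing metadata key {key!r}")
    t = np.asarray(times)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise CapnogramFormatError(
                f"{path}: non-monotonic time column near row {bad}"
            )
        fs = float(meta["sampling_rate_hz"])
        if not np.allclose(dt, 1.0 / fs, atol=0.25 / fs):
            raise CapnogramFormatError(
                f"{path}: time column is not regular at {fs} Hz"
            )
    annotations = None
    apath = _annotation_path(path)
    if apath.exists():
        annotations = json.loads(apath.read_text())
    return CapnogramRecord(
        subject_id=meta["subject_id"],
        cohort=meta["cohort"],
        recorded_at=meta.get("recorded_at", ""),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        pco2_kpa=np.asarray(pco2, dtype=float),
        annotations=annotations,
    )


def write_capnogram(record: CapnogramRecord, path: str | Path) -> Path:
    """Write a record in the capnogram CSV dialect; round-trips to 6 s.f."""
    path = Path(path)
    if len(record.pco2_kpa) == 0:
        raise ValueError("refusing to write a record with no samples")
    lines = [
        f"# subject_id={record.subject_id}",
        f"# cohort={record.cohort}",
        f"# recorded_at={record.recorded_at}",
        f"# sampling_rate_hz={record.sampling_rate_hz!r}",
        "time_s,pco2_kpa",
    ]
    for t, p in zip(record.time_s, record.pco2_kpa):
        lines.append(f"{t:.6f},{p:.6g}")
    path.write_text("\n".join(lines) + "\n")
    if record.annotations is not None:
        _annotation_path(path).write_text(
            json.dumps(record.annotations, indent=1)
        )
    return path


def write_feature_table(
    vectors: list,
    path: str | Path,
    registry: FeatureRegistry | None = None,
) -> Path:
    """Write aggregated feature vectors as a CSV table.

    One row per capnogram; metadata columns then the 159 feature columns in
    registry order.  All vectors must share one registry version.
    """
    registry = registry or default_registry()
    path = Path(path)
    versions = {v.registry_version for v in vectors}
    if versions and versions != {registry.version}:
        raise ValueError(
            f"mixed or mismatched registry versions: {sorted(versions)} "
            f"vs table registry {registry.version!r}"
        )
    rows = []
    for v in vectors:
        row = {
            "subject_id": v.subject_id,
            "cohort": v.cohort,
            "recorded_at": v.recorded_at,
            "n_valid_breaths": v.n_valid_breaths,
        }
        row.update({name: v.features[name] for name in registry.vector_names})
        rows.append(row)
    columns = _METADATA_COLUMNS + registry.vector_names
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
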