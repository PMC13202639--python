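"""Feature registry: the fixed catalogue of capnogram features.

The registry is data, not code: every downstream table (per-breath feature
sets, aggregated per-capnogram vectors, cohort comparison tables) takes its
column names, ordering, waveform-region tags and aggregation rules from here.

Structure
---------
* 44 raw-time per-breath features,
* 43 time-normalized counterparts (everything except breath duration, which
  is identically 1 after time normalization),
* 5 whole-capnogram features,
* median aggregation for all 87 per-breath features and sample-SD aggregation
  for a designated 67-feature subset, giving 87 + 67 + 5 = 159 per-capnogram
  features.

Each per-breath feature carries exactly one waveform-region tag (``alpha``,
``beta``, ``gamma``, ``delta``, ``plateau``, ``upstroke``, ``timing``,
``amplitude``, ``area``) used for region-grouped effect-size summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "FeatureDef",
    "FeatureRegistry",
    "default_registry",
    "build_default_registry",
    "REGIONS",
]

REGIONS = (
    "alpha",
    "beta",
    "gamma",
    "delta",
    "plateau",
    "upstroke",
    "timing",
    "amplitude",
    "area",
    "whole",
)

#: name, region, family. Families drive the SD-aggregation rule below.
_RAW_DEFS = [
    # interior angles at the waveform corners
    ("alpha_deg", "alpha", "angle"),
    ("beta_deg", "beta", "angle"),
    ("gamma_deg", "gamma", "angle"),
    ("delta_deg", "delta", "angle"),
    # fitted phase-tangent gradients (angle-frame units)
    ("grad_phase1", "delta", "gradient"),
    ("grad_phase2", "alpha", "gradient"),
    ("grad_phase3", "alpha", "gradient"),
    ("grad_phase4", "beta", "gradient"),
    # phase durations
    ("dur_phase1_s", "timing", "duration"),
    ("dur_phase2_s", "timing", "duration"),
    ("dur_phase3_s", "timing", "duration"),
    ("dur_phase4_s", "timing", "duration"),
    # breath timing
    ("breath_duration_s", "timing", "timing"),
    ("expiratory_time_s", "timing", "timing"),
    ("inspiratory_time_s", "timing", "timing"),
    ("ei_ratio", "timing", "timing"),
    # amplitudes
    ("etco2_kpa", "amplitude", "amplitude"),
    ("baseline_kpa", "amplitude", "amplitude"),
    ("amplitude_kpa", "amplitude", "amplitude"),
    ("plateau_mean_kpa", "amplitude", "amplitude"),
    # areas
    ("area_total", "area", "area"),
    ("area_phase2", "area", "area"),
    ("area_phase3", "area", "area"),
    ("area_above_chord", "alpha", "area"),
    # fractional rise/fall times
    ("t_up_25", "upstroke", "fractime"),
    ("t_up_50", "upstroke", "fractime"),
    ("t_up_75", "upstroke", "fractime"),
    ("t_down_75", "gamma", "fractime"),
    ("t_down_50", "gamma", "fractime"),
    ("t_down_25", "gamma", "fractime"),
    # landmark positions (fractions of the breath)
    ("pos_etco2", "plateau", "landmark"),
    ("pos_max_upslope", "upstroke", "landmark"),
    ("pos_max_downslope", "gamma", "landmark"),
    # ratios
    ("ratio_dur_2_3", "timing", "ratio"),
    ("area_per_s", "area", "area"),
    ("amplitude_per_s", "amplitude", "ratio"),
    # shape indices
    ("max_upslope", "alpha", "shape"),
    ("upslope_asymmetry", "alpha", "shape"),
    ("plateau_d2_mean", "alpha", "shape"),
    ("plateau_flatness", "plateau", "shape"),
    # residual / texture
    ("resid_rms_phase2", "alpha", "texture"),
    ("resid_rms_phase3", "beta", "texture"),
    ("plateau_sampen", "plateau", "texture"),
    ("plateau_osc_power", "plateau", "texture"),
]

_WHOLE_DEFS = [
    ("resp_rate_per_min", "whole"),
    ("ibi_cv", "whole"),
    ("etco2_trend_kpa_min", "whole"),
    ("n_valid_breaths", "whole"),
    ("breath_quality_pct", "whole"),
]

# SD aggregation: all 44 raw features, plus the normalized-domain shape
# families (angles, gradients, areas, shape indices, texture) and the three
# normalized amplitude summaries whose dispersion is not a duplicate of a
# raw-domain timing/position feature.  44 + 20 + 3 = 67.
_NORM_SD_FAMILIES = {"angle", "gradient", "area", "shape", "texture"}
_NORM_SD_AREA_EXCLUDE = {"norm_area_per_s"}  # keeps the area family at 4
_NORM_SD_EXTRA = {"norm_etco2_kpa", "norm_amplitude_kpa", "norm_plateau_mean_kpa"}


@dataclass(frozen=True)
class FeatureDef:
    name: str
    region: str
    domain: str  # "raw" | "normalized" | "whole"
    sd_aggregated: bool

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region tag {self.region!r}")
        if self.domain not in ("raw", "normalized", "whole"):
            raise ValueError(f"unknown domain {self.domain!r}")


class FeatureRegistry:
    """Ordered, versioned collection of :class:`FeatureDef`."""

    def __init__(self, version: str, defs: list[FeatureDef]):
        self.version = version
        self.defs = list(defs)
        self._by_name = {d.name: d for d in self.defs}
        if len(self._by_name) != len(self.defs):
            raise ValueError("duplicate feature names in registry")
        self._validate_counts()

    def _validate_counts(self) -> None:
        n_raw = sum(d.domain == "raw" for d in self.defs)
        n_norm = sum(d.domain == "normalized" for d in self.defs)
        n_whole = sum(d.domain == "whole" for d in self.defs)
        n_sd = sum(d.sd_aggregated for d in self.defs)
        if n_raw != 44 or n_norm != 43 or n_whole != 5 or n_sd != 67:
            raise ValueError(
                "registry arithmetic violated: expected 44 raw + 43 normalized "
                f"+ 5 whole with 67 SD-aggregated, got {n_raw}/{n_norm}/"
                f"{n_whole}/{n_sd}"
            )

    # -- views -----------------------------------------------------------
    @property
    def per_breath_names(self) -> list[str]:
        return [d.name for d in self.defs if d.domain in ("raw", "normalized")]

    @property
    def whole_names(self) -> list[str]:
        return [d.name for d in self.defs if d.domain == "whole"]

    @property
    def sd_names(self) -> list[str]:
        return [d.name for d in self.defs if d.sd_aggregated]

    @property
    def vector_names(self) -> list[str]:
        """The 159 aggregated per-capnogram feature names, in fixed order."""
        out = [f"median_{n}" for n in self.per_breath_names]
        out += [f"sd_{n}" for n in self.sd_names]
        out += self.whole_names
        return out

    def region_of(self, name: str) -> str:
        """Region tag for a per-breath, aggregated, or whole feature name."""
        base = name
        for prefix in ("median_", "sd_"):
            if base.startswith(prefix):
                base = base[len(prefix):]
                break
        return self._by_name[base].region

    def __len__(self) -> int:
        return len(self.defs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    # -- (de)serialisation ----------------------------------------------
    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "features": [
                {
                    "name": d.name,
                    "region": d.region,
                    "domain": d.domain,
                    "sd_aggregated": d.sd_aggregated,
                }
                for d in self.defs
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureRegistry":
        payload = json.loads(text)
        defs = [FeatureDef(**entry) for entry in payload["features"]]
        return cls(payload["version"], defs)


def build_default_registry() -> FeatureRegistry:
    """Construct the default_v1 registry from the catalogue above."""
    defs: list[FeatureDef] = []
    for name, region, _family in _RAW_DEFS:
        defs.append(FeatureDef(name, region, "raw", True))
    for name, region, family in _RAW_DEFS:
        if name == "breath_duration_s":
            continue  # identically 1 after time normalization
        nname = f"norm_{name}"
        sd = (
            family in _NORM_SD_FAMILIES and nname not in _NORM_SD_AREA_EXCLUDE
        ) or nname in _NORM_SD_EXTRA
        defs.append(FeatureDef(nname, region, "normalized", sd))
    for name, region in _WHOLE_DEFS:
        defs.append(FeatureDef(name, region, "whole", False))
    return FeatureRegistry("default_v1", defs)


def default_registry() -> FeatureRegistry:
    """Load the shipped default_v1 registry (falls back to the builder)."""
    try:
        text = (
            resources.files("capnoshape").joinpath("data/registry_default_v1.json")
        ).read_text()
        return FeatureRegistry.from_json(text)
    except (FileNotFoundError, ModuleNotFoundError):  # pragma: no cover
        return build_default_registry()
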