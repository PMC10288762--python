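"""Analysis configuration: controlled vocabularies and cut-point tables.

All rule tables (region vocabulary, visual-rating cut points, severity-band
thresholds) are loaded from a YAML file rather than hard-coded, so that the
classification rules are auditable and can be versioned alongside a study.
A default configuration ships with the package.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

HEMISPHERES = ("left", "right")
VISITS = ("baseline", "followup")
ARM_LEVELS = ("placebo", "donepezil")
SEX_LEVELS = ("female", "male")
EDUCATION_LEVELS = (
    "none",
    "primary",
    "certification_of_primary",
    "secondary",
    "higher",
)
FIELD_STRENGTH_LEVELS = ("1.5T", "3T")
SEVERITY_BANDS = ("no_atrophy", "mild", "moderate", "severe")
SUBTYPE_LABELS = (
    "typical_AD",
    "limbic_predominant",
    "hippocampal_sparing",
    "minimal_atrophy",
)


@dataclass(frozen=True)
class AgeBand:
    """Half-open age band [lower, upper); the final band of a table is closed."""

    lower: float
    upper: float


@dataclass(frozen=True)
class CutpointTable:
    """Thresholds turning rating scores and the BV/CSF index into labels.

    ``mta_cuts`` maps age bands to the minimum mean MTA score considered
    abnormal. ``pa_cut`` and ``gcaf_cut`` apply at any age. Scores >= cut are
    abnormal. ``severity_band_cuts`` maps age bands to descending BV/CSF
    thresholds (no_atrophy, mild, moderate); an index exactly on a boundary is
    assigned to the less-atrophic band.
    """

    mta_cuts: tuple[tuple[AgeBand, float], ...]
    pa_cut: float = 1.0
    gcaf_cut: float = 1.0
    severity_band_cuts: tuple[tuple[AgeBand, tuple[float, float, float]], ...] = ()

    def __post_init__(self) -> None:
        for bands in (self.mta_cuts, self.severity_band_cuts):
            prev_upper = None
            for band, _ in bands:
                if band.upper <= band.lower:
                    raise ValueError(f"degenerate age band {band}")
                if prev_upper is not None and band.lower != prev_upper:
                    raise ValueError("age bands must be contiguous and non-overlapping")
                prev_upper = band.upper

    @property
    def age_support(self) -> tuple[float, float]:
        return (self.mta_cuts[0][0].lower, self.mta_cuts[-1][0].upper)


@dataclass(frozen=True)
class AnalysisConfig:
    """Vocabulary and rule tables shared by every pipeline stage."""

    cortical_regions: tuple[str, ...]
    subcortical_structures: tuple[str, ...]
    required_subcortical: tuple[str, ...]
    typicality_regions: Mapping[str, tuple[str, ...]]
    signature_regions: tuple[str, ...]
    cutpoints: CutpointTable
    cognitive_tests: tuple[str, ...]
    kruskal_variables: tuple[str, ...] = ()
    hc_ratio_display_scale: float = 100.0

    def __post_init__(self) -> None:
        known = set(self.cortical_regions)
        for name, parts in self.typicality_regions.items():
            unknown = set(parts) - known
            if unknown:
                raise ValueError(f"typicality region {name!r} uses unknown labels {sorted(unknown)}")
        unknown = set(self.signature_regions) - known
        if unknown:
            raise ValueError(f"signature regions use unknown labels {sorted(unknown)}")
        missing = set(self.required_subcortical) - set(self.subcortical_structures)
        if missing:
            raise ValueError(f"required subcortical structures missing from vocabulary: {sorted(missing)}")


def _parse_bands(entries: Sequence[Mapping], keys: Sequence[str]) -> list[tuple[AgeBand, tuple]]:
    out = []
    for e in entries:
        band = AgeBand(float(e["age_min"]), float(e["age_max"]))
        vals = tuple(float(e[k]) for k in keys)
        out.append((band, vals[0] if len(vals) == 1 else vals))
    return out


def config_from_dict(raw: Mapping) -> AnalysisConfig:
    cp = raw["cutpoints"]
    cut_table = CutpointTable(
        mta_cuts=tuple(_parse_bands(cp["mta"], ["cut"])),
        pa_cut=float(cp["pa"]),
        gcaf_cut=float(cp["gcaf"]),
        severity_band_cuts=tuple(
            _parse_bands(cp["severity_bands"], ["no_atrophy", "mild", "moderate"])
        ),
    )
    return AnalysisConfig(
        cortical_regions=tuple(raw["cortical_regions"]),
        subcortical_structures=tuple(raw["subcortical_structures"]),
        required_subcortical=tuple(raw["required_subcortical"]),
        typicality_regions={k: tuple(v) for k, v in raw["typicality_regions"].items()},
        signature_regions=tuple(raw["signature_regions"]),
        cutpoints=cut_table,
        cognitive_tests=tuple(raw["cognitive_tests"]),
        kruskal_variables=tuple(raw.get("kruskal_variables", ())),
        hc_ratio_display_scale=float(raw.get("hc_ratio_display_scale", 100.0)),
    )


def load_config(path) -> AnalysisConfig:
    """Load an analysis configuration from a YAML file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


@functools.lru_cache(maxsize=1)
def default_config() -> AnalysisConfig:
    """The configuration shipped with the package (Desikan vocabulary plus
    published visual-rating cut points; severity-band thresholds are marked
    placeholders in the YAML)."""
    text = resources.files("mrisubtype").joinpath("data/default_config.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
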