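"""Model parameters for a single alveolus, with validation and presets.

All quantities live in a fixed internal unit system: pressures in mmHg,
lengths in micrometres, volumes in cubic micrometres, time in seconds,
temperature in degrees Celsius and oxygen amounts in millilitres of gas
(STPD).  Unit conversion (mmHg <-> kPa) happens only at I/O boundaries.

The default parameter set describes a normal, healthy alveolus: an
alveolar surface of 121,000 um^2 (58 % of the maximal air-exposed
surface), a 1.11 um tissue barrier, a half-recruited capillary bed
(404,000 of 808,000 um^3 perfused), blood flowing at 1 mm/s through
500 um capillaries, and textbook boundary gas tensions (alveolar
pO2/pCO2 100/40 mmHg, mixed-venous blood 40/45 mmHg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

__all__ = [
    "AlveolusParameters",
    "LungScale",
    "PathologyPreset",
    "Violation",
    "PARAMETER_RANGES",
    "PRESETS",
    "default_parameters",
    "validate_parameters",
    "derived_quantities",
    "apply_preset",
    "classify_parameter",
    "convert_pressure",
    "MMHG_PER_KPA",
]

#: 101.325 kPa == 760 mmHg
MMHG_PER_KPA = 760.0 / 101.325
KPA_PER_MMHG = 101.325 / 760.0


class DegenerateGeometryError(ValueError):
    """Capillary radius or length of zero leaves the geometry undefined."""


@dataclass(frozen=True)
class AlveolusParameters:
    """Complete parameter set for one simulation instance.

    ``blood_pO2_in`` / ``blood_pCO2_in`` are the gas tensions of the
    inflowing (mixed-venous) blood at the capillary inlet; the alveolar
    tensions are held fixed during a run (gas lost to the blood is
    treated as instantly replenished by ventilation).
    """

    alveolar_pO2: float = 100.0          # mmHg
    blood_pO2_in: float = 40.0           # mmHg, capillary inlet (venous)
    alveolar_pCO2: float = 40.0          # mmHg
    blood_pCO2_in: float = 45.0          # mmHg, capillary inlet (venous)
    surface_area: float = 121_000.0      # um^2 exposed to air
    barrier_thickness: float = 1.11      # um
    blood_flow_velocity: float = 1.0     # mm/s
    blood_volume: float = 404_000.0      # um^3 perfused ("recruited")
    blood_temperature: float = 37.0      # degC
    ph_rbc: float = 7.24                 # erythrocyte pH
    dpg_concentration: float = 4.65      # mM 2,3-bisphosphoglycerate
    # Fixed morphology (not user-sweepable)
    capillary_length: float = 500.0      # um
    capillary_bed_volume: float = 808_000.0  # um^3, maximal bed
    capillary_radius: float = 3.15       # um
    respiratory_exchange_ratio: float = 0.82  # CO2 produced / O2 consumed


#: Allowed range per adjustable field (inclusive).
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "alveolar_pO2": (1.0, 150.0),
    "blood_pO2_in": (1.0, 150.0),
    "alveolar_pCO2": (1.0, 150.0),
    "blood_pCO2_in": (1.0, 150.0),
    "surface_area": (0.0, 210_000.0),
    "barrier_thickness": (0.1, 3.0),
    "blood_flow_velocity": (0.01, 2.0),
    "blood_volume": (1.0, 808_000.0),
    "blood_temperature": (20.0, 44.0),
    "ph_rbc": (5.8, 8.2),
    "dpg_concentration": (1.0, 10.0),
}

#: Fields that are fixed constants of the configuration.
FIXED_FIELDS = ("capillary_length", "capillary_bed_volume", "capillary_radius")


@dataclass(frozen=True)
class LungScale:
    """Whole-organ reference quantities used for extrapolation."""

    n_alveoli: float = 480e6
    max_surface_area: float = 207_000.0      # um^2, 100 % surface exposure
    max_bed_volume: float = 808_000.0        # um^3, 100 % recruitment
    whole_lung_dmo2_per_kg: float = 0.079    # ml/(s x mmHg x kg), morphometric reference
    body_weight: float = 70.0                # kg

    def __post_init__(self) -> None:
        if self.n_alveoli <= 0 or self.max_surface_area <= 0 or self.max_bed_volume <= 0:
            raise ValueError("lung-scale reference values must be strictly positive")


@dataclass(frozen=True)
class Violation:
    """A single out-of-range parameter value (data, not an exception)."""

    field: str
    value: float
    allowed: tuple[float, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.allowed
        return f"{self.field}={self.value!r} outside allowed range [{lo}, {hi}]"


def default_parameters() -> AlveolusParameters:
    """Return the default (healthy) parameter set."""
    return AlveolusParameters()


def validate_parameters(p: AlveolusParameters) -> list[Violation]:
    """Check every adjustable field against its allowed range.

    Returns an empty list iff the configuration is valid.  A blood
    volume of exactly zero is tolerated as the degenerate no-perfusion
    limit (it yields zero uptake and zero diffusing capacity) but is
    reported as a violation so callers can decide.
    """
    out: list[Violation] = []
    for name, (lo, hi) in PARAMETER_RANGES.items():
        value = getattr(p, name)
        if name == "blood_volume":
            hi = min(hi, p.capillary_bed_volume)
        if not (lo <= value <= hi):
            out.append(Violation(name, value, (lo, hi)))
    return out


def derived_quantities(p: AlveolusParameters, lung: LungScale | None = None) -> dict[str, float]:
    """Quantities computed from the raw parameter set.

    capillary_count
        Number of capillaries the maximal bed volume corresponds to,
        ``round(bed_volume / (pi r^2 L))`` (52 for the default geometry).
    recruitment_fraction
        Perfused share of the maximal capillary bed.
    surface_exposure_fraction
        Share of the maximal air-exposed alveolar surface.
    blood_turnover_rate
        Inverse transit time v/L in 1/s.
    """
    lung = lung or LungScale()
    if p.capillary_radius <= 0 or p.capillary_length <= 0:
        raise DegenerateGeometryError("capillary radius and length must be positive")
    single = math.pi * p.capillary_radius**2 * p.capillary_length
    return {
        "capillary_count": round(p.capillary_bed_volume / single),
        "recruitment_fraction": p.blood_volume / lung.max_bed_volume,
        "surface_exposure_fraction": p.surface_area / lung.max_surface_area,
        "blood_turnover_rate": p.blood_flow_velocity * 1000.0 / p.capillary_length,
    }


# ---------------------------------------------------------------------------
# Pathology presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shift:
    """One parameter shift: relative factor or absolute offset."""

    kind: str      # "relative" | "absolute"
    amount: float  # e.g. -0.3 for a 30 % decrease, +2.0 for +2 degC

    def apply(self, value: float) -> float:
        if self.kind == "relative":
            return value * (1.0 + self.amount)
        return value + self.amount


@dataclass(frozen=True)
class PathologyPreset:
    """Named set of parameter shifts mimicking a pathogenic condition.

    Only shift *directions* are physiologically established; the
    magnitudes used here (30 % for a single-arrow shift, 80 % for a
    double arrow, +2 degC for fever) are this package's documented
    convention and can be overridden by constructing custom presets.
    """

    name: str
    description: str
    parameter_shifts: Mapping[str, Shift] = field(default_factory=dict)


_UP, _DOWN = 0.30, -0.30
_UP2, _DOWN2 = 0.80, -0.80

PRESETS: dict[str, PathologyPreset] = {
    preset.name: preset
    for preset in (
        PathologyPreset(
            "pneumonia",
            "Infection: fever, tissue damage, fluid accumulation",
            {
                "blood_temperature": Shift("absolute", +2.0),
                "surface_area": Shift("relative", _DOWN),
                "barrier_thickness": Shift("relative", _UP),
            },
        ),
        PathologyPreset(
            "ards",
            "Acute respiratory distress syndrome: alveolar collapse, fever",
            {
                "surface_area": Shift("relative", _DOWN2),
                "blood_temperature": Shift("absolute", +2.0),
            },
        ),
        PathologyPreset(
            "copd",
            "Chronic obstructive pulmonary disease: impaired exhalation, tissue damage",
            {
                "alveolar_pCO2": Shift("relative", _UP),
                "blood_pCO2_in": Shift("relative", _UP),
                "alveolar_pO2": Shift("relative", _DOWN),
                "surface_area": Shift("relative", _DOWN),
            },
        ),
        PathologyPreset(
            "pulmonary_fibrosis",
            "Thickened, scarred connective tissue; impaired inhalation",
            {
                "barrier_thickness": Shift("relative", _UP),
                "alveolar_pCO2": Shift("relative", _DOWN),
            },
        ),
        PathologyPreset(
            "pulmonary_embolism",
            "Vascular occlusion: shunt with collapsed perfusion",
            {
                "blood_volume": Shift("relative", _DOWN2),
                "blood_flow_velocity": Shift("relative", _DOWN2),
            },
        ),
    )
}


def apply_preset(p: AlveolusParameters, preset: PathologyPreset) -> AlveolusParameters:
    """Return a copy of *p* with the preset's shifts applied.

    The input is untouched.  Shifted values are clamped to their allowed
    ranges; a shift that would still leave the configuration invalid
    raises ``ValueError`` naming the offending fields.
    """
    updates: dict[str, float] = {}
    for name, shift in preset.parameter_shifts.items():
        if name not in PARAMETER_RANGES:
            raise KeyError(f"preset {preset.name!r} shifts unknown parameter {name!r}")
        lo, hi = PARAMETER_RANGES[name]
        updates[name] = min(hi, max(lo, shift.apply(getattr(p, name))))
    shifted = replace(p, **updates)
    bad = validate_parameters(shifted)
    if bad:
        raise ValueError(f"preset {preset.name!r} produced invalid values: " + "; ".join(map(str, bad)))
    return shifted


# ---------------------------------------------------------------------------
# Traffic-light classification
# ---------------------------------------------------------------------------

#: keyword used when a parameter deviates in the given direction
_KEYWORDS: dict[str, tuple[str, str]] = {
    # field: (keyword when low, keyword when high)
    "blood_temperature": ("hypothermia", "fever"),
    "surface_area": ("tissue damage / collapse", "hyperexpansion"),
    "barrier_thickness": ("thinned barrier", "thickened / scarred tissue"),
    "alveolar_pO2": ("impaired ventilation", "hyperoxia"),
    "alveolar_pCO2": ("impaired inhalation", "impaired exhalation"),
    "blood_pO2_in": ("hypoxemia", "elevated venous oxygen"),
    "blood_pCO2_in": ("hypocapnia", "impaired exhalation"),
    "blood_volume": ("shunt / de-recruitment", "congestion"),
    "blood_flow_velocity": ("shunt / stasis", "hyperperfusion"),
    "ph_rbc": ("acidosis", "alkalosis"),
    "dpg_concentration": ("2,3-DPG depletion", "hypoxia adaptation"),
}

#: absolute half-widths of the healthy band for fields where a relative
#: band makes no physiological sense
_ABSOLUTE_HEALTHY_BAND = {"blood_temperature": 1.0, "ph_rbc": 0.1}


def classify_parameter(name: str, value: float) -> dict[str, str]:
    """Classify a parameter value as healthy, borderline or pathological.

    The default value is always healthy.  The healthy band is +-10 %
    around the default (temperature: +-1 degC, pH: +-0.1 absolute);
    values outside the middle 50 % of the allowed range are
    pathological; everything between is borderline.
    """
    if name not in PARAMETER_RANGES:
        raise KeyError(f"unknown parameter {name!r}")
    default = getattr(default_parameters(), name)
    lo, hi = PARAMETER_RANGES[name]
    if name in _ABSOLUTE_HEALTHY_BAND:
        half = _ABSOLUTE_HEALTHY_BAND[name]
    else:
        half = 0.10 * abs(default)
    quarter = 0.25 * (hi - lo)
    low_kw, high_kw = _KEYWORDS[name]
    if abs(value - default) <= half:
        return {"category": "healthy", "keyword": "normal"}
    keyword = low_kw if value < default else high_kw
    if value < lo + quarter or value > hi - quarter:
        return {"category": "pathological", "keyword": keyword}
    return {"category": "borderline", "keyword": keyword}


def convert_pressure(value: float, target_unit: str) -> float:
    """Convert an internal mmHg pressure to ``"mmHg"`` or ``"kPa"``."""
    if not math.isfinite(value):
        raise ValueError("pressure must be finite")
    if target_unit == "mmHg":
        return value
    if target_unit == "kPa":
        return value * KPA_PER_MMHG
    raise ValueError(f"unknown pressure unit {target_unit!r}")


def pressure_to_mmhg(value: float, source_unit: str) -> float:
    """Inverse of :func:`convert_pressure` (used at input boundaries)."""
    if source_unit == "mmHg":
        return value
    if source_unit == "kPa":
        return value * MMHG_PER_KPA
    raise ValueError(f"unknown pressure unit {source_unit!r}")


def parameters_from_mapping(data: Mapping[str, float]) -> AlveolusParameters:
    """Build a parameter set from a flat mapping; unknown keys rejected."""
    known = {f.name for f in fields(AlveolusParameters)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown parameter key(s): {', '.join(sorted(unknown))}")
    return AlveolusParameters(**dict(data))
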