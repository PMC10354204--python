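"""Body-mass and ontogenetic-age estimation from limb-bone measurements.

Masses come from extant-scaling allometries of the form
log10(mass) = a * log10(circumference) + b, shipped as a versioned JSON
registry (``data/equations.json``) rather than hard-coded, and are reported
in kg with a symmetric error band from the equation's percent prediction
error.  Immature individuals are handled by developmental mass
extrapolation (DME): the mass of a somatically mature reference is scaled
by the cube of a linear-dimension ratio, assuming isometric proportions.
Age for the psittacosaurid comes from an empirical linear femur-length-age
relationship (years = 0.0615 * femur length in mm - 1.9214).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from typing import Mapping

__all__ = [
    "AGE_SLOPE_PER_MM",
    "AGE_INTERCEPT_YR",
    "ScalingEquation",
    "MassEstimate",
    "load_equations",
    "age_from_femur",
    "mass_from_equation",
    "dme_scale",
    "estimate_specimen",
]

# femur-length -> age line for Psittacosaurus lujiatunensis (years, mm)
AGE_SLOPE_PER_MM = 0.0615
AGE_INTERCEPT_YR = -1.9214


@dataclasses.dataclass(frozen=True)
class ScalingEquation:
    """One log10-log10 allometry: mass = 10**(slope*log10(x) + intercept)."""

    name: str
    slope: float
    intercept: float
    input: str  # measurement field the equation consumes, in mm
    output_unit: str  # "g" or "kg"; converted to kg at evaluation
    ppe: float  # percent prediction error as a fraction, e.g. 0.256

    def __post_init__(self):
        if self.output_unit not in ("g", "kg"):
            raise ValueError(f"unknown output unit {self.output_unit!r}")
        if self.ppe < 0:
            raise ValueError("percent prediction error must be >= 0")


@dataclasses.dataclass(frozen=True)
class MassEstimate:
    """Point mass and symmetric error band, both in kg."""

    mass_kg: float
    band_kg: float
    equation: str
    dme_ratio: float = 1.0

    def __post_init__(self):
        if self.mass_kg <= 0 or self.band_kg < 0:
            raise ValueError("mass must be positive and band nonnegative")


def load_equations(path=None) -> dict[str, ScalingEquation]:
    """Load the scaling-equation registry (package data or a user JSON)."""
    if path is None:
        ref = importlib.resources.files("predscale").joinpath("data/equations.json")
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out = {}
    for name, spec in raw["equations"].items():
        out[name] = ScalingEquation(
            name=name,
            slope=float(spec["slope"]),
            intercept=float(spec["intercept"]),
            input=spec["input"],
            output_unit=spec["output_unit"],
            ppe=float(spec["ppe"]),
        )
    return out


def age_from_femur(femur_length_mm: float) -> float:
    """Age in years from femur length via the empirical growth line.

    Valid only above the line's zero-age root (~31.24 mm); returns the
    unrounded value, display rounding is the caller's business.
    """
    root = -AGE_INTERCEPT_YR / AGE_SLOPE_PER_MM
    if femur_length_mm <= root:
        raise ValueError(
            f"femur length must exceed {root:.4f} mm (zero-age root), got {femur_length_mm}"
        )
    return AGE_SLOPE_PER_MM * femur_length_mm + AGE_INTERCEPT_YR


def _measurement_value(eq: ScalingEquation, measurements: Mapping[str, float]) -> float:
    if eq.input == "combined_stylopodial_circumference":
        # combined humeral + femoral minimum shaft circumference
        if "combined_stylopodial_circumference" in measurements:
            val = measurements["combined_stylopodial_circumference"]
        else:
            try:
                val = (
                    measurements["humerus_circumference"]
                    + measurements["femur_circumference"]
                )
            except KeyError as exc:
                raise KeyError(
                    f"equation {eq.name!r} needs humerus and femur circumferences"
                ) from exc
    else:
        try:
            val = measurements[eq.input]
        except KeyError as exc:
            raise KeyError(f"equation {eq.name!r} needs measurement {eq.input!r}") from exc
    val = float(val)
    if val <= 0:
        raise ValueError(f"measurement {eq.input!r} must be positive, got {val}")
    return val


def mass_from_equation(eq: ScalingEquation, measurements: Mapping[str, float]) -> MassEstimate:
    """Evaluate a scaling equation on a measurement mapping (mm -> kg)."""
    import math

    x = _measurement_value(eq, measurements)
    mass = 10.0 ** (eq.slope * math.log10(x) + eq.intercept)
    if eq.output_unit == "g":
        mass /= 1000.0
    return MassEstimate(mass_kg=mass, band_kg=mass * eq.ppe, equation=eq.name)


def dme_scale(reference: MassEstimate, linear_ratio: float) -> MassEstimate:
    """Developmental mass extrapolation: scale mass (and band) by ratio**3."""
    if linear_ratio <= 0:
        raise ValueError(f"linear ratio must be positive, got {linear_ratio}")
    f = linear_ratio**3
    return MassEstimate(
        mass_kg=reference.mass_kg * f,
        band_kg=reference.band_kg * f,
        equation=reference.equation,
        dme_ratio=reference.dme_ratio * linear_ratio,
    )


def estimate_specimen(
    measurements: Mapping[str, float],
    equation: str,
    registry: Mapping[str, ScalingEquation] | None = None,
    dme_linear_ratio: float | None = None,
) -> dict:
    """Compose mass (with optional DME) and age for one specimen.

    Returns a JSON-serializable dict with full provenance: the equation
    used, inputs, DME ratio, and the age estimate when a femur length is
    present.  Re-loading the dict and re-running with the same inputs
    reproduces the identical estimate.
    """
    registry = load_equations() if registry is None else registry
    if equation not in registry:
        raise KeyError(
            f"unknown equation {equation!r}; registered: {sorted(registry)}"
        )
    est = mass_from_equation(registry[equation], measurements)
    if dme_linear_ratio is not None:
        est = dme_scale(est, dme_linear_ratio)
    out = {
        "equation": est.equation,
        "dme_ratio": est.dme_ratio,
        "mass_kg": est.mass_kg,
        "band_kg": est.band_kg,
        "inputs": {k: float(v) for k, v in measurements.items()},
    }
    if "femur_length" in measurements:
        out["age_years"] = age_from_femur(float(measurements["femur_length"]))
    return out
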