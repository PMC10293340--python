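"""Hadlock fetal weight estimation from biometric measurements.

The four Hadlock formulas are empirical log-linear regressions that estimate
fetal weight (grams) from up to four biometric measurements in centimetres:
abdominal circumference (AC), femur length (FL), head circumference (HC) and
biparietal diameter (BPD).  Each formula returns

    weight = 10 ** L(AC, FL, HC, BPD)

with L a fixed linear-plus-interaction expression.  The formulas are known to
be less reliable for very small and very large fetuses; inputs outside the
usual physiological ranges therefore warn rather than fail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .quantification import WeightEstimate

#: Usual physiological ranges (cm) for late-pregnancy biometry.  Values
#: outside these trigger a warning, not an error.
PHYSIOLOGICAL_RANGES_CM = {
    "AC": (15.0, 45.0),
    "FL": (2.0, 9.0),
    "HC": (15.0, 40.0),
    "BPD": (4.0, 12.0),
}

#: Measurements required by each formula.
FORMULA_INPUTS = {
    1: ("AC", "FL"),
    2: ("AC", "FL", "BPD"),
    3: ("AC", "FL", "HC"),
    4: ("AC", "FL", "HC", "BPD"),
}


@dataclass
class BiometrySet:
    """HC/BPD/AC/FL in centimetres; fields a formula does not need may be None."""

    HC: float | None = None
    BPD: float | None = None
    AC: float | None = None
    FL: float | None = None

    def __post_init__(self) -> None:
        for name in ("HC", "BPD", "AC", "FL"):
            v = getattr(self, name)
            if v is None:
                continue
            if v < 0:
                raise ValueError(f"{name} cannot be negative (got {v})")
            lo, hi = PHYSIOLOGICAL_RANGES_CM[name]
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{name} = {v:.2f} cm outside usual range [{lo}, {hi}] cm; "
                    "Hadlock formulas are less reliable for small and large fetuses",
                    stacklevel=2,
                )


def _log10_weight(formula: int, AC: float, FL: float, HC: float, BPD: float) -> float:
    if formula == 1:
        return 1.304 + 0.05281 * AC + 0.1938 * FL - 0.004 * AC * FL
    if formula == 2:
        return 1.335 - 0.0034 * AC * FL + 0.0316 * BPD + 0.0457 * AC + 0.1623 * FL
    if formula == 3:
        return 1.326 - 0.00326 * AC * FL + 0.0107 * HC + 0.0438 * AC + 0.158 * FL
    if formula == 4:
        return (
            1.3596
            - 0.00386 * AC * FL
            + 0.0064 * HC
            + 0.00061 * BPD * AC
            + 0.0424 * AC
            + 0.174 * FL
        )
    raise ValueError(f"formula must be 1..4, got {formula}")


def hadlock_weight(formula: int, b: BiometrySet) -> WeightEstimate:
    """Evaluate Hadlock formula 1–4 on a biometry set; result in grams.

    Formula 1 needs AC and FL; 2 adds BPD; 3 adds HC; 4 uses all four.
    Missing required measurements raise an argument error.
    """
    if formula not in FORMULA_INPUTS:
        raise ValueError(f"formula must be 1..4, got {formula}")
    values = {}
    for name in FORMULA_INPUTS[formula]:
        v = getattr(b, name)
        if v is None:
            raise ValueError(f"Hadlock formula {formula} requires {name}")
        values[name] = float(v)
    L = _log10_weight(
        formula,
        AC=values.get("AC", 0.0),
        FL=values.get("FL", 0.0),
        HC=values.get("HC", 0.0),
        BPD=values.get("BPD", 0.0),
    )
    return WeightEstimate(grams=10.0**L, source=f"hadlock_{formula}")


def ramanujan_perimeter_cm(a_cm: float, b_cm: float) -> float:
    """Ramanujan's approximation to the perimeter of an ellipse (semi-axes in cm).

    P ≈ π [ 3(a+b) − sqrt((3a+b)(a+3b)) ]; exact for a circle and accurate to
    well below 0.01% for the mild eccentricities of head and abdominal
    cross-sections.
    """
    if a_cm < 0 or b_cm < 0:
        raise ValueError("semi-axes must be non-negative")
    return math.pi * (
        3.0 * (a_cm + b_cm) - math.sqrt((3.0 * a_cm + b_cm) * (a_cm + 3.0 * b_cm))
    )


def phantom_biometry(spec) -> BiometrySet:
    """Analytic biometry of a synthetic gravid-uterus phantom.

    BPD is the head ellipsoid's minor full axis; HC and AC are Ramanujan
    perimeters of the head's axial (in-plane) cross-section and of the trunk's
    cross-section perpendicular to its long axis; FL is the femur segment
    length.  All closed form, standing in for the manual caliper measurements
    performed on real images.
    """
    from .phantom import scene_geometry  # local import to avoid a cycle

    geo = scene_geometry(spec)
    head = geo["head_semi_mm"]
    trunk = geo["trunk_semi_mm"]
    # Head long axis is x; axial cross-section is the (x, y) plane.
    hc = ramanujan_perimeter_cm(head[0] / 10.0, head[1] / 10.0)
    bpd = 2.0 * min(head) / 10.0
    # Trunk long axis is x; AC is the (y, z) cross-section.
    ac = ramanujan_perimeter_cm(trunk[1] / 10.0, trunk[2] / 10.0)
    fl = geo["femur_length_mm"] / 10.0
    return BiometrySet(HC=hc, BPD=bpd, AC=ac, FL=fl)
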