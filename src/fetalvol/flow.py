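"""Phase-contrast flow quantification over an ROI, and indexing to fetal weight.

A phase-contrast acquisition yields one signed in-plane velocity map (cm/s)
per reconstructed cardiac phase.  Flow through a vessel is obtained by
summing velocity × pixel area over a region of interest drawn around the
vessel lumen, averaging over the cardiac cycle, and converting to ml/min.
Indexed flow (ml/min/kg) divides by fetal weight to remove the confounding
effect of fetal size on absolute flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default velocity-encoding limit (cm/s); velocities beyond it would alias.
DEFAULT_VENC_CM_S = 150.0


@dataclass
class FlowSeries:
    """Cardiac-phase-resolved velocity maps for one vessel plane.

    velocity_maps: array of shape (n_phases, ny, nx), signed cm/s.
    pixel_area_mm2: in-plane pixel area in mm².
    rr_ms: cardiac cycle duration in ms.
    venc_cm_s: velocity-encoding limit; |velocity| must not exceed it.
    truth_flow_ml_min: analytic ground-truth mean flow (phantoms only).
    """

    velocity_maps: np.ndarray
    pixel_area_mm2: float
    rr_ms: float
    venc_cm_s: float = DEFAULT_VENC_CM_S
    truth_flow_ml_min: float | None = None

    def __post_init__(self) -> None:
        self.velocity_maps = np.asarray(self.velocity_maps, dtype=float)
        if self.velocity_maps.ndim != 3 or self.velocity_maps.shape[0] < 1:
            raise ValueError("velocity_maps must be (n_phases, ny, nx) with ≥ 1 phase")
        if self.pixel_area_mm2 <= 0:
            raise ValueError("pixel_area_mm2 must be positive")
        if self.rr_ms <= 0:
            raise ValueError("rr_ms must be positive")
        if np.max(np.abs(self.velocity_maps)) > self.venc_cm_s + 1e-9:
            raise ValueError("velocity exceeds VENC; aliasing is not modelled")

    @property
    def n_phases(self) -> int:
        return self.velocity_maps.shape[0]


@dataclass
class FlowResult:
    """Mean flow in ml/min, optionally indexed to fetal weight (ml/min/kg)."""

    flow_ml_min: float
    indexed_ml_min_kg: float | None = None
    per_phase_ml_s: np.ndarray | None = None


def flow_ml_per_min(f: FlowSeries, roi: np.ndarray) -> FlowResult:
    """Integrate velocity over an ROI and average over the cardiac cycle.

    Per phase, instantaneous flow = Σ_roi velocity(cm/s) · pixel_area(mm²),
    with 1 cm/s · 1 mm² = 0.01 ml/s.  Phases are weighted equally
    (retrospective cine convention); the result is the cycle average × 60.
    Negative (reversed-flow) pixels subtract.
    """
    roi = np.asarray(roi)
    if roi.shape != f.velocity_maps.shape[1:]:
        raise ValueError(
            f"ROI shape {roi.shape} does not match velocity maps "
            f"{f.velocity_maps.shape[1:]}"
        )
    roi = roi.astype(bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    # (n_phases,) instantaneous flow in ml/s
    per_phase = f.velocity_maps[:, roi].sum(axis=1) * f.pixel_area_mm2 * 0.01
    flow = float(per_phase.mean() * 60.0)
    return FlowResult(flow_ml_min=flow, per_phase_ml_s=per_phase)


def index_flow(flow_ml_min: float, weight) -> float:
    """Index absolute flow to fetal weight: ml/min divided by weight in kg."""
    grams = getattr(weight, "grams", weight)
    if grams <= 0:
        raise ValueError("weight must be positive to index flow")
    return float(flow_ml_min / (grams / 1000.0))
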