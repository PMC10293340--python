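"""Volume, weight and overlap measurements on label maps.

The measurement layer converts a segmentation into the clinically reported
quantities: structure volumes in millilitres (voxel counting), fetal weight
in grams (volume × fetal tissue density of 1.04 kg/l), and the Dice
similarity coefficient against a reference segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import LabelMap

#: Fetal tissue density in kg/l (equivalently g/ml) used for the volume to
#: weight conversion, as established for late-gestation fetuses.
FETAL_DENSITY_KG_L = 1.04


@dataclass
class WeightEstimate:
    """A fetal weight in grams together with its provenance.

    source is "mri_volume" for density-based weights or "hadlock_N"
    (N = 1..4) for biometry-based estimates.
    """

    grams: float
    source: str

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError("weight cannot be negative")


def label_volume_ml(l: LabelMap, class_index: int) -> float:
    """Volume of one label class: voxel count × voxel volume, in ml."""
    if not (0 <= int(class_index) < len(l.class_names)):
        raise ValueError(
            f"class index {class_index} outside alphabet of {len(l.class_names)}"
        )
    n = int(np.count_nonzero(l.labels == int(class_index)))
    return n * l.voxel_volume_mm3 / 1000.0


def all_volumes_ml(l: LabelMap) -> dict[str, float]:
    """Per-class volumes in ml, keyed by class name."""
    return {name: label_volume_ml(l, i) for i, name in enumerate(l.class_names)}


def weight_from_volume(volume_ml: float) -> WeightEstimate:
    """Fetal weight from fetal volume via the 1.04 kg/l density: 1000 ml → 1040 g."""
    if volume_ml < 0:
        raise ValueError("volume cannot be negative")
    return WeightEstimate(grams=FETAL_DENSITY_KG_L * volume_ml, source="mri_volume")


def dice(a, b, class_index: int | None = None) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    ``a`` and ``b`` are binary masks, or :class:`LabelMap`/integer arrays with
    ``class_index`` selecting the class to compare.  Two empty sets are in
    perfect agreement about absence, so that 0/0 case is defined as 1.
    """
    a = a.labels if isinstance(a, LabelMap) else np.asarray(a)
    b = b.labels if isinstance(b, LabelMap) else np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if class_index is not None:
        a = a == class_index
        b = b == class_index
    else:
        a = a.astype(bool)
        b = b.astype(bool)
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)
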