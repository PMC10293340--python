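"""Synthetic gravid-uterus phantoms with analytic ground truth.

The phantom emulates a late-gestation 3D fetal MRI slab: a fetus built from
overlapping ellipsoids (head, trunk) and cylindrical limb segments (including
an explicit femur segment), a placenta modelled as a shell sector on the
uterine wall, a curved umbilical cord tube from placenta to fetal trunk,
amniotic fluid filling the rest of the uterus interior, and maternal
background elsewhere.  Class intensities follow the bright-fluid ordering of
a bSSFP acquisition, corrupted by a smooth multiplicative bias field and
additive Gaussian noise.

Ground-truth structure volumes come from closed-form solid volumes; the few
designed pairwise overlaps between fetal solids are resolved by evaluating
the fetus union on a fine (0.5 mm) quadrature grid that is independent of
the image-grid voxelisation, so every downstream measurement can be checked
against a known answer.  A single ``fetal_scale`` parameter similarity-scales
the whole scene, emulating gestational growth across a cohort spanning
roughly 2000–4000 g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import biometry as _biometry
from .flow import DEFAULT_VENC_CM_S, FlowSeries
from .image_model import (
    AMNIOTIC_FLUID,
    BACKGROUND,
    CLASS_NAMES,
    FETUS,
    PLACENTA,
    UMBILICAL_CORD,
    LabelMap,
    VolumeImage,
)
from .quantification import weight_from_volume

#: Nominal class intensities (arbitrary units), brightest fluid emulating
#: bSSFP contrast.  Indexed by class label.
CLASS_INTENSITIES = np.array([0.20, 0.55, 0.40, 0.50, 1.00])


class GeometryError(ValueError):
    """Raised when the requested fetal geometry does not fit in the uterus."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic gravid-uterus acquisition.

    Geometric fields are given at reference scale (``fetal_scale = 1``) in mm;
    ellipsoid axes are semi-axes.  ``fetal_scale`` similarity-scales the whole
    scene (fetus, uterus, placenta, cord and the grid extent derived from
    them), so any scale yields a geometrically valid phantom.  The default
    voxel spacing matches a typical acquired fetal 3D slab resolution.
    Identical specs produce bit-identical phantoms.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] = (1.8, 1.4, 2.5)
    fetal_scale: float = 1.0
    noise_sigma: float = 0.05
    bias_field_amp: float = 0.2
    head_axes_mm: tuple[float, float, float] = (47.0, 44.0, 45.0)
    trunk_axes_mm: tuple[float, float, float] = (105.0, 62.0, 56.0)
    femur_length_mm: float = 68.0
    uterus_axes_mm: tuple[float, float, float] = (140.0, 112.0, 118.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0.3 <= self.fetal_scale <= 1.6):
            raise ValueError("fetal_scale outside supported range [0.3, 1.6]")
        if self.noise_sigma < 0 or self.bias_field_amp < 0:
            raise ValueError("noise_sigma and bias_field_amp must be ≥ 0")
        for axes in (self.head_axes_mm, self.trunk_axes_mm, self.uterus_axes_mm):
            if any(a <= 0 for a in axes):
                raise ValueError("ellipsoid semi-axes must be positive")
        if self.femur_length_mm <= 0:
            raise ValueError("femur_length_mm must be positive")


@dataclass
class PhantomTruth:
    """Analytic ground truth paired with a generated phantom."""

    volumes_ml: dict[str, float]
    biometry: "_biometry.BiometrySet"
    fetal_weight_g: float


# ---------------------------------------------------------------------------
# Solids.  All are axis-aligned-world primitives with vectorised membership
# tests over (possibly sparse-meshgrid) coordinate arrays, a bounding box,
# and a closed-form volume.


class _Ellipsoid:
    def __init__(self, center, semi):
        self.center = np.asarray(center, dtype=float)
        self.semi = np.asarray(semi, dtype=float)

    def bbox(self):
        return self.center - self.semi, self.center + self.semi

    def contains(self, X, Y, Z):
        cx, cy, cz = self.center
        a, b, c = self.semi
        return (
            ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2
        ) <= 1.0

    @property
    def volume_mm3(self):
        return 4.0 / 3.0 * math.pi * float(np.prod(self.semi))

    def surface_points(self, n_theta=48, n_phi=24):
        th = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
        ph = np.linspace(0, math.pi, n_phi)
        T, P = np.meshgrid(th, ph, indexing="ij")
        pts = np.stack(
            [
                self.center[0] + self.semi[0] * np.sin(P) * np.cos(T),
                self.center[1] + self.semi[1] * np.sin(P) * np.sin(T),
                self.center[2] + self.semi[2] * np.cos(P),
            ],
            axis=-1,
        )
        return pts.reshape(-1, 3)


class _Cylinder:
    """Finite cylinder with flat caps, from p0 along a unit direction."""

    def __init__(self, p0, direction, length, radius):
        self.p0 = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        self.d = d / np.linalg.norm(d)
        self.length = float(length)
        self.radius = float(radius)

    def bbox(self):
        ends = np.stack([self.p0, self.p0 + self.d * self.length])
        return ends.min(axis=0) - self.radius, ends.max(axis=0) + self.radius

    def contains(self, X, Y, Z):
        vx, vy, vz = X - self.p0[0], Y - self.p0[1], Z - self.p0[2]
        t = vx * self.d[0] + vy * self.d[1] + vz * self.d[2]
        r2 = vx**2 + vy**2 + vz**2 - t**2
        return (t >= 0.0) & (t <= self.length) & (r2 <= self.radius**2)

    @property
    def volume_mm3(self):
        return math.pi * self.radius**2 * self.length

    def surface_points(self, n_ang=24, n_len=12):
        # rim circles of both end caps plus intermediate rings; the cylinder
        # is the convex hull of its end-cap rims, so for convex containment
        # checks the end rims are the extreme points.
        ang = np.linspace(0, 2 * math.pi, n_ang, endpoint=False)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(self.d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(self.d, ref)
        u /= np.linalg.norm(u)
        w = np.cross(self.d, u)
        circ = np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w)
        ts = np.linspace(0, self.length, n_len)
        pts = (
            self.p0[None, None, :]
            + ts[:, None, None] * self.d[None, None, :]
            + self.radius * circ[None, :, :]
        )
        return pts.reshape(-1, 3)


class _BezierTube:
    """Tube of constant radius around a quadratic Bézier centreline."""

    def __init__(self, a, c, b, radius, step_mm=0.5):
        self.a = np.asarray(a, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.radius = float(radius)
        # sample the centreline finely; arc length by summed chords
        coarse = self._eval(np.linspace(0, 1, 512))
        chord = np.linalg.norm(np.diff(coarse, axis=0), axis=1)
        self.length = float(chord.sum())
        n = max(16, int(self.length / step_mm))
        self.centerline = self._eval(np.linspace(0, 1, n))

    def _eval(self, t):
        t = np.asarray(t)[:, None]
        return (1 - t) ** 2 * self.a + 2 * (1 - t) * t * self.c + t**2 * self.b

    def bbox(self):
        return (
            self.centerline.min(axis=0) - self.radius,
            self.centerline.max(axis=0) + self.radius,
        )

    def contains(self, X, Y, Z):
        shape = np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z))
        Xf = np.broadcast_to(X, shape).reshape(-1)
        Yf = np.broadcast_to(Y, shape).reshape(-1)
        Zf = np.broadcast_to(Z, shape).reshape(-1)
        out = np.zeros(Xf.shape, dtype=bool)
        r2 = self.radius**2
        cl = self.centerline
        # chunk over points to bound memory: dist² to nearest centreline sample
        chunk = 200_000
        for i in range(0, Xf.size, chunk):
            dx = Xf[i : i + chunk, None] - cl[None, :, 0]
            dy = Yf[i : i + chunk, None] - cl[None, :, 1]
            dz = Zf[i : i + chunk, None] - cl[None, :, 2]
            d2 = dx * dx
            d2 += dy * dy
            d2 += dz * dz
            out[i : i + chunk] = d2.min(axis=1) <= r2
        return out.reshape(shape)

    @property
    def volume_mm3(self):
        # the membership test is distance-to-curve ≤ r, i.e. the Minkowski sum
        # of the centreline with a ball ("sausage"); by the tube formula its
        # volume is exactly πr²L + 4/3πr³ while the bend radius exceeds r
        return math.pi * self.radius**2 * self.length + 4.0 / 3.0 * math.pi * self.radius**3


class _ShellSector:
    """Placental bed: ellipsoidal shell restricted to a cone, in normalised
    coordinates u = (p − centre)/axes.  In u-space this is a true spherical
    shell sector, giving the closed-form volume
    abc · (2π/3)(1 − cos θ)(r_out³ − r_in³)."""

    def __init__(self, axes, r_in, r_out, axis_dir, half_angle_deg):
        self.axes = np.asarray(axes, dtype=float)
        self.r_in = float(r_in)
        self.r_out = float(r_out)
        n = np.asarray(axis_dir, dtype=float)
        self.n = n / np.linalg.norm(n)
        self.cos_half = math.cos(math.radians(half_angle_deg))
        self.half_angle_deg = float(half_angle_deg)

    def bbox(self):
        # loose: the full outer ellipsoid extent (callers intersect bboxes)
        return -self.axes * self.r_out, self.axes * self.r_out

    def normalized(self, X, Y, Z):
        return X / self.axes[0], Y / self.axes[1], Z / self.axes[2]

    def contains(self, X, Y, Z):
        ux, uy, uz = self.normalized(X, Y, Z)
        r = np.sqrt(ux**2 + uy**2 + uz**2)
        along = ux * self.n[0] + uy * self.n[1] + uz * self.n[2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(r > 0, along / np.maximum(r, 1e-12), 1.0)
        return (r >= self.r_in) & (r <= self.r_out) & (cosang >= self.cos_half)

    @property
    def volume_mm3(self):
        return (
            float(np.prod(self.axes))
            * (2.0 * math.pi / 3.0)
            * (1.0 - self.cos_half)
            * (self.r_out**3 - self.r_in**3)
        )


# ---------------------------------------------------------------------------
# Scene layout.  Internal layout constants are expressed relative to the
# trunk/uterus so the scene stays valid under proportional rescaling.

_PLACENTA_R_IN = 0.80
_PLACENTA_HALF_ANGLE = 50.0
_PLACENTA_AXIS = (0.0, 0.87, -0.50)
_CORD_RADIUS_MM = 8.0  # at reference scale


def scene_geometry(spec: PhantomSpec) -> dict:
    """Scaled scene dimensions used by the generator and analytic biometry."""
    s = spec.fetal_scale
    return {
        "scale": s,
        "uterus_semi_mm": tuple(s * a for a in spec.uterus_axes_mm),
        "head_semi_mm": tuple(s * a for a in spec.head_axes_mm),
        "trunk_semi_mm": tuple(s * a for a in spec.trunk_axes_mm),
        "femur_length_mm": s * spec.femur_length_mm,
    }


def _build_scene(spec: PhantomSpec, scale: float | None = None):
    """All solids of the scene at the given scale (default spec.fetal_scale)."""
    s = spec.fetal_scale if scale is None else scale
    U = s * np.asarray(spec.uterus_axes_mm)
    Th = s * np.asarray(spec.trunk_axes_mm)
    Hd = s * np.asarray(spec.head_axes_mm)
    femur = s * spec.femur_length_mm

    Tc = s * np.array([-25.0, 0.0, -8.0])
    trunk = _Ellipsoid(Tc, Th)
    head = _Ellipsoid(Tc + s * np.array([108.0, 0.0, 26.0]), Hd)

    m = 0.5 * (Th[1] + Th[2])  # mean trunk minor semi-axis, sets limb girth
    fetal = {"trunk": trunk, "head": head}
    for side, ys in (("left", 1.0), ("right", -1.0)):
        hip = Tc + np.array([-0.60 * Th[0], ys * 0.45 * Th[1], 0.25 * Th[2]])
        thigh = _Cylinder(hip, (0.60, ys * 0.25, 0.70), femur, 0.32 * m)
        knee = thigh.p0 + thigh.d * thigh.length
        shank = _Cylinder(knee, (0.90, -ys * 0.10, -0.30), 1.05 * femur, 0.29 * m)
        shoulder = Tc + np.array([0.55 * Th[0], ys * 0.40 * Th[1], 0.30 * Th[2]])
        arm = _Cylinder(shoulder, (0.10, ys * 0.25, 0.96), 1.10 * femur, 0.24 * m)
        fetal[f"thigh_{side}"] = thigh
        fetal[f"shank_{side}"] = shank
        fetal[f"arm_{side}"] = arm

    uterus = _Ellipsoid(np.zeros(3), U)
    placenta = _ShellSector(
        U, _PLACENTA_R_IN, 1.0, _PLACENTA_AXIS, _PLACENTA_HALF_ANGLE
    )
    # cord: from mid-placenta (normalised radius 0.86, inside the cone) to a
    # point embedded in the trunk, bowing through the amniotic space
    w = np.array([0.20, 0.95, 0.24])
    w /= np.linalg.norm(w)
    a_pt = 0.86 * w * U
    b_pt = Tc + s * np.array([10.0, 48.0, 8.0])
    c_pt = 0.5 * (a_pt + b_pt) + s * np.array([45.0, 0.0, 30.0])
    cord = _BezierTube(a_pt, c_pt, b_pt, s * _CORD_RADIUS_MM)

    return {"uterus": uterus, "placenta": placenta, "cord": cord, "fetal": fetal}


def _check_containment(scene) -> None:
    """Verify the fetus and cord sit inside the uterus, clear of the placenta."""
    uterus: _Ellipsoid = scene["uterus"]
    placenta: _ShellSector = scene["placenta"]

    def norm_radius(pts):
        u = pts / uterus.semi[None, :]
        return np.linalg.norm(u, axis=1), u

    for name, solid in scene["fetal"].items():
        r, u = norm_radius(solid.surface_points())
        if r.max() > 0.995:
            raise GeometryError(
                f"fetal solid '{name}' extends outside the uterus "
                f"(normalised radius {r.max():.3f})"
            )
        # points that reach placental radii must lie outside the cone
        in_shell = r >= _PLACENTA_R_IN - 0.01
        if in_shell.any():
            cosang = (u[in_shell] @ placenta.n) / r[in_shell]
            if np.any(cosang >= placenta.cos_half - 0.01):
                raise GeometryError(f"fetal solid '{name}' intersects the placenta")
    cord: _BezierTube = scene["cord"]
    r, _ = norm_radius(cord.centerline)
    if r.max() > 0.995:
        raise GeometryError("umbilical cord extends outside the uterus")


# ---------------------------------------------------------------------------
# Analytic (quadrature-resolved) union volumes


def _union_volume_mm3(solids, step_mm=0.5) -> float:
    los, his = zip(*(s.bbox() for s in solids))
    lo = np.min(np.stack(los), axis=0)
    hi = np.max(np.stack(his), axis=0)
    axes = [np.arange(lo[i] + step_mm / 2, hi[i], step_mm) for i in range(3)]
    ny, nz = len(axes[1]), len(axes[2])
    count = 0
    chunk = max(1, int(4e6 / max(1, ny * nz)))
    for i0 in range(0, len(axes[0]), chunk):
        xs = axes[0][i0 : i0 + chunk]
        X = xs[:, None, None]
        Y = axes[1][None, :, None]
        Z = axes[2][None, None, :]
        inside = np.zeros((len(xs), ny, nz), dtype=bool)
        for s in solids:
            inside |= s.contains(X, Y, Z)
        count += int(inside.sum())
    return count * step_mm**3


def _overlap_volume_mm3(a, solids, step_mm=0.5) -> float:
    """Volume of solid ``a`` intersected with the union of ``solids``."""
    lo_a, hi_a = a.bbox()
    los, his = zip(*(s.bbox() for s in solids))
    lo = np.maximum(lo_a, np.min(np.stack(los), axis=0))
    hi = np.minimum(hi_a, np.max(np.stack(his), axis=0))
    if np.any(hi <= lo):
        return 0.0
    axes = [np.arange(lo[i] + step_mm / 2, hi[i], step_mm) for i in range(3)]
    if any(len(ax) == 0 for ax in axes):
        return 0.0
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    in_a = a.contains(X, Y, Z)
    in_union = np.zeros_like(in_a)
    for s in solids:
        in_union |= s.contains(X, Y, Z)
    return float(np.count_nonzero(in_a & in_union)) * step_mm**3


@lru_cache(maxsize=16)
def _reference_truth_mm3(geom_key) -> tuple[float, float]:
    """(fetal union, net cord) volume in mm³ at reference scale 1.

    Cached per geometry; similarity scaling lets any fetal_scale reuse the
    reference value via the cube of the scale factor.
    """
    spec = PhantomSpec(
        seed=0,
        fetal_scale=1.0,
        head_axes_mm=geom_key[0],
        trunk_axes_mm=geom_key[1],
        femur_length_mm=geom_key[2],
        uterus_axes_mm=geom_key[3],
    )
    scene = _build_scene(spec, scale=1.0)
    fetal = list(scene["fetal"].values())
    fetus_mm3 = _union_volume_mm3(fetal)
    cord = scene["cord"]
    cord_mm3 = (
        cord.volume_mm3
        - _overlap_volume_mm3(cord, fetal)
        - _overlap_volume_mm3(cord, [scene["placenta"]])
    )
    return fetus_mm3, cord_mm3


def _geom_key(spec: PhantomSpec):
    return (
        tuple(spec.head_axes_mm),
        tuple(spec.trunk_axes_mm),
        float(spec.femur_length_mm),
        tuple(spec.uterus_axes_mm),
    )


def phantom_truth(spec: PhantomSpec, grid_shape=None) -> PhantomTruth:
    """Analytic per-class volumes, biometry and density-based weight."""
    s = spec.fetal_scale
    scene = _build_scene(spec)
    fetus_mm3, cord_mm3 = (v * s**3 for v in _reference_truth_mm3(_geom_key(spec)))
    uterus_mm3 = scene["uterus"].volume_mm3
    placenta_mm3 = scene["placenta"].volume_mm3
    fluid_mm3 = uterus_mm3 - fetus_mm3 - placenta_mm3 - cord_mm3
    volumes = {
        CLASS_NAMES[FETUS]: fetus_mm3 / 1000.0,
        CLASS_NAMES[PLACENTA]: placenta_mm3 / 1000.0,
        CLASS_NAMES[UMBILICAL_CORD]: cord_mm3 / 1000.0,
        CLASS_NAMES[AMNIOTIC_FLUID]: fluid_mm3 / 1000.0,
    }
    if grid_shape is not None:
        grid_mm3 = float(np.prod(grid_shape) * np.prod(spec.spacing))
        volumes[CLASS_NAMES[BACKGROUND]] = (grid_mm3 - uterus_mm3) / 1000.0
    import warnings

    with warnings.catch_warnings():
        # range warnings concern Hadlock reliability, not phantom validity
        warnings.simplefilter("ignore", UserWarning)
        bio = _biometry.phantom_biometry(spec)
    weight = weight_from_volume(volumes[CLASS_NAMES[FETUS]])
    return PhantomTruth(volumes_ml=volumes, biometry=bio, fetal_weight_g=weight.grams)


# ---------------------------------------------------------------------------
# Voxelisation


def _default_grid_shape(spec: PhantomSpec, margin_mm=6.0):
    U = spec.fetal_scale * np.asarray(spec.uterus_axes_mm)
    return tuple(
        int(math.ceil((2 * U[i] + 2 * margin_mm) / spec.spacing[i])) for i in range(3)
    )


def generate_phantom(spec: PhantomSpec):
    """Generate (VolumeImage, LabelMap, PhantomTruth) for one phantom.

    Voxel labels are assigned with the priority fetus > placenta > cord >
    amniotic fluid > background, matching the ground-truth bookkeeping (the
    cord's insertions into trunk and placental bed belong to those
    structures).  Intensities are the nominal class values times a smooth
    multiplicative bias field, plus Gaussian noise.
    """
    scene = _build_scene(spec)
    _check_containment(scene)

    shape = spec.grid_shape or _default_grid_shape(spec)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = shape * spacing
    origin = -extent / 2.0  # uterus centred in the grid
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)]
    lo_needed = -scene["uterus"].semi
    hi_needed = scene["uterus"].semi
    if np.any(origin > lo_needed) or np.any(origin + extent < hi_needed):
        raise GeometryError(
            f"grid {shape} at spacing {tuple(spacing)} does not cover the uterus"
        )

    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]

    labels = np.zeros(shape, dtype=np.uint8)
    labels[scene["uterus"].contains(X, Y, Z)] = AMNIOTIC_FLUID

    def subgrid(solid):
        lo, hi = solid.bbox()
        sl = tuple(
            slice(
                int(np.searchsorted(axes[i], lo[i])),
                int(np.searchsorted(axes[i], hi[i])),
            )
            for i in range(3)
        )
        sub = [axes[i][sl[i]] for i in range(3)]
        return sl, sub[0][:, None, None], sub[1][None, :, None], sub[2][None, None, :]

    for solid, lab in [(scene["cord"], UMBILICAL_CORD)]:
        sl, x, y, z = subgrid(solid)
        labels[sl][solid.contains(x, y, z)] = lab
    labels[scene["placenta"].contains(X, Y, Z)] = PLACENTA
    for solid in scene["fetal"].values():
        sl, x, y, z = subgrid(solid)
        labels[sl][solid.contains(x, y, z)] = FETUS

    intensities = CLASS_INTENSITIES[labels]
    rng = np.random.default_rng(spec.seed)
    if spec.bias_field_amp > 0:
        xn = (X - origin[0]) / extent[0]
        yn = (Y - origin[1]) / extent[1]
        zn = (Z - origin[2]) / extent[2]
        g = np.zeros(shape)
        for _ in range(3):
            f = rng.uniform(0.5, 1.5, size=3)
            phi = rng.uniform(0, 2 * math.pi)
            g = g + np.cos(2 * math.pi * (f[0] * xn + f[1] * yn + f[2] * zn) + phi)
        intensities = intensities * (1.0 + spec.bias_field_amp * g / 3.0)
    else:
        rng.uniform(size=10)  # keep the noise stream aligned across amp settings
    if spec.noise_sigma > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sigma, size=shape)

    spacing_t = tuple(float(v) for v in spacing)
    origin_t = tuple(float(v) for v in origin)
    vol = VolumeImage(intensities.astype(np.float32), spacing_t, origin_t)
    lab = LabelMap(labels, spacing_t, origin_t)
    truth = phantom_truth(spec, grid_shape=shape)
    return vol, lab, truth


def cohort_specs(
    n: int,
    seed: int,
    scale_range: tuple[float, float] = (0.97, 1.22),
    **overrides,
) -> list[PhantomSpec]:
    """Specs for a cohort of phantoms spanning roughly 2000–4000 g.

    Scales are drawn uniformly from ``scale_range`` (the default maps the
    reference fetus of ~2.2 kg onto the 2–4 kg span of a late-gestation
    cohort); per-phantom seeds derive deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    scales = rng.uniform(scale_range[0], scale_range[1], size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        PhantomSpec(seed=int(seeds[i]), fetal_scale=float(scales[i]), **overrides)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Flow phantom


def poiseuille_roi(n_pixels: int, pixel_mm: float, radius_mm: float) -> np.ndarray:
    """Lumen mask of the flow phantom: pixels whose centre lies in the vessel."""
    c = n_pixels * pixel_mm / 2.0
    coords = (np.arange(n_pixels) + 0.5) * pixel_mm - c
    r2 = coords[:, None] ** 2 + coords[None, :] ** 2
    return r2 <= radius_mm**2


def generate_flow_phantom(
    radius_mm: float = 5.0,
    v_max_cm_s: float = 20.0,
    n_phases: int = 14,
    pixel_mm: float = 1.4,
    rr_ms: float = 430.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    mode: str = "steady",
    venc_cm_s: float = DEFAULT_VENC_CM_S,
) -> FlowSeries:
    """Parabolic (Poiseuille) vessel velocity-map series with known mean flow.

    Each phase holds v(r) = v_peak(t)·(1 − r²/R²) inside the vessel and 0
    outside.  ``steady`` mode keeps v_peak = v_max; ``pulsatile`` modulates
    v_peak(t) = v_max·(0.7 + 0.3·sin(2πt/RR)), whose discrete cycle mean is
    exactly 0.7·v_max.  The stored ground truth is the cycle-mean flow
    Q = mean_t[v_peak]·πR²/2, converted to ml/min.  Defaults emulate a term
    umbilical vein (≈10 mm diameter, peak velocity 20 cm/s → ≈470 ml/min) at
    a typical phase-contrast in-plane resolution and fetal heart rate.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if not (0 < v_max_cm_s <= venc_cm_s):
        raise ValueError(
            f"v_max must lie in (0, VENC = {venc_cm_s} cm/s]; aliasing is not modelled"
        )
    if n_phases < 1:
        raise ValueError("n_phases must be ≥ 1")
    if mode not in ("steady", "pulsatile"):
        raise ValueError("mode must be 'steady' or 'pulsatile'")

    n_pix = int(math.ceil(4.0 * radius_mm / pixel_mm))
    n_pix += n_pix % 2  # even grid keeps the vessel centred symmetrically
    c = n_pix * pixel_mm / 2.0
    coords = (np.arange(n_pix) + 0.5) * pixel_mm - c
    r2 = coords[:, None] ** 2 + coords[None, :] ** 2
    profile = np.where(r2 <= radius_mm**2, 1.0 - r2 / radius_mm**2, 0.0)

    k = np.arange(n_phases)
    if mode == "steady":
        v_peak = np.full(n_phases, v_max_cm_s)
    else:
        v_peak = v_max_cm_s * (0.7 + 0.3 * np.sin(2 * math.pi * k / n_phases))
    maps = v_peak[:, None, None] * profile[None, :, :]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        maps = maps + rng.normal(0.0, noise_sigma, size=maps.shape)
        maps = np.clip(maps, -venc_cm_s, venc_cm_s)

    q_true = float(v_peak.mean()) * math.pi * radius_mm**2 / 2.0 * 0.01 * 60.0
    return FlowSeries(
        velocity_maps=maps,
        pixel_area_mm2=pixel_mm**2,
        rr_ms=rr_ms,
        venc_cm_s=venc_cm_s,
        truth_flow_ml_min=q_true,
    )
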