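"""Synthetic SLO-like scene generator with exact ground truth.

The generator emulates what an infrared-reflectance SLO localizer of the
posterior pole looks like to the measurement pipeline: a dark background,
bright ridge-profiled vessels branching around the posterior pole, a bright
elliptical optic disc, a dark Gaussian foveal spot, optional central light
reflex, and additive Gaussian sensor noise.  Every scene carries exact masks
and analytically known per-curve widths, arc lengths and chord lengths, so
each downstream stage can be tested without any external data.

Geometry is in 0-based (row, col) pixel coordinates; vessel centerlines are
continuous parametric curves sampled at sub-pixel steps, and a vessel's mask
is the set of pixels whose center lies within ``width/2`` of the centerline
(a disc-brush stroke), so the drawn caliber is known by construction.

All randomness flows through seeds stored on the spec; the same spec renders
byte-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .errors import ParameterError
from .io_formats import (
    LABEL_ARTERY,
    LABEL_CROSSING,
    LABEL_DISC,
    LABEL_VEIN,
    LabelMask,
    SLOImage,
    write_binary_mask,
    write_image,
    write_mask,
    write_sidecar,
)

#: radius (px) of the ground-truth fovea mask, matching the circular
#: fovea-label geometry used at the 768x768 working resolution
FOVEA_MASK_RADIUS_PX = 60.0

_SAMPLE_STEP = 0.25  # px; centerline sampling step (<= 0.5 px required)


# ---------------------------------------------------------------------------
# parametric centerline curves
# ---------------------------------------------------------------------------


@dataclass
class VesselCurve:
    """A parametric vessel centerline of constant width.

    kind:
      * ``polyline`` — ``vertices`` is an (M, 2) array of (row, col) points;
      * ``sinusoid`` — sine wave of amplitude ``amplitude`` and period
        ``period`` along an axis starting at ``start`` with direction
        ``angle`` (radians, measured from the +col axis toward +row),
        of axial length ``length``;
      * ``arc`` — circular arc of radius ``radius`` around ``center``
        spanning ``theta0``..``theta1`` (radians).
    """

    kind: str
    width_px: float
    vessel_class: str  # "artery" | "vein"
    vertices: np.ndarray | None = None
    start: tuple | None = None
    angle: float = 0.0
    length: float = 0.0
    amplitude: float = 0.0
    period: float = 100.0
    phase: float = 0.0
    center: tuple | None = None
    radius: float = 0.0
    theta0: float = 0.0
    theta1: float = 0.0

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ParameterError(f"vessel width must be >= 1 px, got {self.width_px}")
        if self.vessel_class not in ("artery", "vein"):
            raise ParameterError(f"unknown vessel class {self.vessel_class!r}")
        if self.kind not in ("polyline", "sinusoid", "arc"):
            raise ParameterError(f"unknown curve kind {self.kind!r}")
        if self.kind == "polyline":
            self.vertices = np.asarray(self.vertices, dtype=float)

    # -- sampling ----------------------------------------------------------

    def sample(self, step: float = _SAMPLE_STEP) -> np.ndarray:
        """Densely sampled (N, 2) array of (row, col) centerline points."""
        if step > 0.5:
            raise ParameterError("centerline sampling step must be <= 0.5 px")
        if self.kind == "polyline":
            pts = []
            v = self.vertices
            for a, b in zip(v[:-1], v[1:]):
                seg_len = float(np.hypot(*(b - a)))
                n = max(2, int(np.ceil(seg_len / step)) + 1)
                t = np.linspace(0.0, 1.0, n)[:, None]
                pts.append(a[None, :] * (1 - t) + b[None, :] * t)
            return np.vstack(pts)
        if self.kind == "sinusoid":
            n = max(2, int(np.ceil(self.length / step)) + 1)
            u = np.linspace(0.0, self.length, n)
            v = self.amplitude * np.sin(2 * np.pi * u / self.period + self.phase)
            d = np.array([np.sin(self.angle), np.cos(self.angle)])  # (row, col)
            nvec = np.array([-d[1], d[0]])
            base = np.asarray(self.start, dtype=float)
            return base[None, :] + u[:, None] * d[None, :] + v[:, None] * nvec[None, :]
        # arc
        span = abs(self.theta1 - self.theta0)
        n = max(2, int(np.ceil(self.radius * span / step)) + 1)
        th = np.linspace(self.theta0, self.theta1, n)
        cy, cx = self.center
        return np.column_stack([cy + self.radius * np.sin(th), cx + self.radius * np.cos(th)])

    # -- analytics ----------------------------------------------------------

    def arc_length(self) -> float:
        """Arc length; closed form where available, quadrature otherwise."""
        if self.kind == "polyline":
            diffs = np.diff(self.vertices, axis=0)
            return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))
        if self.kind == "sinusoid":
            k = 2 * np.pi / self.period

            def speed(u):
                return np.sqrt(
                    1.0 + (self.amplitude * k) ** 2 * np.cos(k * u + self.phase) ** 2
                )

            val, _ = integrate.quad(speed, 0.0, self.length, limit=400, epsabs=1e-10)
            return float(val)
        return float(self.radius * abs(self.theta1 - self.theta0))

    def chord_length(self) -> float:
        pts = self.sample(0.5)
        return float(np.hypot(*(pts[-1] - pts[0])))

    def translated(self, dy: float, dx: float) -> "VesselCurve":
        c = dataclasses.replace(self)
        if self.kind == "polyline":
            c.vertices = self.vertices + np.array([dy, dx])
        elif self.kind == "sinusoid":
            c.start = (self.start[0] + dy, self.start[1] + dx)
        else:
            c.center = (self.center[0] + dy, self.center[1] + dx)
        return c


# ---------------------------------------------------------------------------
# spec and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Complete, seed-deterministic description of one synthetic scene."""

    size: tuple = (768, 768)
    disc_center: tuple | None = None  # (row, col)
    disc_axes: tuple | None = None  # (semi_row, semi_col) of the ellipse
    fovea_center: tuple | None = None  # (row, col)
    curves: list = field(default_factory=list)
    background: float = 60.0
    vessel_contrast: float = 90.0
    artery_contrast_factor: float = 0.8
    disc_contrast: float = 50.0
    fovea_depth: float = 40.0
    fovea_sigma_px: float = 45.0
    reflex: bool = False
    reflex_gain: float = 40.0
    noise_sd: float = 5.0
    laterality: str = "unknown"
    location: str = "unknown"
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-scene truth: masks, landmarks and per-curve analytics."""

    label_mask: LabelMask
    vessel_mask: np.ndarray
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    fovea_mask: np.ndarray
    fovea_xy: tuple | None  # (x=col, y=row)
    disc_center_xy: tuple | None
    disc_axes: tuple | None  # (major, minor) full axis lengths
    disc_diameter_px: float | None
    curves: list = field(default_factory=list)
    laterality: str = "unknown"
    location: str = "unknown"


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _distance_field(points: np.ndarray, reach: float, shape: tuple):
    """Distance from pixel centers to the sampled centerline, evaluated only
    where it can be below ``reach``.

    Returns (rows, cols, distances) of candidate pixels.  A coarse distance
    transform on the rasterized samples shortlists candidates; a KD-tree on
    the continuous samples then gives sub-pixel distances.
    """
    h, w = shape
    canvas = np.ones(shape, dtype=bool)
    rr = np.clip(np.rint(points[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.rint(points[:, 1]).astype(int), 0, w - 1)
    canvas[rr, cc] = False
    coarse = distance_transform_edt(canvas)
    cand = np.nonzero(coarse <= reach + 1.5)
    if cand[0].size == 0:
        return cand[0], cand[1], np.empty(0)
    tree = cKDTree(points)
    d, _ = tree.query(np.column_stack(cand).astype(float), k=1)
    return cand[0], cand[1], d


def render_vessel(curve: VesselCurve | np.ndarray, width: float, shape: tuple) -> np.ndarray:
    """Binary mask of pixels within ``width/2`` of the centerline."""
    if width < 1:
        raise ParameterError(f"vessel width must be >= 1 px, got {width}")
    points = curve.sample() if isinstance(curve, VesselCurve) else np.asarray(curve, float)
    mask = np.zeros(shape, dtype=bool)
    rows, cols, d = _distance_field(points, width / 2.0, shape)
    keep = d <= width / 2.0
    mask[rows[keep], cols[keep]] = True
    return mask


def _ellipse_mask(shape: tuple, center: tuple, axes: tuple) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ry, rx = axes
    rho = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return rho <= 1.0


def _disc_mask_circle(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _validate_curves_inside(spec: SyntheticSpec) -> None:
    h, w = spec.size
    for curve in spec.curves:
        pts = curve.sample(0.5)
        m = curve.width_px / 2.0
        if (
            pts[:, 0].min() < m
            or pts[:, 1].min() < m
            or pts[:, 0].max() > h - 1 - m
            or pts[:, 1].max() > w - 1 - m
        ):
            raise ParameterError(
                f"curve ({curve.kind}, class={curve.vessel_class}) leaves the canvas"
            )


def generate_scene(spec: SyntheticSpec) -> tuple[SLOImage, GroundTruth]:
    """Render one scene and its exact ground truth.

    The image is background + raised-cosine ridge vessels (+ optional bright
    reflex strip of width ``w/3`` along the centerline) + dark Gaussian
    foveal spot + bright elliptical disc + seeded Gaussian noise, quantized
    to 8 bits so that a written-then-read PNG is bit-identical.
    """
    h, w = spec.size
    _validate_curves_inside(spec)

    disc_mask = None
    if spec.disc_center is not None:
        axes = spec.disc_axes or (55.0, 55.0)
        disc_mask = _ellipse_mask(spec.size, spec.disc_center, axes)

    fovea_mask = None
    if spec.fovea_center is not None:
        fovea_mask = _disc_mask_circle(spec.size, spec.fovea_center, FOVEA_MASK_RADIUS_PX)

    if disc_mask is not None and fovea_mask is not None and np.any(disc_mask & fovea_mask):
        raise ParameterError("optic disc and fovea regions overlap")

    img = np.full(spec.size, float(spec.background))

    # optic disc: bright plateau with a short linear edge ramp (the exact
    # ground-truth ellipse is the rho <= 1 region)
    if disc_mask is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = spec.disc_center
        ry, rx = spec.disc_axes or (55.0, 55.0)
        rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        ramp = np.clip((1.1 - rho) / 0.2, 0.0, 1.0)
        img += spec.disc_contrast * ramp

    # foveal pit: dark Gaussian spot
    if spec.fovea_center is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = (yy - spec.fovea_center[0]) ** 2 + (xx - spec.fovea_center[1]) ** 2
        img -= spec.fovea_depth * np.exp(-r2 / (2.0 * spec.fovea_sigma_px**2))

    artery_mask = np.zeros(spec.size, dtype=bool)
    vein_mask = np.zeros(spec.size, dtype=bool)
    for curve in spec.curves:
        pts = curve.sample()
        half = curve.width_px / 2.0
        rows, cols, d = _distance_field(pts, half, spec.size)
        inside = d <= half
        rows, cols, d = rows[inside], cols[inside], d[inside]
        contrast = spec.vessel_contrast
        if curve.vessel_class == "artery":
            contrast *= spec.artery_contrast_factor
        # raised-cosine ridge on a small pedestal: strictly brighter than the
        # local background everywhere inside the vessel support
        profile = contrast * (0.25 + 0.75 * 0.5 * (1.0 + np.cos(np.pi * d / half)))
        if spec.reflex:
            profile = profile + spec.reflex_gain * (d <= curve.width_px / 6.0)
        img[rows, cols] = np.maximum(img[rows, cols], spec.background + profile)
        if curve.vessel_class == "artery":
            artery_mask[rows, cols] = True
        else:
            vein_mask[rows, cols] = True

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.size)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    labels = np.zeros(spec.size, dtype=np.int64)
    if disc_mask is not None:
        labels[disc_mask] = LABEL_DISC
    labels[artery_mask & ~vein_mask] = LABEL_ARTERY
    labels[vein_mask & ~artery_mask] = LABEL_VEIN
    labels[artery_mask & vein_mask] = LABEL_CROSSING

    disc_axes_full = None
    disc_d = None
    disc_xy = None
    if spec.disc_center is not None:
        ry, rx = spec.disc_axes or (55.0, 55.0)
        major, minor = max(2 * ry, 2 * rx), min(2 * ry, 2 * rx)
        disc_axes_full = (float(major), float(minor))
        disc_d = float((major + minor) / 2.0)
        disc_xy = (float(spec.disc_center[1]), float(spec.disc_center[0]))

    truth = GroundTruth(
        label_mask=LabelMask(labels),
        vessel_mask=artery_mask | vein_mask,
        artery_mask=artery_mask,
        vein_mask=vein_mask,
        fovea_mask=fovea_mask if fovea_mask is not None else np.zeros(spec.size, bool),
        fovea_xy=(
            (float(spec.fovea_center[1]), float(spec.fovea_center[0]))
            if spec.fovea_center is not None
            else None
        ),
        disc_center_xy=disc_xy,
        disc_axes=disc_axes_full,
        disc_diameter_px=disc_d,
        curves=[
            {
                "vessel_class": c.vessel_class,
                "width_px": float(c.width_px),
                "arc_length_px": c.arc_length(),
                "chord_length_px": c.chord_length(),
            }
            for c in spec.curves
        ],
        laterality=spec.laterality,
        location=spec.location,
    )

    image = SLOImage(
        pixels=pixels,
        scale_um_per_px=None,
        laterality=spec.laterality,
        location=spec.location,
        image_id=f"synthetic_{spec.location}_{spec.rng_seed}",
    )
    return image, truth


def generate_repeated_pair(
    spec: SyntheticSpec, jitter: tuple = (0, 0)
) -> tuple[tuple[SLOImage, GroundTruth], tuple[SLOImage, GroundTruth]]:
    """Two unregistered acquisitions of the same eye.

    The second scene is the same vessel tree translated by ``jitter``
    (|dy|, |dx| <= 10 px) with an independent noise realization; ground
    truths are transformed consistently.
    """
    dy, dx = jitter
    if abs(dy) > 10 or abs(dx) > 10:
        raise ParameterError("repeat jitter must be at most 10 px per axis")
    seeds = np.random.SeedSequence(spec.rng_seed).generate_state(2)
    spec1 = dataclasses.replace(spec, rng_seed=int(seeds[0]) % (2**31))
    spec2 = dataclasses.replace(
        spec,
        rng_seed=int(seeds[1]) % (2**31),
        curves=[c.translated(dy, dx) for c in spec.curves],
        disc_center=(
            (spec.disc_center[0] + dy, spec.disc_center[1] + dx)
            if spec.disc_center is not None
            else None
        ),
        fovea_center=(
            (spec.fovea_center[0] + dy, spec.fovea_center[1] + dx)
            if spec.fovea_center is not None
            else None
        ),
    )
    return generate_scene(spec1), generate_scene(spec2)


# ---------------------------------------------------------------------------
# realistic default scenes
# ---------------------------------------------------------------------------


def default_scene_spec(
    location: str = "macula",
    laterality: str = "right",
    seed: int = 0,
    size: int = 768,
    n_vessels: int = 8,
    noise_sd: float = 5.0,
    reflex: bool = False,
) -> SyntheticSpec:
    """A plausible posterior-pole scene at the stated field of view.

    Macula-centered scenes put the foveal dip at the image center with the
    optic disc cropped at the nasal edge and vascular arcades sweeping around
    the macula.  Disc-centered scenes put the disc near the center (offset a
    few pixels toward the nasal side so laterality stays decidable) with
    vessels radiating outward and a circumferential arc creating
    arteriovenous crossings.  Veins are drawn wider and brighter than
    arteries (artery width = 0.8x vein width).
    """
    if laterality not in ("right", "left"):
        raise ParameterError("laterality must be 'right' or 'left'")
    if location not in ("macula", "disc"):
        raise ParameterError("location must be 'macula' or 'disc'")
    rng = np.random.default_rng(seed)
    half = size / 2.0
    sign = 1.0 if laterality == "right" else -1.0  # disc toward +col for right eyes
    curves: list[VesselCurve] = []

    if location == "macula":
        fovea = (half, half)
        disc_col = half + sign * (half - 65.0)
        disc = (half, disc_col)
        disc_axes = (62.0, 55.0)
        # arcades: concentric arcs around the fovea, opening toward the disc
        radii = np.linspace(0.22 * size, 0.42 * size, n_vessels)
        for i, r in enumerate(radii):
            vclass = "vein" if i % 2 == 0 else "artery"
            w_vein = float(rng.uniform(8.0, 11.0))
            width = w_vein if vclass == "vein" else 0.8 * w_vein
            # every arc point sits at distance r from the fovea, so staying
            # below half - margin keeps the whole arc on canvas for any span
            margin = width / 2.0 + 6.0
            max_r = half - margin
            base = 0.0 if laterality == "right" else np.pi
            theta_mid = base + np.pi  # arcs open away from the disc
            half_span = min(0.45 * np.pi + 0.35 * np.pi * (i % 3) / 2, 0.75 * np.pi)
            theta0 = theta_mid - half_span
            theta1 = theta_mid + half_span
            curves.append(
                VesselCurve(
                    kind="arc",
                    width_px=width,
                    vessel_class=vclass,
                    center=fovea,
                    radius=float(min(r, max_r)),
                    theta0=float(theta0),
                    theta1=float(theta1),
                )
            )
        # two transverse sinusoids crossing the arcades well clear of the fovea
        for k, row_off in enumerate((-0.24 * size, 0.24 * size)):
            vclass = "artery" if k == 0 else "vein"
            w_vein = float(rng.uniform(8.0, 11.0))
            width = w_vein if vclass == "vein" else 0.8 * w_vein
            margin = width / 2.0 + 12.0
            curves.append(
                VesselCurve(
                    kind="sinusoid",
                    width_px=width,
                    vessel_class=vclass,
                    start=(half + row_off, margin),
                    angle=0.0,
                    length=size - 2 * margin,
                    amplitude=float(rng.uniform(6.0, 14.0)),
                    period=float(rng.uniform(180.0, 260.0)),
                )
            )
    else:
        fovea = None
        disc = (half, half + sign * 25.0)
        disc_axes = (62.0, 55.0)
        n_radial = max(4, n_vessels)
        angles = np.linspace(0.0, 2 * np.pi, n_radial, endpoint=False)
        angles = angles + rng.uniform(-0.15, 0.15, size=n_radial)
        for i, ang in enumerate(angles):
            vclass = "vein" if i % 2 == 0 else "artery"
            w_vein = float(rng.uniform(8.0, 11.0))
            width = w_vein if vclass == "vein" else 0.8 * w_vein
            margin = width / 2.0 + 14.0
            start = (
                disc[0] + (disc_axes[0] - 6.0) * np.sin(ang),
                disc[1] + (disc_axes[1] - 6.0) * np.cos(ang),
            )
            # longest axial run that keeps the sinusoid inside the canvas
            amp = float(rng.uniform(5.0, 12.0))
            length = _length_to_border(start, ang, size, margin + amp)
            if length < 60:
                continue
            curves.append(
                VesselCurve(
                    kind="sinusoid",
                    width_px=width,
                    vessel_class=vclass,
                    start=start,
                    angle=float(ang),
                    length=float(length),
                    amplitude=amp,
                    period=float(rng.uniform(160.0, 240.0)),
                )
            )
        # circumferential arcs to create arteriovenous crossings
        for j, r in enumerate((0.27 * size, 0.38 * size)):
            vclass = "artery" if j % 2 == 0 else "vein"
            w_vein = float(rng.uniform(8.0, 10.0))
            width = w_vein if vclass == "vein" else 0.8 * w_vein
            curves.append(
                VesselCurve(
                    kind="arc",
                    width_px=width,
                    vessel_class=vclass,
                    center=(half, half),
                    radius=float(r),
                    theta0=float(rng.uniform(0, 0.4)),
                    theta1=float(rng.uniform(0, 0.4)) + 1.25 * np.pi,
                )
            )

    return SyntheticSpec(
        size=(size, size),
        disc_center=disc,
        disc_axes=disc_axes,
        fovea_center=fovea,
        curves=curves,
        noise_sd=noise_sd,
        reflex=reflex,
        laterality=laterality,
        location=location,
        rng_seed=seed,
    )


def _length_to_border(start: tuple, angle: float, size: int, margin: float) -> float:
    """Axial distance from ``start`` along ``angle`` to the canvas margin."""
    dy, dx = np.sin(angle), np.cos(angle)
    lo, hi = margin, size - 1 - margin
    best = np.inf
    for pos, d in ((start[0], dy), (start[1], dx)):
        if d > 1e-9:
            best = min(best, (hi - pos) / d)
        elif d < -1e-9:
            best = min(best, (pos - lo) / abs(d))
    return max(0.0, float(best))


# ---------------------------------------------------------------------------
# persistence for batch/CLI use
# ---------------------------------------------------------------------------


def write_scene(
    image: SLOImage,
    truth: GroundTruth,
    out_dir: str | Path,
    stem: str,
    scale_um_per_px: float | None = None,
    masks: bool = True,
) -> Path:
    """Write image + sidecar (+ label/fovea masks + truth JSON) for a scene."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    write_image(img_path, image.pixels)
    write_sidecar(
        img_path,
        {
            "scale_um_per_px": scale_um_per_px,
            "laterality": image.laterality if image.laterality != "unknown" else None,
            "location": image.location if image.location != "unknown" else None,
            "image_id": stem,
        },
    )
    if masks:
        write_mask(truth.label_mask, out_dir / f"{stem}_labels.png")
        write_binary_mask(truth.fovea_mask, out_dir / f"{stem}_fovea.png")
    truth_payload = {
        "fovea_xy": truth.fovea_xy,
        "disc_center_xy": truth.disc_center_xy,
        "disc_axes": truth.disc_axes,
        "disc_diameter_px": truth.disc_diameter_px,
        "laterality": truth.laterality,
        "location": truth.location,
        "curves": truth.curves,
        "vessel_density": float(truth.vessel_mask.mean()),
    }
    (out_dir / f"{stem}_truth.json").write_text(json.dumps(truth_payload, indent=1))
    return img_path
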