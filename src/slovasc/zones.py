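"""Measurement regions of interest: whole image, zone B, zone C.

Zones B and C are the standard peripapillary annuli, defined from the optic
disc margin in units of the disc diameter D: zone B spans 0.5D-1D away from
the margin and zone C spans 0D-2D away.  Treating the disc as a circle of
radius D/2 at the fitted ellipse center, that is radial distance r in
[D, 1.5D] for zone B and [0.5D, 2.5D] for zone C.  The disc is circularized
by default even when the fitted ellipse is eccentric (the zones are defined
by the single diameter D); true elliptical offsets are available via
``shape='elliptical'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, ParameterError, ShapeError
from .landmarks import OpticDisc

ROI_NAMES = ("whole", "zoneB", "zoneC")

#: (inner, outer) radial bounds of each zone in units of D, measured from
#: the disc center
ZONE_RADII_D = {"zoneB": (1.0, 1.5), "zoneC": (0.5, 2.5)}


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ParameterError(f"ROI name must be one of {ROI_NAMES}")
        self.mask = np.asarray(self.mask, bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def whole_image_roi(image_shape: tuple) -> ROIMask:
    """The whole image: an all-ones mask."""
    return ROIMask(name="whole", mask=np.ones(image_shape, dtype=bool))


def zone_roi(
    disc: OpticDisc, which: str, image_shape: tuple, shape: str = "circular"
) -> ROIMask:
    """Peripapillary annulus ``which`` in {'B', 'C'} around the disc.

    ``shape='circular'`` (default) measures plain radial distance from the
    ellipse center; ``'elliptical'`` scales distance anisotropically along
    the fitted axes so the annulus follows the disc's eccentricity.  Both
    bounds are inclusive and the mask is clipped to the image.
    """
    name = f"zone{which.upper()}"
    if name not in ZONE_RADII_D:
        raise ParameterError(f"zone must be 'B' or 'C', got {which!r}")
    if not disc.present or not np.isfinite(disc.diameter_D_px) or disc.diameter_D_px <= 0:
        raise CapabilityError("peripapillary zones require a detected optic disc")
    if shape not in ("circular", "elliptical"):
        raise ParameterError(f"unknown zone shape {shape!r}")

    D = disc.diameter_D_px
    lo, hi = ZONE_RADII_D[name]
    yy, xx = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    dy = yy - disc.center_y_px
    dx = xx - disc.center_x_px
    if shape == "circular":
        r = np.hypot(dy, dx)
    else:
        # rotate into the ellipse frame and weight each axis so that the
        # fitted ellipse boundary sits at r = D/2
        th = disc.orientation_rad
        # regionprops orientation: angle between the 0th axis (rows) and the
        # major axis, counter-clockwise
        u = dy * np.cos(th) - dx * np.sin(th)
        v = dy * np.sin(th) + dx * np.cos(th)
        a = disc.axis_major_px / 2.0
        b = disc.axis_minor_px / 2.0
        r = np.sqrt((u / a) ** 2 + (v / b) ** 2) * (D / 2.0)
    mask = (r >= lo * D) & (r <= hi * D)
    return ROIMask(name=name, mask=mask)


def restrict(vessel_mask: np.ndarray, roi: ROIMask) -> np.ndarray:
    """Elementwise AND: vessel pixels outside the ROI never contribute to
    that ROI's metrics."""
    mask = np.asarray(vessel_mask, bool)
    if mask.shape != roi.mask.shape:
        raise ShapeError(
            f"vessel mask shape {mask.shape} != ROI shape {roi.mask.shape}"
        )
    return mask & roi.mask


def rois_for_location(
    location: str,
    disc: OpticDisc,
    image_shape: tuple,
    shape: str = "circular",
    exclude_disc_from_whole: bool = False,
) -> list[ROIMask]:
    """ROI set per scan location: macula-centered images get the whole image
    only; disc-centered images get whole + zone B + zone C."""
    whole = whole_image_roi(image_shape)
    if exclude_disc_from_whole and disc.present:
        yy, xx = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
        r = np.hypot(yy - disc.center_y_px, xx - disc.center_x_px)
        whole = ROIMask(name="whole", mask=whole.mask & (r > disc.diameter_D_px / 2.0))
    if location != "disc":
        return [whole]
    return [
        whole,
        zone_roi(disc, "B", image_shape, shape=shape),
        zone_roi(disc, "C", image_shape, shape=shape),
    ]
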