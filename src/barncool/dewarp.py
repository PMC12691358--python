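"""Fisheye-to-rectilinear dewarping and its forward (warping) counterpart.

The barn cameras use fisheye lenses whose full field of view (FOV,
default 180 deg) must be remapped onto a perspective view with a chosen
output field of view (PFOV, default 140 deg) before object detection.
The source lens model is configurable; the equidistant projection
(r = f * theta) is the default, the usual assumption for surveillance
fisheyes.

Geometry, all radially symmetric about the image center:

    output pixel at radius r_out  ->  view angle theta = atan(r_out / f_rect)
    f_rect = (W/2) / tan(pfov/2)
    source radius r_in = P(theta) with P the lens projection, scaled so
    that theta = fov/2 lands on the fisheye circle radius w/2.

``warp_to_fisheye`` applies the exact inverse mapping, enabling
round-trip self-tests without any real fisheye footage. Resampling is
done with scipy.ndimage (nearest or bilinear); pixels whose source falls
outside the fisheye domain take ``fill_value``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "DewarpParams",
    "PixelMap",
    "build_pixel_map",
    "apply_dewarp",
    "warp_to_fisheye",
    "dewarp_image",
    "read_image",
    "write_image",
]

Projection = Literal["equidistant", "equisolid", "orthographic", "stereographic"]


@dataclass(frozen=True)
class DewarpParams:
    """Source FOV, output PFOV, lens model, and output raster parameters."""

    fov_deg: float = 180.0
    pfov_deg: float = 140.0
    projection: Projection = "equidistant"
    out_size: tuple[int, int] | None = None  # (height, width); None = input size
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.pfov_deg < 180:
            raise ValueError("pfov_deg must lie in (0, 180): the rectilinear "
                             "tangent diverges at 180")
        if not 0 < self.fov_deg <= 360:
            raise ValueError("fov_deg must lie in (0, 360]")
        if self.out_size is not None and min(self.out_size) <= 0:
            raise ValueError("out_size must be positive")
        if self.projection not in ("equidistant", "equisolid",
                                   "orthographic", "stereographic"):
            raise ValueError(f"unknown projection {self.projection!r}")


@dataclass(frozen=True)
class PixelMap:
    """Fractional source coordinate sampled by each output pixel.

    ``src_y``/``src_x`` are float arrays of the output shape; out-of-domain
    pixels are NaN. Pixel centers sit at integer coordinates, origin top
    left, x right, y down.
    """

    src_y: np.ndarray
    src_x: np.ndarray
    in_size: tuple[int, int]

    @property
    def out_size(self) -> tuple[int, int]:
        return self.src_y.shape


def _theta_to_radius(theta: np.ndarray, f: float, projection: Projection
                     ) -> np.ndarray:
    """Lens projection P(theta): angle from optical axis -> image radius."""
    if projection == "equidistant":
        return f * theta
    if projection == "equisolid":
        return 2.0 * f * np.sin(theta / 2.0)
    if projection == "orthographic":
        return f * np.sin(np.minimum(theta, np.pi / 2))
    if projection == "stereographic":
        return 2.0 * f * np.tan(theta / 2.0)
    raise ValueError(projection)


def _radius_to_theta(r: np.ndarray, f: float, projection: Projection
                     ) -> np.ndarray:
    """Inverse lens projection: image radius -> angle from optical axis."""
    if projection == "equidistant":
        return r / f
    if projection == "equisolid":
        return 2.0 * np.arcsin(np.clip(r / (2.0 * f), -1.0, 1.0))
    if projection == "orthographic":
        return np.arcsin(np.clip(r / f, -1.0, 1.0))
    if projection == "stereographic":
        return 2.0 * np.arctan(r / (2.0 * f))
    raise ValueError(projection)


def _fisheye_focal(params: DewarpParams, radius_px: float) -> float:
    """Focal scale putting theta = fov/2 on the fisheye circle edge."""
    half_fov = np.deg2rad(params.fov_deg) / 2.0
    edge = _theta_to_radius(np.asarray(half_fov), 1.0, params.projection)
    return radius_px / float(edge)


def build_pixel_map(params: DewarpParams, in_size: tuple[int, int]) -> PixelMap:
    """Inverse map from dewarped (rectilinear) pixels to fisheye pixels.

    The output center samples the source center exactly, and source radius
    is a strictly increasing function of output radius (radial
    monotonicity), so the mapping is rotationally symmetric.
    """
    in_h, in_w = in_size
    out_h, out_w = params.out_size if params.out_size is not None else in_size

    cy_o, cx_o = (out_h - 1) / 2.0, (out_w - 1) / 2.0
    cy_i, cx_i = (in_h - 1) / 2.0, (in_w - 1) / 2.0
    yy, xx = np.mgrid[0:out_h, 0:out_w].astype(float)
    dx, dy = xx - cx_o, yy - cy_o
    r_out = np.hypot(dx, dy)

    f_rect = (out_w / 2.0) / np.tan(np.deg2rad(params.pfov_deg) / 2.0)
    theta = np.arctan(r_out / f_rect)

    radius_px = min(in_w, in_h) / 2.0
    f_fish = _fisheye_focal(params, radius_px)
    r_in = _theta_to_radius(theta, f_fish, params.projection)

    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_out > 0, r_in / r_out, 1.0)
    src_x = cx_i + dx * scale
    src_y = cy_i + dy * scale

    out_of_domain = r_in > radius_px
    src_x = np.where(out_of_domain, np.nan, src_x)
    src_y = np.where(out_of_domain, np.nan, src_y)
    return PixelMap(src_y, src_x, (in_h, in_w))


def apply_dewarp(image: np.ndarray, pixel_map: PixelMap,
                 interp: Literal["nearest", "bilinear"] = "bilinear",
                 fill_value: float = 0.0) -> np.ndarray:
    """Resample ``image`` through ``pixel_map``.

    Accepts 2-D (grayscale) or 3-D (H, W, C) arrays; returns float64 of
    the map's output size. Unmapped pixels take ``fill_value``.
    """
    if image.shape[:2] != pixel_map.in_size:
        raise ValueError(
            f"image size {image.shape[:2]} does not match map source size "
            f"{pixel_map.in_size}")
    order = 0 if interp == "nearest" else 1
    bad = np.isnan(pixel_map.src_y)
    coords = np.array([
        np.where(bad, 0.0, pixel_map.src_y),
        np.where(bad, 0.0, pixel_map.src_x),
    ])

    def _one(channel: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(channel.astype(float), coords,
                                      order=order, mode="constant",
                                      cval=fill_value)
        out[bad] = fill_value
        return out

    if image.ndim == 2:
        return _one(image)
    return np.stack([_one(image[..., c]) for c in range(image.shape[2])], axis=-1)


def warp_to_fisheye(image: np.ndarray, params: DewarpParams,
                    interp: Literal["nearest", "bilinear"] = "bilinear"
                    ) -> np.ndarray:
    """Forward model: render a rectilinear image as its fisheye view.

    Exact inverse geometry of :func:`build_pixel_map` with the same
    parameters, so `apply_dewarp(warp_to_fisheye(img, p), build_pixel_map(p))`
    reproduces ``img`` over the shared angular domain up to interpolation
    error.
    """
    in_h, in_w = image.shape[:2]
    out_h, out_w = params.out_size if params.out_size is not None else (in_h, in_w)

    cy_o, cx_o = (out_h - 1) / 2.0, (out_w - 1) / 2.0
    cy_i, cx_i = (in_h - 1) / 2.0, (in_w - 1) / 2.0
    yy, xx = np.mgrid[0:out_h, 0:out_w].astype(float)
    dx, dy = xx - cx_o, yy - cy_o
    r_fish = np.hypot(dx, dy)

    radius_px = min(out_w, out_h) / 2.0
    f_fish = _fisheye_focal(params, radius_px)
    theta = _radius_to_theta(r_fish, f_fish, params.projection)

    f_rect = (in_w / 2.0) / np.tan(np.deg2rad(params.pfov_deg) / 2.0)
    with np.errstate(invalid="ignore"):
        r_rect = np.where(theta < np.pi / 2, f_rect * np.tan(theta), np.inf)
        scale = np.where(r_fish > 0, r_rect / r_fish, 1.0)
    src_x = cx_i + dx * scale
    src_y = cy_i + dy * scale

    half_fov = np.deg2rad(params.fov_deg) / 2.0
    bad = (theta > half_fov) | ~np.isfinite(src_x) | ~np.isfinite(src_y)
    src_x = np.where(bad, np.nan, src_x)
    src_y = np.where(bad, np.nan, src_y)
    pm = PixelMap(src_y, src_x, (in_h, in_w))
    return apply_dewarp(image, pm, interp=interp, fill_value=params.fill_value)


def dewarp_image(image: np.ndarray, params: DewarpParams | None = None,
                 interp: Literal["nearest", "bilinear"] = "bilinear"
                 ) -> np.ndarray:
    """One-call dewarp: build the pixel map for this image and apply it."""
    if params is None:
        params = DewarpParams()
    pm = build_pixel_map(params, image.shape[:2])
    return apply_dewarp(image, pm, interp=interp, fill_value=params.fill_value)


def read_image(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path), dtype=float)


def write_image(image: np.ndarray, path) -> None:
    from PIL import Image

    arr = np.clip(np.round(image), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
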