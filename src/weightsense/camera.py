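"""Pinhole projection, lens rectification and depth/thermal sensor fusion.

Conventions: right-handed camera frame with x right, y down, z along the
optical axis; continuous pixel coordinates ``(u, v)`` with pixel centers at
integers, 0-based.  ``u = cx + fx * x / z`` and ``v = cy + fy * y / z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .cloud import PointCloud

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "load_calibration",
    "project_point",
    "project_points",
    "rectify_pixel",
    "depth_to_cloud",
    "fuse_thermal",
]


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics with Brown distortion coefficients (k1,k2,k3,p1,p2)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 0
    height: int = 0
    dist: Tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")


@dataclass(frozen=True)
class Extrinsics:
    """Rigid transform (rotation, translation) mapping reference-frame points
    into another sensor's frame: ``p' = R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "Extrinsics":
        return Extrinsics(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def load_calibration(path) -> dict:
    """Load sensor calibration from a plain-text YAML file.

    Expected layout: one entry per sensor with the intrinsic parameters, and
    an optional ``extrinsics`` mapping holding one rigid transform per
    non-reference sensor::

        sensors:
          depth:   {fx: 365.0, fy: 365.0, cx: 255.5, cy: 211.5,
                    width: 512, height: 424}
          thermal: {fx: 430.0, fy: 430.0, cx: 190.5, cy: 143.5,
                    width: 382, height: 288, dist: [k1, k2, k3, p1, p2]}
        extrinsics:
          thermal: {rotation: [[...3x3...]], translation: [x, y, z]}

    Returns ``{"sensors": {name: Intrinsics}, "extrinsics": {name: Extrinsics}}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sensors = {}
    for name, params in (raw.get("sensors") or {}).items():
        params = dict(params)
        if "dist" in params:
            params["dist"] = tuple(float(v) for v in params["dist"])
        sensors[name] = Intrinsics(**params)
    extrinsics = {}
    for name, params in (raw.get("extrinsics") or {}).items():
        extrinsics[name] = Extrinsics(
            rotation=np.asarray(params["rotation"], dtype=np.float64),
            translation=np.asarray(params["translation"], dtype=np.float64),
        )
    return {"sensors": sensors, "extrinsics": extrinsics}


def project_points(points: np.ndarray, intr: Intrinsics) -> np.ndarray:
    """Vectorized pinhole projection of ``(n, 3)`` points to ``(n, 2)`` pixels.

    Points with ``z <= 0`` project to NaN pixels.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = intr.cx + intr.fx * pts[:, 0] / pts[:, 2]
        v = intr.cy + intr.fy * pts[:, 1] / pts[:, 2]
    bad = ~(pts[:, 2] > 0)
    uv = np.stack([u, v], axis=1)
    uv[bad] = np.nan
    return uv


def project_point(point, intr: Intrinsics) -> Tuple[float, float]:
    """Project one 3D point; raises for non-positive depth."""
    p = np.asarray(point, dtype=np.float64).reshape(3)
    if not p[2] > 0:
        raise ValueError(f"cannot project point with z={p[2]} (must be > 0)")
    return (intr.cx + intr.fx * p[0] / p[2], intr.cy + intr.fy * p[1] / p[2])


def rectify_pixel(q, intr: Intrinsics):
    """Apply the Brown radial/tangential distortion polynomial to a pixel.

    The pixel is mapped to normalized coordinates, the polynomial in
    ``(k1, k2, k3, p1, p2)`` is evaluated, and the result is mapped back to
    pixels.  All-zero coefficients give the identity.
    """
    q = np.asarray(q, dtype=np.float64)
    single = q.ndim == 1
    q = q.reshape(-1, 2)
    k1, k2, k3, p1, p2 = intr.dist
    x = (q[:, 0] - intr.cx) / intr.fx
    y = (q[:, 1] - intr.cy) / intr.fy
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xt = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yt = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    out = np.stack([intr.cx + intr.fx * xt, intr.cy + intr.fy * yt], axis=1)
    return out[0] if single else out


def depth_to_cloud(depth: np.ndarray, intr: Intrinsics) -> PointCloud:
    """Back-project a depth image (meters along the optical axis) into an
    organized cloud.  Non-positive or NaN depths become invalid points."""
    depth = np.asarray(depth, dtype=np.float64)
    h, w = depth.shape
    v, u = np.mgrid[0:h, 0:w].astype(np.float64)
    z = depth.copy()
    invalid = ~(z > 0)
    z[invalid] = np.nan
    x = (u - intr.cx) / intr.fx * z
    y = (v - intr.cy) / intr.fy * z
    xyz = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    return PointCloud(xyz=xyz, organized=(h, w))


def fuse_thermal(
    cloud: PointCloud,
    thermal: np.ndarray,
    intr_t: Intrinsics,
    extr_t: Extrinsics | None = None,
) -> PointCloud:
    """Attach per-point temperatures by projecting the cloud into a thermal
    image (nearest-pixel sampling).

    Each point is transformed into the thermal camera's frame by ``extr_t``
    (identity if omitted), projected with ``intr_t``, and the temperature of
    the nearest pixel is attached.  Points projecting outside the image (or
    with non-positive depth in the thermal frame) carry NaN temperature.
    Coordinates are never modified.
    """
    thermal = np.asarray(thermal, dtype=np.float64)
    h, w = thermal.shape
    if extr_t is None:
        extr_t = Extrinsics.identity()
    pts = extr_t.apply(cloud.xyz)
    uv = project_points(pts, intr_t)
    temp = np.full(len(cloud), np.nan)
    with np.errstate(invalid="ignore"):
        ui = np.rint(uv[:, 0]).astype(np.float64)
        vi = np.rint(uv[:, 1]).astype(np.float64)
        inside = (
            np.isfinite(ui) & np.isfinite(vi) & (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
        )
    temp[inside] = thermal[vi[inside].astype(int), ui[inside].astype(int)]
    return PointCloud(
        xyz=cloud.xyz.copy(),
        rgb=None if cloud.rgb is None else cloud.rgb.copy(),
        temperature=temp,
        organized=cloud.organized,
        meta=cloud.meta,
    )
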