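"""Point-cloud container shared by every pipeline stage.

A cloud is a flat array of points, each carrying Cartesian coordinates in
meters and, optionally, 8-bit color and a temperature in degrees Celsius.
Clouds produced by projective sensors are *organized*: the points retain the
``(height, width)`` pixel-grid layout of the source depth image, with invalid
pixels encoded as NaN coordinates.  Unorganized clouds are plain point sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["PointCloud", "SubjectMeta", "parse_dataset_filename"]


@dataclass(frozen=True)
class SubjectMeta:
    """Per-frame metadata encoded in the dataset's file names."""

    gender: str  # "female" or "male"
    ground_truth_kg: float
    person_id: int
    frame_id: int

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")
        if not self.ground_truth_kg > 0:
            raise ValueError("ground_truth_kg must be positive")


_FILENAME_RE = re.compile(
    r"^(?P<gender>[A-Za-z]+)_(?P<weight>\d+(?:\.\d+)?)_(?P<person>\d+)_(?P<frame>\d+)\.pcd$"
)

_GENDER_TOKENS = {"f": "female", "female": "female", "m": "male", "male": "male"}


def parse_dataset_filename(name: str) -> SubjectMeta:
    """Parse ``GENDER_GROUNDTRUTH_PERSONID_FRAMEID.pcd`` into :class:`SubjectMeta`.

    Gender tokens ``f/m/female/male`` are accepted case-insensitively.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        raise ValueError(f"file name {name!r} does not match GENDER_WEIGHT_PERSON_FRAME.pcd")
    token = m.group("gender").lower()
    if token not in _GENDER_TOKENS:
        raise ValueError(f"unrecognized gender token {m.group('gender')!r} in {name!r}")
    return SubjectMeta(
        gender=_GENDER_TOKENS[token],
        ground_truth_kg=float(m.group("weight")),
        person_id=int(m.group("person")),
        frame_id=int(m.group("frame")),
    )


@dataclass
class PointCloud:
    """A set of 3D points with optional color and temperature channels.

    Parameters
    ----------
    xyz:
        ``(n, 3)`` float array of coordinates in meters.  NaN rows mark
        invalid points (allowed only so organized clouds keep their grid).
    rgb:
        Optional ``(n, 3)`` uint8 color array.
    temperature:
        Optional ``(n,)`` float array in degrees Celsius; NaN where a point
        carries no temperature.
    organized:
        Optional ``(height, width)`` of the source pixel grid; if given,
        ``height * width`` must equal ``n``.
    meta:
        Optional :class:`SubjectMeta` for dataset frames.
    """

    xyz: np.ndarray
    rgb: Optional[np.ndarray] = None
    temperature: Optional[np.ndarray] = None
    organized: Optional[Tuple[int, int]] = None
    meta: Optional[SubjectMeta] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.uint8).reshape(-1, 3)
            if len(self.rgb) != len(self.xyz):
                raise ValueError("rgb length does not match xyz")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=np.float64).reshape(-1)
            if len(self.temperature) != len(self.xyz):
                raise ValueError("temperature length does not match xyz")
        if self.organized is not None:
            h, w = self.organized
            if h * w != len(self.xyz):
                raise ValueError(
                    f"organized layout {h}x{w} does not match {len(self.xyz)} points"
                )
            self.organized = (int(h), int(w))

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of points with finite coordinates."""
        return np.isfinite(self.xyz).all(axis=1)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def has_temperature(self) -> bool:
        return self.temperature is not None

    def select(self, mask_or_indices: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array.  The result is unorganized."""
        idx = np.asarray(mask_or_indices)
        return PointCloud(
            xyz=self.xyz[idx],
            rgb=None if self.rgb is None else self.rgb[idx],
            temperature=None if self.temperature is None else self.temperature[idx],
            organized=None,
            meta=self.meta,
        )

    def invalidate(self, mask: np.ndarray) -> "PointCloud":
        """Return a copy with the masked points turned invalid (NaN), keeping layout."""
        xyz = self.xyz.copy()
        xyz[np.asarray(mask, dtype=bool)] = np.nan
        return replace(self, xyz=xyz)

    def valid_points(self) -> np.ndarray:
        """``(n_valid, 3)`` array of finite coordinates."""
        return self.xyz[self.valid_mask]

    def centroid(self) -> np.ndarray:
        """Centroid of the valid points."""
        pts = self.valid_points()
        if len(pts) == 0:
            raise ValueError("cloud has no valid points")
        return pts.mean(axis=0)
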