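"""Person/environment segmentation for lying (clinical) and standing/walking scenes.

The scene cloud ``P`` is split into the person's points ``Pp`` and the
environment ``PE`` with ``P = Pp + PE`` over the valid points — every valid
point lands on exactly one side.  Two recipes are provided:

* :func:`segment_lying` — over-stretcher viewpoint: crop to the floor-marker
  region of interest, estimate the stretcher surface by RANSAC, threshold on
  body temperature when a thermal channel is present (else fall back to the
  purely geometric path), keep the largest Euclidean component and clean the
  silhouette morphologically.
* :func:`segment_standing` — background subtraction against a person-free
  reference frame, floor-plane removal, statistical outlier filtering and
  largest-component extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.morphology import disk, opening

from .cloud import PointCloud

__all__ = [
    "PlaneModel",
    "SegmentationConfig",
    "SegmentedScene",
    "EmptySegmentationError",
    "crop_roi",
    "remove_plane_ransac",
    "fit_plane_ransac",
    "thermal_segment",
    "subtract_background",
    "largest_component",
    "morphological_clean",
    "statistical_outlier_filter",
    "segment_lying",
    "segment_standing",
]


class EmptySegmentationError(RuntimeError):
    """Raised when no person points survive the segmentation pipeline."""


@dataclass(frozen=True)
class PlaneModel:
    """Plane ``{p : n . p + d = 0}`` with unit normal ``n`` and offset ``d`` (m)."""

    normal: np.ndarray
    offset: float
    inlier_tolerance: float = 0.015

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("plane normal must be nonzero")
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return pts @ self.normal + self.offset


@dataclass
class SegmentationConfig:
    """Thresholds for both segmentation recipes.

    Defaults: 30 °C separates skin (~33-36 °C) from room surfaces; the 5 cm
    background-change threshold sits a few sigma above typical depth noise at
    2-4 m; RANSAC runs 500 three-point hypotheses at 1.5 cm tolerance.  The
    statistical outlier gate is deliberately conservative (mean + 6 sd of the
    20-NN mean distance): it targets flying-pixel/jumping-edge artifacts that
    sit decimeters off the surface, not silhouette-edge points whose neighbor
    spacing is legitimately wider at grazing incidence.
    """

    thermal_min: float = 30.0
    background_dist_threshold: float = 0.05
    ransac_tolerance: float = 0.015
    ransac_iterations: int = 500
    ransac_seed: int = 0
    roi: Optional[Tuple[Tuple[float, float, float], Tuple[float, float, float]]] = None
    morph_radius: int = 2
    outlier_k: int = 20
    outlier_sigma: float = 6.0
    keep_largest: bool = True
    link_radius: float = 0.05


@dataclass
class SegmentedScene:
    person: PointCloud
    environment: PointCloud
    support_plane: Optional[PlaneModel] = None
    person_indices: Optional[np.ndarray] = None  # indices into the input cloud


def crop_roi(cloud: PointCloud, roi) -> PointCloud:
    """Keep points inside the closed axis-aligned box ``roi = (lo, hi)``."""
    lo = np.asarray(roi[0], dtype=np.float64)
    hi = np.asarray(roi[1], dtype=np.float64)
    if np.any(hi <= lo):
        raise ValueError("roi box is degenerate")
    inside = cloud.valid_mask & np.all((cloud.xyz >= lo) & (cloud.xyz <= hi), axis=1)
    return cloud.select(inside)


def _roi_mask(cloud: PointCloud, roi) -> np.ndarray:
    lo = np.asarray(roi[0], dtype=np.float64)
    hi = np.asarray(roi[1], dtype=np.float64)
    return np.all((cloud.xyz >= lo) & (cloud.xyz <= hi), axis=1)


def fit_plane_ransac(
    points: np.ndarray, tol: float, iters: int = 500, seed: int = 0
) -> PlaneModel:
    """Max-inlier three-point plane hypothesis over ``iters`` seeded draws.

    Ties in inlier count are broken by the lower iteration index; the
    winning hypothesis is returned without refitting, so a fixed seed is
    reproducible bit-exactly.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(pts)
    if n < 3:
        raise ValueError(f"plane fit needs >= 3 points, got {n}")
    rng = np.random.default_rng(seed)
    triples = rng.integers(0, n, size=(iters, 3))
    a = pts[triples[:, 0]]
    b = pts[triples[:, 1]]
    c = pts[triples[:, 2]]
    normals = np.cross(b - a, c - a)
    lengths = np.linalg.norm(normals, axis=1)
    ok = lengths > 1e-12
    best_count = -1
    best = -1
    # chunked inlier counting keeps the distance matrix small
    idx_ok = np.flatnonzero(ok)
    unit = np.zeros_like(normals)
    unit[idx_ok] = normals[idx_ok] / lengths[idx_ok, None]
    offsets = -np.einsum("ij,ij->i", unit, a)
    chunk = 64
    counts = np.full(iters, -1, dtype=np.int64)
    for start in range(0, len(idx_ok), chunk):
        sel = idx_ok[start : start + chunk]
        d = np.abs(pts @ unit[sel].T + offsets[sel])  # (n, chunk)
        counts[sel] = (d <= tol).sum(axis=0)
    best = int(np.argmax(counts))
    best_count = counts[best]
    if best_count < 3:
        raise ValueError("RANSAC found no valid plane hypothesis")
    return PlaneModel(normal=unit[best], offset=float(offsets[best]), inlier_tolerance=tol)


def remove_plane_ransac(
    cloud: PointCloud, tol: float = 0.015, iters: int = 500, seed: int = 0
) -> Tuple[PointCloud, PlaneModel]:
    """Detect the dominant plane and return (remainder, plane).

    Inliers (|signed distance| <= tol) are removed from the remainder.
    """
    valid = cloud.valid_mask
    pts = cloud.xyz[valid]
    plane = fit_plane_ransac(pts, tol=tol, iters=iters, seed=seed)
    dist = np.abs(plane.signed_distance(cloud.xyz))
    keep = valid & ~(dist <= tol)
    return cloud.select(keep), plane


def thermal_segment(cloud: PointCloud, t_min: float) -> PointCloud:
    """Keep points at or above the body-temperature threshold ``t_min`` (°C)."""
    if cloud.temperature is None:
        raise ValueError("cloud carries no temperature channel")
    with np.errstate(invalid="ignore"):
        warm = cloud.temperature >= t_min
    return cloud.select(cloud.valid_mask & warm)


def subtract_background(
    scene: PointCloud, reference: PointCloud, dist_threshold: float
) -> PointCloud:
    """Keep scene points farther than ``dist_threshold`` from the reference.

    Organized clouds on the same grid are compared pixel-wise (a valid scene
    pixel whose reference pixel is invalid counts as changed); otherwise the
    nearest-neighbor distance to the reference cloud is used.
    """
    keep = _background_change_mask(scene, reference, dist_threshold)
    return scene.select(keep)


def _background_change_mask(
    scene: PointCloud, reference: PointCloud, dist_threshold: float
) -> np.ndarray:
    valid = scene.valid_mask
    if scene.organized is not None and reference.organized is not None:
        if scene.organized != reference.organized:
            raise ValueError(
                f"organized grids differ: {scene.organized} vs {reference.organized}"
            )
        ref_valid = reference.valid_mask
        diff = np.linalg.norm(scene.xyz - reference.xyz, axis=1)
        changed = valid & (~ref_valid | (diff > dist_threshold))
        return changed
    ref_pts = reference.valid_points()
    if len(ref_pts) == 0:
        return valid
    tree = cKDTree(ref_pts)
    d = np.full(len(scene), np.inf)
    d[valid], _ = tree.query(scene.xyz[valid], k=1)
    return valid & (d > dist_threshold)


def largest_component(cloud: PointCloud, link_radius: float) -> PointCloud:
    """Largest Euclidean connected component at the given linkage radius.

    A size tie is broken in favor of the component whose centroid is closer
    to the sensor origin.  Empty input returns an empty cloud.
    """
    idx = _largest_component_indices(cloud.valid_points(), link_radius)
    valid_idx = np.flatnonzero(cloud.valid_mask)
    return cloud.select(valid_idx[idx])


def _largest_component_indices(pts: np.ndarray, link_radius: float) -> np.ndarray:
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    if len(pairs) == 0:
        adj = coo_matrix((n, n))
    else:
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best_size = sizes.max()
    winners = np.flatnonzero(sizes == best_size)
    if len(winners) == 1:
        best = winners[0]
    else:
        dists = [np.linalg.norm(pts[labels == w].mean(axis=0)) for w in winners]
        best = winners[int(np.argmin(dists))]
    return np.flatnonzero(labels == best)


def morphological_clean(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening (erosion then dilation) with a disc structuring element.

    Removes isolated speckles smaller than the element; the result is always
    a subset of the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    return opening(mask, footprint=disk(radius)).astype(bool)


def _outlier_keep_mask(pts: np.ndarray, k: int, sigma: float) -> np.ndarray:
    if len(pts) <= k:
        raise ValueError(f"need more than k={k} points, got {len(pts)}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k + 1)  # first neighbor is the point itself
    mean_d = d[:, 1:].mean(axis=1)
    # tolerance keeps float jitter from splitting an exactly-uniform cloud
    cutoff = mean_d.mean() + sigma * mean_d.std() + 1e-9 * mean_d.mean()
    return mean_d <= cutoff


def statistical_outlier_filter(cloud: PointCloud, k: int, sigma: float) -> PointCloud:
    """Drop points whose mean distance to their k nearest neighbors exceeds
    the global mean + sigma * stddev of that statistic."""
    valid_idx = np.flatnonzero(cloud.valid_mask)
    keep = _outlier_keep_mask(cloud.xyz[valid_idx], k, sigma)
    return cloud.select(valid_idx[keep])


def _finalize(
    scene: PointCloud, person_idx: np.ndarray, plane: Optional[PlaneModel]
) -> SegmentedScene:
    valid_idx = np.flatnonzero(scene.valid_mask)
    if len(person_idx) == 0:
        raise EmptySegmentationError("no person points survived segmentation")
    env_mask = np.ones(len(scene), dtype=bool)
    env_mask[person_idx] = False
    env_idx = valid_idx[env_mask[valid_idx]]
    if scene.organized is not None:
        # keep the pixel-grid layout on both sides (invalid elsewhere) so the
        # person cloud stays usable for meshing and silhouette extraction
        person_keep = np.zeros(len(scene), dtype=bool)
        person_keep[person_idx] = True
        person = scene.invalidate(~person_keep)
        env_keep = np.zeros(len(scene), dtype=bool)
        env_keep[env_idx] = True
        environment = scene.invalidate(~env_keep)
    else:
        person = scene.select(person_idx)
        environment = scene.select(env_idx)
    return SegmentedScene(
        person=person,
        environment=environment,
        support_plane=plane,
        person_indices=person_idx,
    )


def _morph_filter_indices(
    scene: PointCloud, person_idx: np.ndarray, radius: int
) -> np.ndarray:
    """Apply morphological opening on the organized validity mask of the
    person subset; unorganized scenes are returned unchanged."""
    if scene.organized is None or radius <= 0 or len(person_idx) == 0:
        return person_idx
    h, w = scene.organized
    mask = np.zeros(h * w, dtype=bool)
    mask[person_idx] = True
    cleaned = morphological_clean(mask.reshape(h, w), radius).ravel()
    return person_idx[cleaned[person_idx]]


def segment_lying(scene: PointCloud, cfg: SegmentationConfig) -> SegmentedScene:
    """Clinical recipe for a patient lying on a stretcher seen from above.

    The point set is first reduced to the floor-marker region of interest.
    The stretcher surface is estimated by RANSAC on that reduced scene and
    kept as the support plane for the later volume feature.  When the cloud
    carries a thermal channel the person candidates are the warm points;
    otherwise the candidates are the non-plane points (geometric fallback —
    bystanders may survive it).  Stretcher-plane inliers are removed from the
    candidates, the largest Euclidean component is kept, and the silhouette
    is cleaned by a morphological opening.
    """
    valid = scene.valid_mask
    idx = np.flatnonzero(valid)
    if cfg.roi is not None:
        idx = idx[_roi_mask(scene.select(idx), cfg.roi)]
    if len(idx) < 3:
        raise EmptySegmentationError("scene has too few valid points in the ROI")
    plane = fit_plane_ransac(
        scene.xyz[idx],
        tol=cfg.ransac_tolerance,
        iters=cfg.ransac_iterations,
        seed=cfg.ransac_seed,
    )
    if scene.has_temperature:
        with np.errstate(invalid="ignore"):
            warm = scene.temperature[idx] >= cfg.thermal_min
        cand = idx[warm]
    else:
        cand = idx
    off_plane = (
        np.abs(plane.signed_distance(scene.xyz[cand])) > cfg.ransac_tolerance
    )
    cand = cand[off_plane]
    if cfg.keep_largest and len(cand) > 0:
        comp = _largest_component_indices(scene.xyz[cand], cfg.link_radius)
        cand = cand[comp]
    cand = _morph_filter_indices(scene, cand, cfg.morph_radius)
    return _finalize(scene, cand, plane)


def segment_standing(
    scene: PointCloud, reference: PointCloud, cfg: SegmentationConfig
) -> SegmentedScene:
    """Standing/walking recipe via background subtraction.

    Scene points that moved relative to the person-free reference frame are
    kept; the dominant plane of the reference scene (the floor in a walking
    lane) is removed from the remainder for a cleaner foot segmentation;
    statistical outliers are filtered and the largest Euclidean component is
    the person.
    """
    changed = _background_change_mask(scene, reference, cfg.background_dist_threshold)
    cand = np.flatnonzero(changed)
    if len(cand) == 0:
        raise EmptySegmentationError("background subtraction left no points")
    plane = fit_plane_ransac(
        reference.valid_points(),
        tol=cfg.ransac_tolerance,
        iters=cfg.ransac_iterations,
        seed=cfg.ransac_seed,
    )
    off_plane = np.abs(plane.signed_distance(scene.xyz[cand])) > cfg.ransac_tolerance
    cand = cand[off_plane]
    if len(cand) > cfg.outlier_k:
        cand = cand[_outlier_keep_mask(scene.xyz[cand], cfg.outlier_k, cfg.outlier_sigma)]
    if cfg.keep_largest and len(cand) > 0:
        comp = _largest_component_indices(scene.xyz[cand], cfg.link_radius)
        cand = cand[comp]
    return _finalize(scene, cand, plane)
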