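"""The 19-element shape descriptor of a segmented person cloud.

Feature groups:

* simple geometry — frontal-surface volume ``v`` (lying subjects only, needs
  the stretcher plane), mesh surface ``s``, point count ``|Pp|`` and scene
  density ``|Pp|/|P|``;
* scatter-matrix eigenvalues ``lambda1 >= lambda2 >= lambda3`` of
  ``S = sum_j (p_j - pbar)(p_j - pbar)^T`` and the eigenvalue-ratio shape
  descriptors sphericity ``lambda3/sum``, flatness ``2(lambda2-lambda3)/sum``
  and linearity ``(lambda1-lambda2)/sum``;
* statistical moments — compactness (RMS distance to the centroid), the
  summed centroid distance, and a fourth-moment variant divided by flatness;
* silhouette descriptors — perimeter/area of the projected outer contour and
  of its convex hull, in pixel units;
* distance to the person and the (given, never inferred) gender.

The scatter matrix is the unnormalized sum of outer products: with ~10^4
points on a ~2 m subject its eigenvalues sit at the 10^3 m^2 scale, and the
ratio features are unaffected by the normalization choice.  The summed
centroid distance is historically labelled "kurtosis" in this descriptor and
the label is kept for continuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image

from .camera import Intrinsics, project_points
from .cloud import PointCloud
from .segmentation import PlaneModel

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FrontalMesh",
    "scatter_eigenvalues",
    "eigen_shape_features",
    "compute_frontal_mesh",
    "compute_surface",
    "compute_volume",
    "statistical_features",
    "silhouette_features",
    "distance_to_person",
    "extract_features",
]

FEATURE_NAMES = (
    "volume",
    "surface",
    "n_person",
    "density",
    "eigenvalue_1",
    "eigenvalue_2",
    "eigenvalue_3",
    "sphericity",
    "flatness",
    "linearity",
    "compactness",
    "kurtosis",
    "alt_compactness",
    "distance",
    "contour_length",
    "contour_area",
    "hull_length",
    "hull_area",
    "gender",
)


@dataclass
class FeatureVector:
    """Values and per-feature availability flags, ordered as :data:`FEATURE_NAMES`."""

    values: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(len(FEATURE_NAMES))
        self.available = np.asarray(self.available, dtype=bool).reshape(len(FEATURE_NAMES))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def is_available(self, name: str) -> bool:
        return bool(self.available[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict:
        out = {}
        for i, name in enumerate(FEATURE_NAMES):
            out[name] = float(self.values[i]) if self.available[i] else None
        return out


@dataclass
class FrontalMesh:
    """Triangle mesh of the person's visible frontal surface."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")


def scatter_eigenvalues(cloud: PointCloud | np.ndarray) -> Tuple[float, float, float]:
    """Eigenvalues of the 3x3 scatter matrix, sorted descending.

    The scatter matrix is the unnormalized sum of centered outer products, so
    the eigenvalues carry units of m^2 times the point count.  They are
    invariant under rigid transforms of the cloud.
    """
    pts = cloud.valid_points() if isinstance(cloud, PointCloud) else np.asarray(cloud)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    scatter = centered.T @ centered
    vals = np.linalg.eigvalsh(scatter)[::-1]
    return (max(vals[0], 0.0), max(vals[1], 0.0), max(vals[2], 0.0))


def eigen_shape_features(l1: float, l2: float, l3: float) -> Tuple[float, float, float]:
    """Sphericity, flatness and linearity from sorted eigenvalues.

    sphericity = lambda3 / sum, flatness = 2 (lambda2 - lambda3) / sum,
    linearity = (lambda1 - lambda2) / sum.  All lie in [0, 1].
    """
    if not (l1 >= l2 >= l3 >= 0):
        raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 >= 0")
    total = l1 + l2 + l3
    if total <= 0:
        raise ValueError("eigenvalue sum must be positive")
    return (l3 / total, 2.0 * (l2 - l3) / total, (l1 - l2) / total)


def compute_frontal_mesh(person: PointCloud, jump_threshold: float = 0.05) -> FrontalMesh:
    """Triangulate the organized person cloud: two triangles per 2x2 pixel
    quad whose four points are valid and whose depth range stays below the
    jump threshold (avoids bridging jumping-edge artifacts)."""
    if person.organized is None:
        raise ValueError("frontal mesh requires an organized cloud")
    h, w = person.organized
    xyz = person.xyz.reshape(h, w, 3)
    valid = np.isfinite(xyz).all(axis=2)
    tl = valid[:-1, :-1] & valid[:-1, 1:] & valid[1:, :-1] & valid[1:, 1:]
    z_hi = np.where(valid, xyz[:, :, 2], -np.inf)
    z_lo = np.where(valid, xyz[:, :, 2], np.inf)
    zq_hi = np.stack([z_hi[:-1, :-1], z_hi[:-1, 1:], z_hi[1:, :-1], z_hi[1:, 1:]])
    zq_lo = np.stack([z_lo[:-1, :-1], z_lo[:-1, 1:], z_lo[1:, :-1], z_lo[1:, 1:]])
    quads = tl & (zq_hi.max(axis=0) - zq_lo.min(axis=0) < jump_threshold)
    qi, qj = np.nonzero(quads)
    if len(qi) == 0:
        return FrontalMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))
    flat = lambda i, j: i * w + j
    a = flat(qi, qj)
    b = flat(qi, qj + 1)
    c = flat(qi + 1, qj)
    d = flat(qi + 1, qj + 1)
    tris = np.concatenate(
        [np.stack([a, c, b], axis=1), np.stack([b, c, d], axis=1)], axis=0
    )
    verts = person.xyz
    v0, v1, v2 = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    tris = tris[areas > 0]
    used = np.unique(tris)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return FrontalMesh(vertices=verts[used], triangles=remap[tris])


def compute_surface(mesh: FrontalMesh) -> float:
    """Total triangle area (m^2) of the frontal mesh."""
    if len(mesh.triangles) == 0:
        return 0.0
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def compute_volume(mesh: FrontalMesh, back_plane: PlaneModel) -> float:
    """Volume (m^3) between the frontal surface and the back plane.

    Each triangle contributes a prism: its area projected onto the plane
    times the mean distance of its vertices to the plane.  The plane's
    normal orientation is irrelevant; the result is clamped at zero.
    """
    if len(mesh.triangles) == 0:
        return 0.0
    n = back_plane.normal
    heights = mesh.vertices @ n + back_plane.offset
    # orient so the mesh lies on the positive side
    if heights.mean() < 0:
        heights = -heights
    proj = mesh.vertices - np.outer(mesh.vertices @ n + back_plane.offset, n)
    t = mesh.triangles
    cross = np.cross(proj[t[:, 1]] - proj[t[:, 0]], proj[t[:, 2]] - proj[t[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    mean_h = heights[t].mean(axis=1)
    return max(float(np.sum(areas * mean_h)), 0.0)


def statistical_features(
    person: PointCloud | np.ndarray,
) -> Tuple[float, float, Optional[float]]:
    """Compactness (RMS centroid distance, m), summed centroid distance, and
    the fourth-moment/flatness ratio (None when flatness is zero)."""
    pts = person.valid_points() if isinstance(person, PointCloud) else np.asarray(person)
    if len(pts) < 2:
        raise ValueError(f"need >= 2 points, got {len(pts)}")
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    compactness = float(np.sqrt(np.mean(d**2)))
    summed = float(d.sum())
    alt: Optional[float] = None
    if len(pts) >= 3:
        l1, l2, l3 = scatter_eigenvalues(pts)
        if l1 + l2 + l3 > 0:
            _, flatness, _ = eigen_shape_features(l1, l2, l3)
            if flatness > 0:
                alt = float(np.mean(d**4) / flatness)
    return compactness, summed, alt


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-border pixel centers of a single 8-connected blob
    (Moore-neighbor tracing, clockwise)."""
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    # clockwise Moore neighborhood starting north
    nbrs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    h, w = mask.shape

    def is_set(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p[0], p[1]]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # raster-first pixel: west is outside
    current = start
    first_move = None
    for _ in range(8 * len(rows) + 8):
        delta = (backtrack[0] - current[0], backtrack[1] - current[1])
        k0 = nbrs.index(delta)
        found = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (current[0] + nbrs[k][0], current[1] + nbrs[k][1])
            if is_set(cand):
                found = cand
                backtrack = (
                    current[0] + nbrs[(k - 1) % 8][0],
                    current[1] + nbrs[(k - 1) % 8][1],
                )
                break
        if found is None:  # isolated pixel
            break
        move = (current, found)
        if found == start and first_move is not None and move == first_move:
            break
        if first_move is None:
            first_move = move
        current = found
        if current == start and len(boundary) > 1:
            break
        boundary.append(current)
    return np.asarray(boundary, dtype=np.float64)


def silhouette_features(
    person: PointCloud, intr: Intrinsics
) -> Tuple[float, float, float, float]:
    """Contour and convex-hull perimeter/area of the projected silhouette.

    The person cloud is projected onto the sensor grid, the largest
    8-connected blob is taken, and its outer border polygon through pixel
    centers gives the contour length; the contour area is the blob's pixel
    count.  The convex hull of the border pixels gives the hull length, and
    the hull area is the pixel count of the filled hull.
    """
    pts = person.valid_points()
    if len(pts) == 0:
        raise ValueError("empty person cloud")
    uv = project_points(pts, intr)
    uv = uv[np.isfinite(uv).all(axis=1)]
    if len(uv) == 0:
        raise ValueError("no points project in front of the camera")
    cols = np.rint(uv[:, 0]).astype(int)
    rows = np.rint(uv[:, 1]).astype(int)
    if intr.width > 0 and intr.height > 0:
        keep = (cols >= 0) & (cols < intr.width) & (rows >= 0) & (rows < intr.height)
        cols, rows = cols[keep], rows[keep]
        if len(cols) == 0:
            raise ValueError("person projects outside the sensor image")
        shape = (intr.height, intr.width)
        r0 = c0 = 0
    else:
        r0, c0 = rows.min(), cols.min()
        rows, cols = rows - r0, cols - c0
        shape = (rows.max() + 1, cols.max() + 1)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    labels = cc_label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    blob = labels == sizes.argmax()
    contour_area = float(blob.sum())
    border = _trace_boundary(blob)
    if len(border) < 2:
        contour_length = 0.0
    else:
        closed = np.vstack([border, border[:1]])
        contour_length = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    hull_area = float(convex_hull_image(blob).sum()) if contour_area > 0 else 0.0
    try:
        hull = ConvexHull(border)
        hp = border[hull.vertices]
        closed = np.vstack([hp, hp[:1]])
        hull_length = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    except (QhullError, IndexError, ValueError):
        # degenerate silhouette (point or line): hull equals the contour
        hull_length = contour_length
        hull_area = contour_area
    return contour_length, contour_area, hull_length, hull_area


def distance_to_person(person: PointCloud, mode: str = "centroid") -> float:
    """Distance (m) from the sensor origin to the person: centroid distance
    by default, nearest-point distance with ``mode='nearest'``."""
    pts = person.valid_points()
    if len(pts) == 0:
        raise ValueError("empty person cloud")
    if mode == "centroid":
        return float(np.linalg.norm(pts.mean(axis=0)))
    if mode == "nearest":
        return float(np.linalg.norm(pts, axis=1).min())
    raise ValueError(f"unknown distance mode {mode!r}")


def extract_features(
    person: PointCloud,
    scene: Optional[PointCloud] = None,
    plane: Optional[PlaneModel] = None,
    intr: Optional[Intrinsics] = None,
    gender: Optional[str] = None,
    jump_threshold: float = 0.05,
    normalized_eigenvalues: bool = False,
) -> FeatureVector:
    """Assemble the full 19-feature descriptor with availability flags.

    Volume needs both an organized person cloud and a back plane; the mesh
    surface needs organization; silhouette features need intrinsics; density
    needs the full scene; gender is an input and stays unavailable without
    one.
    """
    if person.n_valid == 0:
        raise ValueError("empty person cloud")
    values = np.zeros(len(FEATURE_NAMES))
    avail = np.zeros(len(FEATURE_NAMES), dtype=bool)

    def put(name: str, value: Optional[float]) -> None:
        if value is not None:
            i = FEATURE_NAMES.index(name)
            values[i] = value
            avail[i] = True

    if person.organized is not None:
        mesh = compute_frontal_mesh(person, jump_threshold=jump_threshold)
        put("surface", compute_surface(mesh))
        if plane is not None:
            put("volume", compute_volume(mesh, plane))
    put("n_person", float(person.n_valid))
    if scene is not None and scene.n_valid > 0:
        put("density", person.n_valid / scene.n_valid)
    l1, l2, l3 = scatter_eigenvalues(person)
    total = l1 + l2 + l3
    if normalized_eigenvalues and total > 0:
        put("eigenvalue_1", l1 / total)
        put("eigenvalue_2", l2 / total)
        put("eigenvalue_3", l3 / total)
    else:
        put("eigenvalue_1", l1)
        put("eigenvalue_2", l2)
        put("eigenvalue_3", l3)
    if total > 0:
        sph, fla, lin = eigen_shape_features(l1, l2, l3)
        put("sphericity", sph)
        put("flatness", fla)
        put("linearity", lin)
    compactness, summed, alt = statistical_features(person)
    put("compactness", compactness)
    put("kurtosis", summed)
    put("alt_compactness", alt)
    put("distance", distance_to_person(person))
    if intr is not None:
        lc, ac, lh, ah = silhouette_features(person, intr)
        put("contour_length", lc)
        put("contour_area", ac)
        put("hull_length", lh)
        put("hull_area", ah)
    if gender is not None:
        put("gender", {"female": 0.0, "male": 1.0, "f": 0.0, "m": 1.0}[gender.lower()])
    return FeatureVector(values=values, available=avail)
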