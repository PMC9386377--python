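"""Four shape descriptors separating rosette crops from weed morphotypes.

Per blob:

* ``RAT_I_L`` — skeleton point-to-line ratio: merged branch-point count of the
  medial skeleton divided by the skeleton pixel count. Compact rosettes pack
  many intersections into a short skeleton; single stems give near zero.
* ``Rod`` — circularity 4*pi*A / P^2, 1 for a disc.
* ``R`` — maximum inscribed circle radius (distance-transform maximum).
* ``b/a`` — the blob is sliced into 8 concentric annuli of radii k*r/8 about
  its centroid (r = minimum enclosing circle radius); the foreground fraction
  per annulus is fit by a quadratic p_k = a k^2 + b k + c, and b/a summarizes
  how the radial mass distribution falls off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label, perimeter_crofton
from skimage.morphology import skeletonize as _skeletonize

from .preprocess import Blob

__all__ = [
    "SkeletonMask",
    "RingProfile",
    "ShapeFeatures",
    "FeatureScaler",
    "FEATURE_NAMES",
    "skeletonize",
    "branch_points",
    "point_line_ratio",
    "circularity",
    "max_inscribed_radius",
    "min_enclosing_circle",
    "ring_proportions",
    "ba_ratio",
    "compute_features",
]

FEATURE_NAMES = ("rat_i_l", "rod", "r_inscribed", "b_over_a")


@dataclass
class SkeletonMask:
    """Medial skeleton of a blob, in the blob's bounding-box frame."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def length(self) -> int:
        """Skeleton length, defined as the number of skeleton pixels."""
        return int(self.mask.sum())


@dataclass
class RingProfile:
    center: tuple[float, float]
    r: float
    proportions: np.ndarray  # p_k for k = 1..n_rings

    @property
    def n_rings(self) -> int:
        return len(self.proportions)


@dataclass
class ShapeFeatures:
    rat_i_l: float
    rod: float
    r_inscribed: float
    b_over_a: float
    # intermediates kept for inspection / CSV export
    a: float
    b: float
    c: float
    skeleton_len: int
    branches: int
    r_enclosing: float

    def vector(self) -> np.ndarray:
        return np.array([self.rat_i_l, self.rod, self.r_inscribed, self.b_over_a])


def skeletonize(blob: Blob) -> SkeletonMask:
    """1-px-wide connectivity-preserving skeleton via Zhang-Suen thinning."""
    if blob.area == 0:
        raise ValueError("empty blob")
    skel = _skeletonize(blob.mask, method="zhang")
    return SkeletonMask(mask=skel, bbox=blob.bbox)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def branch_points(skel: SkeletonMask) -> tuple[int, np.ndarray]:
    """Skeleton intersections: pixels with >= 3 skeleton 8-neighbors.

    Thinning leaves small clusters of high-degree pixels at a single
    junction, so 8-connected candidate clusters are merged and counted once;
    the reported coordinate is the cluster's rounded centroid (bbox frame).
    """
    sk = skel.mask.astype(np.uint8)
    neighbors = ndi.convolve(sk, _NEIGHBOR_KERNEL, mode="constant", cval=0)
    candidates = skel.mask & (neighbors >= 3)
    labeled, n = label(candidates, connectivity=2, return_num=True)
    coords = np.array(ndi.center_of_mass(candidates, labeled, range(1, n + 1))
                      ).reshape(n, 2)
    return n, np.rint(coords).astype(int)


def point_line_ratio(skel: SkeletonMask) -> float:
    """RAT_I_L = merged branch-point count / skeleton pixel count."""
    if skel.length == 0:
        raise ValueError("empty skeleton")
    n_branches, _ = branch_points(skel)
    return n_branches / skel.length


def circularity(blob: Blob) -> float:
    """Rod = 4*pi*A / P^2 with a Crofton estimate of the outer perimeter.

    P is measured on the hole-filled footprint so that interior gaps
    (soil showing between leaves) do not count toward the contour.
    Degenerate blobs whose perimeter estimate vanishes (single pixels)
    are defined to have Rod = 1.
    """
    if blob.area == 0:
        raise ValueError("empty blob")
    if blob.area == 1:
        return 1.0
    p = perimeter_crofton(ndi.binary_fill_holes(blob.mask), directions=4)
    if p <= 0:
        return 1.0
    return float(4.0 * np.pi * blob.area / p**2)


def max_inscribed_radius(blob: Blob) -> float:
    """R: largest Euclidean distance from a blob pixel to the background."""
    padded = np.pad(blob.mask, 1)
    return float(ndi.distance_transform_edt(padded).max())


def _circle_from(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact circumcircle of 0-3 points."""
    n = len(points)
    if n == 0:
        return np.zeros(2), 0.0
    if n == 1:
        return points[0].astype(float), 0.0
    if n == 2:
        center = points.mean(axis=0)
        return center, float(np.linalg.norm(points[0] - center))
    (ay, ax), (by, bx), (cy, cx) = points.astype(float)
    d = 2.0 * (ay * (bx - cx) + by * (cx - ax) + cy * (ax - bx))
    if abs(d) < 1e-12:  # collinear: span of the farthest pair
        pairs = [(0, 1), (0, 2), (1, 2)]
        i, j = max(pairs, key=lambda ij: np.linalg.norm(points[ij[0]] - points[ij[1]]))
        return _circle_from(points[[i, j]])
    uy = ((ay**2 + ax**2) * (bx - cx) + (by**2 + bx**2) * (cx - ax)
          + (cy**2 + cx**2) * (ax - bx)) / d
    ux = ((ay**2 + ax**2) * (cy - by) + (by**2 + bx**2) * (ay - cy)
          + (cy**2 + cx**2) * (by - ay)) / d
    center = np.array([uy, ux])
    return center, float(np.linalg.norm(points[0] - center))


def _welzl(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Welzl's minimum enclosing circle, iterative form (exact)."""
    pts = points.astype(float)
    rng = np.random.default_rng(0)  # fixed: determinism, not statistics
    pts = pts[rng.permutation(len(pts))]
    center, r = _circle_from(pts[:0])
    eps = 1e-9
    for i, p in enumerate(pts):
        if np.linalg.norm(p - center) <= r + eps:
            continue
        center, r = _circle_from(p[None])
        for j in range(i):
            q = pts[j]
            if np.linalg.norm(q - center) <= r + eps:
                continue
            center, r = _circle_from(np.array([p, q]))
            for k in range(j):
                s = pts[k]
                if np.linalg.norm(s - center) <= r + eps:
                    continue
                center, r = _circle_from(np.array([p, q, s]))
    return center, r


def min_enclosing_circle(blob: Blob) -> tuple[tuple[float, float], float]:
    """Smallest circle containing every blob pixel center (full-image frame).

    Runs Welzl's algorithm on the convex hull of the pixel coordinates, which
    determines the same circle as the full point set.
    """
    rows, cols = np.nonzero(blob.mask)  # local frame: exact translation invariance
    pts = np.column_stack([rows, cols]).astype(float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) blobs: Welzl on all points
    center, r = _welzl(pts)
    return (float(center[0]) + blob.bbox[0],
            float(center[1]) + blob.bbox[1]), float(r)


def ring_proportions(blob: Blob, center: tuple[float, float], r: float,
                     n_rings: int = 8, denominator: str = "annulus") -> RingProfile:
    """Foreground fraction in n concentric annuli of radii k*r/8 about center.

    Ring k collects pixels with (k-1)*r/n < dist <= k*r/n. With
    ``denominator="annulus"`` (default) p_k is normalized by the annulus
    pixel count; ``denominator="blob"`` normalizes by the blob area instead.
    """
    if r <= 0:
        raise ValueError("enclosing radius must be positive")
    if denominator not in ("annulus", "blob"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    cy, cx = center
    # grid covering the full circle, in absolute pixel coordinates
    rows = np.arange(int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1)
    cols = np.arange(int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1)
    dist = np.hypot(rows[:, None] - cy, cols[None, :] - cx)

    fg = np.zeros(dist.shape, dtype=bool)
    pix = blob.pixels
    rr = pix[:, 0] - rows[0]
    cc = pix[:, 1] - cols[0]
    inside = (rr >= 0) & (rr < len(rows)) & (cc >= 0) & (cc < len(cols))
    fg[rr[inside], cc[inside]] = True

    edges = r * np.arange(n_rings + 1) / n_rings
    props = np.zeros(n_rings)
    for k in range(1, n_rings + 1):
        ring = (dist > edges[k - 1]) & (dist <= edges[k])
        denom = int(ring.sum()) if denominator == "annulus" else blob.area
        props[k - 1] = fg[ring].sum() / denom if denom > 0 else 0.0
    return RingProfile(center=(cy, cx), r=float(r), proportions=props)


def ba_ratio(profile: RingProfile) -> tuple[float, float, float, float]:
    """Least-squares quadratic p_k = a k^2 + b k + c over k = 1..n; returns b/a.

    Near-degenerate fits (|a| < 1e-6) clamp the ratio to +/-1e6 with the sign
    of b, or 0 when b also vanishes.
    """
    n = profile.n_rings
    if n < 3:
        raise ValueError("need at least 3 rings for a quadratic fit")
    k = np.arange(1, n + 1, dtype=float)
    a, b, c = np.polyfit(k, profile.proportions, 2)
    if abs(a) < 1e-6:
        ratio = 0.0 if abs(b) < 1e-6 else float(np.sign(b) * 1e6)
    else:
        ratio = float(b / a)
    return float(a), float(b), float(c), ratio


def compute_features(blob: Blob, n_rings: int = 8,
                     ring_denominator: str = "annulus") -> ShapeFeatures:
    """Run the full descriptor stack on one blob."""
    skel = skeletonize(blob)
    n_branches, _ = branch_points(skel)
    rat = point_line_ratio(skel)
    rod = circularity(blob)
    r_in = max_inscribed_radius(blob)
    _, r_enc = min_enclosing_circle(blob)
    profile = ring_proportions(blob, blob.centroid, max(r_enc, 1e-9),
                               n_rings=n_rings, denominator=ring_denominator)
    a, b, c, ratio = ba_ratio(profile)
    return ShapeFeatures(
        rat_i_l=rat, rod=rod, r_inscribed=r_in, b_over_a=ratio,
        a=a, b=b, c=c, skeleton_len=skel.length, branches=n_branches,
        r_enclosing=r_enc,
    )


@dataclass
class FeatureScaler:
    """Min-max scaler to [0, 1] with clamping, fitted on training extremes.

    A feature that is constant in training maps to 0.5 everywhere.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, features: list[ShapeFeatures] | np.ndarray) -> "FeatureScaler":
        X = _as_matrix(features)
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, features: list[ShapeFeatures] | np.ndarray) -> np.ndarray:
        X = _as_matrix(features)
        span = self.maxs - self.mins
        out = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            if span[j] == 0:
                out[:, j] = 0.5
            else:
                out[:, j] = np.clip((X[:, j] - self.mins[j]) / span[j], 0.0, 1.0)
        return out


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features.astype(float))
    return np.array([f.vector() for f in features], dtype=float)
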