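"""Generalized moment-method blob detection.

A particle is a set of above-threshold pixels in which every pixel is within
Euclidean distance ``r`` (between pixel centers) of another pixel of the set,
transitively.  With ``r = 1`` this is classic 4-connected labeling; with
``1 < r <= sqrt(2)`` 8-connected labeling; larger ``r`` tolerates gaps (e.g.
pepper-noise holes splitting a particle image).  Two separate particles must
keep their contours at distance > ``r``.

Sub-pixel centers come from the intensity-weighted centroid, optionally with a
base intensity subtracted from every weight (using the detection threshold as
the base reduces the threshold-induced bias).  Image moments of a blob further
give an orientation angle and, for motion streaks modeled as a disk swept
along a segment (a stadium shape), the travel length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

__all__ = [
    "PixelBlob",
    "BlobConstraints",
    "MomentSet",
    "StreakGeometry",
    "Detection",
    "extract_blobs",
    "filter_blobs",
    "centroid",
    "moments",
    "orientation",
    "streak_length",
]


@dataclass(eq=False)
class PixelBlob:
    """Pixels of one detected particle: integer coordinates and intensities,
    all strictly above ``threshold_used``."""

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    threshold_used: float

    def __len__(self) -> int:
        return self.x.size

    @property
    def extent_x(self) -> float:
        """Max x-coordinate difference within the blob (0 for one pixel)."""
        return float(self.x.max() - self.x.min())

    @property
    def extent_y(self) -> float:
        return float(self.y.max() - self.y.min())

    @property
    def brightness_density(self) -> float:
        """Summed intensity per pixel."""
        return float(self.intensity.mean())

    @property
    def density(self) -> float:
        """Pixel count over the bounding-rectangle area ``xd * yd``; infinite
        when either extent is zero (degenerate envelope)."""
        area = self.extent_x * self.extent_y
        return float(len(self) / area) if area > 0 else math.inf


@dataclass(frozen=True)
class BlobConstraints:
    """Acceptance constraints of the generalized moment method: search radius
    ``r`` and minima on pixel count, x/y extent, density and brightness
    density.  All-zero minima accept every blob."""

    r: float = 1.0
    m_p: int = 0
    m_x: float = 0.0
    m_y: float = 0.0
    m_d: float = 0.0
    m_bd: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("search radius r must be > 0")
        if self.m_p < 0 or self.m_x < 0 or self.m_y < 0 or self.m_d < 0 or self.m_bd < 0:
            raise ValueError("constraint minima must be >= 0")

    def accepts(self, blob: PixelBlob) -> bool:
        return (len(blob) >= self.m_p
                and blob.extent_x >= self.m_x
                and blob.extent_y >= self.m_y
                and blob.density >= self.m_d
                and blob.brightness_density >= self.m_bd)


@dataclass
class MomentSet:
    """Raw moments ``m[i, j] = sum x^i y^j I`` and central moments about the
    raw centroid, for all orders ``i + j <= max_order``."""

    raw: dict[tuple[int, int], float]
    central: dict[tuple[int, int], float]
    x_bar: float
    y_bar: float


@dataclass
class StreakGeometry:
    """Stadium-model streak descriptors: effective area ``A``, maximal pixel
    distance ``l_m``, recovered travel length ``l`` in ``[0, l_m]``, implied
    disk radius and orientation angle (degrees, in (-90, 90])."""

    area: float
    l_max: float
    length: float
    disk_radius: float
    angle_deg: float | None
    consistent: bool = True


@dataclass(eq=False)
class Detection:
    """One localized particle: sub-pixel center, source blob, and optional
    shape descriptors / PSF fit attached by later stages."""

    x: float
    y: float
    blob: PixelBlob
    x_moment: float = math.nan
    y_moment: float = math.nan
    streak: StreakGeometry | None = None
    fit: object | None = None
    fit_converged: bool | None = None


def _neighbor_offsets(r: float) -> np.ndarray:
    """Offsets (dy, dx) with 0 < dy^2+dx^2 <= r^2 and (dy > 0) or
    (dy == 0 and dx > 0): a half-stencil covering each pair once."""
    m = int(math.floor(r))
    offs = []
    for dy in range(0, m + 1):
        for dx in range(-m, m + 1):
            if dy == 0 and dx <= 0:
                continue
            if dx * dx + dy * dy <= r * r:
                offs.append((dy, dx))
    return np.asarray(offs, dtype=np.intp).reshape(-1, 2)


def extract_blobs(img: np.ndarray, threshold: float, r: float = 1.0
                  ) -> list[PixelBlob]:
    """Partition all pixels with intensity strictly above ``threshold`` into
    blobs under the transitive relation "center distance <= r".

    Membership uses ``d <= r`` so that ``r = 1`` connects 4-neighbors (the
    simply connected sets of the classic moment method) and ``r = 1.5``
    additionally connects across corners and one-pixel gaps.  Returns an empty
    list when nothing is above threshold.
    """
    if not r > 0:
        raise ValueError("search radius r must be > 0")
    img = np.asarray(img, dtype=float)
    mask = img > threshold
    ys, xs = np.nonzero(mask)
    n = ys.size
    if n == 0:
        return []
    # node ids on the full grid for O(1) neighbor lookup
    ids = np.full(img.shape, -1, dtype=np.intp)
    ids[ys, xs] = np.arange(n)
    h, w = img.shape
    rows, cols = [], []
    for dy, dx in _neighbor_offsets(r):
        y2 = ys + dy
        x2 = xs + dx
        ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
        ok[ok] &= mask[y2[ok], x2[ok]]
        rows.append(np.arange(n)[ok])
        cols.append(ids[y2[ok], x2[ok]])
    row = np.concatenate(rows) if rows else np.empty(0, dtype=np.intp)
    col = np.concatenate(cols) if cols else np.empty(0, dtype=np.intp)
    graph = coo_matrix((np.ones(row.size, dtype=np.int8), (row, col)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
    vals = img[ys, xs]
    blobs = []
    for k in range(n_comp):
        sel = order[bounds[k]:bounds[k + 1]]
        blobs.append(PixelBlob(x=xs[sel].copy(), y=ys[sel].copy(),
                               intensity=vals[sel].copy(),
                               threshold_used=float(threshold)))
    return blobs


def filter_blobs(blobs: list[PixelBlob], constraints: BlobConstraints
                 ) -> list[PixelBlob]:
    """Keep exactly the blobs meeting all five constraint minima."""
    return [b for b in blobs if constraints.accepts(b)]


def centroid(blob: PixelBlob, i_base: float = 0.0) -> tuple[float, float]:
    """Intensity-weighted centroid with base-intensity correction.

    Weights are ``I(p) - i_base``; with ``i_base = 0`` this is the plain
    raw-moment centroid ``(m10/m00, m01/m00)``.  Using the detection threshold
    as ``i_base`` reduces the bias the threshold cut introduces.
    """
    w = blob.intensity - i_base
    total = w.sum()
    if not total > 0:
        raise ValueError("non-positive weight sum: degenerate blob for this i_base")
    return float((blob.x * w).sum() / total), float((blob.y * w).sum() / total)


def moments(blob: PixelBlob, max_order: int = 3) -> MomentSet:
    """Raw and central image moments of the blob up to total order
    ``max_order``; by construction the first central moments vanish."""
    x = blob.x.astype(float)
    y = blob.y.astype(float)
    w = blob.intensity
    raw = {}
    for i in range(max_order + 1):
        for j in range(max_order + 1 - i):
            raw[(i, j)] = float((x ** i * y ** j * w).sum())
    m00 = raw[(0, 0)]
    if not m00 > 0:
        raise ValueError("m00 must be positive")
    xb = raw[(1, 0)] / m00
    yb = raw[(0, 1)] / m00
    central = {}
    for i in range(max_order + 1):
        for j in range(max_order + 1 - i):
            central[(i, j)] = float(((x - xb) ** i * (y - yb) ** j * w).sum())
    return MomentSet(raw=raw, central=central, x_bar=xb, y_bar=yb)


def orientation(ms: MomentSet, tol: float = 1e-12) -> float:
    """Principal-axis orientation ``alpha = 0.5 * atan2(2 mu11, mu20 - mu02)``
    in degrees, in ``(-90, 90]``, measured from the x-axis.

    Raises for rotationally degenerate (circular) blobs, where the angle is
    undefined.
    """
    mu11 = ms.central[(1, 1)]
    diff = ms.central[(2, 0)] - ms.central[(0, 2)]
    scale = max(ms.central[(0, 0)], 1.0)
    if abs(mu11) < tol * scale and abs(diff) < tol * scale:
        raise ValueError("undefined orientation: rotationally degenerate blob")
    alpha = 0.5 * math.degrees(math.atan2(2.0 * mu11, diff))
    if alpha <= -90.0:
        alpha += 180.0
    return alpha


def _max_pairwise_distance(x: np.ndarray, y: np.ndarray) -> float:
    pts = np.column_stack([x, y]).astype(float)
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 600:
        # reduce to the bounding set: extreme points per row strip
        keep = []
        for yy in np.unique(y):
            sel = np.nonzero(y == yy)[0]
            keep.append(sel[np.argmin(x[sel])])
            keep.append(sel[np.argmax(x[sel])])
        pts = pts[np.unique(keep)]
    return float(pdist(pts).max())


def streak_length(blob: PixelBlob, area_mode: str = "binary",
                  plateau: float | None = None) -> StreakGeometry:
    """Recover the travel length of a motion streak from its blob.

    The streak is modeled as a disk of radius ``rho`` swept along a straight
    segment of length ``l`` (a stadium): area ``A = pi rho^2 + 2 rho l`` and
    maximal chord ``l_m = l + 2 rho``.  Eliminating ``rho`` gives the
    quadratic ``a l^2 + b l + c = 0`` with ``a = pi/4 - 1``,
    ``b = (1 - pi/2) l_m``, ``c = (pi/4) l_m^2 - A``, solved by its lower
    root; a still disk (``A = pi rho^2``, ``l_m = 2 rho``) recovers exactly
    ``l = 0``.

    ``area_mode='binary'`` takes ``A`` as the above-threshold pixel count;
    ``'intensity'`` divides the summed intensity by a caller-supplied
    ``plateau`` level.  An inconsistent (A, l_m) pair (negative discriminant)
    is flagged and returns ``l = 0``.
    """
    if len(blob) == 0:
        raise ValueError("empty blob")
    if area_mode == "binary":
        area = float(len(blob))
    elif area_mode == "intensity":
        if plateau is None or not plateau > 0:
            raise ValueError("intensity mode requires a positive plateau level")
        area = float(blob.intensity.sum() / plateau)
    else:
        raise ValueError("area_mode must be 'binary' or 'intensity'")
    lm = _max_pairwise_distance(blob.x, blob.y)
    a = math.pi / 4.0 - 1.0
    b = (1.0 - math.pi / 2.0) * lm
    c = (math.pi / 4.0) * lm * lm - area
    disc = b * b - 4.0 * a * c
    consistent = True
    if disc < 0:
        if disc < -1e-9 * max(1.0, abs(c)):
            warnings.warn("inconsistent stadium geometry; returning length 0",
                          stacklevel=2)
            consistent = False
        disc = 0.0
    length = (-b - math.sqrt(disc)) / (2.0 * a) if consistent else 0.0
    length = min(max(length, 0.0), lm)
    angle = None
    if len(blob) >= 2:
        try:
            angle = orientation(moments(blob, max_order=2))
        except ValueError:
            angle = None
    return StreakGeometry(area=area, l_max=lm, length=length,
                          disk_radius=(lm - length) / 2.0,
                          angle_deg=angle, consistent=consistent)
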