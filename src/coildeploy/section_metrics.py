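"""Quantification of deployed coil distributions on cross-sections.

Deployed coils form a 3D porous medium whose pore structure cannot be
imaged directly, so coil distributions are quantified on sequential 2D
cross-sections: planes perpendicular to the dome→neck axis, 1 mm apart,
starting near the dome.  Each section is rasterized to a binary image (coil
= black: pixels within the swept tube of radius D2/2 around the deployed
centerline), masked by the sac outline of the *first* section, and scored
with two metrics:

* coil density ``CD`` — black pixel fraction inside the mask;
* lacunarity ``L`` — gliding-box statistic of gap heterogeneity:
  ``Λ(r) = σ²(r)/μ²(r) + 1`` over box masses of an r×r window slid over all
  positions inside the mask bounding box, averaged over a geometric series
  of box sizes.  ``L = 1`` for homogeneous fills, larger for clustered ones.

Aneurysm-averaged (CD, L) points are standardized (z-scores per coordinate
over the pooled point set), and simulated deployments are compared to an
experimental point by Euclidean distances: dMin/dMax over the individual
virtual points and dAvg to their centroid, with Shapiro-Wilk/Levene/t-test
univariate statistics across cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .vascular_geometry import AneurysmCase

__all__ = [
    "SectionPlane",
    "BinaryImage",
    "CoilDistribution",
    "ComparisonResult",
    "extract_sections",
    "rasterize",
    "coil_density",
    "lacunarity",
    "aneurysm_average",
    "standardize",
    "euclidean_distance",
    "distance_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class SectionPlane:
    """Cross-section plane: ``index`` runs 1..n ordered dome → neck."""

    origin: np.ndarray
    normal: np.ndarray
    index: int


@dataclass
class BinaryImage:
    """Binary section image: coil pixels True; ``mask`` = sac interior."""

    pixels: np.ndarray
    resolution: float  # mm / pixel
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixel grid and mask must have the same shape")


@dataclass(frozen=True)
class CoilDistribution:
    cd: float
    lac: float


@dataclass
class ComparisonResult:
    technique_points: dict = field(default_factory=dict)
    distances: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)


def extract_sections(case: AneurysmCase, n: int = 5, spacing: float = 1.0) -> list:
    """Section planes perpendicular to the dome→neck axis, ``spacing`` apart.

    Plane 1 sits one spacing below the dome apex; planes progress toward the
    neck.  Raises (reporting the maximum feasible count) if the sac is too
    shallow for ``n`` planes.
    """
    apex = case.dome_apex()
    neck = case.orifice_contour.mean(axis=0)
    axis = neck - apex
    depth = float(np.linalg.norm(axis))
    axis = axis / depth
    feasible = int(math.floor(depth / spacing))
    if n > feasible:
        raise ValueError(
            f"sac depth {depth:.2f} mm fits at most {feasible} sections at "
            f"{spacing} mm spacing, requested {n}"
        )
    return [
        SectionPlane(origin=apex + axis * spacing * (k + 1), normal=axis, index=k + 1)
        for k in range(n)
    ]


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _sac_plane_circle(case: AneurysmCase, plane: SectionPlane):
    """Radius and center of the (spherical) sac outline on a plane."""
    if case.sac_center is None or case.sac_radius is None:
        raise ValueError("mask outline requires an analytic (synthetic) sac")
    d = float((case.sac_center - plane.origin) @ plane.normal)
    r2 = case.sac_radius**2 - d * d
    if r2 <= 0:
        raise ValueError("section plane does not intersect the sac")
    center = case.sac_center - d * plane.normal
    return center, math.sqrt(r2)


def rasterize(
    centerlines: list,
    plane: SectionPlane,
    case: AneurysmCase,
    coil_d2: float,
    resolution: float | None = None,
    mask_plane: SectionPlane | None = None,
) -> BinaryImage:
    """Binary image of the coil tube ∩ plane, masked by the sac outline.

    A pixel is coil (black) when its 3D center lies within ``D2/2`` of any
    deployed centerline segment — exactly the swept-tube/plane intersection
    (capsule slices).  The mask is the sac outline on ``mask_plane``
    (defaults to this plane; pass section 1's plane to follow the
    first-section-mask convention).  Default resolution is ``D2/8``.
    """
    resolution = resolution or coil_d2 / 8.0
    if resolution > coil_d2 / 4.0:
        raise ValueError("resolution too coarse: coil tube must span >= 4 pixels")
    mask_plane = mask_plane or plane
    mcenter, mradius = _sac_plane_circle(case, mask_plane)
    # grid covering the mask circle, centered on the mask center projected
    # into this plane
    u, v = _plane_basis(plane.normal)
    half = mradius + 2.0 * resolution
    m = int(math.ceil(2.0 * half / resolution))
    coords = (np.arange(m) + 0.5) * resolution - half
    uu, vv = np.meshgrid(coords, coords, indexing="xy")
    origin = plane.origin + ((mcenter - plane.origin) @ u) * u + (
        (mcenter - plane.origin) @ v
    ) * v
    pts = origin[None, None, :] + uu[..., None] * u + vv[..., None] * v
    flat = pts.reshape(-1, 3)

    mask = (uu**2 + vv**2) <= mradius**2

    black = np.zeros(len(flat), dtype=bool)
    r_tube = coil_d2 / 2.0
    for nodes in centerlines:
        nodes = np.asarray(nodes)
        if len(nodes) < 2:
            continue
        a = nodes[:-1]
        d = np.diff(nodes, axis=0)
        ll = np.einsum("ij,ij->i", d, d)
        # keep only segments near the plane
        dist_pl = np.abs((nodes - plane.origin) @ plane.normal)
        near = (dist_pl[:-1] < r_tube + np.sqrt(ll)) | (dist_pl[1:] < r_tube + np.sqrt(ll))
        a, d, ll = a[near], d[near], ll[near]
        if len(a) == 0:
            continue
        chunk = 20000
        for lo in range(0, len(flat), chunk):
            p = flat[lo : lo + chunk]
            rel = p[:, None, :] - a[None, :, :]
            tpar = np.clip(
                np.einsum("nmk,mk->nm", rel, d) / np.maximum(ll, 1e-18)[None, :], 0.0, 1.0
            )
            foot = a[None, :, :] + tpar[..., None] * d[None, :, :]
            d2min = np.min(np.sum((p[:, None, :] - foot) ** 2, axis=2), axis=1)
            black[lo : lo + chunk] |= d2min <= r_tube**2
    pixels = black.reshape(m, m) & mask
    return BinaryImage(pixels=pixels, resolution=resolution, mask=mask)


def coil_density(img: BinaryImage) -> float:
    """Black pixel area inside the mask / total mask area."""
    total = int(img.mask.sum())
    if total == 0:
        raise ValueError("empty mask")
    return float((img.pixels & img.mask).sum()) / total


def _box_masses(binary: np.ndarray, r: int) -> np.ndarray:
    """Masses of every r×r window fully inside ``binary`` (integral image)."""
    ii = np.zeros((binary.shape[0] + 1, binary.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(binary.astype(np.int64), axis=0), axis=1)
    return (
        ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]
    ).ravel()


def lacunarity(img: BinaryImage, box_sizes: list | None = None) -> float:
    """Gliding-box lacunarity over the mask bounding box.

    For each box size r the r×r window slides over every position fully
    inside the mask bounding box; ``Λ(r) = σ²/μ² + 1`` over window masses,
    and ``L`` is the arithmetic mean of Λ(r) over the box-size series
    (default powers of two up to 45% of the smaller bbox dimension).  An
    image with no coil pixels has ``L = 1`` by convention.
    """
    rows = np.any(img.mask, axis=1)
    cols = np.any(img.mask, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    sub = (img.pixels & img.mask)[r0:r1, c0:c1]
    if sub.sum() == 0:
        warnings.warn("no coil pixels: lacunarity = 1 by convention")
        return 1.0
    if box_sizes is None:
        rmax = max(2, int(0.45 * min(sub.shape)))
        box_sizes = []
        r = 2
        while r <= rmax:
            box_sizes.append(r)
            r *= 2
        box_sizes = box_sizes or [2]
    lams = []
    for r in box_sizes:
        if r > min(sub.shape):
            warnings.warn(f"box size {r} exceeds mask bounding box; skipped")
            continue
        masses = _box_masses(sub, r)
        mu = masses.mean()
        if mu == 0:
            lams.append(1.0)
            continue
        lams.append(float(masses.var() / mu**2 + 1.0))
    if not lams:
        raise ValueError("no usable box size for lacunarity")
    return float(np.mean(lams))


def aneurysm_average(sections: list) -> tuple:
    """Arithmetic mean (CD̄, L̄) over a deployment's cross-sections."""
    cds = [s.cd for s in sections]
    ls = [s.lac for s in sections]
    return float(np.mean(cds)), float(np.mean(ls))


def standardize(points: np.ndarray) -> np.ndarray:
    """Per-coordinate z-scores over the pooled point set (ddof=0)."""
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance coordinate: cannot standardize")
    return (pts - mean) / sd


def euclidean_distance(p_sim, p_exp) -> float:
    """Straight-line distance in the standardized CD–L plane."""
    p_sim = np.asarray(p_sim, dtype=float)
    p_exp = np.asarray(p_exp, dtype=float)
    return float(np.sqrt(np.sum((p_sim - p_exp) ** 2)))


def distance_summary(exp_point, virtual_points) -> tuple:
    """(dMin, dMax, dAvg) of an experiment point vs a set of virtual points.

    dMin/dMax are extremes over the individual distances; dAvg is the
    distance to the *centroid* of the virtual points (which can be smaller
    than dMin).
    """
    virtual_points = np.atleast_2d(np.asarray(virtual_points, dtype=float))
    if len(virtual_points) == 0:
        raise ValueError("need at least one virtual point")
    d = [euclidean_distance(p, exp_point) for p in virtual_points]
    d_avg = euclidean_distance(virtual_points.mean(axis=0), exp_point)
    return float(min(d)), float(max(d)), float(d_avg)


def compare_groups(distances_a, distances_b, alpha: float = 0.05) -> dict:
    """Univariate comparison of two groups of Euclidean distances.

    Shapiro-Wilk normality per group (skipped with a warning for n < 3),
    Levene's test of equal variances, then a two-sample Student's t-test
    (equal variances assumed when Levene does not reject).
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("groups must have equal length")
    report: dict = {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
    }
    if len(a) >= 3:
        report["shapiro_a_p"] = float(stats.shapiro(a).pvalue)
        report["shapiro_b_p"] = float(stats.shapiro(b).pvalue)
    else:
        warnings.warn("n < 3: normality test skipped")
    identical = np.allclose(a, b)
    if identical and np.allclose(a, a[0]):
        report.update(levene_p=1.0, t_stat=0.0, p_value=1.0, equal_var=True,
                      significant=False)
        return report
    report["levene_p"] = float(stats.levene(a, b).pvalue)
    equal_var = report["levene_p"] >= alpha
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    report["t_stat"] = float(t.statistic)
    report["p_value"] = float(t.pvalue)
    report["equal_var"] = bool(equal_var)
    report["significant"] = bool(t.pvalue < alpha)
    return report
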