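"""Virtual manufacturing of coil tertiary pre-shapes.

A physical coil acquires its 3D "pre-shape" by winding the secondary
helical structure around a shaped mandrel and heat-treating it.  This module
reproduces that step virtually: a mandrel is a main cylinder of diameter
``D3 − 1.5 mm`` carrying cross-axis cylinders of diameter ``D3``; a winding
pattern wraps a curve over the union of cylinder surfaces without
self-intersecting when inflated to the coil diameter ``D2``; the curve is
truncated to the coil length and discretized into the beam-element
centerline.

Because real mandrel designs and winding paths are proprietary, the cross
cylinder count/spacing/azimuth and the winding pattern are free parameters
with one documented default: a main-axis helix interleaved with one
half-turn pass over each cross cylinder.  Every segment lies exactly on a
cylinder surface, and segments hand over at the junction points where the
main and cross surfaces meet, with tangents aligned by construction (the
approach helix pitch is re-solved to land on the junction), so the sampled
curve is on the surface union to round-off and tangent-continuous to within
a few degrees.

A parametric baseline pre-shape (a spherical spiral of envelope diameter
``D3``) is also provided for A/B comparison against the mandrel-wound
pre-shape; it is a documented stand-in family, not a reproduction of any
published parametric coil equations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CrossCylinder",
    "MandrelSpec",
    "WrapSegment",
    "WindingPattern",
    "CoilCenterline",
    "build_mandrel",
    "default_winding_pattern",
    "wind_on_mandrel",
    "truncate_to_length",
    "discretize",
    "parametric_preshape",
    "arc_length",
    "polyline_self_clearance",
    "segment_pair_distances",
]


# ---------------------------------------------------------------------------
# mandrel


@dataclass(frozen=True)
class CrossCylinder:
    """Cross-axis cylinder: axial position and azimuth on the main cylinder."""

    axial_pos: float
    azimuth: float
    diameter: float

    @property
    def axis_dir(self) -> np.ndarray:
        return np.array([math.cos(self.azimuth), math.sin(self.azimuth), 0.0])

    @property
    def origin(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.axial_pos])


@dataclass(frozen=True)
class MandrelSpec:
    """Mandrel: main cylinder (diameter ``D3 − 1.5``) + cross cylinders (``D3``).

    The main cylinder axis is +z with its base at z = 0.
    """

    d3: float
    main_diameter: float
    main_length: float
    cross_cylinders: tuple[CrossCylinder, ...] = ()

    @property
    def main_radius(self) -> float:
        return self.main_diameter / 2.0


def build_mandrel(d3: float, k_cross: int = 2, spacing: float | None = None) -> MandrelSpec:
    """Construct a mandrel for pre-shape diameter ``d3`` (mm).

    ``k_cross`` cross cylinders are placed ``spacing`` apart axially
    (default ``1.2·d3``), azimuths advancing by 90° — the generalized stand-in
    for proprietary mandrel designs.
    """
    if d3 <= 1.5:
        raise ValueError(
            f"pre-shape diameter D3={d3} mm gives a non-positive main cylinder "
            "(main diameter = D3 - 1.5 mm)"
        )
    if k_cross < 0:
        raise ValueError("cross-cylinder count must be >= 0")
    if spacing is None:
        spacing = 1.2 * d3
    if k_cross > 0 and spacing <= d3:
        raise ValueError(
            f"cross cylinders of diameter {d3} overlap at spacing {spacing}; "
            "need spacing > D3"
        )
    cross = tuple(
        CrossCylinder(axial_pos=spacing * (i + 1), azimuth=(math.pi / 2.0) * i, diameter=d3)
        for i in range(k_cross)
    )
    main_length = spacing * (k_cross + 2)
    return MandrelSpec(
        d3=d3, main_diameter=d3 - 1.5, main_length=main_length, cross_cylinders=cross
    )


def mandrel_surface(mandrel: MandrelSpec, sections: int = 48) -> "object":
    """Mandrel surface as a trimesh mesh (concatenated cylinders), for export."""
    import trimesh

    parts = []
    main = trimesh.creation.cylinder(
        radius=mandrel.main_radius, height=mandrel.main_length, sections=sections
    )
    main.apply_translation([0.0, 0.0, mandrel.main_length / 2.0])
    parts.append(main)
    for c in mandrel.cross_cylinders:
        length = mandrel.main_diameter + 2.0 * c.diameter
        cyl = trimesh.creation.cylinder(radius=c.diameter / 2.0, height=length, sections=sections)
        rot = trimesh.geometry.align_vectors([0, 0, 1], c.axis_dir)
        cyl.apply_transform(rot)
        cyl.apply_translation(c.origin)
        parts.append(cyl)
    return trimesh.util.concatenate(parts)


# ---------------------------------------------------------------------------
# winding pattern


@dataclass(frozen=True)
class WrapSegment:
    """One wrap: ``target`` is "main" or a cross-cylinder index.

    For main segments ``pitch`` is the helix pitch (mm/turn); for cross
    segments it is the radial excursion amplitude of the out-and-back wrap.
    """

    target: str | int
    turns: float
    pitch: float
    handedness: int = 1  # +1 right-handed, -1 left-handed


@dataclass(frozen=True)
class WindingPattern:
    segments: tuple[WrapSegment, ...]
    samples_per_turn: int = 120

    def validate(self, mandrel: MandrelSpec, coil_d2: float) -> None:
        last_cross = -1
        for seg in self.segments:
            if seg.target == "main" and seg.pitch < coil_d2:
                raise ValueError(
                    f"pitch {seg.pitch} mm < coil diameter {coil_d2} mm: adjacent "
                    "loops of the inflated coil would interpenetrate"
                )
            if isinstance(seg.target, int):
                if not (0 <= seg.target < len(mandrel.cross_cylinders)):
                    raise ValueError(f"no cross cylinder {seg.target} on this mandrel")
                if seg.target <= last_cross:
                    raise ValueError("winding must visit cross cylinders in mandrel order")
                if abs(seg.turns - 0.5) > 1e-9:
                    raise ValueError(
                        "junction-connected cross wraps span exactly 0.5 turns "
                        "(bottom junction over the pin to the top junction)"
                    )
                last_cross = seg.target


def default_winding_pattern(mandrel: MandrelSpec, coil_d2: float) -> WindingPattern:
    """Default pattern: main-axis helix with one wrap per cross cylinder.

    A short 1.25-turn approach (so even short, truncated coils reach the
    first wrap), one half-turn pass over each cross cylinder (imprinting a
    loop feature of diameter D3), connecting main helices whose pitch is
    re-solved to land on the junction points, and a long tail for
    truncation.
    """
    pitch_main = max(3.5 * coil_d2, 1.0)
    amp = max(2.75 * coil_d2, 0.8)
    segs: list[WrapSegment] = [WrapSegment("main", turns=1.25, pitch=pitch_main)]
    handed = 1
    for i in range(len(mandrel.cross_cylinders)):
        handed = -handed
        segs.append(WrapSegment(i, turns=0.5, pitch=amp, handedness=handed))
        segs.append(WrapSegment("main", turns=1.0, pitch=pitch_main, handedness=handed))
    segs.append(WrapSegment("main", turns=6.0, pitch=pitch_main, handedness=handed))
    return WindingPattern(segments=tuple(segs))


# ---------------------------------------------------------------------------
# winding geometry


def _helix_on_main(radius, phi0, z0, turns, pitch, handed, n):
    t = np.linspace(0.0, 1.0, n)
    phi = phi0 + handed * 2.0 * math.pi * turns * t
    z = z0 + pitch * turns * t
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])


def _wrap_on_cross(mandrel, cross: CrossCylinder, amplitude, handed, n):
    """Half-turn pass over the cross-cylinder surface between junction points.

    Enters at the bottom junction (on both the main and cross surfaces) with
    an azimuthal tangent matching an incoming helix of handedness ``handed``,
    swings half a turn over the pin while excursing radially outward by
    ``amplitude`` and back, and exits at the top junction with the opposite
    handedness.  Every sample lies exactly on the cross-cylinder surface and
    the angular span never overlaps itself, so the pass cannot
    self-intersect.
    """
    rc = cross.diameter / 2.0
    rm = mandrel.main_radius
    a = cross.axis_dir
    ez = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(a, ez)
    t = np.linspace(0.0, 1.0, n)
    theta = math.pi + handed * math.pi * t
    s = rm + amplitude * np.sin(math.pi * t) ** 2
    return (
        cross.origin[None, :]
        + s[:, None] * a[None, :]
        + rc * (np.cos(theta)[:, None] * ez[None, :] + np.sin(theta)[:, None] * e2[None, :])
    )


def wind_on_mandrel(
    mandrel: MandrelSpec, pattern: WindingPattern, coil_d2: float
) -> np.ndarray:
    """Wind the pattern over the mandrel surface; returns a dense polyline (N,3).

    Every sample lies exactly on one of the cylinder surfaces.  Transitions
    happen at the junction points where the main and cross surfaces meet, so
    consecutive segments share endpoints with closely aligned tangents: the
    approach helix preceding each cross wrap is re-solved (fractional turns
    and pitch, never below the coil diameter) to land on the bottom junction
    of that cross cylinder.  Raises before generating geometry if the
    pattern would make the inflated coil self-intersect or cannot reach a
    junction.
    """
    pattern.validate(mandrel, coil_d2)
    rm = mandrel.main_radius
    segs = pattern.segments
    pieces: list[np.ndarray] = []
    handed = segs[0].handedness
    phi = z = None  # fixed once the first segment is placed

    for idx, seg in enumerate(segs):
        nxt = segs[idx + 1] if idx + 1 < len(segs) else None
        if seg.target == "main":
            turns, pitch = seg.turns, seg.pitch
            if isinstance(getattr(nxt, "target", None), int):
                cross = mandrel.cross_cylinders[nxt.target]
                phi_t = cross.azimuth
                z_t = cross.axial_pos - cross.diameter / 2.0
                if phi is None:
                    # first segment: place its start by working backwards
                    phi = phi_t - handed * 2.0 * math.pi * turns
                    z = z_t - pitch * turns
                    if z <= 0.1:
                        raise ValueError(
                            "first approach segment would start below the mandrel "
                            "base; reduce its turns or pitch"
                        )
                else:
                    dz = z_t - z
                    if dz <= 0:
                        raise ValueError(
                            f"cannot reach cross cylinder {nxt.target}: winding is "
                            f"already past its entry junction (z={z:.2f} > {z_t:.2f})"
                        )
                    frac = (handed * (phi_t - phi)) % (2.0 * math.pi) / (2.0 * math.pi)
                    k = max(0, math.ceil(dz / seg.pitch - frac - 1e-9))
                    turns = k + frac
                    if turns < 0.05:
                        turns += 1.0
                    pitch = dz / turns
                    if pitch < coil_d2:
                        raise ValueError(
                            f"approach to cross cylinder {nxt.target} needs pitch "
                            f"{pitch:.3f} mm < coil diameter {coil_d2} mm: the "
                            "inflated coil would self-intersect"
                        )
            elif phi is None:
                phi, z = 0.0, 1.0
            n = max(8, int(pattern.samples_per_turn * turns))
            pts = _helix_on_main(rm, phi, z, turns, pitch, handed, n)
            phi += handed * 2.0 * math.pi * turns
            z += pitch * turns
        else:
            cross = mandrel.cross_cylinders[seg.target]
            n = max(12, int(pattern.samples_per_turn * seg.turns))
            pts = _wrap_on_cross(mandrel, cross, seg.pitch, handed, n)
            handed = -handed
            phi = cross.azimuth
            z = cross.axial_pos + cross.diameter / 2.0
        pieces.append(pts)
    curve = np.vstack(pieces)
    keep = np.ones(len(curve), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(curve, axis=0), axis=1) > 1e-9
    return curve[keep]


# ---------------------------------------------------------------------------
# curve utilities


def arc_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _cumlen(points):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def truncate_to_length(points: np.ndarray, length: float) -> np.ndarray:
    """Truncate a polyline to arc length ``length``, keeping the start point."""
    s = _cumlen(points)
    total = s[-1]
    if total < length * (1.0 - 1e-9):
        raise ValueError(
            f"curve arc length {total:.4f} mm < requested coil length {length:.4f} mm; "
            "use a longer winding pattern"
        )
    if abs(total - length) <= 1e-9 * max(length, 1.0):
        return points.copy()
    i = int(np.searchsorted(s, length))
    frac = (length - s[i - 1]) / (s[i] - s[i - 1])
    end = points[i - 1] + frac * (points[i] - points[i - 1])
    return np.vstack([points[:i], end])


@dataclass(frozen=True)
class CoilCenterline:
    """Discretized coil centerline: nodes (mm) at equal arc-length spacing ``h``."""

    nodes: np.ndarray
    h: float
    length: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", arc_length(self.nodes))

    @property
    def element_count(self) -> int:
        return len(self.nodes) - 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"h_mm": self.h, "points_mm": self.nodes.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CoilCenterline":
        cfg = json.loads(Path(path).read_text())
        return cls(nodes=np.asarray(cfg["points_mm"], dtype=float), h=float(cfg["h_mm"]))

    def to_obj(self, path: str | Path) -> None:
        """Export the centerline as an OBJ polyline (line-set)."""
        lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in self.nodes]
        lines.append("l " + " ".join(str(i + 1) for i in range(len(self.nodes))))
        Path(path).write_text("\n".join(lines) + "\n")


def discretize(points: np.ndarray, h: float) -> CoilCenterline:
    """Resample a curve at equal arc-length intervals ``h``.

    Element count is ``ceil(l/h)``; every interval is ``h`` except possibly
    the last, which is shorter.
    """
    s = _cumlen(points)
    total = s[-1]
    if h <= 0:
        raise ValueError("element length must be positive")
    if h > total / 4.0:
        raise ValueError(f"element length {h} too large for curve of length {total:.3f}")
    n_el = int(math.ceil(total / h - 1e-9))
    stations = np.minimum(np.arange(n_el + 1) * h, total)
    stations[-1] = total
    nodes = np.empty((n_el + 1, 3))
    for d in range(3):
        nodes[:, d] = np.interp(stations, s, points[:, d])
    return CoilCenterline(nodes=nodes, h=h)


def parametric_preshape(
    d3: float, length: float, h: float = 0.2921, turns_tol: float = 1e-10
) -> CoilCenterline:
    """Spherical-spiral baseline pre-shape (the parametric-curve technique stand-in).

    The curve lies on a sphere of diameter ``d3``; its winding number is
    solved so the arc length equals ``length`` (to ~1e-6 relative), then the
    curve is discretized at spacing ``h``.  This family is a documented
    baseline, not a reproduction of any published parametric coil equations.
    """
    if d3 <= 0 or length <= 0:
        raise ValueError("d3 and length must be positive")
    r = d3 / 2.0
    t = np.linspace(1e-4, math.pi - 1e-4, 6000)

    def curve(nw):
        phi = nw * t
        x = r * np.sin(t) * np.cos(phi)
        y = r * np.sin(t) * np.sin(phi)
        z = r * np.cos(t)
        return np.column_stack([x, y, z])

    def len_err(nw):
        return arc_length(curve(nw)) - length

    lo = 0.0
    hi = max(2.0, 2.0 * length / (math.pi * r))
    while len_err(hi) < 0:
        hi *= 2.0
    if len_err(lo) > 0:
        raise ValueError(f"coil length {length} shorter than a single pole-to-pole arc")
    nw = brentq(len_err, lo, hi, xtol=turns_tol)
    return discretize(curve(nw), h)


# ---------------------------------------------------------------------------
# self-intersection audit

_PAIR_CACHE: dict = {}


def segment_pair_distances(points: np.ndarray, skip: int = 2):
    """Minimum distances between all non-adjacent segment pairs of a polyline.

    Returns the matrix of pair distances for pairs with index gap > ``skip``
    (adjacent segments always touch at shared nodes).  O(n²) — intended for
    audits, not per-step contact.
    """
    p0 = points[:-1]
    d = points[1:] - p0
    n = len(p0)
    key = (n, skip)
    if key not in _PAIR_CACHE:
        _PAIR_CACHE[key] = np.triu_indices(n, k=skip + 1)
    i, j = _PAIR_CACHE[key]
    # Closest points between segments i and j (standard clamped quadratic).
    a = np.einsum("ij,ij->i", d[i], d[i])
    b = np.einsum("ij,ij->i", d[i], d[j])
    c = np.einsum("ij,ij->i", d[j], d[j])
    w0 = p0[i] - p0[j]
    dd = np.einsum("ij,ij->i", d[i], w0)
    e = np.einsum("ij,ij->i", d[j], w0)
    denom = a * c - b * b
    s = np.where(denom > 1e-18, (b * e - c * dd) / np.where(denom > 1e-18, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    tpar = np.where(c > 1e-18, (e + s * b) / np.where(c > 1e-18, c, 1.0), 0.0)
    tpar = np.clip(tpar, 0.0, 1.0)
    # re-clamp s for the clamped t
    s = np.where(a > 1e-18, np.clip((b * tpar - dd) / np.where(a > 1e-18, a, 1.0), 0.0, 1.0), s)
    diff = w0 + s[:, None] * d[i] - tpar[:, None] * d[j]
    return i, j, np.linalg.norm(diff, axis=1)


def polyline_self_clearance(points: np.ndarray, skip: int = 2) -> float:
    """Smallest distance between non-adjacent segments of a polyline."""
    _, _, dist = segment_pair_distances(points, skip=skip)
    return float(dist.min()) if len(dist) else math.inf
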