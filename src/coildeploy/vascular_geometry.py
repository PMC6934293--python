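"""Vessel/aneurysm geometry: STL I/O, synthetic cases, catheter tubes, neck cover.

Coordinates are mm, right-handed; surfaces carry outward normals and
containment means strictly inside.  Patient geometry is accepted as STL plus
a centerline polyline; centerline *computation* from arbitrary surfaces is
out of scope — synthetic cases carry analytic centerlines.

The synthetic generator builds idealized aneurysm cases without any mesh
boolean engine: a *sidewall* case is a spherical sac trimmed exactly along
its intersection curve with the parent-tube surface (found by per-azimuth
root solving), and a *terminal* case is a sac capping the end of the tube
with a planar circular orifice.  The sac surface plus the neck cover forms a
closed watertight region, so point containment can be answered both
analytically and by ray parity on the mesh.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq

__all__ = [
    "read_stl",
    "write_stl",
    "sweep_tube",
    "Centerline",
    "CatheterTube",
    "AneurysmCase",
    "build_catheter",
    "neck_cover",
    "make_synthetic_aneurysm",
    "ray_parity_contains",
    "closest_point_on_mesh",
]


def ray_parity_contains(mesh: "trimesh.Trimesh", points: np.ndarray,
                        direction: np.ndarray | None = None) -> np.ndarray:
    """Point-in-watertight-mesh by ray-crossing parity (brute force).

    Casts one ray per point against *every* triangle (Möller–Trumbore,
    vectorized and chunked) and counts crossings; an odd count means inside.
    The default ray direction is deliberately irrational-ish to avoid
    edge-grazing degeneracies.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if direction is None:
        direction = np.array([0.577350, 0.211325, 0.788675])
    d = direction / np.linalg.norm(direction)
    tri = mesh.triangles  # (F,3,3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)  # (F,3)
    det = np.einsum("fj,fj->f", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    counts = np.zeros(len(points), dtype=np.int64)
    chunk = max(1, int(2e6 // max(len(tri), 1)))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        tvec = p[:, None, :] - v0[None, :, :]           # (P,F,3)
        u = np.einsum("pfj,fj->pf", tvec, pvec) * inv
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("pfj,j->pf", qvec, d) * inv
        t = np.einsum("pfj,fj->pf", qvec, e2) * inv
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        counts[lo:lo + chunk] = hit.sum(axis=1)
    return counts % 2 == 1


def closest_point_on_mesh(mesh: "trimesh.Trimesh", points: np.ndarray):
    """Closest point and distance from each query point to a triangle mesh.

    Brute-force vectorized point–triangle projection over all faces
    (region-based closest point on triangle); adequate for the moderate mesh
    sizes this package produces.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, bc = b - a, c - a, c - b
    best_d2 = np.full(len(points), np.inf)
    best_pt = np.zeros_like(points)
    chunk = max(1, int(1e6 // max(len(tri), 1)))
    eps = 1e-18
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk][:, None, :]            # (P,1,3)
        ap = p - a[None, :, :]
        bp = p - b[None, :, :]
        cp = p - c[None, :, :]
        d1 = np.einsum("pfj,fj->pf", ap, ab)
        d2_ = np.einsum("pfj,fj->pf", ap, ac)
        d3 = np.einsum("pfj,fj->pf", bp, ab)
        d4 = np.einsum("pfj,fj->pf", bp, ac)
        d5 = np.einsum("pfj,fj->pf", cp, ab)
        d6 = np.einsum("pfj,fj->pf", cp, ac)
        vc = d1 * d4 - d3 * d2_
        vb = d5 * d2_ - d1 * d6
        va = d3 * d6 - d5 * d4
        # interior barycentric solution (overwritten by edge/vertex regions)
        denom = va + vb + vc
        denom = np.where(np.abs(denom) > eps, denom, eps)
        v = vb / denom
        w = vc / denom
        # region BC
        m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        t_bc = (d4 - d3) / np.maximum((d4 - d3) + (d5 - d6), eps)
        v = np.where(m, 1.0 - t_bc, v)
        w = np.where(m, t_bc, w)
        # region AC
        m = (vb <= 0) & (d2_ >= 0) & (d6 <= 0)
        w = np.where(m, d2_ / np.maximum(d2_ - d6, eps), w)
        v = np.where(m, 0.0, v)
        # region AB
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        v = np.where(m, d1 / np.maximum(d1 - d3, eps), v)
        w = np.where(m, 0.0, w)
        # vertex regions
        m = (d6 >= 0) & (d5 <= d6)
        v = np.where(m, 0.0, v)
        w = np.where(m, 1.0, w)
        m = (d3 >= 0) & (d4 <= d3)
        v = np.where(m, 1.0, v)
        w = np.where(m, 0.0, w)
        m = (d1 <= 0) & (d2_ <= 0)
        v = np.where(m, 0.0, v)
        w = np.where(m, 0.0, w)
        cand = a[None, :, :] + v[..., None] * ab[None, :, :] + w[..., None] * ac[None, :, :]
        d2min = np.sum((p - cand) ** 2, axis=2)
        j = np.argmin(d2min, axis=1)
        idx = np.arange(len(d2min))
        sel = d2min[idx, j]
        upd = sel < best_d2[lo:lo + chunk]
        best_d2[lo:lo + chunk][upd] = sel[upd]
        best_pt[lo:lo + chunk][upd] = cand[idx, j][upd]
    return best_pt, np.sqrt(best_d2)


# ---------------------------------------------------------------------------
# STL I/O (binary + ASCII dialects via trimesh)


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Load an STL surface (binary or ASCII) as a triangle mesh."""
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: no triangles parsed from STL")
    return mesh


def write_stl(mesh: trimesh.Trimesh, path: str | Path, ascii: bool = False) -> None:
    """Write a triangle mesh as STL; ``ascii=True`` selects the text dialect."""
    path = Path(path)
    if ascii:
        data = trimesh.exchange.stl.export_stl_ascii(mesh)
        path.write_text(data)
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))


# ---------------------------------------------------------------------------
# centerlines


@dataclass
class Centerline:
    """Ordered polyline (mm) with the orifice truncation point marked.

    ``orifice_index`` is the index of the point at the aneurysm orifice
    (default: the last point — the centerline is already truncated).
    """

    points: np.ndarray
    orifice_index: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.orifice_index < 0:
            self.orifice_index = len(self.points) - 1
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arc length must be strictly increasing")
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_length(self) -> float:
        return float(self._cum[-1])

    @property
    def cumulative(self) -> np.ndarray:
        return self._cum

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, self._cum, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.arc_length)
        out = np.empty(np.shape(s) + (3,))
        for d in range(3):
            out[..., d] = np.interp(s, self._cum, self.points[:, d])
        return out

    def min_curvature_radius(self) -> float:
        p = self.points
        if len(p) < 3:
            return math.inf
        a, b, c = p[:-2], p[1:-1], p[2:]
        ab, cb, ca = b - a, b - c, a - c
        cross = np.linalg.norm(np.cross(ab, -cb), axis=1)
        denom = np.where(cross > 1e-14, cross, 1.0)
        r = (
            np.linalg.norm(ab, axis=1)
            * np.linalg.norm(cb, axis=1)
            * np.linalg.norm(ca, axis=1)
        ) / (2.0 * denom)
        r[cross <= 1e-14] = math.inf
        return float(r.min())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"points_mm": self.points.tolist(), "orifice_index": int(self.orifice_index)}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Centerline":
        cfg = json.loads(Path(path).read_text())
        return cls(np.asarray(cfg["points_mm"], dtype=float), int(cfg["orifice_index"]))


# ---------------------------------------------------------------------------
# swept tubes


def _transport_frames(points: np.ndarray):
    """Parallel-transport orthonormal frames (n1, n2) along a polyline."""
    t = np.gradient(points, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n1 = np.empty_like(t)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1[0] = np.cross(t[0], ref)
    n1[0] /= np.linalg.norm(n1[0])
    for i in range(1, len(t)):
        v = n1[i - 1] - (n1[i - 1] @ t[i]) * t[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(t, n1)
    return t, n1, n2


def sweep_tube(
    points: np.ndarray, radius: float, sections: int = 24, cap: bool = True
) -> trimesh.Trimesh:
    """Sweep a circle of ``radius`` along a polyline into a closed tube mesh."""
    points = np.asarray(points, dtype=float)
    _, n1, n2 = _transport_frames(points)
    ang = np.linspace(0.0, 2.0 * math.pi, sections, endpoint=False)
    ca, sa = np.cos(ang), np.sin(ang)
    rings = (
        points[:, None, :]
        + radius * (ca[None, :, None] * n1[:, None, :] + sa[None, :, None] * n2[:, None, :])
    )
    nv = len(points)
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(nv - 1):
        for j in range(sections):
            a = i * sections + j
            b = i * sections + (j + 1) % sections
            c = (i + 1) * sections + j
            d = (i + 1) * sections + (j + 1) % sections
            faces.append([a, b, d])
            faces.append([a, d, c])
    if cap:
        c0 = len(verts)
        verts = np.vstack([verts, points[0], points[-1]])
        for j in range(sections):
            faces.append([c0, (j + 1) % sections, j])
            base = (nv - 1) * sections
            faces.append([c0 + 1, base + j, base + (j + 1) % sections])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    return mesh


# ---------------------------------------------------------------------------
# catheter


@dataclass
class CatheterTube:
    """Swept catheter: inner radius = coil ``D2`` (twice the coil radius).

    ``path`` is the full driving path (proximal straight extension followed by
    the truncated vessel centerline); ``tube_start_s`` is the arc position
    where the physical tube begins (0.0: the extension is part of the tube).
    """

    path: Centerline
    inner_radius: float
    proximal_extension: float
    surface: trimesh.Trimesh = field(repr=False)

    @property
    def length(self) -> float:
        return self.path.arc_length


def build_catheter(
    centerline: Centerline, coil_d2: float, coil_length: float, sections: int = 24
) -> CatheterTube:
    """Build the swept catheter tube for a coil of secondary diameter ``coil_d2``.

    The cylindrical inner radius is ``coil_d2`` (= 2 × coil radius); the tube
    is truncated at the orifice end of ``centerline`` and extended proximally
    by a straight segment of length ``coil_length`` along the inlet tangent.
    """
    inner_radius = coil_d2
    rmin = centerline.min_curvature_radius()
    if rmin <= inner_radius:
        # locate the offending position for the error message
        p = centerline.points
        s = centerline.cumulative
        a, b, c = p[:-2], p[1:-1], p[2:]
        cross = np.linalg.norm(np.cross(b - a, b - c), axis=1)
        denom = np.where(cross > 1e-14, cross, 1.0)
        r = (
            np.linalg.norm(b - a, axis=1)
            * np.linalg.norm(b - c, axis=1)
            * np.linalg.norm(a - c, axis=1)
        ) / (2.0 * denom)
        r[cross <= 1e-14] = math.inf
        bad = int(np.argmin(r))
        raise ValueError(
            f"centerline curvature radius {rmin:.3f} mm <= catheter radius "
            f"{inner_radius:.3f} mm at arc length {s[bad + 1]:.2f} mm"
        )
    t0 = centerline.tangents()[0]
    n_ext = max(2, int(math.ceil(coil_length / 1.0)))
    ext = centerline.points[0] - t0 * np.linspace(coil_length, 0.0, n_ext + 1)[:, None]
    pts = np.vstack([ext[:-1], centerline.points])
    path = Centerline(pts)
    surface = sweep_tube(pts, inner_radius, sections=sections, cap=False)
    return CatheterTube(
        path=path,
        inner_radius=inner_radius,
        proximal_extension=coil_length,
        surface=surface,
    )


# ---------------------------------------------------------------------------
# neck cover


def neck_cover(contour: np.ndarray, toward: np.ndarray | None = None) -> trimesh.Trimesh:
    """Triangulate a surface across a closed orifice contour (centroid fan).

    ``toward``: a point (e.g. the sac centroid) the surface normals are
    oriented to face.  The contour must be closed (first ≈ last point or
    treated as a loop).
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("orifice contour must have at least 3 points")
    if np.linalg.norm(contour[0] - contour[-1]) < 1e-9:
        contour = contour[:-1]
    span = np.linalg.norm(contour - contour.mean(axis=0), axis=1).max()
    gaps = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1)
    if gaps.max() > 0.8 * span:
        raise ValueError("orifice contour is not closed")
    center = contour.mean(axis=0)
    n = len(contour)
    verts = np.vstack([contour, center])
    faces = np.array([[i, (i + 1) % n, n] for i in range(n)])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if toward is not None:
        normal = mesh.face_normals.mean(axis=0)
        if normal @ (np.asarray(toward) - center) < 0:
            mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# synthetic aneurysm cases


@dataclass
class AneurysmCase:
    """Sac + parent artery + orifice + neck cover + centerline.

    For synthetic cases the sac is analytically a sphere (``sac_center``,
    ``sac_radius``) and containment queries have closed forms; imported cases
    fall back to mesh ray queries.
    """

    sac: trimesh.Trimesh = field(repr=False)
    parent_artery: trimesh.Trimesh = field(repr=False)
    orifice_contour: np.ndarray = field(repr=False)
    neck_cover: trimesh.Trimesh = field(repr=False)
    centerline: Centerline = field(repr=False)
    provenance: str = "synthetic"
    sac_center: np.ndarray | None = None
    sac_radius: float | None = None
    vessel_radius: float | None = None
    kind: str = "sidewall"

    def sac_closed(self) -> trimesh.Trimesh:
        """Watertight closed region: sac surface + neck cover (shared boundary)."""
        mesh = trimesh.util.concatenate([self.sac, self.neck_cover])
        mesh.merge_vertices()
        mesh.fix_normals()
        return mesh

    def inside_sac(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Strictly-inside test for the (spherical) sac region, with tolerance band."""
        points = np.atleast_2d(points)
        if self.sac_center is None or self.sac_radius is None:
            return ray_parity_contains(self.sac_closed(), points)
        return np.linalg.norm(points - self.sac_center, axis=1) < self.sac_radius + tol

    def dome_apex(self) -> np.ndarray:
        """The sac point farthest from the orifice center (dome apex)."""
        oc = self.orifice_contour.mean(axis=0)
        if self.sac_center is not None:
            axis = self.sac_center - oc
            axis /= np.linalg.norm(axis)
            return self.sac_center + self.sac_radius * axis
        verts = self.sac.vertices
        return verts[np.argmax(np.linalg.norm(verts - oc, axis=1))]


def _trimmed_sphere(center, radius, psi_star, n_rings=24, n_az=48, pole_axis=None):
    """UV sphere about ``center`` meshed from the apex down to ψ*(φ).

    ``psi_star(phi)`` gives the polar trim angle per azimuth; ``pole_axis``
    is the apex direction (default +z).  Returns (mesh, boundary ring).
    """
    if pole_axis is None:
        pole_axis = np.array([0.0, 0.0, 1.0])
    pole_axis = pole_axis / np.linalg.norm(pole_axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ pole_axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ pole_axis) * pole_axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole_axis, e1)

    phis = np.linspace(0.0, 2.0 * math.pi, n_az, endpoint=False)
    psis = np.array([psi_star(p) for p in phis])
    verts = [center + radius * pole_axis]
    for k in range(1, n_rings + 1):
        u = k / n_rings
        psi = u * psis
        dirs = (
            np.cos(psi)[:, None] * pole_axis[None, :]
            + np.sin(psi)[:, None] * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
        )
        verts.append(center + radius * dirs)
    apex = 0
    ring0 = 1
    faces = []
    for j in range(n_az):
        faces.append([apex, ring0 + j, ring0 + (j + 1) % n_az])
    for k in range(n_rings - 1):
        a0 = 1 + k * n_az
        b0 = 1 + (k + 1) * n_az
        for j in range(n_az):
            j1 = (j + 1) % n_az
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    vv = np.vstack([verts[0][None, :]] + verts[1:])
    mesh = trimesh.Trimesh(vertices=vv, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    boundary = vv[1 + (n_rings - 1) * n_az :]
    return mesh, boundary


def make_synthetic_aneurysm(
    sac_diameter: float,
    vessel_diameter: float,
    vessel_path: str | tuple = "straight",
    kind: str = "sidewall",
    vessel_length: float = 40.0,
    neck_dip_fraction: float = 0.3,
    n_az: int = 48,
) -> AneurysmCase:
    """Idealized aneurysm: spherical sac on (sidewall) or at the end of
    (terminal) a tubular parent artery, with analytic centerline.

    ``neck_dip_fraction`` controls how deep the sidewall sac dips into the
    tube surface (fraction of the sac radius), which sets the orifice width.
    """
    if sac_diameter <= vessel_diameter:
        raise ValueError("sac diameter must exceed vessel diameter")
    rs = sac_diameter / 2.0
    rv = vessel_diameter / 2.0

    if kind == "sidewall":
        if vessel_path != "straight":
            raise NotImplementedError(
                "sidewall cases are generated on straight vessels; curved paths "
                "are supported for terminal cases and for catheter centerlines"
            )
        zc = rv + rs - neck_dip_fraction * rs
        center = np.array([0.0, 0.0, zc])

        def rho_sq(psi, phi):  # radial distance to the x-axis, squared
            y = rs * math.sin(psi) * math.sin(phi)
            z = zc + rs * math.cos(psi)
            return y * y + z * z

        def psi_star(phi):
            f = lambda psi: rho_sq(psi, phi) - rv * rv
            return brentq(f, 1e-6, math.pi - 1e-6)

        sac, boundary = _trimmed_sphere(center, rs, psi_star, n_az=n_az)
        # rotate ring so it starts deterministically; contour = boundary ring
        contour = boundary
        cover = neck_cover(contour, toward=center)
        axis_pts = np.column_stack(
            [
                np.linspace(-vessel_length, vessel_length / 2.0, 60),
                np.zeros(60),
                np.zeros(60),
            ]
        )
        vessel = sweep_tube(axis_pts, rv, sections=max(24, n_az // 2))
        # catheter path: along the axis, then a quadratic-Bezier bend up
        # through the orifice so the tip points into the sac
        x_bend = max(2.0 * rs, 3.0)
        tip = np.array([0.0, 0.0, rv + 0.35 * rs])
        p0 = np.array([-x_bend, 0.0, 0.0])
        ctrl = np.array([0.0, 0.0, 0.0])
        t = np.linspace(0.0, 1.0, 40)[:, None]
        bez = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * tip
        axis_up = np.column_stack(
            [
                np.linspace(-vessel_length, -x_bend, 40, endpoint=False),
                np.zeros(40),
                np.zeros(40),
            ]
        )
        cl = Centerline(np.vstack([axis_up, bez]))
        return AneurysmCase(
            sac=sac,
            parent_artery=vessel,
            orifice_contour=contour,
            neck_cover=cover,
            centerline=cl,
            sac_center=center,
            sac_radius=rs,
            vessel_radius=rv,
            kind="sidewall",
        )

    if kind == "terminal":
        # vessel ends at the sac; planar circular orifice of radius rv
        if vessel_path == "straight":
            s = np.linspace(0.0, 1.0, 60)
            base = np.column_stack([-vessel_length * (1 - s), np.zeros(60), np.zeros(60)])
        elif isinstance(vessel_path, tuple) and vessel_path[0] == "planar-arc":
            ra = float(vessel_path[1])
            ang = vessel_length / ra
            th = np.linspace(-ang, 0.0, 60)
            base = np.column_stack(
                [ra * np.sin(th), np.zeros(60), ra * (1.0 - np.cos(th))]
            )
        else:
            raise ValueError(f"unknown vessel path {vessel_path!r}")
        tangent = base[-1] - base[-2]
        tangent /= np.linalg.norm(tangent)
        x_off = math.sqrt(rs * rs - rv * rv)
        center = base[-1] + tangent * x_off
        psi_max = math.pi - math.asin(rv / rs)

        sac, boundary = _trimmed_sphere(
            center, rs, lambda phi: psi_max, pole_axis=tangent, n_az=n_az
        )
        contour = boundary
        cover = neck_cover(contour, toward=center)
        vessel = sweep_tube(base, rv, sections=max(24, n_az // 2))
        cl = Centerline(base)
        return AneurysmCase(
            sac=sac,
            parent_artery=vessel,
            orifice_contour=contour,
            neck_cover=cover,
            centerline=cl,
            sac_center=center,
            sac_radius=rs,
            vessel_radius=rv,
            kind="terminal",
        )

    raise ValueError(f"unknown aneurysm kind {kind!r}")
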