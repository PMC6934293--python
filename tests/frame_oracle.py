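"""Independent 3D space-frame direct-stiffness solver (test oracle).

A classical linear Euler-Bernoulli frame: 6 DOF per node, 12x12 element
stiffness assembled in global coordinates and solved with a dense/sparse
linear solve.  Used to brute-force the axial stiffness of a discretized
helical spring, independently of any closed-form spring formula in the
package under test.
"""

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve


def beam_stiffness_local(E, G, A, Iy, Iz, J, L):
    """12x12 Euler-Bernoulli 3D beam element stiffness (local axes, x axial)."""
    k = np.zeros((12, 12))
    EA_L = E * A / L
    GJ_L = G * J / L
    # axial
    k[0, 0] = k[6, 6] = EA_L
    k[0, 6] = k[6, 0] = -EA_L
    # torsion
    k[3, 3] = k[9, 9] = GJ_L
    k[3, 9] = k[9, 3] = -GJ_L
    # bending about z (displacement y, rotation rz: dofs 1,5,7,11)
    for (iz, dy, rz1, dy2, rz2) in ((Iz, 1, 5, 7, 11), (Iy, 2, 4, 8, 10)):
        c = E * iz / L**3
        sgn = 1.0 if dy == 1 else -1.0  # sign convention flips for xz plane
        k[dy, dy] += 12 * c
        k[dy2, dy2] += 12 * c
        k[dy, dy2] += -12 * c
        k[dy2, dy] += -12 * c
        k[rz1, rz1] += 4 * c * L**2
        k[rz2, rz2] += 4 * c * L**2
        k[rz1, rz2] += 2 * c * L**2
        k[rz2, rz1] += 2 * c * L**2
        for (d, r) in ((dy, rz1), (dy, rz2)):
            k[d, r] += sgn * 6 * c * L
            k[r, d] += sgn * 6 * c * L
        for (d, r) in ((dy2, rz1), (dy2, rz2)):
            k[d, r] += -sgn * 6 * c * L
            k[r, d] += -sgn * 6 * c * L
    return k


def _element_rotation(p0, p1):
    ex = p1 - p0
    L = np.linalg.norm(ex)
    ex = ex / L
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez]), L


def solve_frame(nodes, elements, E, G, A, Iy, Iz, J, fixed_nodes, loads):
    """Solve K u = f for a 3D frame; returns nodal displacement array (N,6).

    ``elements``: (i, j) node index pairs; ``fixed_nodes``: fully clamped
    node indices; ``loads``: dict node -> 6-vector (Fx..Mz).
    """
    n = len(nodes)
    K = lil_matrix((6 * n, 6 * n))
    for (i, j) in elements:
        R, L = _element_rotation(nodes[i], nodes[j])
        kl = beam_stiffness_local(E, G, A, Iy, Iz, J, L)
        T = np.zeros((12, 12))
        for b in range(4):
            T[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = R
        kg = T.T @ kl @ T
        dofs = np.r_[6 * i : 6 * i + 6, 6 * j : 6 * j + 6]
        K[np.ix_(dofs, dofs)] += kg
    f = np.zeros(6 * n)
    for node, load in loads.items():
        f[6 * node : 6 * node + 6] = load
    free = np.ones(6 * n, dtype=bool)
    for node in fixed_nodes:
        free[6 * node : 6 * node + 6] = False
    Kff = K.tocsr()[free][:, free]
    u = np.zeros(6 * n)
    u[free] = spsolve(Kff.tocsc(), f[free])
    return u.reshape(n, 6)


def helix_axial_stiffness(d_wire, d_mean, n_turns, pitch, E, G,
                          segs_per_turn=40, force=1e-6):
    """Axial stiffness (N/mm) of a discretized helical spring, one end clamped.

    The wire centerline lies on the mean helix (diameter ``d_mean``); the
    wire is a solid circular section of diameter ``d_wire``.  A small axial
    force is applied at the free end and the stiffness is force over the
    axial tip displacement.
    """
    n_seg = int(n_turns * segs_per_turn)
    t = np.linspace(0.0, 2.0 * np.pi * n_turns, n_seg + 1)
    r = d_mean / 2.0
    nodes = np.column_stack([r * np.cos(t), r * np.sin(t),
                             pitch * t / (2.0 * np.pi)])
    elements = [(i, i + 1) for i in range(n_seg)]
    A = np.pi / 4.0 * d_wire**2
    I = np.pi / 64.0 * d_wire**4
    # axial load acting along the helix axis: statically equivalent force +
    # moment at the end node (which sits at radius r off the axis)
    p_end = nodes[-1]
    arm = np.array([-p_end[0], -p_end[1], 0.0])
    F = np.array([0.0, 0.0, force])
    M = np.cross(arm, F)
    u = solve_frame(nodes, elements, E, G, A, I, I, 2 * I,
                    fixed_nodes=[0], loads={n_seg: np.r_[F, M]})
    dz = u[n_seg, 2]
    return force / dz
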