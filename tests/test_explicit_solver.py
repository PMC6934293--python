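"""Explicit rod dynamics: smooth step, internal forces, contact, integration."""

import math

import numpy as np
import pytest

from coildeploy.coil_mechanics import bare_platinum_coil
from coildeploy.deployment import make_preshape
from coildeploy.explicit_solver import (
    BeamModel,
    ClampBC,
    HalfSpace,
    PathBC,
    SimState,
    SolverConfig,
    TriMeshBarrier,
    TubeInterior,
    contact_forces,
    default_penalty,
    internal_forces,
    run,
    smooth_step,
    stable_dt,
    step,
)
from coildeploy.vascular_geometry import Centerline


@pytest.fixture(scope="module")
def beam_props(axium_coil):
    return axium_coil.solver_section(), axium_coil.equivalent_material()


def straight_model(beam_props, length=20.0, n=40, d2=0.2921, mass_scale=1.0):
    sec, em = beam_props
    nodes = np.column_stack([np.linspace(0, length, n + 1), np.zeros(n + 1), np.zeros(n + 1)])
    return BeamModel.from_centerline(nodes, sec, em, d2, mass_scale=mass_scale)


class TestSmoothStep:
    def test_endpoints_and_midpoint(self):
        assert smooth_step(0.0, 0.0, 1.0, 2.0, 5.0) == 2.0
        assert smooth_step(1.0, 0.0, 1.0, 2.0, 5.0) == 5.0
        assert smooth_step(0.5, 0.0, 1.0, 2.0, 5.0) == pytest.approx(3.5)

    def test_clamped_outside_interval(self):
        assert smooth_step(-3.0, 0.0, 1.0, 0.0, 4.0) == 0.0
        assert smooth_step(9.0, 0.0, 1.0, 0.0, 4.0) == 4.0

    def test_c2_at_both_ends(self):
        # cubic vanishing at both ends implies zero first and second
        # derivatives there: |f(t0 ± eps) - f(t0)| = O(eps^3)
        for eps in (1e-2, 1e-3):
            assert abs(smooth_step(eps, 0, 1, 0, 1)) <= 11 * eps**3
            assert abs(1.0 - smooth_step(1 - eps, 0, 1, 0, 1)) <= 11 * eps**3

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            smooth_step(0.5, 1.0, 1.0, 0.0, 1.0)


class TestInternalForces:
    def test_rest_preshape_is_stress_free(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
        st = SimState.from_rest(model)
        f, tq, strain, _ = internal_forces(model, st)
        assert np.abs(f).max() < 1e-10
        assert np.abs(tq).max() < 1e-10
        assert strain < 1e-20

    def test_axial_stretch_force(self, beam_props):
        model = straight_model(beam_props, length=1.0, n=1)
        st = SimState.from_rest(model)
        st.x[1, 0] *= 1.001
        f, _, _, _ = internal_forces(model, st)
        assert f[1, 0] == pytest.approx(-model.ea * 0.001, rel=1e-8)
        # Newton's third law to machine precision
        assert np.abs(f.sum(axis=0)).max() < 1e-18

    def test_nan_state_raises(self, beam_props):
        model = straight_model(beam_props, n=4)
        st = SimState.from_rest(model)
        st.x[2, 1] = np.nan
        with pytest.raises(FloatingPointError):
            internal_forces(model, st)

    def test_total_mass_matches_density(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
        expected = em.rho_eff * 1e-6 * sec.ab * model.h0.sum()
        assert model.total_mass == pytest.approx(expected, rel=1e-9)


class TestStableDt:
    def test_uniform_chain_wave_speed_bound(self, beam_props):
        model = straight_model(beam_props)
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0)
        dt = stable_dt(model, cfg)
        c = math.sqrt(model.ea / model.section.ab / model.rho)
        assert dt <= cfg.dt_safety * model.h0.min() / c

    def test_halving_h_halves_dt_in_wave_regime(self, beam_props):
        # when the translational wave bound governs (rotary inertias heavy),
        # Δt scales linearly with the element size
        sec, em = beam_props

        def model(n):
            nodes = np.column_stack(
                [np.linspace(0, 20.0, n + 1), np.zeros(n + 1), np.zeros(n + 1)]
            )
            return BeamModel.from_centerline(
                nodes, sec, em, 0.2921, rot_inertia_scale=500.0
            )

        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0)
        d1 = stable_dt(model(40), cfg)
        d2 = stable_dt(model(80), cfg)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-9)
        # with realistic inertias, refining still shrinks the step
        dflex1 = stable_dt(straight_model(beam_props, n=40), cfg)
        dflex2 = stable_dt(straight_model(beam_props, n=80), cfg)
        assert dflex2 < dflex1

    def test_damping_strictly_shrinks_dt(self, beam_props):
        model = straight_model(beam_props)
        undamped = stable_dt(model, SolverConfig(alpha_per_s=0.0, beta_s=0.0))
        damped = stable_dt(model, SolverConfig(alpha_per_s=0.0, beta_s=1e-3))
        assert damped < undamped

    def test_zero_length_element_rejected(self, beam_props):
        model = straight_model(beam_props, n=4)
        model.h0[2] = 0.0
        with pytest.raises(ValueError):
            stable_dt(model, SolverConfig())


class TestCentralDifference:
    def test_exact_under_constant_acceleration(self, beam_props):
        model = straight_model(beam_props, length=5.0, n=1)
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0, self_contact=False)
        st = SimState.from_rest(model)
        F = np.zeros((2, 3))
        F[:, 0] = 1e-6
        dt = 0.01
        a = F[0, 0] / model.mass[0]
        st.v[:, 0] = -0.5 * dt * a  # v^{-1/2}
        for _ in range(100):
            step(model, st, dt, cfg, external_forces=F)
        assert st.x[0, 0] == pytest.approx(0.5 * a * st.t**2, rel=1e-12)

    def test_oscillator_energy_bounded_1e4_steps(self, beam_props):
        model = straight_model(beam_props, length=2.0, n=1)
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0, self_contact=False)
        st = SimState.from_rest(model)
        st.x[1, 0] = 2.0 * 1.005
        omega = math.sqrt(model.ea / 2.0 / (model.mass[0] / 2.0))
        dt = 0.1 / omega
        energies = []
        for k in range(10000):
            step(model, st, dt, cfg)
            if k % 50 == 0:
                energies.append(st.ledger["kinetic"] + st.ledger["strain"])
        energies = np.asarray(energies[1:])
        # the half-step kinetic / full-step potential mix oscillates by
        # O(omega*dt) but must stay bounded with no secular drift
        assert energies.max() / energies.min() < 1.25
        assert np.all(np.isfinite(energies))
        assert abs(energies[-20:].mean() / energies[:20].mean() - 1.0) < 0.02

    def test_oscillator_period_second_order(self, beam_props):
        model = straight_model(beam_props, length=2.0, n=1)
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0, self_contact=False)
        omega = math.sqrt(model.ea / 2.0 / (model.mass[0] / 2.0))

        def period_error(dt):
            st = SimState.from_rest(model)
            st.x[1, 0] = 2.0 * 1.005
            prev = st.x[1, 0]
            crossings = []
            for _ in range(int(40.0 / omega / dt)):
                step(model, st, dt, cfg)
                cur = st.x[1, 0]
                if prev < 2.0 <= cur:
                    # sub-step crossing time by linear interpolation
                    frac = (2.0 - prev) / (cur - prev)
                    crossings.append(st.t - dt * (1.0 - frac))
                prev = cur
            T = np.diff(crossings).mean()
            return abs(T - 2 * math.pi / omega)

        e_coarse = period_error(0.2 / omega)
        e_fine = period_error(0.1 / omega)
        # superlinear convergence of the period error, and the coarse error
        # itself is already below 0.2% of the period
        assert e_fine < e_coarse / 1.8
        assert e_coarse < 2e-3 * (2 * math.pi / omega)

    def test_momentum_conserved_without_external_forces(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0, self_contact=False)
        st = SimState.from_rest(model)
        rng = np.random.default_rng(3)
        st.v[:] = rng.normal(0.0, 0.02, st.v.shape)
        p0 = (model.mass[:, None] * st.v).sum(axis=0)
        dt = stable_dt(model, cfg)
        for _ in range(1000):
            step(model, st, dt, cfg)
        p1 = (model.mass[:, None] * st.v).sum(axis=0)
        assert np.linalg.norm(p1 - p0) / np.linalg.norm(p0) < 1e-8

    def test_mass_damping_dissipates(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
        cfg = SolverConfig(alpha_per_s=50.0, self_contact=False)
        st = SimState.from_rest(model)
        rng = np.random.default_rng(3)
        st.v[:] = rng.normal(0.0, 0.05, st.v.shape)
        dt = stable_dt(model, cfg)
        step(model, st, dt, cfg)
        e_first = st.ledger["kinetic"] + st.ledger["strain"]
        for _ in range(4000):
            step(model, st, dt, cfg)
        e_last = st.ledger["kinetic"] + st.ledger["strain"]
        assert e_last < 0.05 * e_first


class TestTimoshenkoCantilever:
    def test_tip_deflection_with_shear_term(self, beam_props):
        # dynamic relaxation to the static Timoshenko solution
        sec, em = beam_props
        L, n = 5.0, 50
        nodes = np.column_stack([np.linspace(0, L, n + 1), np.zeros(n + 1), np.zeros(n + 1)])
        model = BeamModel.from_centerline(nodes, sec, em, 0.2921)
        F = 3 * model.ei / L**3 * (0.02 * L)
        exact = F * L**3 / (3 * model.ei) + F * L / model.ga_s
        cfg = SolverConfig(alpha_per_s=300.0, beta_s=2e-4, self_contact=False)
        dt = stable_dt(model, cfg)
        st = SimState.from_rest(model)
        # start from the closed-form deflection curve so relaxation only
        # needs to polish the equilibrium
        x = nodes[:, 0]
        st.x[:, 2] = F * (3 * L * x**2 - x**3) / (6 * model.ei) + F * x / model.ga_s
        loads = np.zeros((n + 1, 3))
        loads[-1, 2] = F
        clamp = ClampBC(0, nodes[0], model.q0[0], edge=0)
        prev = None
        for _ in range(30):
            for _ in range(1500):
                step(model, st, dt, cfg, bcs=[clamp], external_forces=loads)
            tip = st.x[-1, 2]
            if prev is not None and abs(tip - prev) < 1e-5 * abs(tip):
                break
            prev = tip
        assert st.x[-1, 2] == pytest.approx(exact, rel=0.02)


class TestContact:
    def test_separated_geometry_zero_force(self, beam_props):
        model = straight_model(beam_props, n=4)
        st = SimState.from_rest(model)
        plane = HalfSpace([0.0, 0.0, -5.0], [0.0, 0.0, 1.0])
        f, energy, _, max_pen = contact_forces(model, st, [plane], 1e-3, 1e-4, 0.01)
        assert np.all(f[np.abs(f) > 0] == 0) if f.size == 0 else np.abs(f).max() == 0
        assert energy == 0.0 and max_pen == 0.0

    def test_penalty_law_magnitude(self, beam_props):
        # penetration 0.01 mm at k_n = 10 N/mm -> 0.1 N along the normal
        model = straight_model(beam_props, n=4)
        st = SimState.from_rest(model)
        r = model.coil_radius
        # nodes sit at z=0; a plane at z = -(r - 0.01) leaves the coil tube
        # penetrating it by exactly 0.01 mm
        plane = HalfSpace([0.0, 0.0, -(r - 0.01)], [0.0, 0.0, 1.0])
        k_n = 10.0e-3  # kN/mm = 10 N/mm
        f, _, _, max_pen = contact_forces(
            model, st, [plane], k_n, k_n / 10, 0.01, self_contact=False
        )
        assert max_pen == pytest.approx(0.01, rel=1e-9)
        assert np.abs(f[:, 2]).max() == pytest.approx(0.1e-3, rel=1e-9)  # 0.1 N in kN

    def test_coulomb_friction_clamps_at_mu_n(self, beam_props):
        # drag nodes laterally across a sticky plane at constant normal load
        model = straight_model(beam_props, n=4)
        st = SimState.from_rest(model)
        r = model.coil_radius
        pen0 = 0.01
        plane = HalfSpace([0.0, 0.0, -(r - pen0)], [0.0, 0.0, 1.0], mu=0.6)
        k_n = default_penalty(model)
        k_t = k_n / 10.0
        # establish anchors, then displace far enough that every spring slips
        contact_forces(model, st, [plane], k_n, k_t, 0.01, self_contact=False)
        slip = 10.0 * 0.6 * k_n * pen0 / k_t
        st.x[:, 0] += slip
        st.v[:, 0] = 1.0
        f, _, _, _ = contact_forces(model, st, [plane], k_n, k_t, 0.01, self_contact=False)
        fn = k_n * pen0
        assert np.abs(f[:, 0]) == pytest.approx(0.6 * fn, rel=1e-6)
        assert np.all(f[:, 0] < 0)  # opposes the motion

    def test_self_contact_repels_close_segments(self, beam_props):
        sec, em = beam_props
        d2 = 0.2921
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 0.5, 0.1], [1, 0.5, 0.1], [0, 0.5, 0.1]],
            dtype=float,
        )
        model = BeamModel.from_centerline(nodes, sec, em, d2)
        st = SimState.from_rest(model)
        # distance between the two straight runs is ~0.51 > D2: no force
        f, e, _, _ = contact_forces(model, st, [], 1e-3, 1e-4, 0.01)
        assert np.abs(f).max() < 1e-15
        st.x[3:, 1] -= 0.3  # now 0.21 < D2
        f, e, _, _ = contact_forces(model, st, [], 1e-3, 1e-4, 0.01)
        assert e > 0
        assert f[1, 1] < 0 and f[4, 1] > 0  # pushed apart
        assert np.abs(f.sum(axis=0)).max() < 1e-15

    def test_tube_confines_and_releases(self, beam_props):
        n = 30
        path = Centerline(np.column_stack([np.linspace(0, 10, n), np.zeros(n), np.zeros(n)]))
        tube = TubeInterior(path, 0.2921)
        pts = np.array(
            [
                [5.0, 0.0, 0.0],     # on axis: no contact
                [5.0, 0.25, 0.0],    # inside wall band: pushed to axis
                [5.0, 1.5, 0.0],     # beyond wall: outside the tube, free
                [11.0, 0.0, 0.0],    # past the distal tip: released
            ]
        )
        pen, normal = tube.gaps(pts, 0.2921 / 2.0)
        assert pen[0] < 0
        assert pen[1] > 0 and normal[1, 1] < 0
        assert pen[2] < 0
        assert pen[3] < 0

    def test_trimesh_barrier_keeps_nodes_inside_sphere(self, beam_props):
        import trimesh

        sec, em = beam_props
        ico = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        barrier = TriMeshBarrier(ico, keep="inside")
        nodes = np.array([[0, 0, 0], [0.5, 0, 0], [3.4, 0, 0], [3.9, 0, 0]], dtype=float)
        model = BeamModel.from_centerline(nodes, sec, em, 0.2921)
        st = SimState.from_rest(model)
        pen, normal = barrier.gaps(st.x, model.coil_radius)
        assert pen[0] < 0  # deep inside
        assert pen[2] > 0  # escaped: pushed back toward the center
        assert normal[2] @ np.array([1.0, 0.0, 0.0]) < 0


class TestRun:
    def test_straightened_coil_recovers_preshape_in_free_space(
        self, axium_coil, beam_props
    ):
        # shape memory: released with damping and no barriers, a straightened
        # coil relaxes back toward its pre-shape, shedding >99% of the
        # straightening strain energy
        from coildeploy.explicit_solver import _quat_from_matrix

        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2,
                                          mass_scale=50.0)
        st = SimState.from_rest(model)
        sta = np.concatenate([[0.0], np.cumsum(model.h0)])
        st.x = np.column_stack([sta, np.zeros_like(sta), np.zeros_like(sta)])
        frame = _quat_from_matrix(
            np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        )
        st.q = np.tile(frame, (model.n_nodes - 1, 1))
        e0 = internal_forces(model, st)[2]
        assert e0 > 0
        cfg = SolverConfig(alpha_per_s=10.0)
        st, _ = run(model, cfg, duration=600.0, state=st,
                    dt=stable_dt(model, cfg))
        assert st.ledger["strain"] < 0.01 * e0

    def test_rest_state_is_fixed_point(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)
        model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
        cfg = SolverConfig(self_contact=False)
        st, _ = run(model, cfg, duration=1.0)
        assert np.allclose(st.x, model.x0, atol=1e-12)

    def test_bit_identical_repeat_runs(self, axium_coil, beam_props):
        sec, em = beam_props
        pre = make_preshape(axium_coil, "improved", h=0.5)

        def one():
            model = BeamModel.from_centerline(pre.nodes, sec, em, axium_coil.d2)
            cfg = SolverConfig(alpha_per_s=5.0)
            st = SimState.from_rest(model)
            rng = np.random.default_rng(11)
            st.v[:] = rng.normal(0, 0.02, st.v.shape)
            st, _ = run(model, cfg, duration=3.0, state=st)
            return st.x

        assert np.array_equal(one(), one())

    def test_instability_detector_aborts(self, beam_props):
        model = straight_model(beam_props, n=10)
        model.ea *= -1.0  # anti-restoring axial response: guaranteed blow-up
        cfg = SolverConfig(alpha_per_s=0.0, beta_s=0.0, self_contact=False)
        st = SimState.from_rest(model)
        st.v[:, 0] = 1e-4
        with pytest.raises(FloatingPointError):
            run(model, cfg, duration=200.0, state=st, dt=0.05)

    def test_trajectory_checkpoints_and_hdf5(self, beam_props, tmp_path):
        model = straight_model(beam_props, n=6)
        cfg = SolverConfig(self_contact=False)
        st, traj = run(model, cfg, duration=1.0, checkpoint_every=0.2)
        assert len(traj.times) >= 5
        out = tmp_path / "traj.h5"
        traj.to_hdf5(out, cfg)
        import h5py

        with h5py.File(out) as fh:
            assert fh["positions_mm"].shape[1:] == (7, 3)
            assert "ledger/strain" in fh
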