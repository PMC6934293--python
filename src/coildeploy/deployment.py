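"""Orchestration of the three mechanical coiling steps.

Packaging pulls the pre-shaped coil into the catheter (distal end driven by
a smooth-step displacement of amplitude equal to the coil length);
advancement pushes the packaged coil along the catheter centerline
(amplitude = catheter centerline arc length); deployment pushes it out of
the catheter into the sac, with the neck cover acting as a one-sided
barrier against herniation.  Between steps a short settle phase (boundary
condition held, damping active) runs until kinetic energy is small compared
to strain energy, so each stage starts quasi-statically.

Ensembles replicate the deployment-variability protocol: the pre-shape is
rotated coaxially about the catheter axis in 40° increments (9 runs per
technique) before packaging.  Multi-coil plans run the three steps
sequentially per coil with earlier coils left in place as frozen contact
bodies.

Two techniques are configurable: ``improved`` (mandrel-wound pre-shape,
spring-equivalent moduli, explicit advancement along the parent artery) and
``original`` (parametric pre-shape, platinum-wire moduli, straight catheter
placed perpendicular to the neck, no advancement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .coil_mechanics import CoilSpec, EquivalentMaterial
from .explicit_solver import (
    BeamModel,
    HoldBC,
    NeckBand,
    PathBC,
    SimState,
    SolverConfig,
    SphereCavity,
    TubeInterior,
    default_penalty,
    run,
    stable_dt,
)
from .preshape_factory import (
    CoilCenterline,
    build_mandrel,
    default_winding_pattern,
    discretize,
    parametric_preshape,
    truncate_to_length,
    wind_on_mandrel,
)
from .vascular_geometry import AneurysmCase, CatheterTube, Centerline, build_catheter

__all__ = [
    "TreatmentPlan",
    "DeployedConfiguration",
    "DeploymentSession",
    "CapsuleChainBarrier",
    "make_preshape",
    "place_preshape",
    "run_ensemble",
]


PAPER_ROTATIONS_DEG = tuple(range(0, 360, 40))


@dataclass
class TreatmentPlan:
    """Ordered coil list + ensemble rotations + technique + step durations."""

    coils: list
    rotations_deg: tuple = PAPER_ROTATIONS_DEG
    technique: str = "improved"
    mass_scale: float = 50.0
    element_length: float | None = None  # default D2 of each coil
    pull_speed_frac: float = 0.08        # of the (scaled) shear wave speed
    seed: int = 0


@dataclass
class DeployedConfiguration:
    """Final coil centerlines + per-step energy summaries + provenance."""

    centerlines: list
    energies: dict
    rotation_deg: float
    technique: str
    seed: int
    failed: bool = False
    failure: str = ""


def make_preshape(coil: CoilSpec, technique: str = "improved",
                  h: float | None = None) -> CoilCenterline:
    """Pre-shape centerline: mandrel-wound (improved) or spherical-spiral
    parametric baseline (original)."""
    h = h or coil.d2
    if technique == "improved":
        mandrel = build_mandrel(coil.d3)
        pattern = default_winding_pattern(mandrel, coil.d2)
        curve = wind_on_mandrel(mandrel, pattern, coil.d2)
        curve = truncate_to_length(curve, coil.length)
        return discretize(curve, h)
    if technique == "original":
        return parametric_preshape(coil.d3, coil.length, h=h)
    raise ValueError(f"unknown technique {technique!r}")


def place_preshape(preshape: np.ndarray, path: Centerline,
                   rotation_deg: float = 0.0) -> np.ndarray:
    """Pose the pre-shape at the proximal catheter tip.

    The coil's first node (the distal end, pulled in first) is placed at the
    path start; the pre-shape bulk trails behind the tip, along the reversed
    inlet tangent.  ``rotation_deg`` rotates the pre-shape coaxially about
    the catheter axis (the ensemble initial condition).
    """
    pts = np.asarray(preshape, dtype=float)
    t0 = path.tangents()[0]
    # shortest-arc rotation taking the coil's lead tangent to -t0, so the
    # first stretch of coil trails straight back from the funnel mouth
    tau = pts[1] - pts[0]
    tau = tau / np.linalg.norm(tau)
    target = -t0
    axis = np.cross(tau, target)
    sn = np.linalg.norm(axis)
    cs = float(tau @ target)
    if sn < 1e-12:
        rot_align = np.eye(3) if cs > 0 else -np.eye(3) + 2 * np.outer(tau, tau)
    else:
        axis = axis / sn
        ang = math.atan2(sn, cs)
        rot_align = _axis_angle(axis, ang)
    if rotation_deg % 360.0 == 0.0:
        rot_coax = np.eye(3)  # full rotations are exact identities
    else:
        rot_coax = _axis_angle(t0, math.radians(rotation_deg))
    rot = rot_coax @ rot_align
    local = pts - pts[0]
    placed = local @ rot.T + path.points[0]
    return placed


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


class CapsuleChainBarrier:
    """Frozen earlier coil as a rigid contact body (chain of capsules)."""

    def __init__(self, nodes: np.ndarray, radius: float, mu: float = 0.2):
        self.nodes = np.asarray(nodes, dtype=float)
        self.radius = radius
        self.mu = mu
        self._a = self.nodes[:-1]
        d = np.diff(self.nodes, axis=0)
        self._len = np.linalg.norm(d, axis=1)
        self._dn = d / self._len[:, None]

    def gaps(self, x: np.ndarray, coil_radius: float):
        rel = x[:, None, :] - self._a[None, :, :]
        tpar = np.clip(np.einsum("nmk,mk->nm", rel, self._dn), 0.0, self._len[None, :])
        foot = self._a[None, :, :] + tpar[..., None] * self._dn[None, :, :]
        d2 = np.sum((x[:, None, :] - foot) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        idx = np.arange(len(x))
        dist = np.sqrt(d2[idx, j])
        pen = (self.radius + coil_radius) - dist
        normal = (x - foot[idx, j]) / np.maximum(dist, 1e-12)[:, None]
        return pen, normal


class DeploymentSession:
    """Run packaging → (advancement) → deployment for one coil in one case."""

    def __init__(self, case: AneurysmCase, coil: CoilSpec,
                 technique: str = "improved", mass_scale: float = 50.0,
                 element_length: float | None = None,
                 pull_speed_frac: float = 0.08, seed: int = 0,
                 extra_barriers: tuple = ()):
        self.case = case
        self.coil = coil
        self.technique = technique
        self.seed = seed
        self.extra_barriers = tuple(extra_barriers)

        self.preshape = make_preshape(coil, technique, h=element_length)
        if technique == "improved":
            material = coil.equivalent_material()
        else:
            em = coil.equivalent_material()
            material = EquivalentMaterial(
                eb=coil.wire.ew, gb=coil.wire.gw, rho_eff=em.rho_eff,
                source={"technique": "original (platinum-wire moduli)"},
            )
        self.material = material
        self.section = coil.solver_section()
        self.model = BeamModel.from_centerline(
            self.preshape.nodes, self.section, material, coil.d2,
            mass_scale=mass_scale,
        )
        # scaled quasi-static runs: heavier mass damping than the physical
        # α=1/s so the added inertia is dissipated within each drive ramp;
        # rigid surfaces use an unsaturated (hard) penalty during drives so
        # the tube wall always beats transient fold pressure, while
        # self-contact saturates at half the coil radius
        self.config = SolverConfig(alpha_per_s=30.0, mass_scale=mass_scale,
                                   penetration_cap_frac=0.5,
                                   surface_cap_frac=0.0, seed=seed)
        self.catheter = self._build_catheter()
        ab = self.section.ab
        c_shear = math.sqrt(self.model.ga_s / ab / self.model.rho)
        self.v_drive = pull_speed_frac * c_shear
        self.dt = stable_dt(self.model, self.config,
                            k_contact=default_penalty(self.model))
        self.energies: dict = {}

    # -- geometry -----------------------------------------------------------

    def _build_catheter(self) -> CatheterTube:
        if self.technique == "improved":
            return build_catheter(self.case.centerline, self.coil.d2, self.coil.length)
        # original technique: straight catheter perpendicular to the neck
        oc = self.case.orifice_contour.mean(axis=0)
        sc = self.case.sac_center if self.case.sac_center is not None else oc
        axis = sc - oc
        axis = axis / np.linalg.norm(axis)
        tip = oc + 0.35 * (self.case.sac_radius or 1.0) * axis
        upstream = tip - axis * max(3.0, 0.5 * self.coil.length)
        pts = upstream + np.linspace(0, 1, 30)[:, None] * (tip - upstream)
        return build_catheter(Centerline(pts), self.coil.d2, self.coil.length)

    def _tube(self, funnel: bool) -> TubeInterior:
        # a generous 40-degree loading funnel feeds every ensemble rotation
        # of the pre-shape smoothly into the tube mouth
        return TubeInterior(
            self.catheter.path, self.catheter.inner_radius, mu=0.0,
            funnel_angle_deg=40.0,
            funnel_length=(self.coil.d3 + self.coil.length) if funnel else 0.0,
        )

    def _sac_surfaces(self):
        case = self.case
        surfaces = [SphereCavity(case.sac_center, case.sac_radius, mu=0.6)]
        if case.kind == "sidewall":
            band = NeckBand(
                axis_point=np.zeros(3),
                axis_dir=np.array([1.0, 0.0, 0.0]),
                tube_radius=case.vessel_radius,
                footprint_center=case.orifice_contour.mean(axis=0),
                footprint_radius=1.15 * np.linalg.norm(
                    case.orifice_contour - case.orifice_contour.mean(axis=0), axis=1
                ).max(),
            )
        else:
            oc = case.orifice_contour.mean(axis=0)
            n = case.sac_center - oc
            n /= np.linalg.norm(n)
            from .explicit_solver import HalfSpace

            band = HalfSpace(oc, n)
            band.active_mask = None
        surfaces.append(band)
        return surfaces, band

    # -- mechanical steps ---------------------------------------------------

    def _settle(self, state, surfaces, bcs, max_time=300.0):
        cfg = replace(self.config, alpha_per_s=4.0 * self.config.alpha_per_s)
        for _ in range(6):
            state, _ = run(self.model, cfg, duration=max_time / 6.0, bcs=bcs,
                           surfaces=surfaces, state=state, dt=self.dt)
            led = state.ledger
            if led["kinetic"] < max(1e-3 * led["strain"], 1e-9):
                break
        return state

    def package(self, rotation_deg: float = 0.0,
                duration: float | None = None) -> SimState:
        """Pull the coil into the catheter; distal-node amplitude = coil length."""
        placed = place_preshape(self.preshape.nodes, self.catheter.path, rotation_deg)
        self.model.x0 = placed  # stress-free pre-shape, rigidly reposed
        state = SimState.from_rest(self.model)
        l = self.coil.length
        duration = duration or l / self.v_drive
        tube = self._tube(funnel=True)
        surfaces = [tube, *self.extra_barriers]
        # pre-settle: resolve any pre-shape/funnel overlap with the tip held
        # and a gently saturated penalty, so the pull starts from a clean
        # static state
        hold = HoldBC(0, self.catheter.path.points[0])
        gentle = replace(self.config, surface_cap_frac=0.5)
        cfg_main, self.config = self.config, gentle
        state = self._settle(state, surfaces, [hold], max_time=150.0)
        self.config = cfg_main
        self.ledger_baseline = state.reset_ledger()
        bc = PathBC(node=0, path=self.catheter.path, s0=0.0, amplitude=l,
                    t0=state.t, t1=state.t + duration)
        # the operator feeds the trailing end toward the mouth while the
        # distal end is pulled in, keeping the coil taut so it enters
        # single-file (loops cannot cross inside the tube); the tail arrives
        # at the mouth exactly when packaging completes
        n_tail = self.model.n_nodes - 1
        tail_line = Centerline(
            np.linspace(state.x[n_tail], self.catheter.path.points[0], 8)
        )
        bc_tail = PathBC(node=n_tail, path=tail_line, s0=0.0,
                         amplitude=tail_line.arc_length,
                         t0=state.t, t1=state.t + duration)
        state, traj = run(self.model, self.config, duration=duration,
                          bcs=[bc, bc_tail], surfaces=surfaces, state=state,
                          dt=self.dt)
        # peak straightening strain during the pull: the reference the
        # deployed coil must recover below
        self.energies["packaged_peak_strain"] = max(
            led["strain"] for led in traj.ledgers
        )
        # the pusher wire sits behind the packaged coil: a backstop at the
        # proximal mouth keeps the tail from relaxing back out of the tube
        from .explicit_solver import HalfSpace

        t0_dir = self.catheter.path.tangents()[0]
        backstop = HalfSpace(self.catheter.path.points[0]
                             - self.model.coil_radius * t0_dir, t0_dir)
        self._backstop = backstop
        state = self._settle(state, [*surfaces, backstop], [bc])
        # containment audit: packaged node centers must lie within the
        # catheter's inner radius (2% slack), the protocol's own bound
        _, _, dist = tube.project(state.x)
        if np.any(dist > 1.02 * self.catheter.inner_radius):
            raise RuntimeError(
                "packaging failed: coil node escaped the catheter "
                f"(max radial distance {dist.max():.3f} mm)"
            )
        self.energies["packaged_strain"] = state.ledger["strain"]
        return state

    def advance(self, state: SimState, duration: float | None = None) -> SimState:
        """Push the packaged coil along the catheter; amplitude = centerline length.

        The nominal amplitude is the catheter centerline arc length; it is
        corrected by the discrete coil's actual tip position so the distal
        tip lands at the orifice end of the catheter (within one element).
        """
        amp_nominal = self.case.centerline.arc_length
        n = self.model.n_nodes - 1
        tube = self._tube(funnel=False)
        s_ends, _, _ = tube.project(state.x[[0, n]])
        amp = self.catheter.path.arc_length - float(s_ends[0])
        duration = duration or amp_nominal / self.v_drive
        bc = PathBC(node=n, path=self.catheter.path, s0=float(s_ends[1]),
                    amplitude=amp, t0=state.t, t1=state.t + duration)
        surfaces = [tube, *self.extra_barriers]
        state, traj = run(self.model, self.config, duration=duration, bcs=[bc],
                          surfaces=surfaces, state=state, dt=self.dt)
        state = self._settle(state, surfaces, [bc])
        self.energies["advanced_strain"] = state.ledger["strain"]
        # peak strain carried while traversing the parent artery: the
        # bend-transit loading that a straight path never sees
        self.energies["advanced_peak_strain"] = max(
            led["strain"] for led in traj.ledgers
        )
        return state

    def deploy(self, state: SimState,
               duration: float | None = None) -> tuple[SimState, DeployedConfiguration]:
        """Push the coil out of the catheter into the sac until fully released.

        The default duration drives at half the packaging speed: the coil
        needs time to re-coil inside the sac instead of kinking against the
        already-deployed loops.
        """
        n = self.model.n_nodes - 1
        tube = self._tube(funnel=False)
        s_prox, _, _ = tube.project(state.x[n][None, :])
        total = self.catheter.path.arc_length
        # the pusher guides the coil end a short way past the catheter tip
        # into the sac, so release does not happen right at the mouth
        tangent = self.catheter.path.tangents()[-1]
        overshoot = 0.3 * (self.case.sac_radius or 1.0)
        ext = self.catheter.path.points[-1] + np.linspace(0.1, 1.0, 6)[:, None] \
            * overshoot * tangent[None, :]
        drive_path = Centerline(np.vstack([self.catheter.path.points, ext]))
        amp = drive_path.arc_length - float(s_prox[0])
        duration = duration or 2.0 * amp / self.v_drive
        bc = PathBC(node=n, path=drive_path, s0=float(s_prox[0]),
                    amplitude=amp, t0=state.t, t1=state.t + duration)
        sac_surfaces, band = self._sac_surfaces()
        surfaces = [tube, *sac_surfaces, *self.extra_barriers]

        def update_release(st):
            s, _, _ = tube.project(st.x)
            released = s >= total - 1.5 * self.model.h0.mean()
            if isinstance(band, NeckBand):
                band.active_mask = released

        update_release(state)
        deploy_cfg = replace(self.config, alpha_per_s=2.0 * self.config.alpha_per_s)
        state, _ = run(self.model, deploy_cfg, duration=duration, bcs=[bc],
                       surfaces=surfaces, state=state, dt=self.dt,
                       events=[update_release])
        # free settle inside the sac (coil released from the catheter)
        if isinstance(band, NeckBand):
            band.active_mask = np.ones(self.model.n_nodes, dtype=bool)
        free_surfaces = [*sac_surfaces, *self.extra_barriers]
        state = self._settle(state, free_surfaces, bcs=[])
        self.energies["deployed_strain"] = state.ledger["strain"]

        inside = self.case.inside_sac(state.x, tol=self.coil.d2)
        failed = not bool(np.all(inside))
        failure = "" if not failed else (
            f"herniation/escape: {int((~inside).sum())} node(s) outside the sac"
        )
        cfg = DeployedConfiguration(
            centerlines=[state.x.copy()],
            energies=dict(self.energies),
            rotation_deg=getattr(self, "_rotation", 0.0),
            technique=self.technique,
            seed=self.seed,
            failed=failed,
            failure=failure,
        )
        return state, cfg

    def full_deployment(self, rotation_deg: float = 0.0) -> DeployedConfiguration:
        self._rotation = rotation_deg
        state = self.package(rotation_deg)
        if self.technique == "improved":
            state = self.advance(state)
        _, cfg = self.deploy(state)
        return cfg


def run_ensemble(plan: TreatmentPlan, case: AneurysmCase) -> list:
    """One full deployment per rotation angle; multi-coil plans run
    sequentially with earlier coils frozen as contact bodies.

    Individual run failures are reported per rotation (``failed`` flag on the
    configuration) and the ensemble continues.
    """
    results = []
    for theta in plan.rotations_deg:
        barriers: list = []
        coil_cfgs = []
        ok = True
        for coil in plan.coils:
            session = DeploymentSession(
                case, coil, technique=plan.technique,
                mass_scale=plan.mass_scale,
                element_length=plan.element_length,
                pull_speed_frac=plan.pull_speed_frac,
                seed=plan.seed,
                extra_barriers=tuple(barriers),
            )
            try:
                cfg = session.full_deployment(rotation_deg=theta)
            except (RuntimeError, FloatingPointError) as err:
                cfg = DeployedConfiguration(
                    centerlines=[], energies=dict(session.energies),
                    rotation_deg=theta, technique=plan.technique,
                    seed=plan.seed, failed=True, failure=str(err),
                )
                ok = False
            coil_cfgs.append(cfg)
            if not ok:
                break
            barriers.append(
                CapsuleChainBarrier(cfg.centerlines[0], coil.d2 / 2.0, mu=0.2)
            )
        merged = DeployedConfiguration(
            centerlines=[c for cc in coil_cfgs for c in cc.centerlines],
            energies={f"coil{i}_{k}": v for i, cc in enumerate(coil_cfgs)
                      for k, v in cc.energies.items()},
            rotation_deg=theta,
            technique=plan.technique,
            seed=plan.seed,
            failed=any(c.failed for c in coil_cfgs),
            failure="; ".join(c.failure for c in coil_cfgs if c.failure),
        )
        results.append(merged)
    return results
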