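"""The coupled simulation loop.

Per the alternating (operator-splitting) coupling of the model, each step
advances the cortical species on the frozen membrane, then recomputes forces
and the deformation velocity from the updated actomyosin field and advances
the membrane:

    1. cortical flow v_c = nu grad m
    2. species reaction-advection-diffusion step (phi frozen)
    3. membrane/cortex forces from (phi, m)
    4. momentum solve for u
    5. semi-implicit phase-field step (species frozen)

The time step adapts to the advective CFL bound of the current velocity,
capped at the configured maximum.  Observables (contour, furrow depth,
tracked interface position) are sampled on a fixed cadence; the run ends at
t_end, a configured margin after polarization completes, or on a detected
failure (interface topology change, solver breakdown), which is recorded in
the report rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .config import RunConfig
from .evolution import CFLError, advance_phi
from .flow import MomentumSolveError, solve_momentum, viscosity_field
from .forces import total_membrane_force
from .grid import Grid
from .observables import (
    BehaviorClass,
    ContourTopologyError,
    MembraneContour,
    PolarizationReport,
    classify_behavior,
    extract_contour,
    furrow_profile,
    time_to_polarization,
)
from .phasefield import PhaseFieldState, init_eggshell, init_ellipse_phase_field
from .species import (
    BistabilityError,
    SpeciesState,
    advective_velocity,
    default_profile_spec,
    init_species_profiles,
    interface_mass,
    surface_rd_step,
)

__all__ = ["Trajectory", "run_simulation"]


@dataclass
class Trajectory:
    """Time-stamped record of one run."""

    config: RunConfig
    times: list[float] = field(default_factory=list)
    contours: list[MembraneContour] = field(default_factory=list)
    depths: list[float] = field(default_factory=list)
    furrow_bottoms: list[tuple[float, float] | None] = field(default_factory=list)
    tracked_y: list[float] = field(default_factory=list)
    midpoint_y: list[float] = field(default_factory=list)
    anterior_share: list[float] = field(default_factory=list)
    species_mass: list[dict] = field(default_factory=list)
    force_log: list[dict] = field(default_factory=list)
    n_steps: int = 0
    n_clipped: int = 0
    failure: str | None = None
    # final state for checkpointing / inspection
    final_phi: PhaseFieldState | None = None
    final_species: SpeciesState | None = None
    final_u: tuple[np.ndarray, np.ndarray] | None = None


def _sample_on_contour(grid: Grid, f: np.ndarray,
                       contour: MembraneContour) -> np.ndarray:
    """Bilinear samples of a grid field along contour points (periodic)."""
    ix = (contour.x - grid.x[0]) / grid.dx
    iy = (contour.y - grid.y[0]) / grid.dy
    return scipy.ndimage.map_coordinates(
        f, np.vstack([ix, iy]), order=1, mode="grid-wrap"
    )


def _interface_position(grid: Grid, field: np.ndarray,
                        contour: MembraneContour) -> float:
    """AP (y) position of the steepest transition of a cortical field along
    the membrane (max |df/ds| over contour arc length).

    Used to track polarization before a furrow exists.  The total anterior
    PAR concentration is used as the field: it is polarized from t = 0,
    whereas actomyosin starts uniform and carries no interface yet.
    """
    vals = _sample_on_contour(grid, field, contour)
    pts = contour.points
    seg = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
    ds = 0.5 * (seg + np.roll(seg, 1))
    dm = 0.5 * (np.roll(vals, -1) - np.roll(vals, 1)) / np.maximum(ds, 1e-12)
    return float(pts[int(np.argmax(np.abs(dm))), 1])


def _anterior_share(contour: MembraneContour) -> float:
    """Fraction of the enclosed area anterior of the initial midplane y=0."""
    from shapely.geometry import box

    poly = contour.polygon()
    minx, _, maxx, maxy = poly.bounds
    upper = poly.intersection(box(minx - 1, 0.0, maxx + 1, maxy + 1)).area
    return float(upper / poly.area) if poly.area > 0 else 0.0


def run_simulation(cfg: RunConfig, collect_forces: bool = False) -> tuple[
        Trajectory, PolarizationReport]:
    """Run one polarization simulation and measure it.

    Returns the trajectory (contours and series) and the polarization report
    (T_pol, furrow depth series, average depth, behavior class).  Failures
    (topology change, non-convergence, interface blow-up) terminate the run
    and are recorded on both objects, never raised.
    """
    grid = Grid(cfg.nx, cfg.ny, cfg.Lx, cfg.Ly)
    pf = cfg.phase
    state = init_ellipse_phase_field(grid, cfg.rx, cfg.ry, pf.epsilon)

    # Pre-relax the analytic initial profile to the equilibrium tanh
    # cross-section (force-free, u = 0) so that bending/tension forces do not
    # see a spurious initial profile mismatch.
    zero = np.zeros(grid.shape)
    n_relax = max(1, int(np.ceil(cfg.relax_time / pf.dt)))
    for _ in range(n_relax):
        state = advance_phi(state, zero, zero, pf)

    mech = cfg.mech
    mech.alpha = state.area()
    shell = (
        init_eggshell(grid, cfg.rx, cfg.ry, cfg.e_d)
        if mech.M_s > 0
        else None
    )

    try:
        profile = default_profile_spec(cfg.kin, cfg.pools, K0=cfg.K0,
                                       m0=cfg.m0)
        species = init_species_profiles(profile, grid, cfg.pools, pf.epsilon)
    except BistabilityError:
        rates = [getattr(cfg.kin, k) for k in (
            "kon_A", "koff_A", "kon_Asd", "kon_Add", "kd_plus", "kd_minus",
            "r_A", "kon_P", "koff_P", "r_P", "kon_M", "koff_M")]
        if any(r != 0 for r in rates):
            raise
        # degenerate (reaction-free) configuration, e.g. null-dynamics
        # checks: any uniform state is steady, start PAR-free
        species = SpeciesState(grid, *(np.zeros(grid.shape) for _ in range(4)),
                               m=np.full(grid.shape, cfg.m0), pools=cfg.pools)

    traj = Trajectory(config=cfg)
    t = 0.0
    next_sample = 0.0
    t_reached_mid: float | None = None
    ux = uy = zero
    ux_prev = uy_prev = None

    def sample(u_now) -> None:
        nonlocal t_reached_mid
        contour = extract_contour(grid, state.phi, time=t)
        ref = traj.contours[0] if traj.contours else contour
        # follow the travelling furrow: only dents near the previously
        # tracked AP position qualify (transient dents elsewhere, e.g. at
        # the poles during the initial contraction, are not the furrow)
        near = traj.tracked_y[-1] if traj.tracked_y else None
        furrow = furrow_profile(contour, ref, near_y=near)
        if furrow.bottom is not None:
            tracked = furrow.bottom[1]
        else:
            tracked = _interface_position(grid, species.anterior_total(),
                                          contour)
        mid = contour.midpoint_y()
        traj.times.append(t)
        traj.contours.append(contour)
        traj.depths.append(furrow.depth)
        traj.furrow_bottoms.append(furrow.bottom)
        traj.tracked_y.append(tracked)
        traj.midpoint_y.append(mid)
        traj.anterior_share.append(_anterior_share(contour))
        traj.species_mass.append({
            name: interface_mass(grid, state.phi, f)
            for name, f in species.fields().items()
        })
        if collect_forces:
            traj.force_log.append(_force_decomposition(grid, state, species,
                                                       mech, shell))
        if t_reached_mid is None and tracked >= mid:
            t_reached_mid = t

    try:
        sample(None)
        # initial velocity, so the first time step respects the CFL bound of
        # the (often large) initial force transient
        fx, fy = total_membrane_force(grid, state.phi, species.m, mech, shell)
        eta = viscosity_field(state.phi, species.m, cfg.visc)
        ux, uy = solve_momentum(grid, eta, cfg.visc.xi, fx, fy,
                                rtol=cfg.solver_rtol,
                                maxiter=cfg.solver_maxiter)
        while t < cfg.t_end:
            # 1-2. cortical species on the frozen membrane
            vcx, vcy = advective_velocity(grid, species.m, cfg.kin.nu)
            umax = float(np.max(np.hypot(ux, uy)))
            dt = pf.dt if umax == 0 else min(
                pf.dt, cfg.cfl * min(grid.dx, grid.dy) / umax
            )
            dt = min(dt, cfg.t_end - t, next_sample + cfg.cadence - t)
            species, nclip = surface_rd_step(
                species, state.phi, vcx, vcy, dt, cfg.kin
            )
            traj.n_clipped += nclip
            # 3-4. forces and velocity from the updated protein profile
            fx, fy = total_membrane_force(grid, state.phi, species.m, mech,
                                          shell)
            eta = viscosity_field(state.phi, species.m, cfg.visc)
            # linear extrapolation of the previous two solutions as the
            # Krylov initial guess: u drifts slowly in the quasi-static
            # regime, so this typically saves ~20% of solver iterations
            if ux_prev is None:
                guess = (ux, uy)
            else:
                guess = (2.0 * ux - ux_prev, 2.0 * uy - uy_prev)
            ux_prev, uy_prev = ux, uy
            ux, uy = solve_momentum(
                grid, eta, cfg.visc.xi, fx, fy,
                rtol=cfg.solver_rtol, maxiter=cfg.solver_maxiter,
                u0=guess,
            )
            # 5. membrane step (sub-divide if u outran the CFL estimate)
            nsub = 1
            while True:
                try:
                    s = state
                    for _ in range(nsub):
                        s = advance_phi(s, ux, uy, pf, dt / nsub)
                    state = s
                    break
                except CFLError:
                    nsub *= 2
                    if nsub > 64:
                        raise
            t += dt
            traj.n_steps += 1
            if t >= next_sample + cfg.cadence - 1e-9:
                next_sample += cfg.cadence
                sample((ux, uy))
                if (
                    t_reached_mid is not None
                    and t >= t_reached_mid + cfg.exit_margin
                ):
                    break
    except (ContourTopologyError, MomentumSolveError, CFLError, ValueError) as e:
        traj.failure = f"{type(e).__name__}: {e}"

    traj.final_phi = state
    traj.final_species = species
    traj.final_u = (ux, uy)

    times = np.asarray(traj.times)
    report = PolarizationReport(
        times=times,
        depths=np.asarray(traj.depths),
        tracked_y=np.asarray(traj.tracked_y),
        midpoint_y=np.asarray(traj.midpoint_y),
        anterior_share=np.asarray(traj.anterior_share),
        failure=traj.failure,
    )
    if len(times):
        report.t_pol = time_to_polarization(
            times, report.tracked_y, report.midpoint_y
        )
        behavior, ambiguous = classify_behavior(report)
        report.behavior = behavior
        report.ambiguous = ambiguous
    return traj, report


def _force_decomposition(grid, state, species, mech, shell) -> dict:
    """Max magnitude of each force component (for isolation checks/logs)."""
    from . import forces as F

    phi, m = state.phi, species.m
    eps = mech.epsilon
    out = {}
    for name, (fx, fy) in {
        "bending": F.bending_force(grid, phi, mech.kappa, eps),
        "tension": F.tension_force(grid, phi, m, mech.gamma, mech.c_T, eps),
        "volume": F.volume_force(grid, phi, mech.M1, mech.alpha),
        "actomyosin": F.actomyosin_force(grid, phi, m, mech.c_m, mech.c_g),
        "eggshell": (
            F.eggshell_force(grid, phi, shell.phi_s, mech.M_s)
            if shell is not None
            else (np.zeros(grid.shape), np.zeros(grid.shape))
        ),
    }.items():
        out[name] = float(np.max(np.hypot(fx, fy)))
    return out
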