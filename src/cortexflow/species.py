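"""Cortical PAR / actomyosin reaction-advection-diffusion system.

Five dimensionless species live on the membrane: anterior PAR monomers (a1),
singly and doubly bound anterior dimers (a10, a11), posterior PAR (p) and
actomyosin (m).  Cytoplasmic pools are at quasi-steady state and enter only
as constant source levels.  The two PAR modules mutually remove each other
from the cortex, the posterior module inhibits actomyosin assembly through a
saturating factor, and every species is advected by the cortical flow
v_c = nu * grad m driven by the actomyosin (tension) gradient.

Surface transport is discretized with a diffuse-domain approximation: for a
species field s extended to the whole box, with W = G(phi) + delta the
floored double-well interface weight,

    ds/dt = [ div(W D grad s) - div(W v_c s) ] / W + R(s)

restricts diffusion and advection to the interface band (where W ~ G), while
the weight cancels out of the reaction term: rates act at full strength
wherever the field is meaningful.  Off-band values relax diffusively and are
refreshed by a constant-normal extension of the band values each step.  No-flux conditions at the band edges
are automatic in this weighted form, and the interface-weighted mass
``int W s dx`` is conserved to machine precision by the spectral divergence
whenever reactions are off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.integrate
import scipy.ndimage
import scipy.optimize

from .grid import Grid
from .params import (
    CytoplasmicPools,
    InitialProfileSpec,
    KineticParams,
    SpeciesProfile,
)
from .phasefield import double_well, interface_weight

__all__ = [
    "SpeciesState",
    "SteadyState",
    "BistabilityError",
    "reaction_rhs",
    "advective_velocity",
    "surface_rd_step",
    "interface_mass",
    "bistable_steady_states",
    "init_species_profiles",
    "default_profile_spec",
]

SPECIES_NAMES = ("a1", "a10", "a11", "p", "m")


@dataclass
class SpeciesState:
    """The five cortical concentration fields plus frozen cytoplasmic pools."""

    grid: Grid
    a1: np.ndarray
    a10: np.ndarray
    a11: np.ndarray
    p: np.ndarray
    m: np.ndarray
    pools: CytoplasmicPools

    def __post_init__(self) -> None:
        for name in SPECIES_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape must match grid")
            setattr(self, name, arr)

    def fields(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in SPECIES_NAMES}

    def anterior_total(self) -> np.ndarray:
        """Total cortical anterior PAR, a1 + a10 + a11."""
        return self.a1 + self.a10 + self.a11

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            self.grid,
            *(getattr(self, n).copy() for n in SPECIES_NAMES),
            pools=self.pools,
        )


def reaction_rhs(
    a1, a10, a11, p, m, pools: CytoplasmicPools, kin: KineticParams
):
    """Mass-action reaction rates of the five species (pointwise/vectorized).

    Returns (da1, da10, da11, dp, dm).
    """
    dimer_fwd = kin.kd_plus * a1 * a1
    da1 = (
        kin.kon_A * pools.Ay
        - kin.koff_A * a1
        - 2.0 * dimer_fwd
        + 2.0 * kin.kd_minus * a11
        - kin.kd_plus * pools.Ay * a1
        + kin.kd_minus * a10
        - kin.r_A * p * a1
    )
    da10 = (
        kin.kon_Asd * pools.A2y
        - kin.koff_A * a10
        + kin.kd_plus * pools.Ay * a1
        - kin.kd_minus * a10
        - kin.kon_Add * a10
        + kin.koff_A * a11
        - kin.r_A * p * a10
    )
    da11 = (
        dimer_fwd
        - kin.kd_minus * a11
        - kin.koff_A * a11
        + kin.kon_Add * a10
        - 2.0 * kin.r_A * p * a11
    )
    dp = (
        kin.kon_P * pools.Py
        - kin.koff_P * p
        - kin.r_P * (a1 + a10 + 2.0 * a11) * p
    )
    dm = kin.kon_M * pools.My * kin.k_P / (kin.k_P + p) - kin.koff_M * m
    return da1, da10, da11, dp, dm


def advective_velocity(
    grid: Grid, m: np.ndarray, nu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cortical flow v_c = nu * grad m (spectral gradient)."""
    mx, my = grid.grad(m)
    return nu * mx, nu * my


def _stable_substeps(
    grid: Grid,
    dt: float,
    kin: KineticParams,
    vcx: np.ndarray,
    vcy: np.ndarray,
) -> int:
    """Number of explicit substeps needed for diffusive/advective stability."""
    h2 = min(grid.dx, grid.dy) ** 2
    dmax = max(kin.Dpa, kin.Dpp, kin.Dm)
    limits = []
    if dmax > 0:
        # spectral Laplacian: stability requires dt < 2 h^2 / (D pi^2)
        limits.append(0.15 * h2 / dmax)
    vmax = float(np.max(np.hypot(vcx, vcy)))
    if vmax > 0:
        limits.append(0.5 * min(grid.dx, grid.dy) / vmax)
    if not limits:
        return 1
    return max(1, int(np.ceil(dt / min(limits))))


#: Species values are meaningful where G exceeds this; outside, they are
#: overwritten by the constant-normal extension before each step.
BAND_THRESHOLD = 0.05


def extension_indices(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index maps sending every off-band point to its nearest band point.

    Used to extend species fields constantly along normals off the interface
    band; without the extension the cell interior acts as a spurious
    reservoir that is exchanged with the cortex through the weight floor and
    slowly erodes the polarized pattern.
    """
    offband = double_well(phi) < BAND_THRESHOLD
    _, inds = scipy.ndimage.distance_transform_edt(offband, return_indices=True)
    return inds[0], inds[1]


def surface_rd_step(
    state: SpeciesState,
    phi: np.ndarray,
    vcx: np.ndarray,
    vcy: np.ndarray,
    dt: float,
    kin: KineticParams,
    reactions: bool = True,
    extend: bool = True,
) -> tuple[SpeciesState, int]:
    """Advance all species by dt with phi held fixed (operator splitting).

    Off-band values are first replaced by the constant-normal extension of
    the band values (a no-op for fields that are already extension
    consistent), then the diffuse-domain transport operator is stepped
    explicitly in conservative form, automatically substepped to satisfy the
    diffusive and advective stability bounds.  The advective velocity is
    confined to the interface band with the smooth mask G/W: the cortical
    flow physically exists only on the cortex, and off the band it would
    make the self-advected actomyosin field (anti-diffusion nu*m) unstable.

    Returns the new state and the number of grid points at which a (small)
    negative concentration was clipped to zero; values below -1e-10 are
    counted, anything less negative is treated as roundoff.
    """
    grid = state.grid
    W = interface_weight(phi)
    G = double_well(phi)
    chi = G / W  # band mask for the advective velocity
    nsub = _stable_substeps(grid, dt, kin, vcx, vcy)
    h = dt / nsub
    vx = chi * vcx
    vy = chi * vcy
    diffusivity = {
        "a1": kin.Dpa, "a10": kin.Dpa, "a11": kin.Dpa,
        "p": kin.Dpp, "m": kin.Dm,
    }
    if extend:
        ix, iy = extension_indices(phi)
        fields = {n: getattr(state, n)[ix, iy] for n in SPECIES_NAMES}
    else:
        fields = {n: getattr(state, n).copy() for n in SPECIES_NAMES}
    n_clipped = 0
    for _ in range(nsub):
        if reactions:
            rates = reaction_rhs(
                fields["a1"], fields["a10"], fields["a11"],
                fields["p"], fields["m"], state.pools, kin,
            )
        for i, name in enumerate(SPECIES_NAMES):
            s = fields[name]
            D = diffusivity[name]
            sx, sy = grid.grad(s)
            flux_x = grid.dealias(W * (D * sx - vx * s))
            flux_y = grid.dealias(W * (D * sy - vy * s))
            ds = grid.div(flux_x, flux_y) / W
            if reactions:
                # in the weighted form d(W s)/dt = ... + W R the weight
                # cancels: reactions act at full rate wherever the field is
                # meaningful (off band the values are extensions anyway)
                ds = ds + rates[i]
            s = s + h * ds
            neg = s < 0.0
            if np.any(neg):
                n_clipped += int(np.count_nonzero(s < -1.0e-10))
                s = np.where(neg, 0.0, s)
            fields[name] = s
    new = SpeciesState(grid, **fields, pools=state.pools)
    return new, n_clipped


def interface_mass(grid: Grid, phi: np.ndarray, s: np.ndarray) -> float:
    """Interface-weighted species mass, int W(phi) s dx."""
    return grid.integrate(interface_weight(phi) * s)


# ---------------------------------------------------------------------------
# Well-mixed steady states


@dataclass(frozen=True)
class SteadyState:
    """A homogeneous steady state of the reaction network."""

    a1: float
    a10: float
    a11: float
    p: float
    m: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a10, self.a11, self.p, self.m])

    @property
    def anterior_total(self) -> float:
        return self.a1 + self.a10 + self.a11


class BistabilityError(RuntimeError):
    """The parameter set does not admit two stable homogeneous states."""


def _ode(y: np.ndarray, pools: CytoplasmicPools, kin: KineticParams) -> np.ndarray:
    return np.array(reaction_rhs(*y, pools, kin))


def _settle(
    y0: np.ndarray, pools: CytoplasmicPools, kin: KineticParams
) -> SteadyState | None:
    """Integrate to equilibrium from y0, polish with a Newton solve."""
    sol = scipy.integrate.solve_ivp(
        lambda t, y: _ode(y, pools, kin),
        (0.0, 2.0e5),
        y0,
        method="LSODA",
        rtol=1.0e-10,
        atol=1.0e-12,
    )
    if not sol.success:
        return None
    root = scipy.optimize.root(
        lambda y: _ode(y, pools, kin), sol.y[:, -1], method="hybr", tol=1.0e-13
    )
    # judge by residual, not the solver's success flag (hybr reports failure
    # when it cannot improve an already-converged iterate)
    y = root.x
    if np.max(np.abs(_ode(y, pools, kin))) > np.max(np.abs(_ode(sol.y[:, -1],
                                                               pools, kin))):
        y = sol.y[:, -1]
    if np.any(y < -1.0e-9) or np.max(np.abs(_ode(y, pools, kin))) > 1.0e-10:
        return None
    # local stability: Jacobian eigenvalues strictly in the left half-plane
    jac = scipy.optimize.approx_fprime(y, lambda z: _ode(z, pools, kin), 1.0e-7)
    if np.max(np.real(np.linalg.eigvals(jac))) >= 0.0:
        return None
    return SteadyState(*np.maximum(y, 0.0))


_BISTABLE_CACHE: dict[tuple, tuple[SteadyState, SteadyState]] = {}


def bistable_steady_states(
    kin: KineticParams, pools: CytoplasmicPools
) -> tuple[SteadyState, SteadyState]:
    """The two stable homogeneous states (anterior-high first).

    Found by relaxing the well-mixed ODE from an anterior-dominated and a
    posterior-dominated seed and polishing with a Newton solve; each returned
    root has reaction residual < 1e-10 and a strictly stable Jacobian.
    Raises :class:`BistabilityError` if the two relaxations coalesce.
    Results are cached per parameter set.
    """
    key = tuple(vars(kin).values()) + tuple(vars(pools).values())
    if key in _BISTABLE_CACHE:
        return _BISTABLE_CACHE[key]
    seed_ant = np.array([2.0, 1.0, 2.0, 0.0, 0.7])
    seed_post = np.array([0.0, 0.0, 0.0, 3.0, 0.1])
    high = _settle(seed_ant, pools, kin)
    low = _settle(seed_post, pools, kin)
    if high is None or low is None:
        raise BistabilityError("relaxation did not reach a stable steady state")
    if abs(high.anterior_total - low.anterior_total) < 1.0e-6:
        raise BistabilityError(
            "anterior-high and posterior-high seeds converged to the same "
            "state; parameter set is not bistable"
        )
    if high.anterior_total < low.anterior_total:
        high, low = low, high
    _BISTABLE_CACHE[key] = (high, low)
    return high, low


# ---------------------------------------------------------------------------
# Initial profiles


def _profile_values(y: np.ndarray, prof: SpeciesProfile, epsilon: float) -> np.ndarray:
    arg = -(y - prof.K0) / (0.5 * epsilon)
    if prof.orientation < 0:
        arg = -arg
    return prof.c1 * (0.5 - 0.5 * np.tanh(arg)) + prof.c2


def default_profile_spec(
    kin: KineticParams,
    pools: CytoplasmicPools,
    K0: float = -15.0,
    m0: float = 0.7,
) -> InitialProfileSpec:
    """Initial profiles built from the bistable plateau concentrations.

    Anterior species step from their low (posterior) to high (anterior)
    plateau across y = K0, posterior PAR steps the opposite way; K0 sits in
    the posterior third of the embryo, mimicking the sperm cue.
    """
    high, low = bistable_steady_states(kin, pools)
    return InitialProfileSpec(
        a1=SpeciesProfile(K0, high.a1 - low.a1, low.a1, +1),
        a10=SpeciesProfile(K0, high.a10 - low.a10, low.a10, +1),
        a11=SpeciesProfile(K0, high.a11 - low.a11, low.a11, +1),
        p=SpeciesProfile(K0, low.p - high.p, high.p, -1),
        m0=m0,
    )


def init_species_profiles(
    spec: InitialProfileSpec,
    grid: Grid,
    pools: CytoplasmicPools,
    epsilon: float = 2.0,
    width: float | None = None,
) -> SpeciesState:
    """Tanh step profiles along the anterior-posterior (y) axis.

    Anterior species are high at +y (anterior), posterior PAR is high at -y;
    actomyosin starts uniform at spec.m0.  The step half-width defaults to
    0.5 * epsilon but is floored at 3.5 grid cells: a narrower step is not
    representable spectrally, and reaction-diffusion sharpens any resolvable
    step to the intrinsic front width within the first ~100 s anyway.
    """
    if width is None:
        width = 0.5 * epsilon
    width = max(width, 3.5 * max(grid.dx, grid.dy) / 2.0)
    _, Y = grid.meshgrid()
    return SpeciesState(
        grid,
        a1=_profile_values(Y, spec.a1, 2.0 * width),
        a10=_profile_values(Y, spec.a10, 2.0 * width),
        a11=_profile_values(Y, spec.a11, 2.0 * width),
        p=_profile_values(Y, spec.p, 2.0 * width),
        m=np.full(grid.shape, spec.m0),
        pools=pools,
    )
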