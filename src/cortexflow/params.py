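"""Parameter containers for the mechanical and kinetic model.

Units: lengths in micrometres, time in seconds.  Protein and actomyosin
concentrations are the dimensionless cortical variables (a1, a10, a11, p, m);
rate constants therefore carry units of 1/s (or 1/s per unit concentration
for the bimolecular terms) and the mechanical coefficients are expressed in
the same force-density scale as the momentum balance.

Experimental measurements of the cortical forces are not available for this
organism, so the mechanical defaults below are *calibrated*: they were chosen
(once, by the scripted procedure in :mod:`cortexflow.calibrate`) so that the
default configuration produces the canonical wild-type phenotype -- a
pseudocleavage furrow that forms at the actomyosin gradient, deepens, and
travels with the PAR interface to mid-cell -- with the aligned-contractility
coefficient held at c_g = 500.  The kinetic defaults were likewise chosen so
that the well-mixed reaction network is bistable (anterior-high vs
posterior-high) and the resulting polarization front crosses the embryo on
the tens-of-minutes timescale of the establishment phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = [
    "MechParams",
    "ViscosityParams",
    "PhaseFieldParams",
    "KineticParams",
    "CytoplasmicPools",
    "SpeciesProfile",
    "InitialProfileSpec",
]


def _nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")


@dataclass
class MechParams:
    """Coefficients of the five membrane/cortex force densities.

    kappa   bending rigidity of the membrane (Canham-Helfrich)
    gamma   baseline membrane surface tension
    c_T     tension added per unit actomyosin concentration
    M1      penalty stiffness of the area (2-D volume) constraint
    alpha   target area, set from the initial integral of phi
    M_s     penalty stiffness of the eggshell constraint (0 = shell removed)
    c_m     cross-linked (isotropic) actomyosin contractility
    c_g     aligned actomyosin contractility, acting through |grad m|
    epsilon diffuse-interface width parameter
    """

    kappa: float = 5.0
    gamma: float = 2.0
    c_T: float = 10.0
    M1: float = 12.0
    alpha: float = 0.0  # set at initialization from the relaxed phi
    M_s: float = 2400.0
    c_m: float = 100.0
    c_g: float = 500.0
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "c_T", "M1", "M_s", "c_m", "c_g"):
            _nonneg(name, getattr(self, name))
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ViscosityParams:
    """Viscosities and drag of the momentum balance.

    The cortex is modelled as more viscous than the cytoplasm (eta_m > eta_c);
    the drag xi u represents hydrodynamic resistance of the fluid-filled
    space between membrane and eggshell and makes the momentum operator
    invertible on the periodic box.
    """

    eta_m: float = 2000.0
    eta_c: float = 200.0
    xi: float = 4000.0
    eta_min_frac: float = 1.0e-3  # exterior viscosity floor, fraction of eta_c

    def __post_init__(self) -> None:
        if not (self.eta_m > self.eta_c > 0):
            raise ValueError("require eta_m > eta_c > 0")
        if self.xi <= 0:
            raise ValueError("xi must be positive")


@dataclass
class PhaseFieldParams:
    """Relaxation dynamics of the interface equation."""

    Gamma: float = 0.3  # relaxation coefficient, um/s
    epsilon: float = 2.0
    dt: float = 1.0  # time step in seconds
    stabilize: bool = True  # curvature stabilization term (off only in tests)

    def __post_init__(self) -> None:
        if self.Gamma <= 0 or self.dt <= 0 or self.epsilon <= 0:
            raise ValueError("Gamma, dt, epsilon must be positive")


@dataclass
class CytoplasmicPools:
    """Quasi-steady cytoplasmic levels (held constant within a step)."""

    Ay: float = 1.0
    A2y: float = 1.0
    Py: float = 1.0
    My: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            _nonneg(name, v)


@dataclass
class KineticParams:
    """Rate constants of the five-species cortical network.

    Species: a1 (anterior monomer), a10 (singly bound dimer), a11 (doubly
    bound dimer), p (posterior PAR), m (actomyosin).  The anterior and
    posterior modules remove each other from the cortex (r_A, r_P), and the
    posterior module inhibits actomyosin assembly through the saturating
    factor k_P / (k_P + p).  Dimerization (kd_plus / kd_minus) supplies the
    nonlinearity that makes the well-mixed network bistable.
    """

    # surface diffusivities, um^2/s
    Dpa: float = 0.1
    Dpp: float = 0.1
    Dm: float = 0.03
    # anterior module
    kon_A: float = 0.023 / 4
    koff_A: float = 0.019 / 4
    kon_Asd: float = 0.0004 / 4
    kon_Add: float = 0.043 / 4
    kd_plus: float = 1.28 / 4
    kd_minus: float = 0.12 / 4
    r_A: float = 0.81 / 4
    # posterior module
    kon_P: float = 0.006 / 4
    koff_P: float = 0.0017 / 4
    r_P: float = 0.17 / 4
    # actomyosin
    kon_M: float = 0.014 / 4
    koff_M: float = 0.02 / 4
    k_P: float = 0.15
    # cortical-flow advection coefficient, v_c = nu * grad m  (um^2/s).
    # Note m is advected by the gradient of its own concentration, which acts
    # as anti-diffusion with coefficient nu*m; stability of the transport
    # model itself requires nu * max(m) < Dm (margin ~2.2x at the defaults).
    nu: float = 0.02

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            _nonneg(name, v)


@dataclass
class SpeciesProfile:
    """Initial tanh step for one species along the anterior-posterior axis.

    value(y) = c1 * (0.5 - 0.5 tanh(-(y - K0)/(0.5 eps))) + c2

    which runs from c2 at the posterior pole to c1 + c2 at the anterior pole.
    Posterior-enriched species use the mirrored form (orientation = -1), which
    runs from c1 + c2 at the posterior to c2 at the anterior.
    """

    K0: float
    c1: float
    c2: float
    orientation: int = +1

    def __post_init__(self) -> None:
        _nonneg("c1", self.c1)
        _nonneg("c2", self.c2)
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


@dataclass
class InitialProfileSpec:
    """Initial condition of all five species.

    The step position K0 sits close to the posterior pole, mimicking the
    sperm cue that locally clears the anterior module; the high/low plateau
    concentrations c1 + c2 / c2 are taken from the two stable well-mixed
    steady states (see :func:`cortexflow.species.bistable_steady_states`).
    Actomyosin starts uniformly at ``m0`` (default 0.7).
    """

    a1: SpeciesProfile
    a10: SpeciesProfile
    a11: SpeciesProfile
    p: SpeciesProfile
    m0: float = 0.7

    def __post_init__(self) -> None:
        _nonneg("m0", self.m0)
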