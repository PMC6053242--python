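import numpy as np
import pytest

from cortexflow.forces import (
    actomyosin_force,
    bending_force,
    eggshell_force,
    tension_force,
    total_membrane_force,
    volume_force,
)
from cortexflow.grid import Grid
from cortexflow.params import MechParams
from cortexflow.phasefield import (
    double_well,
    double_well_prime,
    init_eggshell,
    init_ellipse_phase_field,
)
from tests.conftest import equilibrium_circle, equilibrium_stripe


def norm_max(fx, fy):
    return float(np.max(np.hypot(fx, fy)))


def test_uniform_phi_gives_zero_everywhere():
    g = Grid(32, 32, 16.0, 16.0)
    phi = np.full(g.shape, 1.0)
    m = np.full(g.shape, 0.7)
    shell = init_eggshell(g, 3.0, 4.0, 1.0)
    for fx, fy in (
        bending_force(g, phi, 5.0, 2.0),
        tension_force(g, phi, m, 2.0, 10.0, 2.0),
        volume_force(g, phi, 12.0, g.integrate(phi) + 50.0),
        eggshell_force(g, phi, shell.phi_s, 100.0),
        actomyosin_force(g, phi, m, 100.0, 500.0),
    ):
        assert norm_max(fx, fy) < 1e-8


def test_bending_and_tension_vanish_on_flat_equilibrium_profile():
    """eps*lap(phi) - G'/eps = 0 identically on tanh(3d/eps), so a straight
    relaxed interface carries no bending or tension force; the residual
    must shrink under grid refinement."""
    residuals = []
    for n in (128, 256):
        g = Grid(n, 8, 64.0, 64.0 * 8 / n)
        st = equilibrium_stripe(g, 10.0, 2.0)
        bx, by = bending_force(g, st.phi, 1.0, 2.0)
        tx, ty = tension_force(g, st.phi, np.full(g.shape, 0.5), 1.0, 1.0, 2.0)
        residuals.append((norm_max(bx, by), norm_max(tx, ty)))
    assert residuals[1][0] < 0.5 * residuals[0][0]
    assert residuals[1][1] < 0.5 * residuals[0][1]
    assert residuals[1][0] < 1e-3 and residuals[1][1] < 1e-4


def test_forces_homogeneous_in_their_coefficients():
    g = Grid(96, 96, 48.0, 48.0)
    st = equilibrium_circle(g, 10.0, 2.0)
    X, Y = g.meshgrid()
    m = 0.5 + 0.2 * np.cos(2 * np.pi * Y / g.Ly)
    shell = init_eggshell(g, 9.0, 9.0, 0.5)  # overlapping: force nonzero
    b1 = bending_force(g, st.phi, 1.0, 2.0)
    b2 = bending_force(g, st.phi, 2.0, 2.0)
    assert np.allclose(b2[0], 2 * b1[0]) and np.allclose(b2[1], 2 * b1[1])
    v1 = volume_force(g, st.phi, 3.0, st.area() - 10.0)
    v2 = volume_force(g, st.phi, 6.0, st.area() - 10.0)
    v3 = volume_force(g, st.phi, 3.0, st.area() - 20.0)
    assert np.allclose(v2[0], 2 * v1[0])
    assert np.allclose(v3[0], 2 * v1[0])  # linear in the deficit too
    e1 = eggshell_force(g, st.phi, shell.phi_s, 10.0)
    e2 = eggshell_force(g, st.phi, shell.phi_s, 20.0)
    assert np.allclose(e2[1], 2 * e1[1])
    a1 = actomyosin_force(g, st.phi, m, 50.0, 0.0)
    a2 = actomyosin_force(g, st.phi, m, 100.0, 0.0)
    assert np.allclose(a2[0], 2 * a1[0])


def test_volume_force_sign_contracts_excess_area():
    g = Grid(96, 96, 48.0, 48.0)
    st = equilibrium_circle(g, 10.0, 2.0)
    # area exceeds target: force points along grad phi (inward)
    fx, fy = volume_force(g, st.phi, 5.0, st.area() - 30.0)
    gx, gy = g.grad(st.phi)
    band = np.abs(st.phi - 0.5) < 0.3
    assert np.all((fx * gx + fy * gy)[band] > 0)


def test_eggshell_force_zero_inside_and_off_switch():
    g = Grid(96, 96, 48.0, 48.0)
    st = equilibrium_circle(g, 8.0, 2.0)
    shell = init_eggshell(g, 12.0, 12.0, 0.0)  # cell strictly inside
    fx, fy = eggshell_force(g, st.phi, shell.phi_s, 1000.0)
    # residual comes only from the exponential tails of phi and phi_s
    assert norm_max(fx, fy) < 1e-4
    # overlap, but M_s = 0 (eggshell removal experiment): still zero
    tight = init_eggshell(g, 7.0, 7.0, 0.0)
    fx, fy = eggshell_force(g, st.phi, tight.phi_s, 0.0)
    assert norm_max(fx, fy) == 0.0
    # overlap with M_s > 0: force points inward on the overlap region
    fx, fy = eggshell_force(g, st.phi, tight.phi_s, 10.0)
    gx, gy = g.grad(st.phi)
    overlap = (st.phi * tight.phi_s**2 > 1e-3) & (np.hypot(gx, gy) > 0.05)
    assert np.all((fx * gx + fy * gy)[overlap] > 0)


def test_actomyosin_force_structure():
    g = Grid(128, 128, 64.0, 64.0)
    st = equilibrium_circle(g, 12.0, 2.0)
    # uniform m: aligned (c_g) term contributes nothing
    m_uniform = np.full(g.shape, 0.7)
    f_iso = actomyosin_force(g, st.phi, m_uniform, 10.0, 0.0)
    f_both = actomyosin_force(g, st.phi, m_uniform, 10.0, 500.0)
    assert np.allclose(f_iso[0], f_both[0], atol=1e-9)
    # m = 0: no force at all
    f0 = actomyosin_force(g, st.phi, np.zeros(g.shape), 10.0, 500.0)
    assert norm_max(*f0) < 1e-12
    # tanh step in m (made periodic as a stripe: steps at y = +-10): the
    # aligned term peaks at the step midpoint with magnitude
    # c_g * max|grad m| = c_g/(2w) for amplitude 1, width w
    _, Y = g.meshgrid()
    w = 3.0
    m_step = 0.25 * (1 + np.tanh((Y + 10.0) / w)) * (
        1 + np.tanh((10.0 - Y) / w))
    fx, fy = actomyosin_force(g, st.phi, m_step, 0.0, 1.0)
    # the force is magnitude c_g |grad m| along a unit normal, so its peak
    # over the band equals c_g * max|grad m| = 1/(2w)
    gx, gy = g.grad(st.phi)
    band = np.hypot(gx, gy) > 0.3
    assert np.max(np.hypot(fx, fy)[band]) == pytest.approx(1.0 / (2 * w),
                                                           rel=0.05)


def test_tension_laplace_scaling_with_radius():
    """Interface-integrated tension force on a circle scales like 1/R."""
    g = Grid(256, 256, 96.0, 96.0)
    mags = []
    for R in (10.0, 20.0):
        st = equilibrium_circle(g, R, 2.0)
        fx, fy = tension_force(g, st.phi, np.zeros(g.shape), 1.0, 0.0, 2.0)
        # net prefactor integrated across the band, per unit arc length
        mags.append(g.integrate(np.hypot(fx, fy)) / (2 * np.pi * R))
    assert mags[0] / mags[1] == pytest.approx(2.0, rel=0.05)


def test_total_is_sum_of_parts():
    g = Grid(96, 96, 90.0, 90.0)
    st = init_ellipse_phase_field(g, 15.0, 25.0, 3.0)
    _, Y = g.meshgrid()
    m = 0.4 + 0.3 * np.tanh(Y / 4.0)
    shell = init_eggshell(g, 15.0, 25.0, 2.0)
    mech = MechParams(kappa=5.0, gamma=2.0, c_T=10.0, M1=12.0, M_s=100.0,
                      c_m=100.0, c_g=500.0, epsilon=3.0)
    mech.alpha = st.area() - 5.0
    tx, ty = total_membrane_force(g, st.phi, m, mech, shell)
    parts_x = np.zeros(g.shape)
    parts_y = np.zeros(g.shape)
    for fx, fy in (
        bending_force(g, st.phi, mech.kappa, mech.epsilon),
        tension_force(g, st.phi, m, mech.gamma, mech.c_T, mech.epsilon),
        volume_force(g, st.phi, mech.M1, mech.alpha),
        eggshell_force(g, st.phi, shell.phi_s, mech.M_s),
        actomyosin_force(g, st.phi, m, mech.c_m, mech.c_g),
    ):
        parts_x += fx
        parts_y += fy
    assert np.allclose(tx, parts_x) and np.allclose(ty, parts_y)
    # with only M1 active it reduces to the volume force
    mech0 = MechParams(kappa=0.0, gamma=0.0, c_T=0.0, M1=12.0, M_s=0.0,
                       c_m=0.0, c_g=0.0, epsilon=3.0)
    mech0.alpha = mech.alpha
    tx0, ty0 = total_membrane_force(g, st.phi, m, mech0, shell)
    vx, vy = volume_force(g, st.phi, 12.0, mech0.alpha)
    assert np.allclose(tx0, vx) and np.allclose(ty0, vy)


def test_forces_vanish_away_from_interface():
    g = Grid(96, 96, 48.0, 48.0)
    st = equilibrium_circle(g, 10.0, 2.0)
    X, Y = g.meshgrid()
    m = 0.5 + 0.2 * np.cos(2 * np.pi * Y / g.Ly)  # periodic AP-like gradient
    # bending involves 4th derivatives whose spectral ringing is global at
    # the ~1% level; the locality property is about the force model, so
    # check it with bending off and a modest ringing allowance
    mech = MechParams(kappa=0.0, alpha=st.area() - 20.0, epsilon=2.0)
    fx, fy = total_membrane_force(g, st.phi, m, mech, None)
    far = np.hypot(X, Y) < 5.0  # deep interior, |grad phi| ~ 0
    assert np.max(np.hypot(fx, fy)[far]) < 3e-3 * np.max(np.hypot(fx, fy))


def test_energy_decay_under_gradient_flow():
    """Each energy-derived force corresponds to an interface energy that
    decreases under gradient-flow relaxation of phi (u = 0)."""
    g = Grid(96, 96, 48.0, 48.0)
    eps = 2.0

    def tension_energy(phi):
        gx, gy = g.grad(phi)
        return g.integrate(0.5 * eps * (gx**2 + gy**2)
                           + double_well(phi) / eps)

    def bending_energy(phi):
        w = eps * g.laplacian(phi) - double_well_prime(phi) / eps
        return g.integrate(0.5 / eps * w**2)

    def volume_energy(phi, alpha):
        return (g.integrate(phi) - alpha) ** 2

    def shell_energy(phi, phi_s):
        return g.integrate((phi * phi_s) ** 2)

    shell = init_eggshell(g, 8.0, 8.0, 0.0)

    # start from a perturbed circle and relax each functional separately
    st = equilibrium_circle(g, 9.0, eps)
    rng = np.random.default_rng(1)
    phi0 = np.clip(st.phi + 0.05 * g.dealias(rng.normal(size=g.shape))
                   * (st.phi * (1 - st.phi)) * 4, -0.2, 1.2)
    alpha = g.integrate(phi0) - 15.0

    def bending_var(p):
        # dE/dphi = eps (lap - G''/eps^2)(lap p - G'/eps^2)
        w = g.laplacian(p) - double_well_prime(p) / eps**2
        return eps * (g.laplacian(w)
                      - (36 * (6 * p**2 - 6 * p + 1)) * w / eps**2)

    cases = {
        # each entry: (energy functional, its variational derivative dE/dphi)
        "tension": (tension_energy,
                    lambda p: -(eps * g.laplacian(p)
                                - double_well_prime(p) / eps)),
        "bending": (bending_energy, bending_var),
        "volume": (lambda p: volume_energy(p, alpha),
                   lambda p: 2.0 * (g.integrate(p) - alpha)
                   * np.ones(g.shape)),
        "shell": (lambda p: shell_energy(p, shell.phi_s),
                  lambda p: 2.0 * p * shell.phi_s**2),
    }

    # explicit gradient-flow steps: dt below each functional's stiffness
    # bound (volume couples globally, rate ~ 2 * domain area)
    dts = {"tension": 1e-3, "bending": 1e-5,
           "volume": 0.2 / (2 * g.Lx * g.Ly), "shell": 1e-3}
    for name, (energy, var) in cases.items():
        phi = phi0.copy()
        e_prev = energy(phi)
        dt = dts[name]
        for _ in range(20):
            phi = phi - dt * var(phi)
            e = energy(phi)
            assert e <= e_prev + 1e-9 * abs(e_prev), name
            e_prev = e
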