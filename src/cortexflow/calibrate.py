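"""Scripted verification of the calibrated parameter set.

Experimental measurements of cortical forces and kinetic rates are not
available for this system, so the package ships calibrated defaults.  This
module makes the calibration reproducible and checkable: it verifies, from
scratch, the properties the defaults were chosen for:

1. the well-mixed reaction network is bistable, with an anterior-high and a
   posterior-high stable state and strong actomyosin contrast between them;
2. the actomyosin transport model is linearly stable (nu * max(m) < D_m,
   since self-advection by the tension gradient acts as anti-diffusion);
3. a 1-D cortex transect propagates a polarization front toward the anterior
   at a speed that crosses half an embryo length on the establishment-phase
   timescale;
4. (optional, slow) a full 2-D run of the wild-type configuration produces a
   bounded travelling furrow that reaches mid-cell.

Run via ``cortexflow calibrate`` or call :func:`calibration_report`.
"""

from __future__ import annotations

import numpy as np

from .params import CytoplasmicPools, KineticParams
from .species import bistable_steady_states, reaction_rhs

__all__ = ["front_speed_1d", "calibration_report"]


def front_speed_1d(
    kin: KineticParams,
    pools: CytoplasmicPools,
    length: float = 128.0,
    n: int = 512,
    t_end: float = 3000.0,
    zone_half_width: float = 20.0,
) -> float:
    """Polarization front speed on a 1-D periodic cortex transect (um/s).

    A posterior-state zone of the given half-width is embedded in the
    anterior state, actomyosin starts uniformly high, and the front position
    (half-maximum crossing of total anterior PAR) is tracked; returns the
    linear-fit speed over the second half of the run.  Positive = the
    posterior domain expands (the front travels anteriorly).
    """
    high, low = bistable_steady_states(kin, pools)
    dx = length / n
    x = np.arange(n) * dx - length / 2
    k = 2.0 * np.pi * np.fft.rfftfreq(n, d=dx)

    def ddx(f):
        return np.fft.irfft(1j * k * np.fft.rfft(f), n)

    def lap(f):
        return np.fft.irfft(-(k**2) * np.fft.rfft(f), n)

    dmax = max(kin.Dpa, kin.Dpp, kin.Dm)
    dt = 0.7 * 2.0 / (dmax * (np.pi / dx) ** 2)
    zone = (0.5 * (1 + np.tanh((x + zone_half_width) / 2.0))
            * 0.5 * (1 + np.tanh((zone_half_width - x) / 2.0)))
    names = ("a1", "a10", "a11", "p", "m")
    f = {nm: getattr(high, nm) + (getattr(low, nm) - getattr(high, nm)) * zone
         for nm in names}
    f["m"] = np.full(n, 0.7)
    D = {"a1": kin.Dpa, "a10": kin.Dpa, "a11": kin.Dpa,
         "p": kin.Dpp, "m": kin.Dm}
    half = 0.5 * (high.anterior_total + low.anterior_total)
    times, fronts = [], []
    nt = int(t_end / dt)
    sample_every = max(1, nt // 40)
    for it in range(nt):
        v = kin.nu * ddx(f["m"])
        rates = reaction_rhs(f["a1"], f["a10"], f["a11"], f["p"], f["m"],
                             pools, kin)
        for i, nm in enumerate(names):
            f[nm] = np.maximum(
                f[nm] + dt * (D[nm] * lap(f[nm]) - ddx(v * f[nm]) + rates[i]),
                0.0,
            )
        if it % sample_every == 0:
            at = f["a1"] + f["a10"] + f["a11"]
            cross = np.where((at[:-1] - half) * (at[1:] - half) < 0)[0]
            xs = [x[i] + dx * (half - at[i]) / (at[i + 1] - at[i])
                  for i in cross if x[i] > 0]
            if xs:
                times.append(it * dt)
                fronts.append(min(xs))
    times = np.asarray(times)
    fronts = np.asarray(fronts)
    sel = times > 0.5 * times[-1]
    if sel.sum() < 3:
        raise RuntimeError("front lost before speed could be measured")
    return float(np.polyfit(times[sel], fronts[sel], 1)[0])


def calibration_report(kin: KineticParams | None = None,
                       pools: CytoplasmicPools | None = None,
                       front_check: bool = True) -> dict:
    """Verify the calibrated kinetic defaults; returns the measured numbers.

    Raises AssertionError with a descriptive message if a calibration
    property fails, so the check is usable as a test and from the CLI.
    """
    kin = kin or KineticParams()
    pools = pools or CytoplasmicPools()
    high, low = bistable_steady_states(kin, pools)
    report = {
        "anterior_state": vars(high).copy() if hasattr(high, "__dict__") else {
            n: getattr(high, n) for n in ("a1", "a10", "a11", "p", "m")},
        "posterior_state": {
            n: getattr(low, n) for n in ("a1", "a10", "a11", "p", "m")},
        "m_contrast": high.m / max(low.m, 1e-12),
        "anti_diffusion_margin": kin.Dm / max(kin.nu * high.m, 1e-12),
    }
    assert high.anterior_total > 3 * low.anterior_total, \
        "anterior PAR contrast too weak"
    assert low.p > 3 * high.p, "posterior PAR contrast too weak"
    assert report["m_contrast"] > 2, "actomyosin contrast too weak"
    assert report["anti_diffusion_margin"] > 1.2, (
        "nu too large: actomyosin self-advection (anti-diffusion nu*m) is "
        "not safely below D_m"
    )
    if front_check:
        speed = front_speed_1d(kin, pools)
        report["front_speed_um_per_s"] = speed
        assert speed > 0, "front must travel anteriorly"
        # half an embryo length (~20 um) within roughly the establishment
        # phase (a few thousand seconds)
        assert 0.002 < speed < 0.02, (
            f"front speed {speed:.4f} um/s outside the establishment-phase "
            "range"
        )
    return report
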