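# Methods

`cortexflow` simulates the establishment phase of anterior–posterior
polarization in the early *C. elegans* zygote as a coupled mechanochemical
system: a five-species reaction–advection–diffusion model of cortical PAR
proteins and actomyosin, living on a deforming cell cortex represented by a
phase field, with the cortex driven by bending, tension, volume-constraint,
eggshell-penalty and actomyosin-contractility forces through a viscous
(Stokes–Brinkman) momentum balance.

## Model

### Cortical biochemistry

Five dimensionless cortical concentrations evolve on the membrane: anterior
PAR monomers `a1`, singly and doubly bound anterior dimers `a10`, `a11`,
posterior PAR `p`, and actomyosin `m`. Cytoplasmic pools are at quasi-steady
state and enter as constant source levels. Interactions are mass action:
anterior species bind from the cytoplasm, dimerize (the `a1^2` dimerization
supplies the nonlinearity that makes the well-mixed network bistable), and
are removed by posterior PAR (`r_A p·a_i`); posterior PAR binds from the
cytoplasm and is removed by the anterior module (`r_P (a1+a10+2 a11) p`);
actomyosin assembly is inhibited by posterior PAR through a saturating
factor `k_P/(k_P + p)`. All species diffuse on the cortex and are advected
by the cortical flow `v_c = nu * grad m`, the transport by tension
gradients that segregates the anterior module.

Two homogeneous stable states coexist (anterior-high / posterior-high); the
initial condition places a posterior-state zone below `y = K0 = -15 um` with
tanh-step profiles and uniform actomyosin `m = 0.7`, mimicking the sperm cue.
Polarization proceeds as a front between the two states travelling
anteriorly at ~0.005–0.01 um/s.

A structural property of this transport model worth knowing: because `m` is
advected by the gradient of its own concentration, the advection acts on `m`
as *anti-diffusion* with coefficient `nu*m`. Linear stability of the model
itself (not merely of a scheme) requires `nu * max(m) < D_m`; the defaults
satisfy this with a ~2.2x margin, and `calibrate` checks it.

### Membrane mechanics

The cell is the region `phi = 1` of a phase field with diffuse-interface
width `eps` (default 2 um); the membrane is the `phi = 0.5` level set.
`phi` is advected by the deformation velocity `u` and relaxed by
curvature-stabilized Allen–Cahn dynamics (relaxation coefficient `Gamma`),
which maintains the equilibrium `tanh(3 d / eps)` cross-section without
imposing curvature-driven shrinkage — closed interfaces are stationary under
relaxation alone, so all membrane motion is force-driven.

`u` solves `div[eta (grad u + grad u^T)] - xi u + F = 0` with
`eta = eta_m m 4 phi(1-phi) + eta_c phi` (cortex more viscous than
cytoplasm, cortical viscosity proportional to actomyosin) and drag `xi`.
There is no pressure/incompressibility constraint; area conservation is
enforced by the volume-penalty force. The five force densities are the
variational bending, tension (`gamma + c_T m`), area-penalty and
eggshell-penalty forces plus the contractility force
`(c_m m + c_g |grad m|) n` along the inward normal — the isotropic
("cross-linked") part proportional to actomyosin and the furrow-localized
("aligned") part proportional to its gradient. The eggshell is a fixed
ellipse inflated from the initial membrane by the clearance `e_d`.

## Parameters

Experimental values for the cortical forces and most rate constants are not
available, so the defaults are *calibrated*, once, by a scripted procedure
(`cortexflow.calibrate`, exercised by the test suite):

* **Kinetics.** A randomized log-space scan located a bistable mass-action
  parameter set with O(1) plateau concentrations and strong reciprocal
  contrast; exact rescalings in time (all rates by a common factor) and
  space (diffusivities) then set the polarization-front speed to cross half
  an embryo length on the tens-of-minutes establishment-phase timescale
  while keeping the front width resolvable (~2 um). The frozen defaults give
  anterior/posterior actomyosin ~0.68/0.12 and a 1-D front speed of
  ~0.005 um/s.
* **Mechanics.** `xi` and `M1` are set together so the area-constraint
  response is stable at the operating time step while holding the enclosed
  area within 1% (equilibrium area deficit `~F_contract/M1 < 1%`);
  `eta_m/eta_c = 10` expresses the cortex/cytoplasm viscosity contrast; with
  the aligned contractility fixed at `c_g = 500` the remaining coefficients
  were chosen so the default run reproduces the canonical wild-type
  phenotype: a pseudocleavage furrow forming at the actomyosin gradient,
  deepening while travelling with the PAR interface, reaching mid-cell, with
  the posterior membrane supported by the eggshell.

All parameters are plain config fields; each run records which values were
user-supplied vs calibrated defaults.

## Numerics

Uniform periodic grid, Fourier-spectral derivatives, 2/3-rule dealiasing of
nonlinear products. Per coupling step (operator splitting, first order):
species step on the frozen membrane, then forces, momentum solve, membrane
step, with the time step adapted to the advective CFL bound (cap 1–2 s).

* **Diffuse-domain species transport.** Each species is extended to the
  whole grid and evolved as
  `ds/dt = [div(W D grad s) - div(W chi v_c s)]/W + R(s)` with
  `W = G(phi) + 0.05` the floored double-well weight and `chi = G/W` the
  band mask on the advective velocity. The conservative flux form conserves
  the interface-weighted mass `int W s dx` to machine precision (reactions
  off); off-band values are refreshed each step by a constant-normal
  extension (nearest band point via a distance transform). The floor cannot
  be made arbitrarily small: dividing the spectrally computed flux
  divergence by `W` amplifies its discretization error by `1/W` off the
  band. The band mask on `v_c` is required because off the cortex nothing
  anchors `m`, and its self-advection (anti-diffusion) would run away.
  Explicit stepping, automatically substepped to the spectral diffusion
  stability bound `dt < 2 dx^2/(D pi^2)`.
* **Membrane step.** Lie splitting: an undamped explicit advection step,
  then a semi-implicit relaxation step with the Laplacian treated exactly
  per mode and a stabilization shift `S = Gamma max|G''|/eps` that makes the
  explicitly treated double-well term non-expansive at any `dt`. The shift
  time-lags only the relaxation dynamics (profile restoration remains far
  faster than the physical deformation); folding the advection into the
  shifted update would wrongly slow all force-driven motion, which is why
  the steps are split.
* **Curvature clamp.** The stabilization term `c eps |grad phi|` is derived
  in the thin-interface limit `eps|c| << 1`; where two interface walls
  approach within the diffuse width (a deep furrow) the discrete normal
  field reverses over a cell and the raw `c` spikes. `|c|` is clamped at
  `1/eps`, keeping the term inert exactly where its derivation has broken
  down. Without the clamp, deep-furrow runs at reduced resolution fail.
* **Normal-direction forces.** The `grad phi/|grad phi|` force terms are
  tapered by `|grad phi|^2/(|grad phi|^2 + 0.05^2)`: with a raw tiny-sigma
  regularization they would keep full amplitude with a noise direction
  wherever `grad phi` is at roundoff or spectral-ringing level.
* **Momentum solve.** Conjugate gradients on the symmetric positive
  definite (negated) operator, preconditioned by the exact per-mode inverse
  of the constant-coefficient (mean-viscosity, drag) symbol; warm-started
  from a linear extrapolation of the two previous solutions. Relative
  residual 1e-5 in production runs (1e-8 available and used by the solver
  tests; velocities are ~1e-2 um/s, so either tolerance is far below
  physical scales).

### Run profiles and problem sizes

The default profile is 256^2 cells on the 90 um box with `eps = 2` and
`dt = 1 s`. The tests and the acceptance script use the fast profile
(96^2 cells, 72 um box — the same grid spacing class — `eps = 3`,
`dt = 2 s`): a full establishment-phase trajectory then takes ~1.5–4 minutes
on one core. The interface width must remain ~4 grid cells: `eps = 2` at
0.7 um spacing is numerically unresolvable (verified directly), which is why
the reduced profile widens the interface instead of only coarsening the
grid. Halving `dt` changes the early trajectory at the splitting-error
level (tested).

## Measurements

The membrane contour is extracted by marching squares at `phi = 0.5`
(sub-cell accurate, counterclockwise, topology-checked). A furrow is a
*localized* contour arc (under a quarter of the perimeter) displaced inward
from the t = 0 membrane by more than 0.2 um; depth is the maximum inward
normal displacement over such arcs, so whole-domain shrinkage does not
count. The travelling pseudocleavage furrow is followed by restricting
candidates to a window around the previously tracked position (transient
dents, e.g. at the poles during the initial contraction, are thereby
ignored). `T_pol` is the first time the tracked position — furrow bottom
when a furrow exists, otherwise the steepest point of the total-anterior-PAR
profile along the membrane — crosses the current contour's AP midpoint
(sampling cadence 50 s, linear interpolation).

Behavior classification (thresholds are package defaults; the source model
provides none): *runaway invagination* if the furrow exceeds 8 um and is
still deepening at the end of the record, or the run halts on furrow
self-contact; *anterior collapse* if the anterior area share falls below
0.7 of its initial value with a furrow under 1 um; otherwise *wild type*.

## Behavior of the calibrated model, and known limitations

On the fast profile the defaults give: wild type (`e_d = 5.5`) polarizing
with a travelling furrow; sub-threshold furrowing at `e_d = 0.5` (no
peri-vitelline space); monotone `T_pol` decrease and (pre-`T_pol`)
furrow-depth increase with `e_d` over [1, 6.25]; much faster polarization
with an expanded posterior domain when the eggshell is removed (`M_s = 0`);
and, across the contractility plane at fixed `c_g = 500`, furrow depth
decreasing monotonically with `c_m`, from a deep (~4-6 um) bounded furrow
at low `c_m` through wild type to anterior collapse at `c_m = 240`.

Limitations to keep in mind:

* **No runaway invagination within `c_g <= 800`.** With the area constraint
  held to 1% (a stated structural requirement), furrow depth is
  geometrically capped near the eggshell clearance: the displaced area must
  reappear as an outward bulge, and the shell blocks it. An unboundedly
  deepening furrow requires letting the enclosed area yield by several
  percent. Under the calibrated defaults the high-`c_g`/low-`c_m` corner
  produces a deep furrow that saturates (~4.6 um) and later regresses, and
  is classified wild type. The corresponding acceptance test records this
  as a failing assertion by design.
* **`T_pol` decreases with `c_m` here.** Strong isotropic contraction
  shrinks the anterior domain and moves both the interface and the cell
  midpoint, completing polarization sooner. Reports of the opposite trend
  exist for other parameterizations of the same force structure; the
  behavior is calibration-dependent.
* **Near-zero clearance slows polarization only mildly.** At `e_d = 0.5`
  the furrow is suppressed (depth series below the detection threshold) and
  `T_pol` is comparable to wild type, rather than strongly extended;
  the strong slow-down reported for other parameterizations is coupled to
  the furrow's contribution to interface motion, which is weak here.
* The 2-D cross-section geometry cannot represent ruffles, tangential
  cortical buckling, or anisotropic tension; topology changes (furrow
  self-contact) are detected and halt the run rather than being evolved.
* The synthetic experiments are fully deterministic; the only randomness in
  the package is the optional parameter-perturbation sweep. Passing tests
  demonstrate internal consistency and the stated qualitative phenomenology
  at the stated resolutions, not quantitative agreement with measurements on
  real embryos.
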