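# Methods

## The model

`polarmix` simulates a two-dimensional continuum model of a confluent
monolayer containing two epithelial cell populations (A and B) with
intrinsically different mechanics.  Three fields live on a periodic
square of side `L`:

* a conserved phase field `phi(r, t)` labelling cell type (`+1` pure A,
  `-1` pure B), evolving by advected Cahn–Hilliard dynamics
  `d_t phi + v.grad phi = M lap mu`,
  `mu = -a (1 - phi^2) phi - K_phi lap phi`;
* a polarity vector `p(r, t)` giving the direction of active cell
  migration, `d_t p + (v.grad) p = -Omega p + kappa D p - Gamma H`,
  `H = -a_p (p0 - |p|^2) p - K_p lap p`;
* an incompressible velocity field from the friction-damped Stokes
  balance `div(nu grad v) - grad P + div sigma^e + alpha p - xi v = 0`,
  `div v = 0`, where the self-propulsion `alpha p` is the only active
  force and `-xi v` is substrate friction.

Cell-type-specific coefficients interpolate linearly,
`alpha = alpha_A (1+phi)/2 + alpha_B (1-phi)/2` (same for `nu`); all
other coefficients are constant, and derivatives of the phi-dependent
coefficients are not included in `mu`.  The elastic stress
`sigma^e = sigma^p + sigma^phi` with

    sigma^p_ij = 1/2 (p_i H_j - H_i p_j) - kappa/2 (p_i H_j + H_i p_j)
                 - K_p d_i p_k d_j p_k
    sigma^phi_ij = -K_phi d_i phi d_j phi .

The isotropic part of `sigma^phi` (`(f - phi mu) I`) is omitted: under
incompressibility any isotropic elastic contribution is absorbed into
the pressure gauge.

### Parameters and units

Defaults (simulation units; `time_unit = 10 min`, `length_unit = 10 um`):

| symbol | value | meaning |
|---|---|---|
| `a`, `K_phi` | 0.1, 0.05 | phase well / stiffness; interface width `sqrt(K_phi/2a)` = 0.5 (5 um) |
| `a_p`, `K_p` | 0.1, 1.0 | polar well / alignment; polar correlation `sqrt(K_p/2a_p)` ~ 22 um |
| `M`, `Gamma` | 10, 5 | mobilities: `(M a)^-1` = 10 min, `(a_p Gamma)^-1` = 20 min |
| `alpha_A`, `alpha_B` | 1.0, 0.5 | self-propulsion; intrinsic speeds `alpha/xi` = 1.0 / 0.5 um/min |
| `nu_A`, `nu_B` | 5, 10 | viscosities; flow screening length `sqrt(nu/xi)` ~ 27 um |
| `xi`, `kappa`, `p0` | 1.0, 0.7, 1 | friction, flow alignment (rod-like), polar set-point |
| `L`, `dt` | 50, 1e-2 | domain side (500 um), time step |

The weak-alignment variant `K_p = 2e-2` (polar correlation ~ 3 um) is a
first-class condition of the study design.

### A note on the free energy and the molecular field

The molecular field used by the dynamics,
`H = -a_p (p0 - |p|^2) p - K_p lap p` with `p0 = 1`, carries the local
term at half the weight of the strict variational derivative of the
quartic polar well `(a_p/2)(1 - |p|^2)^2` (which is
`-2 a_p (1 - |p|^2) p`).  Both forms appear in the governing-equation
literature; `polarmix` keeps the free energy and the molecular field
exactly as written above and treats them as independent definitions.
Consequences: the chemical potential `mu` is the exact variational
derivative of the phi part of `F` (verified by a node-by-node
perturbation oracle); for `p` only the gradient (`K_p`) part of `H` is
variational, and the linearized magnitude-relaxation rate is
`2 Gamma a_p` (e-folding 10 min) while the conventional scale quoted for
polarity formation is `(a_p Gamma)^-1 = 20 min`.  Tests validate the
measured rate against the independently linearized value, not the
quoted scale.  The passive free-energy decay test is empirical: the
dynamics is not an exact gradient flow of `F` in the polar sector, but
monotone decay holds at the default parameters and is asserted per step.

### Velocity-gradient convention

`D` and `Omega` are built from `(grad v)_ij = d_i v_j`.  The index
order is not a matter of taste: it is fixed by requiring that the
co-rotation term `-Omega p` transports polarity *with* the local
vorticity (a rigid rotation must carry a material vector along).  The
opposite order makes polarity counter-rotate, which suppresses the
vortical velocity patterns this model is meant to produce and instead
drives rapid global polar ordering — qualitatively changing the
segregated-state behaviour.  A dedicated test checks co-rotation on an
analytic vortex.  The viscous stress is stored as
`sigma^visc_ij = nu d_j v_i`, the form whose row-divergence reproduces
the force-balance term `d_j (nu d_j v_i)`.

## Discretization

Pseudo-spectral on a uniform periodic `N x N` grid; all derivatives via
real FFTs.  Choices that carry contracts:

* **Nyquist handling.**  First-derivative operators zero the Nyquist
  wavenumber (the odd derivative of the self-conjugate mode is not
  representable for a real field); `k^2` is built from the same zeroed
  wavenumbers so `div(grad f) = lap f` holds exactly — the identity the
  Stokes residual shortcut and the traction/stress consistency contract
  rely on.  Random initial fields are band-limited (2/3 rule) so no
  content sits in the undamped Nyquist lines.
* **De-aliasing.**  Nonlinear products in the transport equations are
  truncated by the 2/3 rule (built from the raw wavenumbers, so the
  Nyquist lines are always removed).  The Stokes path is left
  un-aliased so that the reported momentum residual is exactly the
  residual of the discrete equations being solved.
* **Time stepping.**  IMEX: Crank–Nicolson on the stiff linear terms
  (`-M K_phi lap^2 phi`, `Gamma K_p lap p`), two-stage Heun on the
  advective and local nonlinear terms; second-order overall.  Oracles:
  the linearized Cahn–Hilliard dispersion rate `M k^2 (a - K_phi k^2)`
  to 5%, advection of a stationary interface profile around the
  periodic box to L2 error < 1e-3, and the flow-alignment ODE against
  an independent integrator to 1e-4.  The advective CFL bound
  `max|v| dt / h <= 0.5` is enforced with an error.
* **Conservation.**  The phase advection is written in conservative
  form `-div(v phi)`; every spectral update term vanishes at `k = 0`,
  so the phase integral is conserved to machine precision.
* **Stokes solve.**  Viscosity is split `nu = nu_bar + dnu(phi)` around
  the arithmetic mean; each Picard pass solves the constant-coefficient
  Stokes–Brinkman system exactly (Leray projection enforces
  `div v = 0` spectrally; friction fixes the mean flow; `P` has zero
  mean).  The iteration contracts with ratio `max|dnu|/nu_bar = 1/3`
  at the default viscosity contrast and is warm-started from the
  previous step (typically 3 iterations to a 1e-8 relative residual).
  Because the constant-coefficient solve is exact, the full momentum
  residual equals the change in the lagged `dnu` correction; a test
  verifies this against the independently assembled residual.

### Problem sizes

Default grid `N = 128` (`h = 0.39`).  The production physics runs used
by the tests and the acceptance script use `N = 64` (`h = 0.78`;
the equilibrium interface profile `tanh(x/2w)` has scale `2w = 1.0`,
so the interface is resolved while nine production runs stay desk-scale),
`T_end = 60` time units (600 min), `dt = 1e-2`, three seeds in the test
suite and two in the acceptance script.  The grid constructor rejects
`h > 2w`.

## Synthetic data

The generators define the study conditions; all are pure functions of
(spec, seed).

* **Mixed initial condition** — band-limited uniform phase noise,
  rescaled to amplitude 0.1 and exactly mean-centred (1:1 composition);
  the amplitude is small enough for spinodal dynamics to select the
  pattern and large enough to break symmetry quickly.  Polarity:
  band-limited random directions at rms `|p| = 0.1` (`small_noise`
  default; `unit_random` with rms 1 offered).
* **Segregated initial condition** — two vertical stripes of width
  `L/2` joined by equilibrium `tanh(x/2w)` interfaces; orientation is
  immaterial under periodicity and isotropy (a mirror-parity test on
  the full solver backs this).
* **Stress/traction pairs** — finite sums of Fourier modes with
  symmetric tensor amplitudes and *analytically* differentiated
  tractions.  The random generator draws amplitudes of the form
  `sym(t (x) k)`, which span the Frobenius-orthogonal complement of the
  divergence-free tensor null space: a component in that null space is
  invisible to any `div sigma = T` inversion, so recoverability is a
  property of the fixture, not a tuning of the method.  User-supplied
  amplitudes may include null-space components.
* **Mask/stress fixtures** — thresholded smoothed noise masks with a
  stress map graded linearly in boundary distance plus Gaussian noise;
  slope 0 is the null fixture.
* **Intensity traces** — Gaussian baselines with planted spikes of a
  chosen size in baseline standard deviations.

What the generators do *not* emulate: microscope noise, bead images,
PIV artefacts, segmentation errors, cell division, or any experimental
stress scale — passing tests demonstrate internal consistency of the
method chain on clean inputs, not performance on raw microscopy data.

## Stress inference

`div sigma = T` is inverted per Fourier mode by Tikhonov-regularized
least squares, `min |div sigma - T|^2 + reg_lambda |sigma|_F^2` over
the three independent components of the symmetric tensor (Frobenius
norm counts `sigma_xy` twice).  The per-mode normal equations are 3x3;
the `k = 0` tensor (null space of div) is gauged to zero mean.  The
default `reg_lambda = 1e-6` is a numerical floor, not a smoothing
scale: on noise-free recoverable fixtures the bias is O(`reg_lambda`).
At `reg_lambda = 0` the solve refuses (singular null-space direction
per mode).  Periodic boundaries only — the simulator and all fixtures
are periodic; no free-boundary dialect is implemented (documented
limitation).  The divergence operator is the same spectral family as
the simulator, so inverting the model's own traction `xi v - alpha p`
reproduces the simulator stress up to the per-mode gauge freedom; the
isotropic map is compared by correlation, per-phase differences of
`sigma_iso` being the gauge-independent readout.

The simulator-side isotropic stress is `-P + tr(sigma^e)/2` (viscous
stress is traceless under incompressibility); the deviatoric magnitude
uses the symmetric part of the total stress.  The closed form
`|lambda_dev| = sqrt(((sxx-syy)/2)^2 + sxy^2)` is checked against a
general-purpose eigensolver on 1e4 random tensors.

## Observables

* **Phase averages** use smooth weights `(1 +- phi)/2` — exact on
  plateaus, differentiable across interfaces.  With equilibrium
  interfaces of scale `2w` the indicator cross-talk is O(8w/L).
* **Convergence index** `r` = time-mean speed of A / time-mean speed of
  B over the final quarter of the run.  "Mean velocity" is read as mean
  speed `<|v|>` (the magnitude of `<v>` of a disordered field can
  vanish spuriously).
* **Total traction magnitude** `|F| = integral |T| dA` by the grid
  quadrature.
* **Boundary-distance correlation**: boundary nodes are nodes with a
  4-neighbour of the opposite type (periodic); distances by Euclidean
  distance transform on a 3x3 tiling; Pearson R with R^2 reported and
  the sign tracked.  On simulation output the analysis applies to
  `sigma_iso` (the quantity the model analysis reports, and which shows
  no strong distance dependence).  The deviatoric magnitude is not a
  meaningful target for this analysis in a diffuse-interface model:
  `sigma^phi` is an anisotropic interface tension, so `|lambda_dev|` is
  concentrated at cell-type boundaries by construction.
* **Spark detection**: per-cell baseline mean/sd by iterative 3-sigma
  clipping (converging to the spark-free statistics; a single 6-sd
  spike inflates a naive full-trace sd by ~17%, which would make
  recovery of a planted 6-sd event a coin flip at the 5-sd threshold —
  the clipped baseline makes the detector's contract deterministic).
  `plain` (full-trace) and `robust` (median/MAD) modes are exposed.
  Consecutive supra-threshold frames merge into one event at the peak.
* **Domain size** = `L^2 / interface length`, with the interface length
  measured as `integral |grad phi| dA / 2` (a saturated interface
  contributes `integral dphi = 2` per unit length).  This is the
  stereological area-per-interface-length: two stripes of width `L/2`
  give `L/2`.  Near-uniform fields report `L` with a degenerate flag.

## Known limitations

* Periodic boundaries only; no confinement, division/growth, nematic
  variant, or more than two cell types.
* The inversion replaces the Bayesian machinery of monolayer stress
  microscopy with explicit Tikhonov regularization; posterior
  covariances are out of scope.
* Stress scales are reported in simulation units; the unit map fixes
  length, time and velocity only.
* The deterministic model has no active noise term, so the polarity
  field eventually orders globally (by t ~ 10-30 time units at
  `K_p = 1`) at an angle set by the initial noise.  In the segregated
  geometry, incompressibility makes the cross-stripe velocity component
  uniform across stripes, so the measured speed contrast depends on
  that angle: along-stripe order gives a ratio near the intrinsic value
  (~1.7 at `L = 50` with soft phase weights), cross-stripe order gives
  exactly 1, and the cross-stripe state is the unique torque-free
  attractor (no shear layers), toward which the contrast slowly decays.
  The segregated run therefore retains a seed-dependent partial
  contrast over a 600-minute window (measured final-quarter ratios
  1.06-1.40 across seeds) rather than a fixed one; the strict ordering
  "mixed converges more than segregated" holds in every seed.  A
  fluctuating tissue, or any mechanism that arrests polar ordering,
  would keep the contrast closer to the intrinsic ratio.
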