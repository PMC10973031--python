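"""Time integration of the binary active-polar mixture on a periodic square.

The coupled system is

    d_t phi + v . grad phi = div(M grad mu)                (conserved phase)
    d_t p   + v . grad p   = -Omega p + kappa D p - Gamma H  (polarity)
    div(nu grad v) - grad P + div sigma^e + alpha p - xi v = 0   (force balance)
    div v = 0                                               (incompressibility)

Discretization choices (see docs/methods.md):

* pseudo-spectral in space on a uniform periodic grid, nonlinear products
  de-aliased by the 2/3 rule in the transport equations;
* semi-implicit (IMEX) time stepping: the stiff linear terms
  (-M K_phi lap^2 phi and Gamma K_p lap p) are integrated with
  Crank-Nicolson, the advective and local nonlinear terms explicitly
  with a two-stage Heun predictor-corrector (second order overall);
* quasi-static flow: the friction-damped Stokes problem is re-solved once
  per time step from the current phi, p by Picard iteration around a
  constant-coefficient solve (friction xi > 0 fixes the mean flow, the
  Leray projection enforces div v = 0 to machine precision).

The k = 0 mode of phi is untouched by every update term, so the phase
integral is conserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .energy import (
    elastic_stress_phase,
    elastic_stress_polar,
    free_energy,
    interpolate_coefficient,
    molecular_field,
    strain_vorticity,
)
from .fields import DerivedFields, FieldState
from .params import ModelParams
from .spectral import Grid

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "StokesConvergenceError",
    "CFLError",
    "solve_stokes",
    "stokes_residual",
    "advance_phase",
    "advance_polarity",
    "run_simulation",
    "model_traction",
    "compute_derived",
]

CFL_BOUND = 0.5  # max |v| dt / h admitted by the explicit advective stage


class StokesConvergenceError(RuntimeError):
    """Picard iteration for the variable-viscosity Stokes solve failed."""

    def __init__(self, residual: float, iters: int):
        self.residual = residual
        self.iters = iters
        super().__init__(
            f"Stokes solve did not reach tolerance in {iters} iterations "
            f"(relative residual {residual:.3e})"
        )


class CFLError(RuntimeError):
    """Advective CFL bound max|v| dt / h > 0.5 violated."""


def compute_derived(state: FieldState, params: ModelParams) -> DerivedFields:
    """All constitutive fields of a state in one call."""
    from .energy import chemical_potential

    grid = state.grid
    mu = chemical_potential(state.phi, params, grid)
    H = molecular_field(state.p, params, grid)
    D, Omega = strain_vorticity(state.v, grid)
    sig_p = elastic_stress_polar(state.p, H, params, grid)
    sig_phi = elastic_stress_phase(state.phi, params, grid)
    return DerivedFields(mu=mu, H=H, D=D, Omega=Omega, sigma_p=sig_p, sigma_phi=sig_phi)


# ---------------------------------------------------------------------------
# Stokes solve
# ---------------------------------------------------------------------------

def _elastic_force(phi, p, params, grid):
    H = molecular_field(p, params, grid)
    sig = elastic_stress_polar(p, H, params, grid) + elastic_stress_phase(
        phi, params, grid
    )
    return grid.tensor_divergence(sig)


def _constant_coefficient_solve(g, params, grid):
    """Solve (xi - nu_bar lap) v + grad P = g, div v = 0 spectrally."""
    gx = grid.fft(g[0])
    gy = grid.fft(g[1])
    k2 = grid.k2
    with np.errstate(divide="ignore", invalid="ignore"):
        kdotg_over_k2 = np.where(k2 > 0, (grid.kx * gx + grid.ky * gy) / k2, 0.0)
    Ph = -1j * kdotg_over_k2
    proj_x = gx - grid.kx * kdotg_over_k2
    proj_y = gy - grid.ky * kdotg_over_k2
    denom = params.xi + params.nu_mean * k2
    v = np.stack([grid.ifft(proj_x / denom), grid.ifft(proj_y / denom)])
    P = grid.ifft(Ph)
    return v, P


def stokes_residual(
    phi: np.ndarray,
    p: np.ndarray,
    v: np.ndarray,
    P: np.ndarray,
    params: ModelParams,
    grid: Grid,
) -> np.ndarray:
    """Momentum residual div(nu grad v) - grad P + div sigma^e + alpha p - xi v."""
    nu = interpolate_coefficient(phi, params.nu_A, params.nu_B)
    alpha = interpolate_coefficient(phi, params.alpha_A, params.alpha_B)
    gP = grid.grad(P)
    res = np.empty_like(v)
    for i in range(2):
        gv = grid.grad(v[i])
        res[i] = (
            grid.divergence(np.stack([nu * gv[0], nu * gv[1]]))
            - gP[i]
            + alpha * p[i]
            - params.xi * v[i]
        )
    res += _elastic_force(phi, p, params, grid)
    return res


def solve_stokes(
    phi: np.ndarray,
    p: np.ndarray,
    params: ModelParams,
    grid: Grid,
    tol: float = 1.0e-8,
    max_iters: int = 200,
    v0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Quasi-static force balance for (v, P) at fixed phi, p.

    Picard iteration: the viscosity is split as nu = nu_bar + dnu(phi) and
    the dnu term lagged, so each pass is an exact constant-coefficient
    Stokes-Brinkman solve.  Converges linearly with ratio
    max|dnu| / nu_bar (1/3 for the default viscosity contrast).

    Returns (v, P, info); P has zero spatial mean.  Raises
    StokesConvergenceError if the relative momentum residual does not
    reach ``tol`` within ``max_iters``.
    """
    nu = interpolate_coefficient(phi, params.nu_A, params.nu_B)
    alpha = interpolate_coefficient(phi, params.alpha_A, params.alpha_B)
    dnu = nu - params.nu_mean
    f_fixed = _elastic_force(phi, p, params, grid) + alpha * p

    scale = float(np.sqrt(np.mean(f_fixed[0] ** 2 + f_fixed[1] ** 2)))
    if scale == 0.0:
        n = grid.n
        return np.zeros((2, n, n)), np.zeros((n, n)), {"iters": 0, "residual": 0.0}

    def _correction(vel):
        corr = np.empty_like(vel)
        for i in range(2):
            gv = grid.grad(vel[i])
            corr[i] = grid.divergence(np.stack([dnu * gv[0], dnu * gv[1]]))
        return corr

    v = np.zeros_like(f_fixed) if v0 is None else v0.copy()
    corr = _correction(v) if np.any(v) else np.zeros_like(f_fixed)
    for it in range(1, max_iters + 1):
        v, P = _constant_coefficient_solve(f_fixed + corr, params, grid)
        corr_new = _correction(v)
        # the constant-coefficient solve is spectrally exact, so the full
        # momentum residual equals the change in the lagged dnu correction
        res = corr_new - corr
        rel = float(np.sqrt(np.mean(res[0] ** 2 + res[1] ** 2))) / scale
        corr = corr_new
        if rel <= tol:
            return v, P, {"iters": it, "residual": rel}
    raise StokesConvergenceError(rel, max_iters)


# ---------------------------------------------------------------------------
# Field updates (IMEX Heun)
# ---------------------------------------------------------------------------

def _check_cfl(v: np.ndarray, dt: float, grid: Grid) -> None:
    vmax = float(np.max(np.hypot(v[0], v[1])))
    cfl = vmax * dt / grid.h
    if cfl > CFL_BOUND:
        raise CFLError(
            f"advective CFL number {cfl:.3f} exceeds bound {CFL_BOUND} "
            f"(max|v|={vmax:.3f}, dt={dt}, h={grid.h:.3f})"
        )


def _phi_explicit_hat(phi, v, params, grid):
    """Spectral explicit RHS: conservative advection + local Cahn-Hilliard flux."""
    fxh = grid.dealias(grid.fft(v[0] * phi))
    fyh = grid.dealias(grid.fft(v[1] * phi))
    adv = -1j * (grid.kx * fxh + grid.ky * fyh)
    local = params.a * (phi**3 - phi)
    ch = -grid.k2 * params.M * grid.dealias(grid.fft(local))
    return adv + ch


def advance_phase(
    phi: np.ndarray,
    v: np.ndarray,
    params: ModelParams,
    grid: Grid,
    dt: float | None = None,
) -> np.ndarray:
    """One conserved Cahn-Hilliard/advection step for phi.

    Two-stage IMEX Heun with Crank-Nicolson on the biharmonic term;
    conserves the phase integral to machine precision (every update term
    vanishes at k = 0).
    """
    dt = params.dt if dt is None else dt
    _check_cfl(v, dt, grid)
    lam = params.M * params.K_phi * grid.k2**2  # stiff biharmonic rate
    denom = 1.0 + 0.5 * dt * lam
    phih = grid.fft(phi)
    base = phih * (1.0 - 0.5 * dt * lam)

    e1 = _phi_explicit_hat(phi, v, params, grid)
    phi_star = grid.ifft((base + dt * e1) / denom)
    e2 = _phi_explicit_hat(phi_star, v, params, grid)
    return grid.ifft((base + 0.5 * dt * (e1 + e2)) / denom)


def _p_explicit(p, v, D, Omega, params, grid):
    """Real-space explicit RHS of the polarity equation (all but Gamma K_p lap p)."""
    out = np.empty_like(p)
    mag2 = p[0] ** 2 + p[1] ** 2
    relax = params.Gamma * params.a_p * (params.p0 - mag2)
    for i in range(2):
        gp = grid.grad(p[i])
        adv = v[0] * gp[0] + v[1] * gp[1]
        rot = Omega[i, 0] * p[0] + Omega[i, 1] * p[1]
        ali = D[i, 0] * p[0] + D[i, 1] * p[1]
        out[i] = -adv - rot + params.kappa * ali + relax * p[i]
    return out


def advance_polarity(
    p: np.ndarray,
    v: np.ndarray,
    params: ModelParams,
    grid: Grid,
    dt: float | None = None,
    D: np.ndarray | None = None,
    Omega: np.ndarray | None = None,
) -> np.ndarray:
    """One polarity step (advection, co-rotation, flow alignment, relaxation).

    The Gamma K_p lap p part of -Gamma H is Crank-Nicolson; the rest is
    explicit in a two-stage Heun.  D and Omega may be supplied (e.g. a
    frozen imposed shear); by default they are computed from v.
    """
    dt = params.dt if dt is None else dt
    _check_cfl(v, dt, grid)
    if D is None or Omega is None:
        D, Omega = strain_vorticity(v, grid)
    lam = params.Gamma * params.K_p * grid.k2  # stiff alignment-diffusion rate
    denom = 1.0 + 0.5 * dt * lam

    ph = np.stack([grid.fft(p[0]), grid.fft(p[1])])
    base = ph * (1.0 - 0.5 * dt * lam)

    def _implicit(source_hat):
        return np.stack(
            [grid.ifft(source_hat[0] / denom), grid.ifft(source_hat[1] / denom)]
        )

    e1 = _p_explicit(p, v, D, Omega, params, grid)
    e1h = np.stack([grid.dealias(grid.fft(e1[0])), grid.dealias(grid.fft(e1[1]))])
    p_star = _implicit(base + dt * e1h)
    e2 = _p_explicit(p_star, v, D, Omega, params, grid)
    e2h = np.stack([grid.dealias(grid.fft(e2[0])), grid.dealias(grid.fft(e2[1]))])
    return _implicit(base + 0.5 * dt * (e1h + e2h))


# ---------------------------------------------------------------------------
# Traction
# ---------------------------------------------------------------------------

def model_traction(state: FieldState, params: ModelParams):
    """Substrate-exchange force density T = xi v - alpha p.

    This is the divergence of the total tissue stress
    nu grad v - P I + sigma^e whenever the force balance holds, i.e. the
    model-side analogue of the traction entering div sigma = T.
    """
    from .inversion import TractionField

    alpha = interpolate_coefficient(state.phi, params.alpha_A, params.alpha_B)
    tx = params.xi * state.v[0] - alpha * state.p[0]
    ty = params.xi * state.v[1] - alpha * state.p[1]
    return TractionField(tx=tx, ty=ty, h=state.grid.h, units="sim")


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Run specification for :func:`run_simulation`.

    ``initial_condition`` is either an InitialConditionSpec (see
    polarmix.synth), a ready FieldState, or a callable grid, params -> FieldState.
    ``freeze_flow`` keeps v = 0 throughout (passive gradient-flow runs).
    """

    params: ModelParams
    N: int = 128
    T_end: float = 60.0
    save_every: float = 1.0
    initial_condition: object = None
    stokes_tol: float = 1.0e-8
    max_picard_iters: int = 200
    freeze_flow: bool = False

    def make_grid(self) -> Grid:
        grid = Grid(self.N, self.params.L)
        # interface must be resolved: equilibrium profile scale is 2w
        if grid.h > 2.0 * self.params.interface_width:
            raise ValueError(
                f"grid spacing h={grid.h:.3f} does not resolve the phase "
                f"interface (scale {2 * self.params.interface_width:.3f}); "
                "increase N"
            )
        return grid


@dataclass
class Trajectory:
    """Ordered snapshots of one run plus its config and diagnostic log."""

    states: list
    config: SimulationConfig
    seed: int
    log: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def __len__(self):
        return len(self.states)


def _build_initial_state(config: SimulationConfig, grid: Grid) -> FieldState:
    from .synth import InitialConditionSpec, initial_state

    ic = config.initial_condition
    if ic is None:
        ic = InitialConditionSpec(kind="random_mixed", seed=config.params.seed)
    if isinstance(ic, FieldState):
        return ic.copy()
    if callable(ic) and not isinstance(ic, InitialConditionSpec):
        return ic(grid, config.params)
    return initial_state(grid, config.params, ic)


def run_simulation(config: SimulationConfig, progress: Callable | None = None) -> Trajectory:
    """Integrate the coupled system and return saved snapshots.

    Per step: quasi-static Stokes solve (warm-started from the previous
    velocity), then the phase and polarity updates.  Fully deterministic
    for a fixed seed.
    """
    params = config.params
    grid = config.make_grid()
    state = _build_initial_state(config, grid)

    n_steps = int(round(config.T_end / params.dt))
    stride = max(1, int(round(config.save_every / params.dt)))

    if not config.freeze_flow:
        v, P, info = solve_stokes(
            state.phi, state.p, params, grid,
            tol=config.stokes_tol, max_iters=config.max_picard_iters,
        )
        state.v, state.P = v, P

    log = {k: [] for k in ("t", "free_energy", "phase_mass", "picard_iters", "stokes_residual")}

    def _log(st, info):
        log["t"].append(st.t)
        log["free_energy"].append(free_energy(st.phi, st.p, params, grid))
        log["phase_mass"].append(st.phase_mass)
        log["picard_iters"].append(info.get("iters", 0))
        log["stokes_residual"].append(info.get("residual", 0.0))

    info = {"iters": 0, "residual": 0.0}
    snapshots = [state.copy()]
    _log(state, info)

    phi, p, v = state.phi, state.p, state.v
    t = state.t
    for step in range(1, n_steps + 1):
        try:
            phi = advance_phase(phi, v, params, grid)
            p = advance_polarity(p, v, params, grid)
            t = state.t + step * params.dt
            if config.freeze_flow:
                vP = (np.zeros_like(v), np.zeros_like(phi))
                info = {"iters": 0, "residual": 0.0}
            else:
                vnew, Pnew, info = solve_stokes(
                    phi, p, params, grid,
                    tol=config.stokes_tol,
                    max_iters=config.max_picard_iters,
                    v0=v,
                )
                vP = (vnew, Pnew)
            v, P = vP
        except (StokesConvergenceError, CFLError) as err:
            err.args = (f"at step {step} (t={t:.3f}): {err}",)
            raise
        if step % stride == 0 or step == n_steps:
            snap = FieldState(grid=grid, phi=phi.copy(), p=p.copy(),
                              v=v.copy(), P=P.copy(), t=t)
            snapshots.append(snap)
            _log(snap, info)
            if progress is not None:
                progress(step, n_steps, snap)

    log = {k: np.asarray(vals) for k, vals in log.items()}
    return Trajectory(states=snapshots, config=config, seed=params.seed, log=log)
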