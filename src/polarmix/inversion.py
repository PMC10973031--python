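"""Traction-to-stress inversion and stress decompositions.

Monolayer stress microscopy recovers the symmetric 2-D intercellular
stress tensor sigma from the measured traction T through the mechanical
balance div sigma = T.  Here the inversion is a regularized least squares
on the periodic grid: per Fourier mode we minimize

    | div sigma - T |^2 + reg_lambda * |sigma|_F^2

over the three independent components (sigma_xy counted twice in the
Frobenius norm).  The divergence map has a one-dimensional null space per
mode (and constant tensors at k = 0), so the regularizer selects the
minimum-Frobenius-norm solution and the spatial mean of sigma is gauged
to zero.  This replaces the Bayesian prior machinery of the original
stress-microscopy method with an explicit variational stand-in honouring
the same div sigma = T contract.

Decompositions follow the standard 2-D split: sigma_iso = tr(sigma)/2
(negative of tissue pressure; < 0 compression, > 0 tension) and the
traceless deviator with eigenvalues +-lambda_dev, where

    |lambda_dev| = sqrt( ((sigma_xx - sigma_yy)/2)^2 + sigma_xy^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (
    elastic_stress_phase,
    elastic_stress_polar,
    interpolate_coefficient,
    molecular_field,
)
from .fields import FieldState
from .params import ModelParams
from .spectral import Grid

__all__ = [
    "TractionField",
    "StressTensorField",
    "StressDecomposition",
    "invert_traction_to_stress",
    "decompose_stress",
    "simulator_stress_tensor",
    "simulator_stress_iso",
]


@dataclass
class TractionField:
    """2-D traction vector field on a uniform grid (force per area)."""

    tx: np.ndarray
    ty: np.ndarray
    h: float
    units: str = "sim"

    def __post_init__(self):
        if self.tx.shape != self.ty.shape:
            raise ValueError("traction components must share one grid shape")
        if not (np.all(np.isfinite(self.tx)) and np.all(np.isfinite(self.ty))):
            raise ValueError("traction field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)


@dataclass
class StressTensorField:
    """Symmetric 2-D stress tensor field (sigma_xy stored once)."""

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    h: float
    units: str = "sim"

    def __post_init__(self):
        if not (self.sxx.shape == self.syy.shape == self.sxy.shape):
            raise ValueError("stress components must share one grid shape")
        for comp in (self.sxx, self.syy, self.sxy):
            if not np.all(np.isfinite(comp)):
                raise ValueError("stress field contains non-finite values")

    def as_tensor(self) -> np.ndarray:
        """Full (2, 2, n, n) array."""
        return np.stack(
            [np.stack([self.sxx, self.sxy]), np.stack([self.sxy, self.syy])]
        )


@dataclass
class StressDecomposition:
    """Isotropic part and deviatoric eigenvalue magnitude of a stress field."""

    sigma_iso: np.ndarray
    lambda_dev: np.ndarray


def invert_traction_to_stress(
    traction: TractionField, reg_lambda: float = 1.0e-6
) -> StressTensorField:
    """Recover the symmetric stress field from div sigma = T.

    Spectral divergence (the same operator family as the simulator) with
    Frobenius-norm Tikhonov regularization; the k = 0 tensor mode (the
    null space of div) is gauged to zero mean.  reg_lambda must be
    positive: at zero the per-mode system is singular because a
    divergence-free tensor field can be added to any solution.
    """
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be non-negative")
    if reg_lambda == 0:
        raise np.linalg.LinAlgError(
            "reg_lambda = 0 leaves the system singular: div has a "
            "divergence-free tensor null space per mode; use reg_lambda > 0"
        )
    n = traction.tx.shape[0]
    grid = Grid(n, n * traction.h)
    txh = grid.fft(traction.tx)
    tyh = grid.fft(traction.ty)

    kx, ky = grid.kx, grid.ky
    shape = txh.shape
    kxb = np.broadcast_to(kx, shape)
    kyb = np.broadcast_to(ky, shape)

    # Per-mode normal equations (A^H A + lam W) s = A^H T with
    # A = i [[kx, 0, ky], [0, ky, kx]],  W = diag(1, 1, 2).
    lam = float(reg_lambda)
    M = np.zeros(shape + (3, 3), dtype=float)
    M[..., 0, 0] = kxb**2 + lam
    M[..., 1, 1] = kyb**2 + lam
    M[..., 2, 2] = kxb**2 + kyb**2 + 2.0 * lam
    M[..., 0, 2] = M[..., 2, 0] = kxb * kyb
    M[..., 1, 2] = M[..., 2, 1] = kxb * kyb

    rhs = np.empty(shape + (3,), dtype=complex)
    rhs[..., 0] = -1j * kxb * txh
    rhs[..., 1] = -1j * kyb * tyh
    rhs[..., 2] = -1j * (kyb * txh + kxb * tyh)

    s = np.linalg.solve(M, rhs[..., None])[..., 0]
    s[0, 0, :] = 0.0  # zero-mean gauge for the constant tensor mode

    sxx = grid.ifft(s[..., 0])
    syy = grid.ifft(s[..., 1])
    sxy = grid.ifft(s[..., 2])
    return StressTensorField(sxx=sxx, syy=syy, sxy=sxy, h=traction.h, units=traction.units)


def decompose_stress(sigma: StressTensorField) -> StressDecomposition:
    """Isotropic/deviatoric split of a symmetric 2-D stress field.

    sigma_iso = (sigma_xx + sigma_yy)/2;
    |lambda_dev| = sqrt(((sigma_xx - sigma_yy)/2)^2 + sigma_xy^2), the
    common magnitude of the two deviator eigenvalues.
    """
    siso = 0.5 * (sigma.sxx + sigma.syy)
    lam = np.sqrt((0.5 * (sigma.sxx - sigma.syy)) ** 2 + sigma.sxy**2)
    return StressDecomposition(sigma_iso=siso, lambda_dev=lam)


def simulator_stress_tensor(state: FieldState, params: ModelParams) -> np.ndarray:
    """Total model stress nu grad v - P I + sigma^e, shape (2, 2, n, n).

    Its row-wise divergence equals the traction xi v - alpha p up to the
    Stokes solver residual.  The viscous part nu (grad v)_ij = nu d_j v_i
    and the polar stress are generally asymmetric; observables use the
    symmetric part.
    """
    grid = state.grid
    nu = interpolate_coefficient(state.phi, params.nu_A, params.nu_B)
    H = molecular_field(state.p, params, grid)
    sig = elastic_stress_polar(state.p, H, params, grid) + elastic_stress_phase(
        state.phi, params, grid
    )
    for i in range(2):
        gv = grid.grad(state.v[i])
        sig[i, 0] += nu * gv[0]
        sig[i, 1] += nu * gv[1]
        sig[i, i] -= state.P
    return sig


def simulator_stress_iso(state: FieldState, params: ModelParams) -> np.ndarray:
    """Isotropic stress of the simulated tissue: -P + tr(sigma^e)/2.

    The viscous stress is traceless under incompressibility
    (tr nu grad v = nu div v = 0), so only the pressure and elastic parts
    contribute; the zero-mean pressure gauge pins the overall constant.
    """
    grid = state.grid
    H = molecular_field(state.p, params, grid)
    sig_e = elastic_stress_polar(state.p, H, params, grid) + elastic_stress_phase(
        state.phi, params, grid
    )
    return -state.P + 0.5 * (sig_e[0, 0] + sig_e[1, 1])
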