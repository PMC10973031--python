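"""Free energy and constitutive fields of the binary active-polar mixture.

The free energy

    F = \\int [ a/4 (1 - phi^2)^2 + K_phi/2 |grad phi|^2
              + a_p/2 (1 - |p|^2)^2 + K_p/2 |grad p|^2 ] dA

drives phase separation of the two cell types (phi -> +-1, interface
width sqrt(K_phi/2a)) and local polar order (|p| -> 1, correlation length
sqrt(K_p/2a_p)).  The chemical potential mu and molecular field H used by
the dynamics take the standard forms:

    mu  = -a (1 - phi^2) phi - K_phi lap phi
    H_i = -a_p (p0 - |p|^2) p_i - K_p lap p_i

Note that with p0 = 1 the local term of H carries half the weight of the
strict variational derivative of the quartic polar well (dF/dp_i has
-2 a_p (1 - |p|^2) p_i); the gradient (K_p) part is exactly variational.
Both forms are kept as written and the relation is documented; see
docs/methods.md.

Velocity-gradient convention: ``(grad v)_ij = d_i v_j`` (see
``strain_vorticity`` — the index order is fixed by requiring that
``-Omega p`` co-rotates the polarity with the flow).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .spectral import Grid

__all__ = [
    "interpolate_coefficient",
    "chemical_potential",
    "molecular_field",
    "strain_vorticity",
    "elastic_stress_polar",
    "elastic_stress_phase",
    "free_energy",
    "variational_molecular_field",
]


def interpolate_coefficient(phi: np.ndarray, value_A: float, value_B: float) -> np.ndarray:
    """Linear per-node interpolation value_A (1+phi)/2 + value_B (1-phi)/2.

    phi need not lie exactly in [-1, 1] transiently; non-finite input is
    rejected.
    """
    phi = np.asarray(phi)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase field contains non-finite values")
    return value_A * (1.0 + phi) / 2.0 + value_B * (1.0 - phi) / 2.0


def chemical_potential(phi: np.ndarray, params: ModelParams, grid: Grid) -> np.ndarray:
    """mu = -a (1 - phi^2) phi - K_phi lap phi on the periodic grid."""
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase field contains non-finite values")
    return -params.a * (1.0 - phi**2) * phi - params.K_phi * grid.laplacian(phi)


def molecular_field(p: np.ndarray, params: ModelParams, grid: Grid) -> np.ndarray:
    """H_i = -a_p (p0 - |p|^2) p_i - K_p lap p_i, componentwise."""
    mag2 = p[0] ** 2 + p[1] ** 2
    local = -params.a_p * (params.p0 - mag2)
    return np.stack(
        [
            local * p[0] - params.K_p * grid.laplacian(p[0]),
            local * p[1] - params.K_p * grid.laplacian(p[1]),
        ]
    )


def variational_molecular_field(p: np.ndarray, params: ModelParams, grid: Grid) -> np.ndarray:
    """Exact variational derivative dF/dp of the polar part of the free energy.

    Equals ``molecular_field`` in its gradient (K_p) term; the local term is
    -2 a_p (1 - |p|^2) p_i.  Used by the variational-consistency oracle.
    """
    mag2 = p[0] ** 2 + p[1] ** 2
    local = -2.0 * params.a_p * (1.0 - mag2)
    return np.stack(
        [
            local * p[0] - params.K_p * grid.laplacian(p[0]),
            local * p[1] - params.K_p * grid.laplacian(p[1]),
        ]
    )


def strain_vorticity(v: np.ndarray, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric (D) and antisymmetric (Omega) parts of grad v.

    Gradient convention (grad v)_ij = d_i v_j, so
    D_ij = (d_i v_j + d_j v_i)/2 and Omega_ij = (d_i v_j - d_j v_i)/2.
    This is the pairing under which -Omega p co-rotates the polarity with
    the local vorticity (a rigid rotation v = omega z x r carries p along
    with it); the opposite index order would make p counter-rotate.
    """
    dvx = grid.grad(v[0])  # (d_x v_x, d_y v_x)
    dvy = grid.grad(v[1])
    gv = np.empty((2, 2) + v.shape[1:])
    gv[0, 0], gv[0, 1] = dvx[0], dvy[0]  # row i: d_i v_j
    gv[1, 0], gv[1, 1] = dvx[1], dvy[1]
    gvT = np.swapaxes(gv, 0, 1)
    return (gv + gvT) / 2.0, (gv - gvT) / 2.0


def elastic_stress_polar(
    p: np.ndarray, H: np.ndarray, params: ModelParams, grid: Grid
) -> np.ndarray:
    """Polar elastic stress.

    sigma^p_ij = 1/2 (p_i H_j - H_i p_j) - kappa/2 (p_i H_j + H_i p_j)
                 - K_p d_i p_k d_j p_k

    The first term is antisymmetric, so the full 2x2 tensor is stored.
    """
    n = p.shape[-1]
    sig = np.empty((2, 2, n, n))
    gpx = grid.grad(p[0])
    gpy = grid.grad(p[1])
    for i in range(2):
        for j in range(2):
            sig[i, j] = (
                0.5 * (p[i] * H[j] - H[i] * p[j])
                - 0.5 * params.kappa * (p[i] * H[j] + H[i] * p[j])
                - params.K_p * (gpx[i] * gpx[j] + gpy[i] * gpy[j])
            )
    return sig


def elastic_stress_phase(phi: np.ndarray, params: ModelParams, grid: Grid) -> np.ndarray:
    """Phase elastic stress sigma^phi_ij = -K_phi d_i phi d_j phi.

    Symmetric and negative-semidefinite; its trace is -K_phi |grad phi|^2.
    The isotropic (f - phi mu) delta_ij contribution is absorbed into the
    pressure gauge under incompressibility and therefore omitted.
    """
    g = grid.grad(phi)
    n = phi.shape[-1]
    sig = np.empty((2, 2, n, n))
    for i in range(2):
        for j in range(2):
            sig[i, j] = -params.K_phi * g[i] * g[j]
    return sig


def free_energy(phi: np.ndarray, p: np.ndarray, params: ModelParams, grid: Grid) -> float:
    """Total free energy; quadrature consistent with the spectral gradients."""
    gphi = grid.grad(phi)
    gpx = grid.grad(p[0])
    gpy = grid.grad(p[1])
    mag2 = p[0] ** 2 + p[1] ** 2
    integrand = (
        params.a / 4.0 * (1.0 - phi**2) ** 2
        + params.K_phi / 2.0 * (gphi[0] ** 2 + gphi[1] ** 2)
        + params.a_p / 2.0 * (1.0 - mag2) ** 2
        + params.K_p
        / 2.0
        * (gpx[0] ** 2 + gpx[1] ** 2 + gpy[0] ** 2 + gpy[1] ** 2)
    )
    return grid.integrate(integrand)
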