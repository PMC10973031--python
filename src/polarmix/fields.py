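"""Field containers for the binary active-polar mixture.

Scalars have shape ``(n, n)``, vectors ``(2, n, n)`` with component order
(x, y), and rank-2 tensors ``(2, 2, n, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import Grid

__all__ = ["FieldState", "DerivedFields"]


@dataclass
class FieldState:
    """Snapshot of all model fields at one time.

    ``phi`` is the cell-type phase field, ``p`` the polarity vector field,
    ``v`` the velocity and ``P`` the pressure (zero spatial mean gauge).
    """

    grid: Grid
    phi: np.ndarray
    p: np.ndarray
    v: np.ndarray
    P: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        n = self.grid.n
        if self.phi.shape != (n, n) or self.P.shape != (n, n):
            raise ValueError("scalar fields must have grid shape (n, n)")
        if self.p.shape != (2, n, n) or self.v.shape != (2, n, n):
            raise ValueError("vector fields must have shape (2, n, n)")

    @classmethod
    def quiescent(cls, grid: Grid, phi: np.ndarray, p: np.ndarray, t: float = 0.0):
        """State with the given phi and p and zero flow."""
        n = grid.n
        return cls(
            grid=grid,
            phi=np.asarray(phi, dtype=float),
            p=np.asarray(p, dtype=float),
            v=np.zeros((2, n, n)),
            P=np.zeros((n, n)),
            t=t,
        )

    def copy(self) -> "FieldState":
        return FieldState(
            grid=self.grid,
            phi=self.phi.copy(),
            p=self.p.copy(),
            v=self.v.copy(),
            P=self.P.copy(),
            t=self.t,
        )

    @property
    def phase_mass(self) -> float:
        """Conserved integral of phi over the domain."""
        return self.grid.integrate(self.phi)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v[0], self.v[1])


@dataclass
class DerivedFields:
    """Constitutive fields derived from one FieldState.

    ``mu`` chemical potential, ``H`` molecular field, ``D``/``Omega``
    symmetric/antisymmetric velocity-gradient parts, ``sigma_p`` and
    ``sigma_phi`` elastic stresses (sigma_p is generally asymmetric).
    """

    mu: np.ndarray
    H: np.ndarray
    D: np.ndarray
    Omega: np.ndarray
    sigma_p: np.ndarray
    sigma_phi: np.ndarray

    @property
    def sigma_elastic(self) -> np.ndarray:
        return self.sigma_p + self.sigma_phi
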