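"""Synthetic inputs: initial conditions, stress/traction fixtures, masks, traces.

Every generator is a pure function of its spec and seed.  The two initial
conditions reproduce the study's regimes: a well-mixed 1:1 composition
(zero-mean phase noise) and a completely segregated two-stripe state with
equilibrium tanh interfaces.  The remaining generators emulate the inputs
of the measurement pipeline: periodic stress fields with their exact
analytic tractions (for the div sigma = T inversion), two-phase masks with
distance-graded stress maps (for boundary-distance correlation), and
fluorescence-like intensity traces with planted transient events (for the
spark detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import FieldState
from .params import ModelParams
from .spectral import Grid

__all__ = [
    "InitialConditionSpec",
    "SyntheticStressSpec",
    "initial_state",
    "random_mixed_ic",
    "segregated_ic",
    "synthetic_stress_traction_pair",
    "random_stress_spec",
    "synthetic_mask_stress",
    "synthetic_intensity_traces",
]


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialConditionSpec:
    """Spec for an initial condition.

    kind: "random_mixed" or "segregated"; noise_amplitude applies to the
    phase noise of the mixed state; polarity_init is "small_noise"
    (|p| = 0.1, random directions) or "unit_random" (|p| = 1).
    """

    kind: str = "random_mixed"
    noise_amplitude: float = 0.1
    polarity_init: str = "small_noise"
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("random_mixed", "segregated"):
            raise ValueError(f"unknown initial-condition kind {self.kind!r}")
        if not 0.0 < self.noise_amplitude <= 0.5:
            raise ValueError("noise_amplitude must lie in (0, 0.5]")
        if self.polarity_init not in ("small_noise", "unit_random"):
            raise ValueError(f"unknown polarity_init {self.polarity_init!r}")


def _polarity(grid: Grid, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Random-direction polarity, band-limited to the resolved (de-aliased)
    spectral band and rescaled to rms magnitude 0.1 (small_noise) or 1."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(grid.n, grid.n))
    mag = 1.0 if mode == "unit_random" else 0.1
    p = np.stack([grid.smooth(np.cos(theta)), grid.smooth(np.sin(theta))])
    rms = np.sqrt(np.mean(p[0] ** 2 + p[1] ** 2))
    return p * (mag / rms)


def random_mixed_ic(grid: Grid, spec: InitialConditionSpec, params: ModelParams) -> FieldState:
    """Well-mixed state: zero-mean band-limited phase noise (1:1 composition).

    Uniform white noise is low-pass filtered to the resolved spectral
    band, rescaled so max|phi| equals the requested amplitude, and the
    spatial mean removed exactly.
    """
    seed = params.seed if spec.seed is None else spec.seed
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-1.0, 1.0, size=(grid.n, grid.n))
    phi = grid.smooth(phi)
    phi *= spec.noise_amplitude / np.abs(phi).max()
    phi -= phi.mean()
    p = _polarity(grid, spec.polarity_init, rng)
    return FieldState.quiescent(grid, phi, p)


def segregated_ic(
    grid: Grid, params: ModelParams, spec: InitialConditionSpec | None = None
) -> FieldState:
    """Completely segregated state: two vertical stripes of width L/2.

    Plateaus phi = +-1 are joined by the equilibrium interface profile
    tanh(x / delta) with delta = sqrt(2 K_phi / a) = 2 w, where
    w = sqrt(K_phi / 2a) is the interface width parameter.
    """
    spec = spec or InitialConditionSpec(kind="segregated")
    seed = params.seed if spec.seed is None else spec.seed
    rng = np.random.default_rng(seed)
    delta = 2.0 * params.interface_width
    L = params.L
    x = grid.x
    phi = np.tanh((x - L / 4.0) / delta) - np.tanh((x - 3.0 * L / 4.0) / delta) - 1.0
    p = _polarity(grid, spec.polarity_init, rng)
    return FieldState.quiescent(grid, phi, p)


def initial_state(grid: Grid, params: ModelParams, spec: InitialConditionSpec) -> FieldState:
    if spec.kind == "random_mixed":
        return random_mixed_ic(grid, spec, params)
    return segregated_ic(grid, params, spec)


# ---------------------------------------------------------------------------
# Analytic stress / traction fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStressSpec:
    """Periodic stress field as a finite sum of Fourier modes.

    ``modes`` is a sequence of (mx, my, amp) where (mx, my) are integer
    wavenumbers and amp is a real symmetric 2x2 amplitude applied as
    amp_cos * cos(k.x) + amp_sin * sin(k.x); each entry is
    (mx, my, amp_cos, amp_sin) with 2x2 arrays (amp_sin optional -> 0).
    """

    n: int
    length: float
    modes: tuple = ()

    def __post_init__(self):
        for entry in self.modes:
            for amp in entry[2:]:
                amp = np.asarray(amp)
                if amp.shape != (2, 2) or not np.allclose(amp, amp.T):
                    raise ValueError("mode amplitudes must be symmetric 2x2 arrays")


def synthetic_stress_traction_pair(spec: SyntheticStressSpec):
    """Build sigma from the spec and its *analytic* divergence T.

    The traction is differentiated symbolically mode by mode
    (d/dx cos -> -k sin etc.), not numerically, so the pair serves as an
    independent ground truth for the inversion.
    """
    from .inversion import StressTensorField, TractionField

    grid = Grid(spec.n, spec.length)
    n = spec.n
    sxx = np.zeros((n, n))
    syy = np.zeros((n, n))
    sxy = np.zeros((n, n))
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    for entry in spec.modes:
        mx, my = int(entry[0]), int(entry[1])
        amp_cos = np.asarray(entry[2], dtype=float)
        amp_sin = (
            np.asarray(entry[3], dtype=float) if len(entry) > 3 else np.zeros((2, 2))
        )
        kx = 2.0 * np.pi * mx / spec.length
        ky = 2.0 * np.pi * my / spec.length
        phase = kx * grid.x + ky * grid.y
        c, s = np.cos(phase), np.sin(phase)
        sxx += amp_cos[0, 0] * c + amp_sin[0, 0] * s
        syy += amp_cos[1, 1] * c + amp_sin[1, 1] * s
        sxy += amp_cos[0, 1] * c + amp_sin[0, 1] * s
        # T_i = d_j sigma_ij, analytically: d cos = -k sin, d sin = +k cos
        tx += (-(kx * amp_cos[0, 0] + ky * amp_cos[0, 1])) * s + (
            kx * amp_sin[0, 0] + ky * amp_sin[0, 1]
        ) * c
        ty += (-(kx * amp_cos[0, 1] + ky * amp_cos[1, 1])) * s + (
            kx * amp_sin[0, 1] + ky * amp_sin[1, 1]
        ) * c
    sigma = StressTensorField(sxx=sxx, syy=syy, sxy=sxy, h=grid.h, units="sim")
    traction = TractionField(tx=tx, ty=ty, h=grid.h, units="sim")
    return sigma, traction


def random_stress_spec(
    n: int,
    length: float,
    n_modes: int = 6,
    max_wavenumber: int = 4,
    amplitude: float = 1.0,
    seed: int = 0,
) -> SyntheticStressSpec:
    """Random recoverable stress spec.

    Amplitudes are drawn in the row space of the divergence operator
    (sigma = sym part of  t (x) k + k (x) t for a random vector t), because
    per Fourier mode the map sigma -> div sigma has a one-dimensional null
    space: a component in it is invisible to *any* traction-based
    inversion.  The resulting tensors are symmetric and fully general as
    traction sources.
    """
    rng = np.random.default_rng(seed)
    modes = []
    seen = set()
    while len(modes) < n_modes:
        mx, my = rng.integers(-max_wavenumber, max_wavenumber + 1, size=2)
        if (mx, my) == (0, 0) or (mx, my) in seen or (-mx, -my) in seen:
            continue
        seen.add((mx, my))
        kx = 2.0 * np.pi * mx / length
        ky = 2.0 * np.pi * my / length
        k = np.array([kx, ky])
        amps = []
        for _ in range(2):  # cos and sin parts
            t = rng.normal(0.0, amplitude, size=2)
            outer = np.outer(t, k)
            amps.append((outer + outer.T) / (2.0 * np.linalg.norm(k)))
        modes.append((int(mx), int(my), amps[0], amps[1]))
    return SyntheticStressSpec(n=n, length=length, modes=tuple(modes))


# ---------------------------------------------------------------------------
# Mask / stress-map fixture for boundary-distance correlation
# ---------------------------------------------------------------------------

def synthetic_mask_stress(
    grid: Grid,
    domain_scale: float,
    slope: float,
    noise_sd: float,
    seed: int = 0,
):
    """Two-phase mask plus a stress map graded with boundary distance.

    The mask is thresholded smoothed Gaussian noise with characteristic
    domain size ``domain_scale`` (simulation length units); the stress map
    is slope * (Euclidean distance to the nearest phase boundary, in
    length units) + N(0, noise_sd).
    """
    if domain_scale >= grid.length:
        raise ValueError("domain_scale must be smaller than the domain side")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(grid.n, grid.n))
    sigma_nodes = domain_scale / grid.h / 2.0
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_nodes, mode="wrap")
    mask = smooth > np.median(smooth)

    from .observables import boundary_distance_map

    dist = boundary_distance_map(mask, grid.h)
    stress = slope * dist + rng.normal(0.0, noise_sd, size=dist.shape)
    return mask, stress


# ---------------------------------------------------------------------------
# Intensity traces with planted spark events
# ---------------------------------------------------------------------------

def synthetic_intensity_traces(
    n_cells: int,
    n_frames: int,
    baseline: float = 100.0,
    sd: float = 5.0,
    spark_frames: dict | None = None,
    spark_sigma: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian baseline traces with planted spikes of spark_sigma s.d.

    ``spark_frames`` maps cell index -> iterable of frame indices; returns
    an (n_cells, n_frames) matrix.  A planted frame is set to exactly
    ``baseline + spark_sigma * sd`` (replacing that frame's noise), so the
    spike amplitude in baseline standard deviations is exact — a 4-sd
    plant is genuinely sub-threshold at a 5-sd criterion for every seed.
    """
    rng = np.random.default_rng(seed)
    traces = rng.normal(baseline, sd, size=(n_cells, n_frames))
    spark_frames = spark_frames or {}
    for cell, frames in spark_frames.items():
        for f in np.atleast_1d(frames):
            if not 0 <= f < n_frames:
                raise ValueError(f"spark frame {f} outside trace of {n_frames} frames")
            traces[cell, int(f)] = baseline + spark_sigma * sd
    return traces
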