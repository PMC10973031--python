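"""Quantitative readouts: per-type mechanics, correlations, spark events.

Per-cell-type averages use the smooth phase weights (1 + phi)/2 and
(1 - phi)/2, which are exact on the +-1 plateaus and differentiable
across interfaces.  The headline readout is the convergence index: the
ratio of the time-averaged mean speeds of the two cell types over a late
window — near 1 when the mixture mechanically converges, near the
intrinsic-speed ratio alpha_A/alpha_B when the populations stay apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .inversion import (
    StressTensorField,
    TractionField,
    decompose_stress,
    simulator_stress_iso,
    simulator_stress_tensor,
)
from .solver import Trajectory, model_traction
from .spectral import Grid

__all__ = [
    "PhaseTimeSeries",
    "SparkEvent",
    "DomainSize",
    "phase_average",
    "per_phase_series",
    "convergence_index",
    "total_traction_magnitude",
    "boundary_distance_map",
    "boundary_distance_correlation",
    "detect_sparks",
    "domain_size_metric",
]


# ---------------------------------------------------------------------------
# Phase-conditioned averages
# ---------------------------------------------------------------------------

def phase_average(field: np.ndarray, phi: np.ndarray, which: str) -> float:
    """Mean of ``field`` weighted by the occupancy of one cell type.

    <q>_A = sum q (1+phi)/2 / sum (1+phi)/2, and the mirror for B.
    Raises on vanishing weight mass (asking for an absent phase).
    """
    if field.shape != phi.shape:
        raise ValueError("field and phi must share one grid shape")
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    w = (1.0 + phi) / 2.0 if which == "A" else (1.0 - phi) / 2.0
    mass = float(np.sum(w))
    if mass <= 1.0e-9 * phi.size:
        raise ValueError(f"phase {which} has vanishing weight mass")
    return float(np.sum(field * w) / mass)


@dataclass
class PhaseTimeSeries:
    """Per-cell-type mechanical time series of one trajectory."""

    times: np.ndarray
    mean_speed_A: np.ndarray
    mean_speed_B: np.ndarray
    mean_siso_A: np.ndarray
    mean_siso_B: np.ndarray
    mean_lamdev_A: np.ndarray
    mean_lamdev_B: np.ndarray
    F_total: np.ndarray
    units: str = "sim"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean_speed_A": self.mean_speed_A,
                "mean_speed_B": self.mean_speed_B,
                "mean_siso_A": self.mean_siso_A,
                "mean_siso_B": self.mean_siso_B,
                "mean_lamdev_A": self.mean_lamdev_A,
                "mean_lamdev_B": self.mean_lamdev_B,
                "F_total": self.F_total,
            }
        )


def per_phase_series(traj: Trajectory) -> PhaseTimeSeries:
    """Mean speed, sigma_iso, |lambda_dev| per cell type, and |F(t)|."""
    if len(traj) == 0:
        raise ValueError("trajectory holds no snapshots")
    params = traj.config.params
    cols = {k: [] for k in (
        "speed_A", "speed_B", "siso_A", "siso_B", "lam_A", "lam_B", "F")}
    for state in traj.states:
        speed = state.speed
        siso = simulator_stress_iso(state, params)
        sig = simulator_stress_tensor(state, params)
        sym_xy = 0.5 * (sig[0, 1] + sig[1, 0])
        lam = np.sqrt((0.5 * (sig[0, 0] - sig[1, 1])) ** 2 + sym_xy**2)
        cols["speed_A"].append(phase_average(speed, state.phi, "A"))
        cols["speed_B"].append(phase_average(speed, state.phi, "B"))
        cols["siso_A"].append(phase_average(siso, state.phi, "A"))
        cols["siso_B"].append(phase_average(siso, state.phi, "B"))
        cols["lam_A"].append(phase_average(lam, state.phi, "A"))
        cols["lam_B"].append(phase_average(lam, state.phi, "B"))
        cols["F"].append(total_traction_magnitude(model_traction(state, params)))
    return PhaseTimeSeries(
        times=traj.times,
        mean_speed_A=np.array(cols["speed_A"]),
        mean_speed_B=np.array(cols["speed_B"]),
        mean_siso_A=np.array(cols["siso_A"]),
        mean_siso_B=np.array(cols["siso_B"]),
        mean_lamdev_A=np.array(cols["lam_A"]),
        mean_lamdev_B=np.array(cols["lam_B"]),
        F_total=np.array(cols["F"]),
    )


def convergence_index(series: PhaseTimeSeries, window: tuple | None = None) -> float:
    """Speed ratio A/B time-averaged over a window (default: final quarter)."""
    t = series.times
    if window is None:
        window = (t[-1] - (t[-1] - t[0]) / 4.0, t[-1])
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if not np.any(sel):
        raise ValueError("window contains no snapshots")
    denom = float(np.mean(series.mean_speed_B[sel]))
    if denom == 0.0:
        raise ZeroDivisionError("mean speed of phase B vanishes on the window")
    return float(np.mean(series.mean_speed_A[sel])) / denom


def total_traction_magnitude(traction: TractionField) -> float:
    """|F| = integral of |T| over the domain (force units)."""
    return float(np.sum(traction.magnitude) * traction.h**2)


# ---------------------------------------------------------------------------
# Boundary-distance correlation
# ---------------------------------------------------------------------------

def boundary_distance_map(mask: np.ndarray, h: float, periodic: bool = True) -> np.ndarray:
    """Euclidean distance (length units) to the nearest cell-type boundary node.

    Boundary nodes are nodes with a 4-neighbour of the opposite type.
    """
    mask = np.asarray(mask, dtype=bool)
    boundary = np.zeros_like(mask)
    for axis in (0, 1):
        for shift in (1, -1):
            boundary |= mask != np.roll(mask, shift, axis=axis)
    if not boundary.any():
        raise ValueError("mask contains a single phase; no boundary exists")
    if periodic:
        tiled = np.tile(~boundary, (3, 3))
        dist = ndimage.distance_transform_edt(tiled)
        n0, n1 = mask.shape
        dist = dist[n0 : 2 * n0, n1 : 2 * n1]
    else:
        dist = ndimage.distance_transform_edt(~boundary)
    return dist * h


def boundary_distance_correlation(
    stress_map: np.ndarray,
    mask: np.ndarray,
    cell_type: str = "A",
    h: float = 1.0,
    periodic: bool = True,
):
    """Pearson correlation of stress with distance to the type boundary.

    Returns (R, R^2, pairs) where pairs is an (n_nodes, 2) array of
    (distance, stress) samples for the requested cell type (A = mask
    True, B = mask False).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("mask contains a single phase")
    if cell_type not in ("A", "B"):
        raise ValueError("cell_type must be 'A' or 'B'")
    dist = boundary_distance_map(mask, h, periodic=periodic)
    sel = mask if cell_type == "A" else ~mask
    d = dist[sel].ravel()
    s = np.asarray(stress_map)[sel].ravel()
    r = float(stats.pearsonr(d, s).statistic)
    return r, r * r, np.column_stack([d, s])


# ---------------------------------------------------------------------------
# Calcium sparks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SparkEvent:
    """One supra-threshold intensity transient."""

    cell: int
    frame: int
    z: float


def _clipped_baseline(trace: np.ndarray, clip_sd: float = 3.0, max_iter: int = 20):
    """Mean/sd of the spark-free baseline via iterative sigma clipping."""
    keep = np.ones(trace.size, dtype=bool)
    for _ in range(max_iter):
        mean = trace[keep].mean()
        sd = trace[keep].std(ddof=1) if keep.sum() > 1 else 0.0
        if sd == 0.0:
            return mean, 0.0
        new = np.abs(trace - mean) <= clip_sd * sd
        if new.sum() < 3 or np.array_equal(new, keep):
            break
        keep = new
    return float(mean), float(sd)


def detect_sparks(
    traces: np.ndarray,
    threshold_sd: float = 5.0,
    baseline: str = "clipped",
) -> list[SparkEvent]:
    """Detect transient events exceeding baseline mean + threshold_sd * sd.

    Baseline statistics are computed per cell over its own trace;
    ``baseline`` selects the estimator: "clipped" (default; iterative
    3-sigma clipping, converging to the spark-free statistics), "plain"
    (full-trace mean/sd) or "robust" (median / 1.4826 MAD).  Consecutive
    supra-threshold frames merge into one event at the peak frame.
    Constant traces yield no events (warning).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] < 10:
        raise ValueError("traces must have at least 10 frames")
    events: list[SparkEvent] = []
    for cell, trace in enumerate(traces):
        if baseline == "clipped":
            mean, sd = _clipped_baseline(trace)
        elif baseline == "plain":
            mean, sd = float(trace.mean()), float(trace.std(ddof=1))
        elif baseline == "robust":
            mean = float(np.median(trace))
            sd = float(1.4826 * np.median(np.abs(trace - mean)))
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
        if sd == 0.0:
            warnings.warn(f"cell {cell}: constant trace, no spark detection")
            continue
        above = trace > mean + threshold_sd * sd
        if not above.any():
            continue
        # merge consecutive supra-threshold frames into single events
        idx = np.flatnonzero(above)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            peak = run[np.argmax(trace[run])]
            events.append(
                SparkEvent(cell=cell, frame=int(peak), z=float((trace[peak] - mean) / sd))
            )
    return events


# ---------------------------------------------------------------------------
# Domain size
# ---------------------------------------------------------------------------

class DomainSize(NamedTuple):
    """Characteristic domain length; degenerate flags a near-uniform field."""

    value: float
    degenerate: bool


def domain_size_metric(phi: np.ndarray, grid: Grid) -> DomainSize:
    """Characteristic domain length L^2 / (interface length).

    The interface length is measured as integral |grad phi| dA / 2, since
    a saturated interface contributes integral dphi = 2 per unit length.
    Area per unit interface length is the stereological domain width: a
    two-stripe state (two interfaces of length L) yields L/2, the stripe
    width.  A uniform field (no interface) reports the maximum L with the
    degenerate flag set; the value is capped at L.
    """
    g = grid.grad(phi)
    total = grid.integrate(np.hypot(g[0], g[1]))
    L = grid.length
    if total < 1.0e-12 * L:
        return DomainSize(L, True)
    length = total / 2.0
    value = L**2 / length
    if value >= L:
        return DomainSize(L, True)
    return DomainSize(float(value), False)
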