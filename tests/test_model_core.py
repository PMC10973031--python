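"""Free energy, constitutive fields, coefficient interpolation, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polarmix as pm
from polarmix.energy import variational_molecular_field


def _uniform(grid, value):
    return np.full((grid.n, grid.n), float(value))


# ---------------------------------------------------------------------------
# coefficient interpolation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "phi_val, expected",
    [(1.0, 1.0), (-1.0, 0.5), (0.0, 0.75)],
)
def test_interpolate_coefficient_pure_and_mid(grid32, phi_val, expected):
    out = pm.interpolate_coefficient(_uniform(grid32, phi_val), 1.0, 0.5)
    assert np.allclose(out, expected)


@given(
    phi=st.floats(-2.0, 2.0),
    a=st.floats(-5.0, 5.0),
    b=st.floats(-5.0, 5.0),
)
@settings(derandomize=True, max_examples=50)
def test_interpolate_coefficient_is_linear(phi, a, b):
    """Values at phi and -phi average to the midpoint (exact linearity)."""
    phi_arr = np.array([[phi]])
    plus = pm.interpolate_coefficient(phi_arr, a, b)
    minus = pm.interpolate_coefficient(-phi_arr, a, b)
    assert np.allclose((plus + minus) / 2.0, (a + b) / 2.0, atol=1e-12)


def test_interpolate_coefficient_rejects_nonfinite():
    with pytest.raises(ValueError):
        pm.interpolate_coefficient(np.array([[np.nan]]), 1.0, 0.5)


# ---------------------------------------------------------------------------
# chemical potential and molecular field
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi_val, mu_val", [(0.0, 0.0), (1.0, 0.0), (0.5, -0.0375)])
def test_chemical_potential_uniform(grid32, params, phi_val, mu_val):
    mu = pm.chemical_potential(_uniform(grid32, phi_val), params, grid32)
    assert np.allclose(mu, mu_val, atol=1e-14)


def test_molecular_field_uniform(grid32, params):
    n = grid32.n
    # unit-magnitude uniform polarity sits at the set-point: H = 0
    p = np.zeros((2, n, n))
    p[0] = 1.0
    assert np.allclose(pm.molecular_field(p, params, grid32), 0.0, atol=1e-14)
    # zero polarity: both terms vanish
    assert np.allclose(pm.molecular_field(np.zeros((2, n, n)), params, grid32), 0.0)
    # p = (0.5, 0): H_x = -a_p (1 - 0.25) 0.5 = -0.0375
    p[0] = 0.5
    H = pm.molecular_field(p, params, grid32)
    assert np.allclose(H[0], -0.0375, atol=1e-14)
    assert np.allclose(H[1], 0.0, atol=1e-14)


# ---------------------------------------------------------------------------
# velocity gradient decomposition
# ---------------------------------------------------------------------------

def test_strain_vorticity_zero_field(grid32):
    D, W = pm.strain_vorticity(np.zeros((2, grid32.n, grid32.n)), grid32)
    assert np.allclose(D, 0.0) and np.allclose(W, 0.0)


def test_strain_vorticity_periodic_shear(grid32):
    """v = (A sin(2 pi y / L), 0): locally a simple shear with rate
    gamma(y) = A (2 pi / L) cos(2 pi y / L)."""
    L = grid32.length
    A = 0.3
    v = np.zeros((2, grid32.n, grid32.n))
    v[0] = A * np.sin(2 * np.pi * grid32.y / L)
    gamma = A * (2 * np.pi / L) * np.cos(2 * np.pi * grid32.y / L)
    D, W = pm.strain_vorticity(v, grid32)
    assert np.allclose(D[0, 1], gamma / 2, atol=1e-10)
    assert np.allclose(D[1, 0], gamma / 2, atol=1e-10)
    assert np.allclose(D[0, 0], 0.0, atol=1e-10)
    # (grad v)_ij = d_i v_j: Omega_xy = (d_x v_y - d_y v_x)/2 = -gamma/2
    assert np.allclose(W[0, 1], -gamma / 2, atol=1e-10)
    assert np.allclose(W[1, 0], gamma / 2, atol=1e-10)
    # D symmetric, Omega antisymmetric, D + Omega = grad v
    assert np.allclose(D, np.swapaxes(D, 0, 1))
    assert np.allclose(W, -np.swapaxes(W, 0, 1))
    assert np.allclose((D + W)[1, 0], gamma, atol=1e-10)


def test_vorticity_corotates_polarity(grid32):
    """Periodic vortical flow: -Omega p rotates p with the local vorticity.

    At the cell-centre of the Taylor-Green-like vortex the flow is locally
    a rigid rotation; a material vector must turn the same way.
    """
    L = grid32.length
    k = 2 * np.pi / L
    v = np.zeros((2, grid32.n, grid32.n))
    v[0] = np.sin(k * grid32.x) * np.cos(k * grid32.y)
    v[1] = -np.cos(k * grid32.x) * np.sin(k * grid32.y)
    _, W = pm.strain_vorticity(v, grid32)
    omega_z = grid32.dx(v[1]) - grid32.dy(v[0])  # scalar vorticity
    # -Omega p with p = x_hat gives (0, omega_z/2): the +z vorticity turns
    # x_hat toward +y
    rot_y = -W[1, 0]  # (-Omega p)_y for p = (1, 0)
    assert np.allclose(rot_y, omega_z / 2.0, atol=1e-10)


# ---------------------------------------------------------------------------
# elastic stresses
# ---------------------------------------------------------------------------

def test_elastic_stress_polar_uniform(grid32, params):
    n = grid32.n
    p = np.zeros((2, n, n))
    p[0] = 0.5
    H = pm.molecular_field(p, params, grid32)
    sig = pm.elastic_stress_polar(p, H, params, grid32)
    # sigma_xx = -kappa p_x H_x = -0.7 * 0.5 * (-0.0375)
    assert np.allclose(sig[0, 0], 0.013125, atol=1e-14)
    assert np.allclose(sig[0, 1], 0.0, atol=1e-14)
    assert np.allclose(sig[1, 0], 0.0, atol=1e-14)


def test_elastic_stress_polar_antisymmetric_part(grid32, params):
    rng = np.random.default_rng(3)
    n = grid32.n
    p = np.stack([grid32.smooth(rng.normal(size=(n, n))) for _ in range(2)])
    H = pm.molecular_field(p, params, grid32)
    sig = pm.elastic_stress_polar(p, H, params, grid32)
    antisym = (sig - np.swapaxes(sig, 0, 1)) / 2.0
    expected = 0.5 * (p[0] * H[1] - H[0] * p[1])
    assert np.allclose(antisym[0, 1], expected, atol=1e-12)


def test_elastic_stress_phase_tanh_interface(params):
    grid = pm.Grid(128, params.L)
    delta = 2.0 * params.interface_width
    L = params.L
    phi = (
        np.tanh((grid.x - L / 4) / delta)
        - np.tanh((grid.x - 3 * L / 4) / delta)
        - 1.0
    )
    sig = pm.elastic_stress_phase(phi, params, grid)
    dphidx = grid.dx(phi)
    assert np.allclose(sig[0, 0], -params.K_phi * dphidx**2, atol=1e-10)
    assert np.allclose(sig[0, 1], 0.0, atol=1e-10)
    assert np.allclose(sig[1, 1], 0.0, atol=1e-10)
    # trace identity: tr sigma_phi = -K_phi |grad phi|^2 <= 0
    trace = sig[0, 0] + sig[1, 1]
    g = grid.grad(phi)
    assert np.allclose(trace, -params.K_phi * (g[0] ** 2 + g[1] ** 2), atol=1e-12)
    assert np.all(trace <= 1e-15)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def test_free_energy_ground_state_and_constant(grid32, params):
    n = grid32.n
    p = np.zeros((2, n, n))
    p[0] = 1.0
    assert pm.free_energy(_uniform(grid32, 1.0), p, params, grid32) == pytest.approx(0.0, abs=1e-12)
    # phi = 0, p = 0: F = (a/4 + a_p/2) L^2 = 0.075 * 2500
    F = pm.free_energy(_uniform(grid32, 0.0), np.zeros((2, n, n)), params, grid32)
    assert F == pytest.approx(187.5, rel=1e-12)


def test_free_energy_even_in_phi(grid32, params):
    rng = np.random.default_rng(5)
    n = grid32.n
    phi = grid32.smooth(rng.uniform(-0.5, 0.5, size=(n, n)))
    p = np.stack([grid32.smooth(rng.normal(size=(n, n))) for _ in range(2)])
    F1 = pm.free_energy(phi, p, params, grid32)
    F2 = pm.free_energy(-phi, p, params, grid32)
    assert F1 == pytest.approx(F2, rel=1e-12)
    assert F1 >= 0.0


def test_variational_consistency_on_small_grid(params):
    """mu and dF/dp match node-by-node central-difference perturbation of F.

    The local term of the dynamical molecular field H carries half the
    variational weight; its gradient (K_p) part is exactly variational.
    """
    grid = pm.Grid(8, params.L)
    rng = np.random.default_rng(11)
    n = grid.n
    phi = grid.smooth(rng.uniform(-0.5, 0.5, size=(n, n)))
    p = np.stack([grid.smooth(rng.normal(0, 0.5, size=(n, n))) for _ in range(2)])
    eps = 1e-6
    h2 = grid.h**2

    mu = pm.chemical_potential(phi, params, grid)
    num_mu = np.zeros_like(phi)
    for i in range(n):
        for j in range(n):
            up, dn = phi.copy(), phi.copy()
            up[i, j] += eps
            dn[i, j] -= eps
            num_mu[i, j] = (
                pm.free_energy(up, p, params, grid) - pm.free_energy(dn, p, params, grid)
            ) / (2 * eps * h2)
    assert np.allclose(num_mu, mu, atol=1e-6)

    H_var = variational_molecular_field(p, params, grid)
    num_H = np.zeros_like(p)
    for c in range(2):
        for i in range(n):
            for j in range(n):
                up, dn = p.copy(), p.copy()
                up[c, i, j] += eps
                dn[c, i, j] -= eps
                num_H[c, i, j] = (
                    pm.free_energy(phi, up, params, grid)
                    - pm.free_energy(phi, dn, params, grid)
                ) / (2 * eps * h2)
    assert np.allclose(num_H, H_var, atol=1e-6)

    # dynamical H: same K_p part, local part at half the variational weight
    H_pub = pm.molecular_field(p, params, grid)
    mag2 = p[0] ** 2 + p[1] ** 2
    local_pub = -params.a_p * (params.p0 - mag2) * p
    local_var = -2.0 * params.a_p * (1.0 - mag2) * p
    assert np.allclose(H_var - local_var, H_pub - local_pub, atol=1e-10)
    assert np.allclose(2.0 * local_pub, local_var, atol=1e-12)


# ---------------------------------------------------------------------------
# units and parameters
# ---------------------------------------------------------------------------

def test_to_physical_mappings(params):
    assert pm.to_physical(params.alpha_A / params.xi, "velocity", params) == 1.0
    assert pm.to_physical(params.interface_width, "length", params) == 5.0
    assert pm.to_physical(0.0, "time", params) == 0.0
    with pytest.raises(ValueError):
        pm.to_physical(1.0, "mass", params)


def test_characteristic_scales(params):
    scales = pm.characteristic_scales(params)
    assert scales["interface_width_um"] == pytest.approx(5.0)
    assert scales["speed_A_um_per_min"] == pytest.approx(1.0)
    assert scales["speed_B_um_per_min"] == pytest.approx(0.5)
    assert scales["speed_ratio"] == pytest.approx(2.0)
    assert scales["phase_relaxation_min"] == pytest.approx(10.0)
    assert scales["polarity_time_min"] == pytest.approx(20.0)


def test_default_preset_matches_reference_values():
    p = pm.reference_params()
    assert (p.alpha_A, p.alpha_B) == (1.0, 0.5)
    assert (p.nu_A, p.nu_B) == (5.0, 10.0)
    assert (p.xi, p.a, p.K_phi) == (1.0, 0.1, 0.05)
    assert (p.Gamma, p.M, p.a_p, p.kappa) == (5.0, 10.0, 0.1, 0.7)
    assert (p.L, p.dt) == (50.0, 1.0e-2)
    assert (p.time_unit, p.length_unit) == (10.0, 10.0)


def test_params_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        pm.ModelParams(a=-1.0)
    with pytest.raises(ValueError):
        pm.ModelParams(alpha_A=-0.1)
    p = pm.reference_params(K_p=2.0e-2, seed=42)
    path = tmp_path / "params.yaml"
    p.to_yaml(path)
    assert pm.ModelParams.from_yaml(path) == p
    with pytest.raises(ValueError, match="unknown parameter"):
        pm.ModelParams.from_dict({"a": 0.1, "bogus": 1.0})
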