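"""Core estimator: direction normalization, basis, group LASSO, refit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sivcmscreen.sivcm import (
    SivcmConfig,
    angle_between,
    build_basis,
    bic_select_lambda,
    group_lasso_coefficients,
    local_linear_refit,
    lssglasso_fit,
    normalize_direction,
    update_direction,
)
from sivcmscreen.sivcm import lambda_max, kkt_violation, _expanded_design, _rss
from sivcmscreen.synthetic import SivcmTruth, gen_sivcm_data


# ---------------------------------------------------------------------------
# normalize_direction
# ---------------------------------------------------------------------------

def test_normalize_reported_direction_is_canonical():
    # a published estimate in this convention should pass through unchanged
    theta = np.array([0.9346, -0.3380, -0.1109])
    nd = normalize_direction(theta)
    assert abs(np.linalg.norm(theta) - 1.0) < 1e-3
    np.testing.assert_allclose(nd.theta, theta, atol=2e-4)


def test_normalize_sign_and_scale():
    np.testing.assert_allclose(normalize_direction([-1, 0, 0]).theta, [1, 0, 0])
    np.testing.assert_allclose(normalize_direction([3, 4, 0]).theta, [0.6, 0.8, 0])


def test_normalize_tie_cascade():
    np.testing.assert_allclose(normalize_direction([0, -2, 0]).theta, [0, 1, 0])
    np.testing.assert_allclose(normalize_direction([0, 0, -5]).theta, [0, 0, 1])


def test_normalize_rejects_zero():
    with pytest.raises(ValueError):
        normalize_direction([0.0, 0.0, 0.0])


@given(st.lists(st.floats(-10, 10), min_size=2, max_size=5))
@settings(max_examples=100, deadline=None)
def test_normalize_idempotent_and_unit(v):
    arr = np.asarray(v)
    if np.linalg.norm(arr) < 1e-6:
        return
    nd = normalize_direction(arr)
    assert np.linalg.norm(nd.theta) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(normalize_direction(nd.theta).theta, nd.theta, atol=1e-12)


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def test_basis_partition_of_unity(rng):
    u = rng.standard_normal(200)
    basis = build_basis(u)
    assert basis.dim == 12  # 8 interior + cubic + 1
    B = basis.design(np.linspace(u.min(), u.max(), 57))
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_basis_clamps_outside_boundary(rng):
    u = rng.standard_normal(100)
    basis = build_basis(u)
    B = basis.design(np.array([u.min() - 5.0, u.max() + 5.0]))
    assert np.all(np.isfinite(B))
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_basis_rejects_too_few_points():
    with pytest.raises(ValueError):
        build_basis(np.arange(5, dtype=float))


def test_basis_derivative_matches_finite_difference(rng):
    u = rng.standard_normal(150)
    basis = build_basis(u)
    pts = np.linspace(u.min() + 0.1, u.max() - 0.1, 11)
    eps = 1e-6
    dB = basis.deriv_design(pts)
    fd = (basis.design(pts + eps) - basis.design(pts - eps)) / (2 * eps)
    np.testing.assert_allclose(dB, fd, atol=1e-5)


# ---------------------------------------------------------------------------
# group LASSO
# ---------------------------------------------------------------------------

def _instance(seed, n=50, p=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    u = rng.standard_normal(n)
    y = np.sin(u) + X[:, 1] * u + 0.3 * rng.standard_normal(n)
    return y, X, build_basis(u), u


def test_lambda_zero_matches_normal_equations():
    y, X, basis, u = _instance(0, n=80, p=2)
    gc = group_lasso_coefficients(y, X, basis, u, 0.0)
    D = _expanded_design(X, basis.design(u))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    np.testing.assert_allclose(D @ gc.gamma.ravel(), D @ beta, atol=1e-8)


def test_lambda_max_empties_selection():
    y, X, basis, u = _instance(1, n=60, p=3)
    lmax = lambda_max(y, X, basis, u)
    gc = group_lasso_coefficients(y, X, basis, u, lmax * (1 + 1e-10))
    assert gc.selected == []
    # and slightly below, at least one group is active
    gc2 = group_lasso_coefficients(y, X, basis, u, lmax * 0.95)
    assert gc2.selected != []


@pytest.mark.parametrize("seed", range(6))
def test_kkt_certificate(seed):
    y, X, basis, u = _instance(seed, n=50, p=2)
    lmax = lambda_max(y, X, basis, u)
    for frac in (0.5, 0.1, 0.02):
        gc = group_lasso_coefficients(y, X, basis, u, lmax * frac)
        assert kkt_violation(y, X, basis, u, lmax * frac, gc.gamma) < 1e-6


def test_group_lasso_rejects_negative_lambda():
    y, X, basis, u = _instance(2)
    with pytest.raises(ValueError):
        group_lasso_coefficients(y, X, basis, u, -0.1)


def test_intercept_group_never_penalized():
    y, X, basis, u = _instance(3)
    lmax = lambda_max(y, X, basis, u)
    gc = group_lasso_coefficients(y, X, basis, u, lmax * 10)
    assert np.linalg.norm(gc.gamma[0]) > 0
    assert gc.selected == []


# ---------------------------------------------------------------------------
# direction update
# ---------------------------------------------------------------------------

def _noiseless(n=500, seed=0):
    theta = normalize_direction([2.0, -1.0, 0.5]).theta
    zero = lambda u: np.zeros_like(u)
    gs = [lambda u: np.sin(u), lambda u: 1.0 + u, lambda u: u * u, zero]
    truth = SivcmTruth(theta, gs, noise_sd=0.0, n=n, seed=seed)
    return truth, gen_sivcm_data(truth)


def test_direction_fixed_point_at_truth():
    # polynomial coefficient functions lie exactly in the cubic spline space,
    # so the residual at the truth is zero and the step must not move theta
    theta = normalize_direction([2.0, -1.0, 0.5]).theta
    zero = lambda u: np.zeros_like(u)
    gs = [lambda u: 1.0 + u, lambda u: u * u, lambda u: 0.5 * u, zero]
    truth = SivcmTruth(theta, gs, noise_sd=0.0, n=500, seed=0)
    d = gen_sivcm_data(truth)
    u = d["u"]
    basis = build_basis(u)
    gc = group_lasso_coefficients(d["y"], d["X"], basis, u, 0.0)
    gc._basis = basis
    theta0 = normalize_direction(truth.theta_true)
    theta1, accepted = update_direction(d["y"], d["X"], d["Z"], gc, theta0)
    assert angle_between(theta1.theta, truth.theta_true) < 1e-6


def test_direction_step_never_increases_rss():
    truth, d = _noiseless(n=300, seed=4)
    start = normalize_direction(truth.theta_true + np.array([0.3, -0.2, 0.25]))
    u = d["Z"] @ start.theta
    basis = build_basis(u)
    gc = group_lasso_coefficients(d["y"], d["X"], basis, u, 0.0)
    gc._basis = basis
    theta = start
    for _ in range(5):
        rss_before = _rss(d["y"], d["X"], basis, d["Z"] @ theta.theta, gc.gamma)
        theta, accepted = update_direction(d["y"], d["X"], d["Z"], gc, theta)
        rss_after = _rss(d["y"], d["X"], basis, d["Z"] @ theta.theta, gc.gamma)
        assert rss_after <= rss_before + 1e-10


def test_direction_recovery_from_perturbed_start():
    # noiseless data, start ~5 degrees off: converge to within 1 degree
    truth, d = _noiseless(n=500, seed=1)
    cfg = SivcmConfig()
    perturbed = normalize_direction(truth.theta_true + 0.09 * np.array([0.0, 1.0, -0.5]))
    assert 3 < angle_between(perturbed.theta, truth.theta_true) < 8
    from sivcmscreen.sivcm import _alternating_fit

    theta, gc, basis, rss, n_alt = _alternating_fit(
        d["y"], d["X"], d["Z"], perturbed, lam=1e-6, config=cfg
    )
    assert angle_between(theta.theta, truth.theta_true) < 1.0


# ---------------------------------------------------------------------------
# BIC path
# ---------------------------------------------------------------------------

def test_bic_single_element_grid():
    truth, d = _noiseless(n=200, seed=2)
    rec, path = bic_select_lambda(d["y"], d["X"], d["Z"], lambda_grid=np.array([0.05]))
    assert rec["lam"] == 0.05
    assert len(path) == 1


def test_bic_chooses_minimum_and_records_path(small_sivcm_dataset):
    truth, d = small_sivcm_dataset
    cfg = SivcmConfig(n_lambda=12)
    fit = lssglasso_fit(d["y"], d["X"], d["Z"], cfg)
    assert fit.bic_path.min() == pytest.approx(
        fit.bic_path[np.argwhere(fit.lambda_path == fit.lambda_star)[0, 0]]
    )
    # the automatic path has the configured points, possibly extended upward
    # so its sparse end always contains the empty model
    assert len(fit.lambda_path) >= 12


# ---------------------------------------------------------------------------
# full fit properties
# ---------------------------------------------------------------------------

def test_fit_determinism(small_sivcm_dataset):
    truth, d = small_sivcm_dataset
    cfg = SivcmConfig(n_lambda=8, seed=5)
    f1 = lssglasso_fit(d["y"], d["X"], d["Z"], cfg)
    f2 = lssglasso_fit(d["y"], d["X"], d["Z"], cfg)
    np.testing.assert_array_equal(f1.theta.theta, f2.theta.theta)
    assert f1.selected == f2.selected
    np.testing.assert_array_equal(f1.bic_path, f2.bic_path)


def test_fit_requires_min_rows():
    truth, d = _noiseless(n=20)
    with pytest.raises(ValueError):
        lssglasso_fit(d["y"], d["X"], d["Z"], SivcmConfig(min_rows=30))


def test_fit_requires_ones_column(small_sivcm_dataset):
    truth, d = small_sivcm_dataset
    X = d["X"].copy()
    X[:, 0] = 2.0
    with pytest.raises(ValueError):
        lssglasso_fit(d["y"], X, d["Z"])


def test_fit_intercept_always_present_and_selection_permutes(small_sivcm_dataset):
    truth, d = small_sivcm_dataset
    cfg = SivcmConfig(n_lambda=10, seed=3)
    fit = lssglasso_fit(d["y"], d["X"], d["Z"], cfg)
    assert np.linalg.norm(fit.coeffs.gamma[0]) > 0  # intercept never dropped
    # permute predictor columns 1..p and check the selected set permutes
    p = d["X"].shape[1] - 1
    rng = np.random.default_rng(0)
    perm = rng.permutation(p)
    Xp = d["X"][:, [0] + [1 + int(k) for k in perm]]
    fit_p = lssglasso_fit(d["y"], Xp, d["Z"], cfg)
    # original column j=perm[k]+1 now sits at position k+1
    remapped = sorted(int(perm[j - 1]) + 1 for j in fit_p.selected)
    assert remapped == fit.selected


def test_report_serializes(small_sivcm_dataset):
    import json

    truth, d = small_sivcm_dataset
    fit = lssglasso_fit(d["y"], d["X"], d["Z"], SivcmConfig(n_lambda=6))
    blob = json.dumps(fit.to_report())
    assert "theta" in blob


# ---------------------------------------------------------------------------
# local-linear refit
# ---------------------------------------------------------------------------

def test_loclin_reproduces_constant():
    rng = np.random.default_rng(0)
    u = np.sort(rng.uniform(-1, 1, 300))
    y = np.full(300, 2.5)
    X = np.ones((300, 1))
    grid = np.linspace(-0.8, 0.8, 21)
    est = local_linear_refit(y, X, u, selected=[0], grid=grid, bandwidth=0.3)
    np.testing.assert_allclose(est[0], 2.5, atol=1e-8)


def test_loclin_reproduces_linear():
    rng = np.random.default_rng(1)
    u = np.sort(rng.uniform(-1, 1, 400))
    y = 1.0 + 2.0 * u
    X = np.ones((400, 1))
    grid = np.linspace(-0.7, 0.7, 15)
    est = local_linear_refit(y, X, u, selected=[0], grid=grid, bandwidth=0.25)
    np.testing.assert_allclose(est[0], 1.0 + 2.0 * grid, atol=1e-8)


def test_loclin_sine_benchmark():
    rng = np.random.default_rng(2)
    n = 1000
    u = rng.uniform(0, 1, n)
    y = np.sin(2 * np.pi * u) + rng.normal(0, 0.1, n)
    X = np.ones((n, 1))
    grid = np.linspace(0.05, 0.95, 50)
    est = local_linear_refit(y, X, u, selected=[0], grid=grid)
    rmse = np.sqrt(np.mean((est[0] - np.sin(2 * np.pi * grid)) ** 2))
    assert rmse < 0.1


def test_loclin_rejects_nonpositive_bandwidth():
    with pytest.raises(ValueError):
        local_linear_refit(
            np.zeros(20), np.ones((20, 1)), np.linspace(0, 1, 20),
            selected=[0], grid=np.array([0.5]), bandwidth=0.0,
        )


def test_loclin_backfitting_two_functions():
    # y = g0(u) + g1(u) x1 with smooth truths; backfit recovers both closely
    rng = np.random.default_rng(3)
    n = 800
    u = rng.uniform(-1, 1, n)
    x1 = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x1])
    g0 = lambda v: np.cos(v)
    g1 = lambda v: v
    y = g0(u) + g1(u) * x1 + rng.normal(0, 0.05, n)
    grid = np.linspace(-0.8, 0.8, 30)
    est = local_linear_refit(y, X, u, selected=[0, 1], grid=grid)
    assert np.sqrt(np.mean((est[0] - g0(grid)) ** 2)) < 0.08
    assert np.sqrt(np.mean((est[1] - g1(grid)) ** 2)) < 0.08
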