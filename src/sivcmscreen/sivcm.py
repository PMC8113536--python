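"""Single-index varying coefficient model (SIVCM) estimation and selection.

The model is

    y_i = sum_j g_j(theta' Z_i) * x_ij + eps_i,      x_i0 = 1,

where ``theta`` is a unit-norm index direction over the covariates ``Z``
(here longitude, latitude, year) and the ``g_j`` are smooth coefficient
functions. Estimation expands each ``g_j`` in a cubic B-spline basis and
alternates between (a) a group-LASSO fit of the spline coefficient blocks,
which zeroes entire coefficient functions and thereby selects variables,
and (b) a damped Gauss-Newton update of the index direction. The penalty
level is tuned by a BIC-type criterion over a lambda path; selected
functions are then re-estimated by local-linear kernel regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "IndexDirection",
    "SplineBasis",
    "GroupCoefficients",
    "SIVCMFit",
    "SivcmConfig",
    "normalize_direction",
    "build_basis",
    "group_lasso_coefficients",
    "update_direction",
    "bic_select_lambda",
    "lssglasso_fit",
    "local_linear_refit",
    "angle_between",
]


# ---------------------------------------------------------------------------
# index direction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexDirection:
    """Unit-norm index direction with a sign convention.

    The SIVCM index theta is identifiable only up to sign and scale, so the
    canonical representative has unit Euclidean norm and a positive leading
    component (with a tie cascade when leading components are exactly zero).
    """

    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))

    @property
    def dim(self) -> int:
        return self.theta.shape[0]


def normalize_direction(raw: Sequence[float]) -> IndexDirection:
    """Scale a vector to the canonical unit-norm index direction.

    Sign convention: flip the sign so the first nonzero component is
    positive (checking components in order — the "tie cascade").

    Raises
    ------
    ValueError
        If the vector is zero (the direction is undefined).
    """
    v = np.asarray(raw, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0 or not np.isfinite(nrm):
        raise ValueError("index direction must be a finite nonzero vector")
    v = v / nrm
    for comp in v:
        if comp > 0:
            break
        if comp < 0:
            v = -v
            break
    return IndexDirection(theta=v)


def angle_between(a: Sequence[float], b: Sequence[float]) -> float:
    """Angle in degrees between two directions, ignoring sign."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# spline basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """Cubic (by default) B-spline basis on the observed index range.

    Interior knots sit at empirical quantiles of the index values; the basis
    dimension is ``n_interior + degree + 1``. Index values outside the
    boundary knots are clamped to the boundary before evaluation, so the
    design never contains NaNs during direction updates.
    """

    knots: np.ndarray          # full knot vector (with repeated boundaries)
    degree: int
    lo: float
    hi: float

    @property
    def dim(self) -> int:
        return len(self.knots) - self.degree - 1

    def _clamp(self, u: np.ndarray) -> np.ndarray:
        return np.clip(u, self.lo, self.hi)

    def design(self, u: np.ndarray) -> np.ndarray:
        """n x L matrix of basis values at (clamped) index values."""
        u = self._clamp(np.asarray(u, float))
        return BSpline.design_matrix(u, self.knots, self.degree).toarray()

    def deriv_design(self, u: np.ndarray) -> np.ndarray:
        """n x L matrix of first derivatives of the basis functions.

        Zero outside the boundary (consistent with clamping).
        """
        u = np.asarray(u, float)
        inside = (u >= self.lo) & (u <= self.hi)
        uc = self._clamp(u)
        L = self.dim
        out = np.empty((u.shape[0], L))
        for l in range(L):
            c = np.zeros(L)
            c[l] = 1.0
            out[:, l] = BSpline(self.knots, c, self.degree)(uc, nu=1)
        out[~inside, :] = 0.0
        return out


def build_basis(u: np.ndarray, n_interior: int = 8, degree: int = 3) -> SplineBasis:
    """B-spline basis with interior knots at empirical quantiles of ``u``.

    With the defaults (8 interior knots, cubic) the dimension is 12.
    """
    u = np.asarray(u, float)
    L = n_interior + degree + 1
    if np.unique(u).size < L:
        raise ValueError(
            f"need at least {L} distinct index values for a basis of dimension {L}"
        )
    lo, hi = float(u.min()), float(u.max())
    qs = np.quantile(u, np.linspace(0, 1, n_interior + 2)[1:-1])
    # strictly inside the boundary to keep the knot vector valid
    qs = np.clip(qs, lo + 1e-10 * (hi - lo + 1), hi - 1e-10 * (hi - lo + 1))
    knots = np.concatenate([np.full(degree + 1, lo), np.sort(qs), np.full(degree + 1, hi)])
    return SplineBasis(knots=knots, degree=degree, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# group LASSO on the spline-expanded design
# ---------------------------------------------------------------------------

@dataclass
class GroupCoefficients:
    """Spline coefficient blocks gamma_j, one length-L block per predictor.

    ``gamma[0]`` parametrizes the intercept function g_0 and is never
    penalized; the selected set is the penalized blocks with nonzero norm.
    """

    gamma: np.ndarray            # (p+1, L)
    converged: bool = True
    n_iter: int = 0

    @property
    def selected(self) -> list[int]:
        return [j for j in range(1, self.gamma.shape[0]) if np.linalg.norm(self.gamma[j]) > 0]


def _expanded_design(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-blocked design D with block j = x_j (columnwise) * basis."""
    n, L = B.shape
    p1 = X.shape[1]
    D = np.empty((n, p1 * L))
    for j in range(p1):
        D[:, j * L:(j + 1) * L] = X[:, [j]] * B
    return D


def _block_solve(
    S_eig: tuple[np.ndarray, np.ndarray],
    c: np.ndarray,
    lam_w: float,
    mu_init: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Exact minimizer of (1/2) g'Sg - c'g + lam_w ||g||_2.

    ``S_eig`` is the eigendecomposition (vals, vecs) of the PSD block Gram
    matrix S. The solution is zero iff ||c|| <= lam_w; otherwise its norm
    solves a monotone scalar secular equation, found by safeguarded Newton
    (warm-startable at ``mu_init``). Returns (solution, mu) so callers can
    warm-start the next solve for the same block.
    """
    import math

    s, U = S_eig
    ct = U.T @ c
    ct2 = ct * ct
    cn = math.sqrt(float(ct2.sum()))
    if cn <= lam_w:
        return np.zeros_like(c), 0.0
    if lam_w == 0.0:
        return U @ (ct / np.maximum(s, 1e-300)), 0.0

    # g(mu) = mu * ||q(mu)|| - lam_w with q_k = ct_k/(s_k+mu) is increasing
    def g_and_slope(mu):
        d = s + mu
        r = ct2 / (d * d)
        phi = math.sqrt(float(r.sum()))
        gval = mu * phi - lam_w
        dphi = -float((r / d).sum()) / phi
        return gval, phi + mu * dphi

    lo, hi = 0.0, cn
    gval, _ = g_and_slope(hi)
    while gval < 0:
        lo = hi
        hi *= 2.0
        gval, _ = g_and_slope(hi)
    mu = mu_init if lo < mu_init < hi else 0.5 * (lo + hi)
    for _ in range(100):
        gval, slope = g_and_slope(mu)
        if abs(gval) <= 1e-12 * lam_w:
            break
        if gval > 0:
            hi = mu
        else:
            lo = mu
        step = mu - gval / slope if slope > 0 else None
        mu = step if (step is not None and lo < step < hi) else 0.5 * (lo + hi)
    return U @ (ct / (s + mu)), mu


def group_lasso_coefficients(
    y: np.ndarray,
    X: np.ndarray,
    basis: SplineBasis,
    u: np.ndarray,
    lam: float,
    gamma0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    kkt_tol: float = 1e-7,
) -> GroupCoefficients:
    """Group-LASSO fit of the spline coefficient blocks at fixed index.

    Minimizes ``(1/2n) ||y - sum_j (x_j * B) gamma_j||^2 +
    lam * sum_{j>=1} w_j ||gamma_j||_2`` with weights ``w_j = sqrt(L)``, by
    block coordinate descent with exact block minimization (the intercept
    block j=0 is unpenalized). Returned solutions satisfy the group-KKT
    conditions to high precision.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.shape[0]
    p1 = X.shape[1]
    B = basis.design(u)
    L = basis.dim
    w = np.sqrt(L)

    blocks = [X[:, [j]] * B for j in range(p1)]

    if lam == 0.0:
        # unpenalized limit: ordinary least squares on the expanded design
        D = np.hstack(blocks)
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        return GroupCoefficients(gamma=coef.reshape(p1, L), converged=True, n_iter=1)

    grams = [(b.T @ b) / n for b in blocks]
    eigs = [np.linalg.eigh(g) for g in grams]

    gamma = np.zeros((p1, L)) if gamma0 is None else np.array(gamma0, float, copy=True)
    fitted = sum(blocks[j] @ gamma[j] for j in range(p1))
    resid = y - fitted

    D = np.hstack(blocks)  # for the vectorized KKT check

    def kkt_resid():
        grads = -(D.T @ resid / n).reshape(p1, L)
        worst = float(np.linalg.norm(grads[0]))
        lam_w = lam * w
        for j in range(1, p1):
            gn = float(np.linalg.norm(gamma[j]))
            if gn > 0:
                worst = max(worst, float(np.linalg.norm(grads[j] + lam_w * gamma[j] / gn)))
            else:
                worst = max(worst, max(0.0, float(np.linalg.norm(grads[j])) - lam_w))
        return worst

    converged = False
    it = 0
    mu_warm = np.zeros(p1)
    nonzero = np.array([bool(np.any(gamma[j])) for j in range(p1)])
    for it in range(1, max_iter + 1):
        max_move = 0.0
        for j in range(p1):
            gj = gamma[j]
            if nonzero[j]:
                resid = resid + blocks[j] @ gj
            c = blocks[j].T @ resid / n
            lam_w = 0.0 if j == 0 else lam * w
            new, mu_warm[j] = _block_solve(eigs[j], c, lam_w, mu_init=mu_warm[j])
            gamma[j] = new
            move = float(np.max(np.abs(new - gj)))
            if move > max_move:
                max_move = move
            nonzero[j] = bool(np.any(new))
            if nonzero[j]:
                resid = resid - blocks[j] @ new
        if max_move <= max(tol, 1e-7) or it % 50 == 0:
            if kkt_resid() <= kkt_tol:
                converged = True
                break
    return GroupCoefficients(gamma=gamma, converged=converged, n_iter=it)


def lambda_max(y: np.ndarray, X: np.ndarray, basis: SplineBasis, u: np.ndarray) -> float:
    """Smallest lambda at which every penalized block is zero.

    Computed from the residual after fitting the unpenalized intercept
    block alone: ``max_j ||(x_j * B)' r0||_2 / (n w_j)``.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.shape[0]
    B = basis.design(u)
    L = basis.dim
    w = np.sqrt(L)
    D0 = X[:, [0]] * B
    coef0, *_ = np.linalg.lstsq(D0, y, rcond=None)
    r0 = y - D0 @ coef0
    lmax = 0.0
    for j in range(1, X.shape[1]):
        Dj = X[:, [j]] * B
        lmax = max(lmax, np.linalg.norm(Dj.T @ r0) / (n * w))
    return lmax


def kkt_violation(
    y: np.ndarray,
    X: np.ndarray,
    basis: SplineBasis,
    u: np.ndarray,
    lam: float,
    gamma: np.ndarray,
) -> float:
    """Maximum group-KKT residual of a candidate group-LASSO solution.

    Active penalized blocks must satisfy ``grad + lam*w*gamma/||gamma|| = 0``,
    inactive blocks ``||grad|| <= lam*w``, and the intercept block
    ``grad = 0`` (gradients of the smooth part, scaled by 1/n).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.shape[0]
    B = basis.design(u)
    L = basis.dim
    w = np.sqrt(L)
    blocks = [X[:, [j]] * B for j in range(X.shape[1])]
    resid = y - sum(blocks[j] @ gamma[j] for j in range(X.shape[1]))
    worst = 0.0
    for j in range(X.shape[1]):
        grad = -blocks[j].T @ resid / n
        gj = gamma[j]
        if j == 0:
            worst = max(worst, float(np.linalg.norm(grad)))
        elif np.linalg.norm(gj) > 0:
            worst = max(worst, float(np.linalg.norm(grad + lam * w * gj / np.linalg.norm(gj))))
        else:
            worst = max(worst, float(max(0.0, np.linalg.norm(grad) - lam * w)))
    return worst


# ---------------------------------------------------------------------------
# index direction update
# ---------------------------------------------------------------------------

def _rss(y, X, basis, u, gamma) -> float:
    B = basis.design(u)
    fitted = np.einsum("nj,jl,nl->n", X, gamma, B)
    r = y - fitted
    return float(r @ r)


def update_direction(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    coeffs: GroupCoefficients,
    theta_current: IndexDirection,
    max_halvings: int = 10,
) -> tuple[IndexDirection, bool]:
    """One damped Gauss-Newton step on theta with the spline blocks fixed.

    Uses the analytic basis derivative to form the Jacobian of the fitted
    values with respect to theta; the step is renormalized to the canonical
    direction and accepted only if the RSS does not increase (halving the
    step up to ``max_halvings`` times). Returns ``(theta, accepted)``; a
    singular Jacobian returns the current direction flagged not-accepted.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    gamma = coeffs.gamma
    theta = theta_current.theta
    basis = coeffs._basis  # set by caller (lssglasso internals)

    u = Z @ theta
    B = basis.design(u)
    dB = basis.deriv_design(u)
    fitted = np.einsum("nj,jl,nl->n", X, gamma, B)
    r = y - fitted
    slope = np.einsum("nj,jl,nl->n", X, gamma, dB)   # d fitted / d u
    J = slope[:, None] * Z                            # d fitted / d theta
    JtJ = J.T @ J
    try:
        delta = np.linalg.solve(JtJ + 1e-10 * np.eye(JtJ.shape[0]), J.T @ r)
    except np.linalg.LinAlgError:
        return theta_current, False
    if not np.all(np.isfinite(delta)):
        return theta_current, False

    rss_old = float(r @ r)
    step = 1.0
    for _ in range(max_halvings + 1):
        cand = theta + step * delta
        if np.linalg.norm(cand) > 0:
            cand_dir = normalize_direction(cand)
            rss_new = _rss(y, X, basis, Z @ cand_dir.theta, gamma)
            if rss_new <= rss_old:
                return cand_dir, True
        step *= 0.5
    return theta_current, False


# ---------------------------------------------------------------------------
# full LSSGLASSO fit
# ---------------------------------------------------------------------------

@dataclass
class SivcmConfig:
    """Tuning constants for the LSSGLASSO procedure."""

    n_interior_knots: int = 8
    degree: int = 3
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    max_alternations: int = 200
    rel_tol: float = 1e-6
    min_rows: int = 30
    n_restarts: int = 3            # theta starts: OLS plus random, pilot-screened
    pilot_lambda_ratio: float = 0.01
    pilot_alternations: int = 50
    # interior path solves run at a looser certificate for speed; the chosen
    # solution is re-polished at the tight tolerance before it is returned
    path_kkt_tol: float = 1e-5
    final_kkt_tol: float = 1e-7
    refit_grid_size: int = 100
    bandwidth: float | None = None  # None -> rule of thumb
    seed: int = 0
    standardize: bool = True


@dataclass
class SIVCMFit:
    """Complete result of an LSSGLASSO fit."""

    theta: IndexDirection
    coeffs: GroupCoefficients
    basis: SplineBasis
    selected: list[int]
    lambda_path: np.ndarray
    bic_path: np.ndarray
    lambda_star: float
    rss: float
    n_obs: int
    refit_grid: np.ndarray | None = None
    refit_values: dict[int, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_report(self) -> dict:
        """Plain-JSON-serializable summary of the fit."""
        return {
            "theta": self.theta.theta.tolist(),
            "selected": list(self.selected),
            "lambda_star": float(self.lambda_star),
            "lambda_path": self.lambda_path.tolist(),
            "bic_path": self.bic_path.tolist(),
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "refit_grid": None if self.refit_grid is None else self.refit_grid.tolist(),
            "refit_values": {str(j): v.tolist() for j, v in self.refit_values.items()},
        }


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd


def _alternating_fit(y, X, Z, theta_init, lam, config, gamma_warm=None):
    """Alternate group-LASSO block fits and theta steps at one lambda.

    The basis knots are frozen at the start (from the warm-start index) so
    the objective is well-defined and monotone across the alternation.
    """
    theta = theta_init
    u = Z @ theta.theta
    basis = build_basis(u, config.n_interior_knots, config.degree)
    kkt_tol = config.path_kkt_tol
    coeffs = group_lasso_coefficients(y, X, basis, u, lam, gamma0=gamma_warm,
                                      tol=1e-6, kkt_tol=kkt_tol)
    coeffs._basis = basis
    rss = _rss(y, X, basis, u, coeffs.gamma)
    n_alt = 0
    for n_alt in range(1, config.max_alternations + 1):
        theta_new, accepted = update_direction(y, X, Z, coeffs, theta)
        theta = theta_new
        u = Z @ theta.theta
        coeffs = group_lasso_coefficients(y, X, basis, u, lam, gamma0=coeffs.gamma,
                                          tol=1e-6, kkt_tol=kkt_tol)
        coeffs._basis = basis
        new_rss = _rss(y, X, basis, u, coeffs.gamma)
        done = abs(rss - new_rss) <= config.rel_tol * max(rss, 1e-12)
        rss = new_rss
        if done:
            break
    return theta, coeffs, basis, rss, n_alt


def _direction_grid(d: int, n_points: int = 60) -> list[np.ndarray]:
    """Coarse deterministic grid of unit directions on the half-sphere."""
    if d == 1:
        return [np.array([1.0])]
    if d == 2:
        angles = np.linspace(0, np.pi, n_points, endpoint=False)
        return [np.array([np.cos(a), np.sin(a)]) for a in angles]
    # Fibonacci sphere for d = 3; generic Gaussian grid for d > 3
    if d == 3:
        pts = []
        golden = (1 + 5 ** 0.5) / 2
        for k in range(2 * n_points):
            z = 1 - (2 * k + 1) / (2 * n_points)  # upper half only
            if z < 0:
                break
            r = np.sqrt(max(0.0, 1 - z * z))
            phi = 2 * np.pi * k / golden
            pts.append(np.array([r * np.cos(phi), r * np.sin(phi), z]))
        return pts
    rng = np.random.default_rng(0)
    return [v / np.linalg.norm(v) for v in rng.standard_normal((4 * n_points, d))]


def _profile_rss(y, Z, theta, n_interior, degree):
    """RSS of the intercept-only single-index spline y ~ g0(theta'Z)."""
    u = Z @ theta
    try:
        basis = build_basis(u, n_interior, degree)
    except ValueError:
        return np.inf
    B = basis.design(u)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    r = y - B @ coef
    return float(r @ r)


def _ols_theta_init(y, Z):
    Zc = np.column_stack([np.ones(len(y)), Z])
    beta, *_ = np.linalg.lstsq(Zc, y, rcond=None)
    v = beta[1:]
    if np.linalg.norm(v) < 1e-12:
        v = np.ones(Z.shape[1])
    return normalize_direction(v)


def bic_select_lambda(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    config: SivcmConfig | None = None,
    lambda_grid: np.ndarray | None = None,
    theta_init: IndexDirection | None = None,
):
    """Run the alternating fit along a decreasing lambda path, tuned by BIC.

    BIC(lambda) = n log(RSS/n) + df log(n) with df = L * (|S|+1); ties go to
    the larger (sparser) lambda. Returns (lambda_star, path diagnostics).
    """
    config = config or SivcmConfig()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    n = len(y)
    theta0 = theta_init or _ols_theta_init(y, Z)

    u0 = Z @ theta0.theta
    basis0 = build_basis(u0, config.n_interior_knots, config.degree)
    L = basis0.dim
    extend_top = lambda_grid is None
    if lambda_grid is None:
        lmax = lambda_max(y, X, basis0, u0)
        if lmax <= 0:
            lmax = 1e-8
        lambda_grid = np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    def fit_one(lam, theta, gamma_warm):
        theta, coeffs, basis, rss, n_alt = _alternating_fit(
            y, X, Z, theta, lam, config, gamma_warm=gamma_warm
        )
        k = len(coeffs.selected)
        bic = n * np.log(max(rss, 1e-300) / n) + L * (k + 1) * np.log(n)
        return dict(lam=lam, bic=bic, rss=rss, theta=theta, coeffs=coeffs,
                    basis=basis, n_alt=n_alt, converged=coeffs.converged)

    records = []
    theta, gamma_warm = theta0, None

    # the top of the path must contain the empty model: lambda_max is exact
    # only at the initial index, and the direction update can let groups
    # re-enter, so extend upward until the sparsest fit really is empty
    top = fit_one(lambda_grid[0], theta, gamma_warm)
    extensions = []
    lam_top = lambda_grid[0]
    for _ in range(8 if extend_top else 0):
        if not top["coeffs"].selected:
            break
        extensions.append(top)
        lam_top *= 2.0
        top = fit_one(lam_top, top["theta"], None)
    records.append(top)
    records.extend(reversed(extensions))
    theta, gamma_warm = records[-1]["theta"], records[-1]["coeffs"].gamma

    for lam in lambda_grid[1:]:
        rec = fit_one(lam, theta, gamma_warm)
        theta, gamma_warm = rec["theta"], rec["coeffs"].gamma
        records.append(rec)
    if all(not r["converged"] for r in records):
        raise RuntimeError("no lambda on the path produced a converged fit")
    bics = np.array([r["bic"] for r in records])
    # grid is decreasing, so argmin picks the largest lambda among ties
    best = int(np.argmin(bics))
    return records[best], records


def lssglasso_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    config: SivcmConfig | None = None,
) -> SIVCMFit:
    """Full LSSGLASSO: standardize, tune lambda by BIC, local-linear refit.

    ``X`` must carry its leading ones column; ``Z`` holds the index
    covariates. Responses, predictors (except the ones column) and index
    covariates are standardized before fitting. Raises on fewer than
    ``config.min_rows`` observations (drives per-year skip logic upstream).
    """
    config = config or SivcmConfig()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    n = len(y)
    if n < config.min_rows:
        raise ValueError(f"need at least {config.min_rows} rows, got {n}")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("X must have a leading all-ones column")

    if config.standardize:
        ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        Xs = X.copy()
        if X.shape[1] > 1:
            Xs[:, 1:] = _standardize(X[:, 1:])
        Zs = _standardize(Z)
    else:
        ys, Xs, Zs = y, X, Z

    rng = np.random.default_rng(config.seed)
    d = Zs.shape[1]
    starts = [_ols_theta_init(ys, Zs)]
    for _ in range(max(0, config.n_restarts - 1)):
        starts.append(normalize_direction(rng.standard_normal(d)))
    # coarse global screen of the intercept-only profile (one spline
    # regression per grid direction), keeping the best few grid directions
    grid = [(normalize_direction(v), _profile_rss(
        ys, Zs, normalize_direction(v).theta, config.n_interior_knots, config.degree
    )) for v in _direction_grid(d)]
    grid.sort(key=lambda t: t[1])
    starts += [th for th, _ in grid[:3]]

    # two-stage start screening: refine every candidate on the cheap
    # intercept-only single-index profile (y ~ g0(theta'Z)), then run the
    # group-LASSO pilot from the two best profiles and keep the lowest RSS
    if len(starts) > 1:
        ones = np.ones((len(ys), 1))
        profile_cfg = SivcmConfig(
            **{**config.__dict__, "max_alternations": config.pilot_alternations}
        )
        refined = []
        for th0 in starts:
            theta_r, _, _, rss_r, _ = _alternating_fit(ys, ones, Zs, th0, 0.0, profile_cfg)
            refined.append((rss_r, theta_r))
        refined.sort(key=lambda t: t[0])
        finalists = [th for _, th in refined[:2]]

        u0 = Zs @ finalists[0].theta
        basis0 = build_basis(u0, config.n_interior_knots, config.degree)
        lam_pilot = lambda_max(ys, Xs, basis0, u0) * config.pilot_lambda_ratio
        pilot_cfg = SivcmConfig(
            **{**config.__dict__, "max_alternations": config.pilot_alternations}
        )
        best_theta, best_rss = None, np.inf
        for th0 in finalists:
            theta_p, _, _, rss_p, _ = _alternating_fit(ys, Xs, Zs, th0, lam_pilot, pilot_cfg)
            if rss_p < best_rss:
                best_theta, best_rss = theta_p, rss_p
        starts = [best_theta]

    best_rec, best_path, best_bic = None, None, np.inf
    for th0 in starts:
        rec, path = bic_select_lambda(ys, Xs, Zs, config, theta_init=th0)
        if rec["bic"] < best_bic:
            best_rec, best_path, best_bic = rec, path, rec["bic"]

    theta = best_rec["theta"]
    basis = best_rec["basis"]
    u = Zs @ theta.theta
    # polish the chosen solution at the tight certificate tolerance
    coeffs = group_lasso_coefficients(
        ys, Xs, basis, u, best_rec["lam"], gamma0=best_rec["coeffs"].gamma,
        kkt_tol=config.final_kkt_tol,
    )
    coeffs._basis = basis
    best_rec["rss"] = _rss(ys, Xs, basis, u, coeffs.gamma)

    grid = np.linspace(np.quantile(u, 0.02), np.quantile(u, 0.98), config.refit_grid_size)
    refit_vals = local_linear_refit(
        ys, Xs, u, selected=[0] + coeffs.selected, grid=grid,
        bandwidth=config.bandwidth,
    )

    return SIVCMFit(
        theta=theta,
        coeffs=coeffs,
        basis=basis,
        selected=coeffs.selected,
        lambda_path=np.array([r["lam"] for r in best_path]),
        bic_path=np.array([r["bic"] for r in best_path]),
        lambda_star=float(best_rec["lam"]),
        rss=float(best_rec["rss"]),
        n_obs=n,
        refit_grid=grid,
        refit_values=refit_vals,
        diagnostics={
            "n_alternations": best_rec["n_alt"],
            "converged": bool(best_rec["converged"]),
            "n_starts": len(starts),
        },
    )


# ---------------------------------------------------------------------------
# local-linear re-estimation
# ---------------------------------------------------------------------------

def _epanechnikov(t: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - t * t)
    out[np.abs(t) >= 1.0] = 0.0
    return out


def _loclin_smooth(r, x, u, eval_points, h, min_neighbors=10):
    """Local-linear estimate of g in r_i ~ g(u_i) x_i at eval_points.

    At each point solves the kernel-weighted least squares in (a, b) for
    r ~ (a + b (u - u0)) x; widens the bandwidth locally to keep at least
    ``min_neighbors`` observations in the window.
    """
    est = np.empty(len(eval_points))
    for k, u0 in enumerate(eval_points):
        d = np.abs(u - u0)
        hk = h
        if np.sum(d < hk) < min_neighbors:
            hk = np.partition(d, min(min_neighbors, len(d) - 1))[
                min(min_neighbors, len(d) - 1)
            ] * (1 + 1e-12) + 1e-300
        wgt = _epanechnikov((u - u0) / hk)
        m = wgt > 0
        Xd = np.column_stack([x[m], x[m] * (u[m] - u0)])
        W = wgt[m]
        A = Xd.T @ (Xd * W[:, None])
        bvec = Xd.T @ (W * r[m])
        try:
            sol = np.linalg.solve(A + 1e-12 * np.eye(2), bvec)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, bvec, rcond=None)[0]
        est[k] = sol[0]
    return est


def rule_of_thumb_bandwidth(u: np.ndarray) -> float:
    """h = 1.06 sd(u) n^(-1/5)."""
    u = np.asarray(u, float)
    return float(1.06 * u.std() * len(u) ** (-0.2))


def local_linear_refit(
    y: np.ndarray,
    X: np.ndarray,
    u: np.ndarray,
    selected: Sequence[int],
    grid: np.ndarray,
    bandwidth: float | None = None,
    max_cycles: int = 5,
    rel_tol: float = 1e-5,
) -> dict[int, np.ndarray]:
    """Re-estimate selected coefficient functions by local-linear backfitting.

    Cycles over the selected functions; each g_j is refit by Epanechnikov
    local-linear regression of the partial residual on the index with
    design weight x_j, for ``max_cycles`` cycles or until the fitted values
    change by less than ``rel_tol`` (relative). Returns estimates on
    ``grid`` keyed by predictor number.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    u = np.asarray(u, float)
    grid = np.asarray(grid, float)
    sel = list(selected)
    h = bandwidth if bandwidth is not None else rule_of_thumb_bandwidth(u)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    g_at_data = {j: np.zeros(len(y)) for j in sel}
    for cycle in range(max_cycles):
        max_change = 0.0
        for j in sel:
            partial = y - sum(g_at_data[k] * X[:, k] for k in sel if k != j)
            new = _loclin_smooth(partial, X[:, j], u, u, h)
            change = np.max(np.abs(new - g_at_data[j]))
            scale = max(1.0, np.max(np.abs(new)))
            max_change = max(max_change, change / scale)
            g_at_data[j] = new
        if max_change < rel_tol:
            break

    out = {}
    for j in sel:
        partial = y - sum(g_at_data[k] * X[:, k] for k in sel if k != j)
        out[j] = _loclin_smooth(partial, X[:, j], u, grid, h)
    return out
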