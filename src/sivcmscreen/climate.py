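"""Associating selection patterns and responses with climate indices.

Two stages mirror the screening analysis:

1. For each environmental variable within a species-response, a logistic
   regression of the binary per-year selection indicator on the lagged
   seasonal amplitude of a climate index (PDO / MEI / NPGO), compared with
   an intercept-only model by a likelihood-ratio chi-square test, with
   Benjamini-Hochberg FDR adjustment within the species-response family.

2. A Gaussian additive model per response with three penalized cubic
   B-spline smooths, one per climate-index amplitude, with smoothing
   levels chosen by generalized cross-validation; reported per smooth are
   the effective degrees of freedom and a Wald-type p-value, plus the
   model's deviance explained (1 - RSS/TSS in the Gaussian case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import chi2, f as f_dist

__all__ = [
    "climate_amplitude",
    "logistic_lrt",
    "bh_adjust",
    "AssociationResult",
    "screen_selection_series",
    "GamSummary",
    "fit_additive_model",
    "deviance_explained",
    "SCREENING_YEARS",
]

SCREENING_YEARS = (1985, 2013)


# ---------------------------------------------------------------------------
# climate amplitudes
# ---------------------------------------------------------------------------

def climate_amplitude(
    monthly: pd.DataFrame,
    year: int,
    djf_year_convention: str = "previous",
) -> float:
    """mean(Jun,Jul,Aug) - mean(Dec,Jan,Feb) of a monthly index series.

    ``monthly`` has columns year,month,value. December belongs to year t-1
    under the 'previous' convention (winter preceding the summer) or to
    year t under 'same'. Any missing required month yields NaN.
    """
    vals = monthly.set_index(["year", "month"])["value"]
    vals = vals[~vals.index.duplicated(keep="last")]

    def get(yr, m):
        return vals.get((yr, m), float("nan"))

    jja = [get(year, m) for m in (6, 7, 8)]
    dec_year = year - 1 if djf_year_convention == "previous" else year
    djf = [get(dec_year, 12), get(year, 1), get(year, 2)]
    allv = jja + djf
    if any(not np.isfinite(v) for v in allv):
        return float("nan")
    return float(np.mean(jja) - np.mean(djf))


def climate_amplitude_series(
    monthly: pd.DataFrame,
    djf_year_convention: str = "previous",
) -> pd.Series:
    """Per-year JJA-DJF amplitudes for one index's monthly series."""
    years = sorted(monthly["year"].unique())
    return pd.Series(
        {y: climate_amplitude(monthly, y, djf_year_convention) for y in years},
        name="amplitude",
    ).rename_axis("year")


# ---------------------------------------------------------------------------
# logistic likelihood-ratio screening
# ---------------------------------------------------------------------------

def logistic_lrt(selection: np.ndarray, amplitude: np.ndarray) -> dict:
    """LRT of a logistic slope on the amplitude vs an intercept-only model.

    Fits a binomial GLM with logit link (IRLS, via statsmodels); the
    statistic is null deviance minus model deviance, referred to a
    chi-square with 1 df. Degenerate inputs are flagged instead of raising:
    a constant selection series is 'untestable'; (quasi-)complete
    separation is 'separation'; both report a missing p-value.
    """
    import statsmodels.api as sm

    sel = np.asarray(selection, float)
    amp = np.asarray(amplitude, float)
    m = np.isfinite(sel) & np.isfinite(amp)
    sel, amp = sel[m], amp[m]
    out = {"lrt": float("nan"), "p": float("nan"), "df": 1, "flag": "ok", "n": int(len(sel))}
    if len(sel) < 5:
        out["flag"] = "too_few_years"
        return out
    if np.all(sel == sel[0]):
        out["flag"] = "untestable"
        return out

    Xd = sm.add_constant(amp)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(sel, Xd, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e3:
            out["flag"] = "separation"
            return out
        mu = res.fittedvalues
        if np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            out["flag"] = "separation"
            return out
        lrt = float(res.null_deviance - res.deviance)
    except Exception:
        out["flag"] = "separation"
        return out
    out["lrt"] = max(lrt, 0.0)
    out["p"] = float(chi2.sf(out["lrt"], df=1))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through.

    adjusted p_(i) = min_{j >= i} min(1, m p_(j) / j) in sort order, mapped
    back to the original order; the family size m counts non-missing tests.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    adj = np.minimum(1.0, m * ranked / np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class AssociationResult:
    """Per (variable, climate index) screening outcome."""

    species: str
    response: str
    variable: str
    index: str
    lrt: float
    p: float
    p_adj: float
    flag: str
    n_years: int


def screen_selection_series(
    selection: pd.DataFrame,
    climate_amps: dict[str, pd.Series],
    species: str,
    response: str,
    years: tuple[int, int] = SCREENING_YEARS,
    lag: int = 5,
) -> pd.DataFrame:
    """Logistic LRT of every (variable, index) pair, BH-adjusted per family.

    ``selection`` is a binary variable x year frame (columns = integer
    years); ``climate_amps`` maps index name to its per-year amplitude
    series (unlagged years). The response year t is paired with the
    amplitude at t - lag. Screening is restricted to the years window. The
    BH family is all (variable x index) tests within the species-response.
    """
    y0, y1 = years
    use_years = [c for c in selection.columns if isinstance(c, (int, np.integer)) and y0 <= c <= y1]
    rows = []
    for var, sel_row in selection.iterrows():
        sel = sel_row[use_years].to_numpy(float)
        for idx_name, amps in climate_amps.items():
            amp = np.array([amps.get(t - lag, np.nan) for t in use_years], float)
            r = logistic_lrt(sel, amp)
            rows.append(
                dict(species=species, response=response, variable=var, index=idx_name,
                     lrt=r["lrt"], p=r["p"], flag=r["flag"], n_years=r["n"])
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# penalized-spline additive model
# ---------------------------------------------------------------------------

def _smooth_basis(x: np.ndarray, df: int = 10, degree: int = 3):
    """Centered B-spline basis with a second-difference penalty.

    Builds a ``df``-column B-spline basis with interior knots at quantiles,
    then reparametrizes into the (df-1)-dimensional subspace orthogonal to
    the column-mean vector so the smooth sums to zero over the data (the
    model's intercept carries the level). Returns (basis matrix, penalty).
    """
    x = np.asarray(x, float)
    n_segments = df - degree
    if n_segments < 1:
        raise ValueError("df too small for the requested degree")
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo if hi > lo else 1.0
    h = span / n_segments
    # uniform extended knots (Eilers-Marx P-spline): every basis coefficient
    # sits at an equally spaced Greville site, so the second-difference
    # penalty's null space contains exactly the linear functions of x
    knots = lo + h * np.arange(-degree, n_segments + degree + 1)
    B = BSpline.design_matrix(
        np.clip(x, knots[degree], knots[-degree - 1]), knots, degree
    ).toarray()

    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    S = D.T @ D

    c = B.mean(axis=0)
    # orthonormal basis of the null space of c' (QR of c, drop first column)
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, : k - 1]]))
    Znull = q[:, 1:k]
    return B @ Znull, Znull.T @ S @ Znull


@dataclass
class GamSummary:
    """Per-response additive-model summary."""

    smooth_names: list[str]
    edf: dict[str, float]
    p_values: dict[str, float]
    deviance_explained: float
    fitted: np.ndarray
    intercept: float
    lambdas: dict[str, float]
    flags: list[str] = field(default_factory=list)


def deviance_explained(y: np.ndarray, fitted: np.ndarray) -> float:
    """Gaussian deviance explained, 1 - RSS/TSS; NaN when TSS is zero."""
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    if len(y) != len(fitted):
        raise ValueError("y and fitted must have equal length")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return float("nan")
    rss = float(np.sum((y - fitted) ** 2))
    return 1.0 - rss / tss


GCV_GAMMA = 1.4  # df inflation in GCV (Kim & Gu); tempers undersmoothing


def _gam_solve(X, y, S_blocks, slices, lambdas):
    """Penalized normal equations, edf per block, and GCV score."""
    n, p = X.shape
    P = np.zeros((p, p))
    for (sl, S), lam in zip(zip(slices, S_blocks), lambdas):
        P[sl, sl] += lam * S
    XtX = X.T @ X
    A = XtX + P
    Ainv = np.linalg.solve(A, np.eye(p))
    beta = Ainv @ (X.T @ y)
    # influence matrix trace by blocks of F = (X'X + P)^-1 X'X
    F = Ainv @ XtX
    edf_total = float(np.trace(F))
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    # floor the numerator at numerical zero so near-interpolating fits tie
    # on RSS and GCV resolves toward the smoother (lower-edf) candidate;
    # the gamma = 1.4 df inflation guards against small-sample undersmoothing
    tss = float(np.sum((y - y.mean()) ** 2))
    gcv = n * max(rss, 1e-10 * tss) / max(n - GCV_GAMMA * edf_total, 1e-8) ** 2
    return beta, Ainv, F, fitted, rss, edf_total, gcv


def fit_additive_model(
    y: np.ndarray,
    covariates: pd.DataFrame,
    basis_df: int = 10,
    degree: int = 3,
    lambda_grid: np.ndarray | None = None,
    min_years: int = 15,
) -> GamSummary:
    """Gaussian additive model with one penalized cubic spline per covariate.

    E(y) = f0 + f1(x1) + f2(x2) + f3(x3) with second-difference penalties;
    per-smooth smoothing parameters are chosen by generalized cross-
    validation (with the usual gamma = 1.4 df inflation) via coordinate-wise
    grid search. Per-smooth p-values are Wald-type statistics on the
    smooth's coefficients under the Bayesian coefficient covariance, with
    the smooth's effective df, referred to an F distribution with residual
    df from the fitted influence trace.
    """
    y = np.asarray(y, float)
    cov = covariates.copy()
    m = np.isfinite(y) & np.isfinite(cov.to_numpy(float)).all(axis=1)
    y, cov = y[m], cov.loc[m]
    n = len(y)
    if n < min_years:
        raise ValueError(f"need at least {min_years} complete cases, got {n}")

    names = list(cov.columns)
    bases, penalties, slices = [], [], []
    start = 1
    for c in names:
        Bc, Sc = _smooth_basis(cov[c].to_numpy(float), df=basis_df, degree=degree)
        bases.append(Bc)
        penalties.append(Sc)
        slices.append(slice(start, start + Bc.shape[1]))
        start += Bc.shape[1]
    X = np.column_stack([np.ones(n)] + bases)
    flags = []
    if np.linalg.matrix_rank(X) < min(X.shape):
        flags.append("rank_deficient")

    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-4, 1e7, 23)

    grid_desc = np.sort(np.asarray(lambda_grid, float))[::-1]
    lambdas = np.full(len(names), float(grid_desc[0]))
    # coordinate-wise GCV search, two sweeps; ties favor the smoother fit
    for _ in range(2):
        for k in range(len(names)):
            best_g, best_l = np.inf, lambdas[k]
            for lam in grid_desc:
                trial = lambdas.copy()
                trial[k] = lam
                *_, gcv = _gam_solve(X, y, penalties, slices, trial)
                if gcv < best_g:
                    best_g, best_l = gcv, lam
            lambdas[k] = best_l

    beta, Ainv, F, fitted, rss, edf_total, _ = _gam_solve(X, y, penalties, slices, lambdas)
    sigma2 = rss / max(n - edf_total, 1.0)
    Vb = sigma2 * Ainv   # Bayesian covariance of beta, as in mgcv's smooth tests

    edf, pvals = {}, {}
    resid_df = max(n - edf_total, 1.0)
    for name, sl in zip(names, slices):
        edf_k = float(np.trace(F[sl, sl]))
        edf_k = max(edf_k, 1e-8)
        bk = beta[sl]
        Vk = Vb[sl, sl]
        # rank-truncated Wald statistic at the smooth's effective dimension
        evals, evecs = np.linalg.eigh(Vk)
        r = int(np.clip(np.ceil(edf_k - 1e-8), 1, len(bk)))
        idx = np.argsort(evals)[::-1][:r]
        use = evals[idx] > max(evals.max(), 0) * 1e-10
        T = 0.0
        for i, keep in zip(idx, use):
            if keep:
                proj = evecs[:, i] @ bk
                T += proj * proj / evals[i]
        df1 = edf_k
        pvals[name] = float(f_dist.sf(T / df1, df1, resid_df))
        edf[name] = edf_k

    return GamSummary(
        smooth_names=names,
        edf=edf,
        p_values=pvals,
        deviance_explained=deviance_explained(y, fitted),
        fitted=fitted,
        intercept=float(beta[0]),
        lambdas=dict(zip(names, lambdas.tolist())),
        flags=flags,
    )
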