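"""Preprocessing: VIF screening, IDW interpolation, amplitudes, lag alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sivcmscreen.preprocess import (
    compute_vif,
    haversine_km,
    idw_interpolate,
    lag_align,
    seasonal_amplitude,
    vif_backward_eliminate,
)


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def brute_force_eliminate(M: np.ndarray, threshold: float = 5.0):
    """Independent oracle: recompute all VIFs from scratch every round."""
    cols = list(range(M.shape[1]))
    removed = []
    while len(cols) >= 2:
        sub = M[:, cols]
        vifs = []
        for i in range(sub.shape[1]):
            yi = sub[:, i]
            Xi = np.hstack([np.ones((len(yi), 1)), np.delete(sub, i, axis=1)])
            coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
            r2 = 1 - np.sum((yi - Xi @ coef) ** 2) / np.sum((yi - yi.mean()) ** 2)
            vifs.append(np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2))
        over = [(v, i) for i, v in enumerate(vifs) if v > threshold]
        if not over:
            break
        vmax = max(v for v, _ in over)
        cand = [i for v, i in over if v == vmax or (np.isinf(v) and np.isinf(vmax))]
        worst = cand[-1]  # same tie rule: later column removed
        removed.append(cols[worst])
        cols.pop(worst)
    return removed, cols


def test_vif_orthogonal_columns_are_unity(rng):
    # exactly orthogonal centered columns -> VIF = 1 for both
    a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
    assert abs(a @ b) < 1e-12
    vif = compute_vif(np.column_stack([a, b]))
    np.testing.assert_allclose(vif, [1.0, 1.0], atol=1e-10)


def test_vif_duplicated_column_infinite(rng):
    x = rng.standard_normal(30)
    M = np.column_stack([x, x, rng.standard_normal(30)])
    vif = compute_vif(M)
    assert np.isinf(vif[0]) and np.isinf(vif[1])
    assert np.isfinite(vif[2])


def test_vif_planted_r2(rng):
    # construct column 0 with R^2 = 0.8 against the others by scaling noise
    n = 2000
    others = rng.standard_normal((n, 3))
    signal = others @ np.array([1.0, -0.5, 0.25])
    signal = (signal - signal.mean()) / signal.std()
    noise = rng.standard_normal(n)
    # project noise out of the span of (1, others) so R^2 is exact
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), others]))
    noise = noise - Q @ (Q.T @ noise)
    noise = noise / noise.std()
    # also orthogonalize the signal's residual structure: R^2 = var(signal part)
    col = np.sqrt(0.8) * signal + np.sqrt(0.2) * noise
    M = np.column_stack([col, others])
    vif = compute_vif(M)
    # R^2 = 0.8 -> VIF = 5 (up to sampling of the standardization)
    assert vif[0] == pytest.approx(5.0, abs=0.05)


def test_vif_constant_column_flagged(rng):
    M = np.column_stack([np.ones(20), rng.standard_normal(20), rng.standard_normal(20)])
    vif = compute_vif(M)
    assert np.isnan(vif[0])


def test_vif_requires_shape():
    with pytest.raises(ValueError):
        compute_vif(np.ones((10, 1)))
    with pytest.raises(ValueError):
        compute_vif(np.ones((3, 5)))


def test_backward_eliminate_keeps_independent(rng):
    M = rng.standard_normal((200, 5))
    rep = vif_backward_eliminate(M)
    assert rep.removal_order == []
    assert rep.retained == [f"x{i}" for i in range(5)]


def test_backward_eliminate_duplicated_pair(rng):
    x = rng.standard_normal(100)
    M = np.column_stack([x, rng.standard_normal(100), x])
    rep = vif_backward_eliminate(M)
    # exactly one of the duplicated pair removed, the later one by the tie rule
    assert rep.removal_order == ["x2"]
    assert set(rep.retained) == {"x0", "x1"}


@pytest.mark.parametrize("seed", range(8))
def test_backward_eliminate_matches_bruteforce(seed):
    # planted near-dependencies among <= 8 columns; oracle = full recompute
    rng = np.random.default_rng(seed)
    n, p = 120, rng.integers(4, 9)
    M = rng.standard_normal((n, p))
    # plant a 3-variable near-dependency
    M[:, 0] = M[:, 1] + M[:, 2] + 0.2 * rng.standard_normal(n)
    if p >= 6:
        M[:, 5] = 0.7 * M[:, 3] + 0.05 * rng.standard_normal(n)
    rep = vif_backward_eliminate(M)
    removed_oracle, retained_oracle = brute_force_eliminate(M)
    assert rep.removal_order == [f"x{i}" for i in removed_oracle]
    assert rep.retained == [f"x{i}" for i in retained_oracle]
    # audit invariants: every removed variable was round-maximal and over threshold
    for rnd in rep.rounds[:-1]:
        vifs = {k: v for k, v in rnd["vifs"].items() if not np.isnan(v)}
        assert rnd["removed"] is not None
        assert vifs[rnd["removed"]] > 5.0
    final = rep.rounds[-1]["vifs"]
    assert all(v <= 5.0 for v in final.values() if not np.isnan(v))


# ---------------------------------------------------------------------------
# IDW
# ---------------------------------------------------------------------------

def test_idw_zero_distance_returns_station_value():
    v = idw_interpolate(
        np.array([-150.0, -140.0]), np.array([55.0, 57.0]),
        np.array([3.3, 9.9]), -150.0, 55.0,
    )
    assert v == 3.3


def test_idw_equidistant_average():
    # two stations symmetric about the target -> simple mean
    v = idw_interpolate(
        np.array([-150.0, -148.0]), np.array([55.0, 55.0]),
        np.array([2.0, 4.0]), -149.0, 55.0,
    )
    assert v == pytest.approx(3.0, abs=1e-9)


def test_idw_weight_formula_oracle():
    # stations at distances d and 2d: value = (v1/d^2 + v2/(2d)^2)/(1/d^2 + 1/(2d)^2)
    # with v = (0, 6): 6*0.25/1.25 = 1.2
    lat = 0.0
    lon1, lon2 = 1.0, 2.0  # distances along the equator scale linearly
    v = idw_interpolate(
        np.array([lon1, lon2]), np.array([lat, lat]),
        np.array([0.0, 6.0]), 0.0, 0.0, power=2.0,
    )
    assert v == pytest.approx(1.2, rel=1e-9)


def test_idw_empty_slice_is_missing_flag():
    assert np.isnan(idw_interpolate(np.array([]), np.array([]), np.array([]), 0.0, 0.0))


@given(
    vals=st.lists(st.floats(-100, 100), min_size=1, max_size=6),
    tlon=st.floats(-170, -130),
    tlat=st.floats(40, 60),
)
@settings(max_examples=50, deadline=None)
def test_idw_bounded_by_station_values(vals, tlon, tlat):
    rng = np.random.default_rng(abs(hash((tlon, tlat))) % 2**31)
    lons = rng.uniform(-171, -129, len(vals))
    lats = rng.uniform(39, 61, len(vals))
    v = idw_interpolate(lons, lats, np.array(vals), tlon, tlat)
    assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9


def test_haversine_known_distance():
    # one degree of latitude is ~111.2 km anywhere
    d = haversine_km(0.0, 0.0, 0.0, 1.0)
    assert d == pytest.approx(111.2, abs=0.3)


# ---------------------------------------------------------------------------
# seasonal amplitudes
# ---------------------------------------------------------------------------

def test_amplitude_constant_series_is_zero():
    rows = [(1990, m, 7.7) for m in range(1, 13)] + [(1989, 12, 7.7)]
    df = pd.DataFrame(rows, columns=["year", "month", "value"])
    amp = seasonal_amplitude(df, "physical")
    assert amp.loc[1990] == 0.0


def test_amplitude_physical_jja_minus_djf(monthly_series):
    amp = seasonal_amplitude(monthly_series, "physical")
    # 1991, 1992 have a previous-year December; 1990 does not -> NaN
    assert amp.loc[1991] == pytest.approx(8.0)
    assert amp.loc[1992] == pytest.approx(8.0)
    assert np.isnan(amp.loc[1990])


def test_amplitude_physical_same_year_convention(monthly_series):
    amp = seasonal_amplitude(monthly_series, "physical", djf_year_convention="same")
    assert amp.loc[1990] == pytest.approx(8.0)


def test_amplitude_chembio_aso_minus_mam():
    rows = []
    for month in range(1, 13):
        val = 5.0 if month in (8, 9, 10) else (7.0 if month in (3, 4, 5) else 1.0)
        rows.append((2000, month, val))
    df = pd.DataFrame(rows, columns=["year", "month", "value"])
    amp = seasonal_amplitude(df, "chembio")
    assert amp.loc[2000] == pytest.approx(-2.0)


def test_amplitude_missing_month_flags_year():
    rows = [(2000, m, 1.0) for m in range(1, 13) if m != 7]
    df = pd.DataFrame(rows, columns=["year", "month", "value"])
    amp = seasonal_amplitude(df, "physical", djf_year_convention="same")
    assert np.isnan(amp.loc[2000])


def test_amplitude_linearity(monthly_series):
    base = seasonal_amplitude(monthly_series, "physical", "same")
    scaled = monthly_series.assign(value=3.5 * monthly_series["value"] + 11.0)
    amp = seasonal_amplitude(scaled, "physical", "same")
    np.testing.assert_allclose(amp.to_numpy(), 3.5 * base.to_numpy())


def test_amplitude_rejects_bad_class(monthly_series):
    with pytest.raises(ValueError):
        seasonal_amplitude(monthly_series, "biological")


# ---------------------------------------------------------------------------
# lag alignment
# ---------------------------------------------------------------------------

def _amp_table():
    rows = []
    for year in range(1980, 1996):
        for var in ("WTMP", "plankton"):
            rows.append((var, -150.0, 55.0, year, float(year % 7)))
    return pd.DataFrame(rows, columns=["variable", "lon", "lat", "year", "amplitude"])


def _resp_table(species="sablefish", years=(1990,)):
    return pd.DataFrame(
        [(species, "CPUE", -150.0, 55.0, y, 1.0 + y % 3) for y in years],
        columns=["species", "response", "lon", "lat", "year", "value"],
    )


def test_lag5_pairs_1990_with_1985():
    dm = lag_align(_amp_table(), _resp_table(years=(1990,)), lag_years=5)
    assert len(dm.y) == 1
    # amplitude year 1985 -> 1985 % 7 = 4 for both variables
    np.testing.assert_allclose(dm.X[0, 1:], [1985 % 7, 1985 % 7])
    assert dm.Z[0, 2] == 1990  # Z keeps the response year


def test_lag10_pairs_1995_with_1985():
    dm = lag_align(_amp_table(), _resp_table(species="halibut", years=(1995,)), lag_years=10)
    np.testing.assert_allclose(dm.X[0, 1:], [1985 % 7, 1985 % 7])


def test_lag0_identity_and_ones_column():
    dm = lag_align(_amp_table(), _resp_table(years=(1990, 1991)), lag_years=0)
    assert np.all(dm.X[:, 0] == 1.0)
    np.testing.assert_allclose(dm.X[:, 1], [1990 % 7, 1991 % 7])


def test_lag_unmatched_rows_dropped_and_counted():
    dm = lag_align(_amp_table(), _resp_table(years=(1981,)), lag_years=5)
    # 1981 - 5 = 1976 has no amplitudes
    assert len(dm.y) == 0
    assert dm.n_dropped == 1


def test_lag_rejects_negative():
    with pytest.raises(ValueError):
        lag_align(_amp_table(), _resp_table(), lag_years=-1)
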