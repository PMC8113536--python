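"""Preprocessing: collinearity screening, interpolation, seasonal amplitudes.

Turns raw monthly station series and survey locations into the lagged
seasonal-amplitude design matrix the SIVCM consumes:

* variance-inflation-factor (VIF) backward elimination prunes collinear
  environmental variables (threshold 5 by default);
* inverse-distance-weighted (IDW) interpolation moves monthly station
  values to survey locations, within each (variable, year, month) slice,
  using great-circle distances;
* seasonal amplitudes are summer-minus-winter differences for physical
  variables and fall-minus-spring differences for chemical/biological
  variables;
* responses at year t are aligned with amplitudes at year t - lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VifReport",
    "compute_vif",
    "vif_backward_eliminate",
    "haversine_km",
    "idw_interpolate",
    "seasonal_amplitude",
    "amplitude_table",
    "lag_align",
    "DesignMatrix",
]

EARTH_RADIUS_KM = 6371.0088

PHYSICAL_MONTHS = {"high": (6, 7, 8), "low": (12, 1, 2)}   # JJA minus DJF
CHEMBIO_MONTHS = {"high": (8, 9, 10), "low": (3, 4, 5)}    # ASO minus MAM


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

def compute_vif(M: np.ndarray | pd.DataFrame) -> np.ndarray:
    """VIF_i = 1/(1 - R_i^2), column i regressed (with intercept) on the rest.

    Exactly collinear columns get +inf; a constant column (undefined VIF)
    gets NaN as its flag. Requires at least two columns and more rows than
    columns.
    """
    M = np.asarray(M, float)
    n, p = M.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for i in range(p):
        yi = M[:, i]
        if np.ptp(yi) == 0:
            out[i] = np.nan  # constant column flagged
            continue
        Xi = np.hstack([ones, np.delete(M, i, axis=1)])
        coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ coef
        tss = np.sum((yi - yi.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss
        if r2 >= 1.0 - 1e-12:
            out[i] = np.inf
        else:
            out[i] = 1.0 / (1.0 - r2)
    return out


@dataclass
class VifReport:
    """Audit trail of VIF backward elimination."""

    rounds: list[dict] = field(default_factory=list)  # per round: vifs, removed
    removal_order: list = field(default_factory=list)
    retained: list = field(default_factory=list)
    threshold: float = 5.0


def vif_backward_eliminate(
    M: pd.DataFrame | np.ndarray,
    threshold: float = 5.0,
) -> VifReport:
    """Iteratively drop the worst-VIF variable until all VIF <= threshold.

    Each round recomputes all VIFs, removes the single variable with the
    largest VIF exceeding the threshold, and records the round. Ties are
    broken toward the variable later in column order (deterministic and
    auditable). Infinite VIFs (exact collinearity) are removed first.
    """
    if isinstance(M, pd.DataFrame):
        df = M.copy()
    else:
        M = np.asarray(M, float)
        df = pd.DataFrame(M, columns=[f"x{i}" for i in range(M.shape[1])])
    report = VifReport(threshold=threshold)
    while df.shape[1] >= 2:
        vifs = compute_vif(df.to_numpy())
        vmap = dict(zip(df.columns, vifs))
        # NaN-flagged constant columns are not eliminated on VIF grounds
        finite_or_inf = {c: v for c, v in vmap.items() if not np.isnan(v)}
        over = {c: v for c, v in finite_or_inf.items() if v > threshold}
        if not over:
            report.rounds.append({"vifs": vmap, "removed": None})
            break
        vmax = max(over.values())
        # tie rule: among maximal VIFs, remove the latest in column order
        worst = [c for c, v in over.items() if v == vmax or (np.isinf(v) and np.isinf(vmax))][-1]
        report.rounds.append({"vifs": vmap, "removed": worst})
        report.removal_order.append(worst)
        df = df.drop(columns=[worst])
    report.retained = list(df.columns)
    return report


# ---------------------------------------------------------------------------
# IDW interpolation
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in kilometres between decimal-degree points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float), np.asarray(lat1, float),
                                              np.asarray(lon2, float), np.asarray(lat2, float)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def idw_interpolate(
    station_lons: np.ndarray,
    station_lats: np.ndarray,
    station_values: np.ndarray,
    target_lon: float,
    target_lat: float,
    power: float = 2.0,
) -> float:
    """Inverse-distance-weighted value at the target location.

    Weights are d^(-power) with great-circle distances; a station at the
    exact target location returns its value directly. An empty station set
    returns NaN (the missing-value flag) rather than raising.
    """
    vals = np.asarray(station_values, float)
    if vals.size == 0:
        return float("nan")
    d = haversine_km(station_lons, station_lats, target_lon, target_lat)
    zero = d < 1e-9
    if np.any(zero):
        return float(vals[zero][0])
    w = d ** (-power)
    return float(np.sum(w * vals) / np.sum(w))


def interpolate_env_to_targets(
    env: pd.DataFrame,
    targets: pd.DataFrame,
    power: float = 2.0,
) -> pd.DataFrame:
    """IDW every (variable, year, month) station slice onto target locations.

    ``env`` has columns variable,lon,lat,year,month,value; ``targets`` has
    lon,lat (deduplicated). Output: one row per (variable, target, year,
    month) with the interpolated value, NaN where a slice has no stations.
    """
    tlocs = targets[["lon", "lat"]].drop_duplicates().to_numpy()
    rows = []
    for (var, year, month), g in env.groupby(["variable", "year", "month"], sort=True):
        slons = g["lon"].to_numpy()
        slats = g["lat"].to_numpy()
        svals = g["value"].to_numpy()
        ok = np.isfinite(svals)
        for lon, lat in tlocs:
            if not ok.any():
                v = float("nan")
            else:
                v = idw_interpolate(slons[ok], slats[ok], svals[ok], lon, lat, power)
            rows.append((var, lon, lat, year, month, v))
    return pd.DataFrame(rows, columns=["variable", "lon", "lat", "year", "month", "value"])


# ---------------------------------------------------------------------------
# seasonal amplitudes
# ---------------------------------------------------------------------------

def seasonal_amplitude(
    monthly: pd.DataFrame,
    variable_class: str,
    djf_year_convention: str = "previous",
) -> pd.Series:
    """Per-year seasonal amplitude of one variable at one location.

    ``monthly`` needs columns year,month,value. Physical variables use
    mean(Jun,Jul,Aug) - mean(Dec,Jan,Feb); chemical/biological variables use
    mean(Aug,Sep,Oct) - mean(Mar,Apr,May). Winter Dec is taken from year
    t-1 when ``djf_year_convention='previous'`` (the winter preceding the
    summer), or from year t when 'same'. Years missing any required month
    get NaN.
    """
    if variable_class not in ("physical", "chembio"):
        raise ValueError("variable_class must be 'physical' or 'chembio'")
    if djf_year_convention not in ("previous", "same"):
        raise ValueError("djf_year_convention must be 'previous' or 'same'")
    months = PHYSICAL_MONTHS if variable_class == "physical" else CHEMBIO_MONTHS

    vals = monthly.set_index(["year", "month"])["value"]
    vals = vals[~vals.index.duplicated(keep="last")]
    years = sorted(monthly["year"].unique())

    def month_value(year: int, month: int) -> float:
        yr = year
        if variable_class == "physical" and month == 12 and djf_year_convention == "previous":
            yr = year - 1
        return vals.get((yr, month), float("nan"))

    out = {}
    for year in years:
        high = [month_value(year, m) for m in months["high"]]
        low = [month_value(year, m) for m in months["low"]]
        vals_all = high + low
        if any(not np.isfinite(v) for v in vals_all):
            out[year] = float("nan")
        else:
            out[year] = float(np.mean(high) - np.mean(low))
    return pd.Series(out, name="amplitude").rename_axis("year")


def amplitude_table(
    monthly_at_targets: pd.DataFrame,
    variable_classes: dict[str, str],
    djf_year_convention: str = "previous",
) -> pd.DataFrame:
    """Seasonal amplitudes per (variable, location, year).

    ``monthly_at_targets`` has columns variable,lon,lat,year,month,value
    (already interpolated to survey locations); ``variable_classes`` maps
    variable name to 'physical' or 'chembio'. Output columns: variable,
    lon, lat, year, amplitude (NaN where months were missing).
    """
    rows = []
    for (var, lon, lat), g in monthly_at_targets.groupby(["variable", "lon", "lat"], sort=True):
        cls = variable_classes.get(var)
        if cls is None:
            raise KeyError(f"no variable class for {var!r}")
        amps = seasonal_amplitude(g[["year", "month", "value"]], cls, djf_year_convention)
        for year, amp in amps.items():
            rows.append((var, lon, lat, int(year), amp))
    return pd.DataFrame(rows, columns=["variable", "lon", "lat", "year", "amplitude"])


# ---------------------------------------------------------------------------
# lag alignment into a design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Assembled SIVCM inputs: y, X (leading ones column), Z = (lon,lat,year)."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    predictor_names: list[str]
    meta: pd.DataFrame              # species, response, per-row provenance
    n_dropped: int = 0

    def __post_init__(self):
        assert len(self.y) == self.X.shape[0] == self.Z.shape[0]


def lag_align(
    amplitudes: pd.DataFrame,
    responses: pd.DataFrame,
    lag_years: int,
) -> DesignMatrix:
    """Pair responses at (location, year t) with amplitudes at year t - lag.

    ``amplitudes``: variable,lon,lat,year,amplitude. ``responses``:
    species,response,lon,lat,year,value. Amplitudes are pivoted wide (one
    column per variable); rows with any missing lagged amplitude or missing
    response are dropped listwise and counted. A leading all-ones column is
    added to X.
    """
    if lag_years < 0:
        raise ValueError("lag_years must be nonnegative")
    wide = amplitudes.pivot_table(
        index=["lon", "lat", "year"], columns="variable", values="amplitude", aggfunc="last"
    ).reset_index()
    predictor_names = [c for c in wide.columns if c not in ("lon", "lat", "year")]

    resp = responses.copy()
    resp["amp_year"] = resp["year"] - lag_years
    merged = resp.merge(
        wide.rename(columns={"year": "amp_year"}),
        on=["lon", "lat", "amp_year"],
        how="left",
    )
    total = len(merged)
    complete = merged.dropna(subset=predictor_names + ["value"])
    n_dropped = total - len(complete)
    if complete.empty:
        import warnings

        warnings.warn("lag alignment produced an empty design (no overlapping years)")
    y = complete["value"].to_numpy(float)
    Xp = complete[predictor_names].to_numpy(float)
    X = np.column_stack([np.ones(len(complete)), Xp]) if len(complete) else np.empty((0, len(predictor_names) + 1))
    Z = complete[["lon", "lat", "year"]].to_numpy(float)
    meta = complete[["species", "response", "lon", "lat", "year"]].reset_index(drop=True)
    return DesignMatrix(
        y=y, X=X, Z=Z, predictor_names=predictor_names, meta=meta, n_dropped=n_dropped
    )
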