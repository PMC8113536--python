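"""File schemas, configuration and pipeline orchestration.

The interchange formats are plain delimited text with fixed headers
(coordinates in decimal degrees, longitude in [-180, 180], months 1-based,
missing values as empty fields):

* survey:  ``species,response,lon,lat,year,value``
* environment: ``variable,lon,lat,year,month,value``
* climate: ``index,year,month,value``

``run_pipeline`` chains simulate -> preprocess -> select -> associate and
writes a manifest (inputs, row counts, seeds, config hash) per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sivcmscreen")

__all__ = [
    "PipelineConfig",
    "read_survey_table",
    "read_env_table",
    "read_climate_table",
    "run_pipeline",
]

SURVEY_COLUMNS = ["species", "response", "lon", "lat", "year", "value"]
ENV_COLUMNS = ["variable", "lon", "lat", "year", "month", "value"]
CLIMATE_COLUMNS = ["index", "year", "month", "value"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    The species->lag map defaults to 10 years for Pacific halibut (late
    maturity) and 5 years for every other species (maturity around 5).
    """

    out_dir: str = "pipeline_out"
    species_lags: dict = field(default_factory=lambda: {"default": 5, "halibut": 10})
    vif_threshold: float = 5.0
    idw_power: float = 2.0
    n_interior_knots: int = 8
    spline_degree: int = 3
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    min_rows: int = 30
    djf_year_convention: str = "previous"
    fdr_family: str = "pooled"          # pooled across indices per response
    seed: int = 0
    # simulate-stage knobs
    sim_n: int = 600
    sim_p: int = 10
    sim_noise_sd: float = 1.0
    sim_years: tuple = (1984, 2013)

    def __post_init__(self):
        for name in ("vif_threshold", "idw_power", "min_rows", "n_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if "default" not in self.species_lags:
            raise ValueError("species_lags must include a 'default' entry")

    def lag_for(self, species: str) -> int:
        return int(self.species_lags.get(species, self.species_lags["default"]))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim_years" in raw:
            raw["sim_years"] = tuple(raw["sim_years"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sivcm_config(self):
        from .sivcm import SivcmConfig

        return SivcmConfig(
            n_interior_knots=self.n_interior_knots,
            degree=self.spline_degree,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            min_rows=self.min_rows,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_typed(path, columns, numeric, int_cols=(), allow_missing_value=True):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    df = df[columns]
    rejected = []
    parsed = df.copy()
    for c in numeric:
        vals = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
        bad = vals.isna() & (df[c] != "")
        if c == "value" and allow_missing_value:
            pass
        else:
            bad |= df[c] == ""
        rejected.append(bad)
        parsed[c] = vals
    bad_any = np.logical_or.reduce(rejected) if rejected else np.zeros(len(df), bool)
    if bad_any.any():
        lines = (np.flatnonzero(bad_any) + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: rejected %d unparseable row(s) at line(s) %s", path, bad_any.sum(), lines)
    out = parsed.loc[~bad_any].reset_index(drop=True)
    for c in int_cols:
        out[c] = out[c].astype(int)
    out.attrs["n_rejected"] = int(bad_any.sum())
    out.attrs["rejected_lines"] = (np.flatnonzero(bad_any) + 2).tolist()
    return out


def read_survey_table(path) -> pd.DataFrame:
    """Read a survey table; unparseable numeric rows are dropped and logged.

    Empty ``value`` fields survive as NaN (missing-flagged responses).
    """
    return _read_typed(path, SURVEY_COLUMNS, ["lon", "lat", "year", "value"], int_cols=["year"])


def read_env_table(path) -> pd.DataFrame:
    """Read monthly environmental station series; month must be in 1..12.

    Duplicate (variable, location, year, month) keys resolve last-wins with
    a warning.
    """
    df = _read_typed(path, ENV_COLUMNS, ["lon", "lat", "year", "month", "value"],
                     int_cols=["year", "month"])
    bad_month = ~df["month"].between(1, 12)
    if bad_month.any():
        logger.warning("%s: rejected %d row(s) with month outside 1..12", path, bad_month.sum())
        df = df.loc[~bad_month].reset_index(drop=True)
    key = ["variable", "lon", "lat", "year", "month"]
    dups = df.duplicated(subset=key, keep="last")
    if dups.any():
        logger.warning("%s: %d duplicate key row(s); keeping the last", path, dups.sum())
        df = df.loc[~dups].reset_index(drop=True)
    return df


def read_climate_table(path) -> pd.DataFrame:
    """Read a monthly climate-index table (index,year,month,value)."""
    df = _read_typed(path, CLIMATE_COLUMNS, ["year", "month", "value"], int_cols=["year", "month"])
    bad_month = ~df["month"].between(1, 12)
    if bad_month.any():
        logger.warning("%s: rejected %d row(s) with month outside 1..12", path, bad_month.sum())
        df = df.loc[~bad_month].reset_index(drop=True)
    dups = df.duplicated(subset=["index", "year", "month"], keep="last")
    if dups.any():
        logger.warning("%s: %d duplicate key row(s); keeping the last", path, dups.sum())
        df = df.loc[~dups].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, **info):
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **info,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def simulate_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Emit synthetic survey, environment and climate files plus truth sidecar."""
    from . import synthetic
    from .sivcm import normalize_direction

    rng_seed = config.seed
    truth = synthetic.SivcmTruth(
        theta_true=normalize_direction([2.0, -1.0, 0.5]).theta,
        g_funcs=synthetic.default_g_funcs(config.sim_p),
        noise_sd=config.sim_noise_sd,
        n=config.sim_n,
        seed=rng_seed,
    )
    survey, data = synthetic.gen_survey_table(truth, species="sablefish", response="CPUE",
                                              z_sampler={"year_range": config.sim_years})
    survey.to_csv(out_dir / "survey.csv", index=False)

    # predictor sidecar: the X the synthetic SIVCM actually used, so select
    # can run without re-deriving amplitudes from the synthetic stations
    xcols = {f"x{j}": data["X"][:, j] for j in range(1, data["X"].shape[1])}
    pd.DataFrame({**{"lon": survey["lon"], "lat": survey["lat"], "year": survey["year"]}, **xcols}).to_csv(
        out_dir / "predictors.csv", index=False
    )

    env_spec = synthetic.StationSeriesSpec(
        locations=[(-160.0, 55.0), (-150.0, 57.0), (-140.0, 59.0)],
        years=config.sim_years,
        month_means={"WTMP": [2, 2, 4, 6, 8, 10, 11, 10, 8, 6, 4, 2]},
        noise_sd=0.2,
        variable_class="physical",
    )
    synthetic.gen_monthly_env(env_spec, seed=rng_seed + 1).to_csv(out_dir / "env.csv", index=False)

    years_span = (config.sim_years[0] - 10, config.sim_years[1])
    rng = np.random.default_rng(rng_seed + 2)
    amp_params = {
        name: {y: float(a) for y, a in zip(
            range(years_span[0], years_span[1] + 1),
            rng.normal(0, 1, years_span[1] - years_span[0] + 1),
        )}
        for name in ("PDO", "MEI", "NPGO")
    }
    climate, climate_truth = synthetic.gen_climate_indices(years_span, amp_params, seed=rng_seed + 3)
    climate.to_csv(out_dir / "climate.csv", index=False)
    climate_truth.to_csv(out_dir / "climate_truth.csv", index=False)

    truth_sidecar = {
        "theta_true": truth.theta_true.tolist(),
        "true_support": truth.true_support,
        "noise_sd": truth.noise_sd,
        "n": truth.n,
        "p": truth.p,
        "seed": truth.seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_sidecar, indent=2))
    _write_manifest(out_dir, "simulate", config, n_rows=len(survey))
    return {"survey": survey, "truth": truth_sidecar}


def select_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Run per-year + all-years selection from simulate-stage files."""
    from .preprocess import DesignMatrix
    from .selection import run_yearly_selection, selection_matrix_to_table

    survey = read_survey_table(out_dir / "survey.csv")
    preds = pd.read_csv(out_dir / "predictors.csv")
    xnames = [c for c in preds.columns if c.startswith("x")]
    n = len(survey)
    design = DesignMatrix(
        y=survey["value"].to_numpy(float),
        X=np.column_stack([np.ones(n), preds[xnames].to_numpy(float)]),
        Z=survey[["lon", "lat", "year"]].to_numpy(float),
        predictor_names=xnames,
        meta=survey[["species", "response", "lon", "lat", "year"]],
    )
    species = survey["species"].iloc[0]
    response = survey["response"].iloc[0]
    matrix = run_yearly_selection(
        design, config.sivcm_config(), species=species, response=response,
        lag=config.lag_for(species),
    )
    path = out_dir / f"selection_{species}_{response}.tsv"
    selection_matrix_to_table(matrix, path)
    _write_manifest(out_dir, "select", config, n_rows=n,
                    n_per_column={str(k): v for k, v in matrix.n_per_column.items()})
    return {"matrix": matrix, "path": path}


def associate_stage(config: PipelineConfig, out_dir: Path) -> dict:
    """Climate screening + additive models from select-stage outputs."""
    from .climate import climate_amplitude_series, fit_additive_model, screen_selection_series
    from .selection import read_selection_table

    climate = read_climate_table(out_dir / "climate.csv")
    amps = {
        name: climate_amplitude_series(g[["year", "month", "value"]], config.djf_year_convention)
        for name, g in climate.groupby("index")
    }

    results = []
    gam_rows = []
    for tsv in sorted(out_dir.glob("selection_*.tsv")):
        parts = tsv.stem.split("_")
        species, response = parts[1], parts[2]
        table = read_selection_table(tsv)
        numeric = table.map(lambda v: np.nan if v == "NA" else float(v))
        lag = config.lag_for(species)
        res = screen_selection_series(
            numeric, amps, species=species, response=response, lag=lag,
        )
        results.append(res)

    assoc = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    assoc_path = out_dir / "associations.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False)

    # additive model per response: yearly mean response vs lagged climate amps
    survey = read_survey_table(out_dir / "survey.csv")
    for (species, response), g in survey.groupby(["species", "response"]):
        lag = config.lag_for(species)
        yearly = g.groupby("year")["value"].mean()
        years = [y for y in yearly.index if 1985 <= y <= 2013]
        if len(years) < 15:
            continue
        cov = pd.DataFrame({
            "PDO": [amps["PDO"].get(y - lag, np.nan) for y in years],
            "MEI": [amps["MEI"].get(y, np.nan) for y in years],
            "NPGO": [amps["NPGO"].get(y, np.nan) for y in years],
        })
        try:
            gs = fit_additive_model(yearly.loc[years].to_numpy(), cov)
        except ValueError:
            continue
        gam_rows.append({
            "species": species, "response": response,
            "deviance_explained": gs.deviance_explained,
            **{f"edf_{k}": v for k, v in gs.edf.items()},
            **{f"p_{k}": v for k, v in gs.p_values.items()},
        })
    gam = pd.DataFrame(gam_rows)
    gam_path = out_dir / "gam_summaries.tsv"
    gam.to_csv(gam_path, sep="\t", index=False)
    _write_manifest(out_dir, "associate", config, n_tests=len(assoc), n_gams=len(gam))
    return {"associations": assoc, "gams": gam}


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> select -> associate, with manifests, into config.out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for stage, fn in (("simulate", simulate_stage), ("select", select_stage),
                      ("associate", associate_stage)):
        try:
            artifacts[stage] = fn(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
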