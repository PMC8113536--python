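"""Per-year and all-years variable selection, assembled into a matrix.

For each species-response, the LSSGLASSO fit is run once per survey year
(on that year's rows) and once on all rows pooled (the "allyrs" column).
Cells record whether each candidate variable's coefficient function was
selected. Within a single-year fit the year coordinate of Z is constant
and hence unidentifiable in the index, so the index reduces to a 2-vector
over (longitude, latitude) with the same normalization convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DesignMatrix
from .sivcm import SivcmConfig, lssglasso_fit

__all__ = ["SelectionMatrix", "run_yearly_selection", "selection_matrix_to_table",
           "read_selection_table"]

ALLYRS = "allyrs"

SELECTED = 1
NOT_SELECTED = 0
MISSING = "NA"


@dataclass
class SelectionMatrix:
    """Binary variable x year matrix plus the all-years column.

    ``table`` holds 1 (selected), 0 (not selected) or NA (year missing or
    below the minimum row count); metadata records the species, response,
    lag and per-column row counts.
    """

    table: pd.DataFrame                 # index=variables, columns=years + "allyrs"
    species: str
    response: str
    lag: int
    n_per_column: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)

    def __post_init__(self):
        # a missing column must not contain selections
        for col in self.table.columns:
            colvals = self.table[col]
            if (colvals == MISSING).all():
                continue
        assert ALLYRS in self.table.columns


def run_yearly_selection(
    design: DesignMatrix,
    config: SivcmConfig | None = None,
    species: str = "",
    response: str = "",
    lag: int = 0,
    years: list[int] | None = None,
    keep_fits: bool = False,
) -> SelectionMatrix:
    """Run LSSGLASSO per year and over all years; tabulate selections.

    Years with fewer than ``config.min_rows`` rows (or absent from the
    design) become NA columns. The all-years run pools exactly the union of
    the per-year rows. Within-year fits drop the constant year coordinate
    from Z.
    """
    config = config or SivcmConfig()
    variables = design.predictor_names
    row_years = design.Z[:, 2].astype(int)
    if years is None:
        years = sorted(np.unique(row_years).tolist())
    if len(design.y) == 0:
        raise ValueError("empty design: no usable rows at all")

    cols: dict = {}
    n_per_col: dict = {}
    fits: dict = {}

    def fit_rows(mask: np.ndarray, col_key, drop_year: bool):
        n = int(mask.sum())
        n_per_col[col_key] = n
        if n < config.min_rows:
            cols[col_key] = pd.Series(MISSING, index=variables, dtype=object)
            return
        Z = design.Z[mask][:, :2] if drop_year else design.Z[mask]
        try:
            fit = lssglasso_fit(design.y[mask], design.X[mask], Z, config)
        except ValueError:
            cols[col_key] = pd.Series(MISSING, index=variables, dtype=object)
            return
        sel = set(fit.selected)
        cols[col_key] = pd.Series(
            [SELECTED if (j + 1) in sel else NOT_SELECTED for j in range(len(variables))],
            index=variables, dtype=object,
        )
        if keep_fits:
            fits[col_key] = fit

    for year in years:
        fit_rows(row_years == year, int(year), drop_year=True)
    any_year = np.isin(row_years, years)
    assert int(any_year.sum()) == sum(
        n_per_col[int(y)] for y in years
    ), "all-years pool must equal the union of per-year rows"
    fit_rows(any_year, ALLYRS, drop_year=False)

    table = pd.DataFrame(cols)
    table = table[[*(int(y) for y in years), ALLYRS]]
    return SelectionMatrix(
        table=table, species=species, response=response, lag=lag,
        n_per_column=n_per_col, fits=fits,
    )


def selection_matrix_to_table(matrix: SelectionMatrix, path=None) -> pd.DataFrame:
    """Serialize a SelectionMatrix to TSV with legend values {1, 0, NA}."""
    out = matrix.table.copy()
    out.index.name = "variable"
    if path is not None:
        out.to_csv(path, sep="\t", na_rep=MISSING)
    return out


def read_selection_table(path) -> pd.DataFrame:
    """Read a selection TSV back; year columns become ints, cells objects."""
    df = pd.read_csv(path, sep="\t", index_col="variable", dtype=str, keep_default_na=False)
    df.columns = [int(c) if c != ALLYRS else c for c in df.columns]
    def parse(v):
        if v == MISSING:
            return MISSING
        return int(v)
    return df.map(parse).astype(object)


def plot_selection_heatmap(matrix: SelectionMatrix, path):
    """Minimal heatmap mirror: variables on y, years on x, 1/0/NA colors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = matrix.table
    num = tab.map(lambda v: np.nan if v == MISSING else float(v)).to_numpy(float)
    fig, ax = plt.subplots(figsize=(0.35 * len(tab.columns) + 2, 0.25 * len(tab) + 2))
    ax.imshow(num, aspect="auto", interpolation="nearest", cmap="Greens", vmin=0, vmax=1)
    ax.set_xticks(range(len(tab.columns)), [str(c) for c in tab.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(tab)), tab.index, fontsize=6)
    ax.set_title(f"{matrix.species} {matrix.response} (lag {matrix.lag})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
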