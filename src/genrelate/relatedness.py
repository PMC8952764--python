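"""Taxonomic-degree encoding, regression and correlation of relatedness.

The degree of taxonomic relatedness between a reference strain and another
strain is the ordinal code of the most specific rank they share:

    1 = same species, 2 = same genus, 3 = same family,
    4 = same order, 5 = same subphylum.

ANIb and dDDH percentages are regressed on the degree (with 95% confidence
and prediction bands), and Pearson product-moment correlations are computed
between ANIb, dDDH and the per-category homologous-gene percentages.

A relatedness table for *Beauveria pseudobassiana* RGM 2184 against 27
entomopathogenic fungal strains ships with the package
(``load_reference_table``), so the headline statistics can be reproduced
without any genome download.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RANKS",
    "TaxonomyRecord",
    "RGM2184",
    "RegressionFit",
    "encode_degree",
    "pearson",
    "linear_regression",
    "correlation_matrix",
    "load_reference_table",
    "read_relatedness_table",
    "VARIABLES",
]

RANKS = ("species", "genus", "family", "order", "subphylum")

#: Columns entering the correlation matrix, in display order.
VARIABLES = ("anib", "ddh", "exo_pct", "toxin_pct", "nrps_pct", "pks_pct")


@dataclass(frozen=True)
class TaxonomyRecord:
    strain_id: str
    species: str
    genus: str
    family: str
    order: str
    subphylum: str

    def __post_init__(self) -> None:
        for rank in RANKS:
            if not getattr(self, rank):
                raise ValueError(
                    f"strain {self.strain_id!r}: rank {rank!r} is empty"
                )


#: Taxonomy of the reference strain used by the packaged table.
RGM2184 = TaxonomyRecord(
    strain_id="Beauveria pseudobassiana RGM 2184",
    species="Beauveria pseudobassiana",
    genus="Beauveria",
    family="Cordycipitaceae",
    order="Hypocreales",
    subphylum="Pezizomycotina",
)


def encode_degree(reference: TaxonomyRecord, other: TaxonomyRecord) -> int:
    """Ordinal code (1-5) of the most specific shared rank; symmetric."""
    for degree, rank in enumerate(RANKS, start=1):
        if getattr(reference, rank) == getattr(other, rank):
            return degree
    raise ValueError(
        f"{reference.strain_id!r} and {other.strain_id!r} share no rank, "
        "not even the subphylum"
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass
class RegressionFit:
    """Least-squares line of y on x with the usual summary quantities.

    ``confidence_band(x0)`` gives the 95% interval for the mean response at
    x0; ``prediction_band(x0)`` the 95% limits for a new observation.
    """

    slope: float
    intercept: float
    r: float
    r_squared: float  # percent
    residual_sd: float
    n: int
    _results: object = None

    def predict(self, x0) -> np.ndarray:
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        return self.intercept + self.slope * x0

    def _bands(self, x0, kind: str, alpha: float = 0.05):
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        pred = self._results.get_prediction(sm.add_constant(x0, has_constant="add"))
        frame = pred.summary_frame(alpha=alpha)
        if kind == "mean":
            return frame["mean_ci_lower"].values, frame["mean_ci_upper"].values
        return frame["obs_ci_lower"].values, frame["obs_ci_upper"].values

    def confidence_band(self, x0, alpha: float = 0.05):
        return self._bands(x0, "mean", alpha)

    def prediction_band(self, x0, alpha: float = 0.05):
        return self._bands(x0, "obs", alpha)


def linear_regression(x, y) -> RegressionFit:
    """OLS fit of y on x (degrees vs percentages, typically)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    results = sm.OLS(y, sm.add_constant(x)).fit()
    r = pearson(x, y) if np.ptp(y) > 0 else float("nan")
    return RegressionFit(
        slope=float(results.params[1]),
        intercept=float(results.params[0]),
        r=r,
        r_squared=float(results.rsquared * 100.0),
        residual_sd=float(np.sqrt(results.mse_resid)),
        n=len(x),
        _results=results,
    )


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson matrix over the six relatedness variables.

    Zero-variance columns yield NaN entries (flagged as missing rather than
    silently set to 0).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = [c for c in VARIABLES if c in table.columns]
    mat = table[cols].astype(float).corr(method="pearson")
    for c in cols:
        if np.ptp(table[c].astype(float).values) == 0:
            mat.loc[c, :] = np.nan
            mat.loc[:, c] = np.nan
    np.fill_diagonal(mat.values, 1.0)
    for c in cols:
        if np.ptp(table[c].astype(float).values) == 0:
            mat.loc[c, c] = np.nan
    return mat


def _attach_degrees(df: pd.DataFrame, reference: TaxonomyRecord) -> pd.DataFrame:
    degrees = []
    for _, row in df.iterrows():
        rec = TaxonomyRecord(
            strain_id=row["strain"],
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            subphylum=row["subphylum"],
        )
        degrees.append(encode_degree(reference, rec))
    out = df.copy()
    out["degree"] = degrees
    return out


def read_relatedness_table(
    path: str | Path, reference: TaxonomyRecord | None = None
) -> pd.DataFrame:
    """Read a relatedness TSV and (optionally) encode degrees.

    Expected columns: strain, species, genus, family, order, subphylum, plus
    the numeric variables anib, ddh, exo_pct, toxin_pct, nrps_pct, pks_pct.
    Lines starting with ``#`` are comments.  If the file carries no
    ``degree`` column, one is derived from the taxonomy columns against
    ``reference``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "degree" not in df.columns:
        if reference is None:
            raise ValueError("no degree column and no reference taxonomy")
        df = _attach_degrees(df, reference)
    bad = df.loc[~df["degree"].isin([1, 2, 3, 4, 5])]
    if len(bad):
        raise ValueError(f"degrees outside 1-5 for {list(bad['strain'])}")
    return df


def load_reference_table() -> pd.DataFrame:
    """The packaged RGM 2184 vs 27 EPF strains relatedness table.

    The reference strain itself (a degree-0 self-comparison) is not a row:
    the table holds the 27 comparison strains only.
    """
    resource = importlib.resources.files("genrelate.data") / "table1.tsv"
    with importlib.resources.as_file(resource) as path:
        return read_relatedness_table(path, reference=RGM2184)
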