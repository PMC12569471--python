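"""From multivariate fit to interpretable trait-predictor associations.

Also houses the climate preprocessing: a PCA of the five climate
variables (temperature, precipitation, wind speed, vapour pressure, solar
radiation), of which the first two components are carried forward as
abiotic predictors.

A predictor's *regression score* for a species is the orthogonal
projection of that species' (column-centred) morphospace position onto
the unit direction of the predictor's coefficient vector; zero means no
association, and the sign gives the direction. A trait state is *strongly*
associated with a predictor when all species bearing the state have
scores strictly on one side of zero, and shows a *tendency* when the
interquartile range of their scores lies strictly on one side while
outliers may cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mvpgls import MvPglsFit

CLIMATE_COLUMNS = (
    "temperature",
    "precipitation",
    "wind_speed",
    "vapour_pressure",
    "solar_radiation",
)


@dataclass
class ClimatePcs:
    """First two principal components of the climate variables."""

    labels: list[str]
    scores: pd.DataFrame  # columns pc1, pc2
    loadings: pd.DataFrame  # 5 x 2
    var_explained: np.ndarray  # length 2, shares of total variance

    def to_frame(self) -> pd.DataFrame:
        return self.scores


def climate_pca(climate: pd.DataFrame, scale: bool = True) -> ClimatePcs:
    """PCA of the five climate columns; retain the first two axes.

    ``scale=True`` (default) standardizes columns first (correlation-matrix
    PCA), appropriate because the five inputs have incommensurate units.
    Component signs follow the largest-|loading|-positive convention.
    """
    missing = [c for c in CLIMATE_COLUMNS if c not in climate.columns]
    if missing:
        raise ValidationError(f"missing climate columns: {missing}")
    x = climate.loc[:, list(CLIMATE_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("missing values in climate table")
    n = x.shape[0]
    if n <= len(CLIMATE_COLUMNS):
        raise ValidationError("need more rows than climate variables")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(CLIMATE_COLUMNS, sd) if s == 0]
        raise ValidationError(f"constant climate columns: {bad}")
    if scale:
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(vt.shape[0]):  # deterministic sign
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s**2
    shares = var / var.sum()
    scores = pd.DataFrame(
        (u * s)[:, :2], index=climate.index, columns=["pc1", "pc2"]
    )
    loadings = pd.DataFrame(
        vt[:2].T, index=list(CLIMATE_COLUMNS), columns=["pc1", "pc2"]
    )
    return ClimatePcs(
        labels=list(climate.index),
        scores=scores,
        loadings=loadings,
        var_explained=shares[:2],
    )


@dataclass
class RegressionScores:
    """Per-species projection onto one predictor's coefficient direction."""

    predictor: str
    scores: pd.Series  # indexed by species


def regression_scores(
    Y: pd.DataFrame, fit: MvPglsFit, predictor: str
) -> RegressionScores:
    """Project centred morphospace coordinates onto a predictor's axis.

    score_i = (Y_i - Ybar) . b / ||b|| with b the predictor's coefficient
    row; invariant to positive rescaling of b. A zero coefficient vector
    yields all-zero scores with a warning.
    """
    if predictor not in fit.coefficients.index:
        raise ValidationError(f"predictor {predictor!r} not in fit")
    cols = list(fit.coefficients.columns)
    missing = [c for c in cols if c not in Y.columns]
    if missing:
        raise ValidationError(f"response axes absent from Y: {missing}")
    yc = Y.loc[:, cols].to_numpy(dtype=float)
    yc = yc - yc.mean(axis=0)
    b = fit.coefficients.loc[predictor].to_numpy(dtype=float)
    norm = np.linalg.norm(b)
    if norm == 0:
        warnings.warn(f"zero coefficient vector for {predictor!r}; scores are 0")
        values = np.zeros(len(Y))
    else:
        values = yc @ (b / norm)
    return RegressionScores(
        predictor=predictor, scores=pd.Series(values, index=Y.index, name=predictor)
    )


ASSOCIATION_CLASSES = (
    "strong_positive",
    "strong_negative",
    "tendency_positive",
    "tendency_negative",
    "none",
)


@dataclass
class AssociationSummary:
    """Association class of one trait state with one predictor."""

    predictor: str
    trait_state: str
    cls: str
    n_species: int
    q1: float
    median: float
    q3: float


def classify_association(
    scores: RegressionScores,
    mask: Sequence[bool],
    trait_state: str = "",
) -> AssociationSummary:
    """Classify a trait state's association from its species' scores.

    strong_{positive,negative}: every score strictly on one side of zero
    (an exact zero blocks 'strong'); tendency_{positive,negative}: the
    [Q1, Q3] interval strictly on one side (quartiles by linear
    interpolation, zero endpoints count as straddling); otherwise none.
    """
    mask = np.asarray(mask, dtype=bool)
    values = scores.scores.to_numpy(dtype=float)[mask]
    if values.size == 0:
        raise ValidationError("empty trait mask")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    if np.all(values > 0):
        cls = "strong_positive"
    elif np.all(values < 0):
        cls = "strong_negative"
    elif q1 > 0:
        cls = "tendency_positive"
    elif q3 < 0:
        cls = "tendency_negative"
    else:
        cls = "none"
    return AssociationSummary(
        predictor=scores.predictor,
        trait_state=trait_state,
        cls=cls,
        n_species=int(values.size),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
    )


def association_table(
    Y: pd.DataFrame, fit: MvPglsFit, indicators: pd.DataFrame
) -> pd.DataFrame:
    """Classify every trait state x predictor pair.

    ``indicators`` is the species x trait-state 0/1 frame (one column per
    state). Returns a long frame with one row per (predictor, state).
    """
    rows = []
    ind = indicators.loc[Y.index]
    for predictor in fit.terms:
        sc = regression_scores(Y, fit, predictor)
        for state in ind.columns:
            mask = ind[state].to_numpy(dtype=bool)
            if not mask.any():
                continue
            summary = classify_association(sc, mask, trait_state=state)
            rows.append(summary.__dict__)
    df = pd.DataFrame(rows)
    return df.rename(columns={"cls": "association"})
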