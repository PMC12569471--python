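"""Multivariate phylogenetic regression with permutation inference (RRPP).

The morphospace coordinates (all retained PCoA axes jointly) are regressed
on a set of scaled-and-centred predictors under a Brownian-motion
covariance: both response and design (including the intercept) are
whitened by C^(-1/2), and sums of squares are decomposed sequentially
(type I) in formula order, measuring each term's SS as the trace reduction
in the residual cross-product matrix between nested models.

Significance is assessed by residual randomization (RRPP): for each term,
rows of the reduced-model whitened residuals are permuted, added back to
the reduced-model fitted values, and the term's F is recomputed; the
permutation p-value is (1 + #{F* >= F_obs}) / (n_perm + 1). The effect
size Z is the standard deviate of log F within its permutation
distribution (observed arrangement included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ValidationError
from .phylo import PhyloCovariance, inv_sqrt


def prepare_predictors(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale and centre every predictor column to mean 0, sd 1 (ddof=1).

    The binary island flag is treated like any continuous predictor; this
    changes coefficient scale only, never SS/F/p. Zero-variance columns
    are an error (they carry no information and break scaling).
    """
    df = raw.copy()
    if df.index.has_duplicates:
        raise ValidationError("duplicate labels in predictor table")
    if df.isna().any().any():
        bad = sorted(df.columns[df.isna().any()])
        raise ValidationError(f"missing values in predictor columns: {bad}")
    out = {}
    for col in df.columns:
        x = df[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValidationError(f"zero-variance predictor column: {col!r}")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=df.index)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from an ordinary (non-phylogenetic) regression of column j
    on the remaining columns plus an intercept — a screening diagnostic.
    Rank-deficient designs yield infinite VIF for the implicated columns.
    """
    if X.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 columns")
    values = X.to_numpy(dtype=float)
    n = values.shape[0]
    out = {}
    for j, col in enumerate(X.columns):
        y = values[:, j]
        others = np.column_stack(
            [np.ones(n), np.delete(values, j, axis=1)]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1 - resid @ resid / tss if tss > 0 else 1.0
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class MvPglsFit:
    """Sequential-SS multivariate PGLS fit with RRPP inference.

    ``anova`` has one row per term (df, SS, MS, R2, F, Z, p_perm) plus
    residual and total rows; ``coefficients`` is the (1 + p) x k matrix of
    whitened-model coefficients (intercept first).
    """

    terms: list[str]
    anova: pd.DataFrame
    coefficients: pd.DataFrame
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int
    labels: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "terms": self.terms,
            "anova": self.anova.reset_index().to_dict(orient="records"),
            "coefficients": {
                term: self.coefficients.loc[term].tolist()
                for term in self.coefficients.index
            },
            "response_axes": list(self.coefficients.columns),
            "residual_ss": self.residual_ss,
            "total_ss": self.total_ss,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _align(Y: pd.DataFrame, X: pd.DataFrame, C: PhyloCovariance):
    if set(Y.index) != set(X.index) or set(Y.index) != set(C.labels):
        raise AlignmentError("labels of Y, X and C do not match")
    order = list(C.labels)
    return Y.loc[order], X.loc[order], order


def fit(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    C: PhyloCovariance,
    n_perm: int = 999,
    seed: int = 0,
) -> MvPglsFit:
    """Fit the multivariate phylogenetic regression with RRPP inference.

    Y: species x response-axes (e.g. all retained PCoA axes); X: species x
    predictors, already scaled/centred; C: Brownian covariance. Terms are
    added sequentially in X's column order. The same permutation index set
    is used for every term within an iteration, and the observed
    arrangement counts as one permutation, so p >= 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    Y, X, order = _align(Y, X, C)
    yv = Y.to_numpy(dtype=float)
    xv = X.to_numpy(dtype=float)
    n, k = yv.shape
    p = xv.shape[1]
    if n < p + 2:
        raise ValidationError(f"n={n} too small for {p} predictors")

    P = inv_sqrt(C)
    yw = P @ yv
    design = P @ np.column_stack([np.ones(n), xv])  # whitened intercept + terms

    # residual-maker projectors for the nested model sequence
    Q = []  # Q[j]: residual maker of model with intercept + first j terms
    for j in range(p + 1):
        q, _ = np.linalg.qr(design[:, : j + 1])
        Q.append(np.eye(n) - q @ q.T)
    Qfull = Q[p]

    df_res = n - p - 1
    terms = list(X.columns)
    rng = np.random.default_rng(seed)
    perm_idx = np.stack(
        [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    )  # (n_perm + 1, n); row 0 = observed
    m = n_perm + 1

    ss_obs = np.empty(p)
    f_obs = np.empty(p)
    p_perm = np.empty(p)
    z_scores = np.empty(p)
    for j, _term in enumerate(terms):
        r_red = Q[j] @ yw  # reduced-model residuals (term j+1 excluded)
        # permuted residual stacks: (n, m * k)
        g = r_red[perm_idx].transpose(1, 0, 2).reshape(n, m * k)
        ss_red = ((Q[j] @ g) ** 2).reshape(n, m, k).sum(axis=(0, 2))
        ss_full = ((Q[j + 1] @ g) ** 2).reshape(n, m, k).sum(axis=(0, 2))
        ss_term = ss_red - ss_full
        ss_resid = ((Qfull @ g) ** 2).reshape(n, m, k).sum(axis=(0, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            f_all = (ss_term / 1.0) / (ss_resid / df_res)
        ss_obs[j] = ss_term[0]
        f_obs[j] = f_all[0]
        p_perm[j] = np.count_nonzero(f_all[1:] >= f_all[0] - 1e-12) + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.log(np.maximum(f_all, 1e-300))
        sd = logf.std(ddof=1)
        z_scores[j] = (logf[0] - logf.mean()) / sd if sd > 0 else np.nan
    p_perm /= m

    total_ss = float(((Q[0] @ yw) ** 2).sum())
    residual_ss = float(((Qfull @ yw) ** 2).sum())
    # a total SS at rounding-noise level (constant response) means R2 = 0
    degenerate = total_ss <= 1e-12 * max(float((yw**2).sum()), 1.0)
    coef, *_ = np.linalg.lstsq(design, yw, rcond=None)

    rows = []
    for j, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": 1,
                "SS": ss_obs[j],
                "MS": ss_obs[j],
                "R2": 0.0 if degenerate else ss_obs[j] / total_ss,
                "F": f_obs[j],
                "Z": z_scores[j],
                "p_perm": p_perm[j],
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": df_res,
            "SS": residual_ss,
            "MS": residual_ss / df_res,
            "R2": np.nan if degenerate else residual_ss / total_ss,
            "F": np.nan,
            "Z": np.nan,
            "p_perm": np.nan,
        }
    )
    rows.append(
        {
            "term": "total",
            "df": n - 1,
            "SS": total_ss,
            "MS": np.nan,
            "R2": np.nan if degenerate else 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p_perm": np.nan,
        }
    )
    anova = pd.DataFrame(rows).set_index("term")
    coefficients = pd.DataFrame(
        coef, index=["intercept"] + terms, columns=list(Y.columns)
    )
    return MvPglsFit(
        terms=terms,
        anova=anova,
        coefficients=coefficients,
        residual_ss=residual_ss,
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed,
        labels=order,
    )


@dataclass
class GlsFit:
    """Closed-form univariate phylogenetic GLS with parametric t-tests."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2_terms: pd.Series
    residual_ss: float
    total_ss: float
    df_resid: int


def gls_univariate(y: pd.Series, X: pd.DataFrame, C: PhyloCovariance) -> GlsFit:
    """Phylogenetic GLS of a single continuous response.

    b = (X' C^-1 X)^-1 X' C^-1 y with an intercept column; standard errors
    and t-tests are parametric; per-term marginal R^2 is the sequential
    SS share of the whitened total SS.
    """
    Yf = y.to_frame("y")
    Yf, X, order = _align(Yf, X, C)
    yv = Yf["y"].to_numpy(dtype=float)
    xv = X.to_numpy(dtype=float)
    n, p = xv.shape
    P = inv_sqrt(C)
    yw = P @ yv
    design = P @ np.column_stack([np.ones(n), xv])
    names = ["intercept"] + list(X.columns)

    xtx = design.T @ design
    if np.linalg.cond(xtx) > 1e12:
        raise ValidationError("singular design matrix")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ design.T @ yw
    resid = yw - design @ beta
    df_resid = n - p - 1
    sigma2 = resid @ resid / df_resid
    bse = np.sqrt(np.diag(xtx_inv) * sigma2)
    tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)

    # sequential SS decomposition on whitened data
    q0, _ = np.linalg.qr(design[:, :1])
    total_ss = float(((yw - q0 @ (q0.T @ yw)) ** 2).sum())
    r2 = {}
    prev_rss = total_ss
    for j in range(1, p + 1):
        qj, _ = np.linalg.qr(design[:, : j + 1])
        rss = float(((yw - qj @ (qj.T @ yw)) ** 2).sum())
        r2[names[j]] = (prev_rss - rss) / total_ss if total_ss > 0 else 0.0
        prev_rss = rss
    return GlsFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        r2_terms=pd.Series(r2),
        residual_ss=float(resid @ resid),
        total_ss=total_ss,
        df_resid=df_resid,
    )
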