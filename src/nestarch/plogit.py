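"""Univariate comparison arm: phylogenetic logistic regression per state.

Each of the 17 nest trait states is recoded to a presence/absence
indicator and regressed on the same predictor set as the multivariate
model. The estimator is a Firth-bias-adjusted quasi-score method for
Bernoulli responses whose latent correlation follows the phylogeny:

* mean model: P(y_i = 1) = expit(x_i' beta), exactly logistic;
* working covariance: V = W^(1/2) R(s) W^(1/2) with W = diag(p(1-p)) and
  R(s) = I + s (Chat - I), where Chat is the Brownian correlation matrix
  of the tree (covariance normalized to unit diagonal) and s in [0, 1] is
  the phylogenetic signal weight;
* beta solves the bias-adjusted quasi-score equation, which at s = 0 (or
  on a star tree, where Chat = I) is exactly Firth-penalized logistic
  regression, so coefficients stay finite even under complete separation;
* s is chosen on a coarse grid refined by golden-section search of a
  REML-type Gaussian pseudo-likelihood of the Pearson residuals.

Wald z statistics and p-values come from the inverse quasi-information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import AlignmentError, ValidationError
from .phylo import PhyloCovariance, Phylogeny, vcv
from .traits import NOMINAL_TRAITS, STATE_SPACE, RecodedRecord

_PCLIP = 1e-10

#: default grid for the phylogenetic signal weight s (0 first: ties -> 0)
DEFAULT_S_GRID = (0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.99)


def binarize_traits(records: Sequence[RecodedRecord]) -> pd.DataFrame:
    """One presence/absence column per trait state (17 columns).

    Columns are named ``<trait>_<state>`` (e.g. ``site_cliff``); within
    each trait the indicators of a species sum to exactly 1.
    """
    index = [r.species_id for r in records]
    data = {}
    for trait in NOMINAL_TRAITS:
        for state in STATE_SPACE[trait]:
            data[f"{trait}_{state}"] = [
                1 if getattr(r, trait) == state else 0 for r in records
            ]
    return pd.DataFrame(data, index=index)


@dataclass
class LogisticFit:
    """One phylogenetic logistic fit (one trait state)."""

    trait_state: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    phylo_signal: float  # s in [0, 1]; 0 = no phylogenetic correlation
    converged: bool
    n_iter: int = 0
    s_bounds: tuple[float, float] = (0.0, 0.99)

    def row(self) -> dict:
        out = {"trait_state": self.trait_state, "phylo_signal": self.phylo_signal,
               "converged": self.converged}
        for name in self.params.index:
            out[f"coef_{name}"] = self.params[name]
            out[f"se_{name}"] = self.bse[name]
            out[f"z_{name}"] = self.zvalues[name]
            out[f"p_{name}"] = self.pvalues[name]
        return out


class _Correlation:
    """Eigendecomposition of Chat, reused across signal-weight values."""

    def __init__(self, chat: np.ndarray):
        self.n = chat.shape[0]
        lam, u = np.linalg.eigh((chat + chat.T) / 2)
        self.lam = lam
        self.u = u
        self.is_identity = bool(np.allclose(chat, np.eye(self.n), atol=1e-14))

    def apply_inv(self, s: float, m: np.ndarray) -> np.ndarray:
        if s == 0.0 or self.is_identity:
            return m
        d = 1.0 + s * (self.lam - 1.0)
        scale = d[:, None] if m.ndim == 2 else d
        return self.u @ ((self.u.T @ m) / scale)

    def apply_inv_sqrt(self, s: float, m: np.ndarray) -> np.ndarray:
        if s == 0.0 or self.is_identity:
            return m
        d = np.sqrt(1.0 + s * (self.lam - 1.0))
        scale = d[:, None] if m.ndim == 2 else d
        return self.u @ ((self.u.T @ m) / scale)

    def logdet(self, s: float) -> float:
        if s == 0.0 or self.is_identity:
            return 0.0
        return float(np.log(1.0 + s * (self.lam - 1.0)).sum())


def _irls(y: np.ndarray, design: np.ndarray, corr: _Correlation, s: float,
          max_iter: int = 100, tol: float = 1e-10):
    """Bias-adjusted quasi-score IRLS for fixed signal weight s."""
    n, q = design.shape
    beta = np.zeros(q)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        w = p * (1 - p)
        sw = np.sqrt(w)
        g = sw[:, None] * design  # W^{1/2} X
        b = corr.apply_inv_sqrt(s, g)  # R^{-1/2} W^{1/2} X
        info = b.T @ b
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, p, info, it, False
        h = np.einsum("ij,jk,ik->i", b, info_inv, b)
        adj = y - p + h * (0.5 - p)
        score = (corr.apply_inv(s, g)).T @ (adj / sw)
        step = info_inv @ score
        # dampen huge steps for stability under near-separation
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = design @ beta
    p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
    sw = np.sqrt(p * (1 - p))
    b = corr.apply_inv_sqrt(s, sw[:, None] * design)
    info = b.T @ b
    return beta, p, info, it, converged


def _pseudo_loglik(y, p, corr, s, info) -> float:
    """REML-type working Gaussian criterion on Pearson residuals."""
    sw = np.sqrt(p * (1 - p))
    r = (y - p) / sw
    quad = float(r @ corr.apply_inv(s, r))
    sign, logdet_info = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return -0.5 * (corr.logdet(s) + quad + logdet_info)


def phyloglm_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree: Phylogeny | PhyloCovariance,
    trait_state: str = "",
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit one phylogenetic logistic regression (see module docstring).

    ``tree`` may be a Phylogeny or a precomputed Brownian covariance. The
    signal weight is searched over ``s_grid`` and refined by golden
    section; ties prefer the smallest s, so data with no phylogenetic
    structure reduce deterministically to Firth logistic regression.
    """
    C = tree if isinstance(tree, PhyloCovariance) else vcv(tree)
    if set(y.index) != set(X.index) or set(y.index) != set(C.labels):
        raise AlignmentError("labels of y, X and tree do not match")
    order = list(C.labels)
    yv = y.loc[order].to_numpy(dtype=float)
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValidationError("response must be binary 0/1")
    if yv.min() == yv.max():
        raise ValidationError("response is constant; cannot fit")
    xv = X.loc[order].to_numpy(dtype=float)
    n = len(yv)
    design = np.column_stack([np.ones(n), xv])
    names = ["intercept"] + list(X.columns)

    d = np.sqrt(np.diag(C.values))
    chat = C.values / np.outer(d, d)
    corr = _Correlation(chat)

    def objective(s: float):
        beta, p, info, it, conv = _irls(yv, design, corr, s, max_iter=max_iter)
        crit = _pseudo_loglik(yv, p, corr, s, info) if conv else -np.inf
        return crit, (beta, p, info, it, conv)

    grid = list(s_grid)
    if corr.is_identity:
        # star tree: no shared ancestry, so every s gives the same fit
        grid = [min(grid)]
    results = [objective(s) for s in grid]
    crits = [r[0] for r in results]
    best = int(np.argmax(crits))  # ties -> first (smallest s)

    s_best, (crit_best, fit_best) = grid[best], results[best]
    # golden-section refinement inside the bracketing neighbours, unless
    # the criterion is flat there (e.g. star trees)
    lo = grid[best - 1] if best > 0 else grid[best]
    hi = grid[best + 1] if best < len(grid) - 1 else grid[best]
    flat = all(abs(c - crit_best) < 1e-9 for c in crits)
    if hi > lo and not flat and len(grid) > 1:
        phi = (np.sqrt(5.0) - 1) / 2
        a, b_ = lo, hi
        c1 = b_ - phi * (b_ - a)
        c2 = a + phi * (b_ - a)
        f1, r1 = objective(c1)
        f2, r2 = objective(c2)
        for _ in range(8):
            if f1 >= f2:
                b_, c2, f2, r2 = c2, c1, f1, r1
                c1 = b_ - phi * (b_ - a)
                f1, r1 = objective(c1)
            else:
                a, c1, f1, r1 = c1, c2, f2, r2
                c2 = a + phi * (b_ - a)
                f2, r2 = objective(c2)
        for s_c, (f_c, fit_c) in [(c1, (f1, r1)), (c2, (f2, r2))]:
            if f_c > crit_best:
                crit_best, s_best, fit_best = f_c, s_c, fit_c

    beta, p, info, it, conv = fit_best
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(len(beta), np.nan)
        conv = False
    zvals = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    return LogisticFit(
        trait_state=trait_state,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        zvalues=pd.Series(zvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        phylo_signal=float(s_best),
        converged=bool(conv),
        n_iter=it,
        s_bounds=(float(min(s_grid)), float(max(s_grid))),
    )


def run_univariate_suite(
    records: Sequence[RecodedRecord],
    X: pd.DataFrame,
    tree: Phylogeny | PhyloCovariance,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Fit all 17 trait-state indicators against the shared predictor set.

    ``exclude`` lists species ids removed before fitting (e.g. extreme
    body-mass outliers). Constant indicators or failed fits are flagged
    (converged = False) and the suite continues. A Holm-adjusted p-value
    column is added per predictor (adjusted across the 17 models).
    """
    keep = [r for r in records if r.species_id not in set(exclude)]
    indicators = binarize_traits(keep)
    ids = list(indicators.index)
    Xk = X.loc[ids]
    C = tree if isinstance(tree, PhyloCovariance) else vcv(tree)
    Ck = C.reorder(ids)

    rows = []
    names = ["intercept"] + list(X.columns)
    for state in indicators.columns:
        yi = indicators[state]
        try:
            fit = phyloglm_fit(yi, Xk, Ck, trait_state=state)
            rows.append(fit.row())
        except (ValidationError, np.linalg.LinAlgError) as exc:
            row = {"trait_state": state, "phylo_signal": np.nan,
                   "converged": False, "error": str(exc)}
            for nm in names:
                for pre in ("coef", "se", "z", "p"):
                    row[f"{pre}_{nm}"] = np.nan
            rows.append(row)
    suite = pd.DataFrame(rows).set_index("trait_state")
    for pred in X.columns:
        suite[f"p_holm_{pred}"] = _holm(suite[f"p_{pred}"].to_numpy(dtype=float))
    return suite


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; NaNs are passed through."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    adj = np.maximum.accumulate((m - np.arange(m)) * pv[order])
    out_ok = np.empty(m)
    out_ok[order] = np.minimum(adj, 1.0)
    out[ok] = out_ok
    return out


def congruence_report(
    suite: pd.DataFrame, associations: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Tabulate sign agreement between the two analysis arms.

    For every (trait state, predictor): the univariate coefficient sign
    (where p < alpha, else 0) against the multivariate association class
    sign (strong/tendency direction, else 0); ``agree`` is True when both
    are non-zero and share a sign.
    """
    sign_of_class = {
        "strong_positive": 1, "tendency_positive": 1,
        "strong_negative": -1, "tendency_negative": -1, "none": 0,
    }
    rows = []
    for _, a in associations.iterrows():
        state, pred = a["trait_state"], a["predictor"]
        mv_sign = sign_of_class[a["association"]]
        uni_sign = 0
        uni_p = np.nan
        if state in suite.index and f"p_{pred}" in suite.columns:
            uni_p = suite.loc[state, f"p_{pred}"]
            coef = suite.loc[state, f"coef_{pred}"]
            if np.isfinite(uni_p) and uni_p < alpha and np.isfinite(coef):
                uni_sign = int(np.sign(coef))
        rows.append(
            {
                "trait_state": state,
                "predictor": pred,
                "multivariate_sign": mv_sign,
                "univariate_sign": uni_sign,
                "univariate_p": uni_p,
                "agree": bool(mv_sign != 0 and uni_sign == mv_sign),
            }
        )
    return pd.DataFrame(rows)
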