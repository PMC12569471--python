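"""Multivariate phylogenetic signal: Blomberg's K generalized by traces.

K compares the observed ratio of among-species to phylogenetically
corrected variation against its expectation under Brownian motion, so K
is calibrated to 1 when traits evolve by Brownian motion on the given
tree. The multivariate generalization replaces quadratic forms by traces
over all trait columns:

    K = [tr(E'E) / tr(E'C^-1 E)] / [(tr(C) - n / sum(C^-1)) / (n - 1)]

where E are deviations of the tip data from the phylogenetic (GLS) grand
mean. The permutation test shuffles whole species rows across tips,
preserving within-species trait covariance; the observed arrangement is
counted, so with 1000 permutations the smallest attainable p is 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import AlignmentError, NumericalError, ValidationError
from .phylo import MAX_CONDITION, PhyloCovariance


@dataclass
class PhyloSignalResult:
    K_mult: float
    p_perm: float
    n_permutations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "K_mult": self.K_mult,
                "p_perm": self.p_perm,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            },
            indent=2,
        )


def _k_statistic(y: np.ndarray, cinv: np.ndarray, ones_cinv: np.ndarray,
                 denom_expect: float, sum_cinv: float) -> float:
    ahat = (ones_cinv @ y) / sum_cinv  # phylogenetic grand mean, row vector
    e = y - ahat
    num = float((e * e).sum())
    den = float((e * (cinv @ e)).sum())
    if den <= 0:
        raise NumericalError("degenerate data: zero phylogenetic variance")
    return (num / den) / denom_expect


def kmult(
    Y: pd.DataFrame | np.ndarray,
    C: PhyloCovariance,
    n_perm: int = 1000,
    seed: int = 0,
) -> PhyloSignalResult:
    """Multivariate Blomberg's K with a tip-shuffling permutation test."""
    if isinstance(Y, pd.DataFrame):
        if set(Y.index) != set(C.labels):
            raise AlignmentError("labels of Y and C do not match")
        y = Y.loc[list(C.labels)].to_numpy(dtype=float)
    else:
        y = np.asarray(Y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != len(C.labels):
            raise AlignmentError("row count of Y does not match C")
    if y.ndim != 2 or y.shape[1] == 0:
        raise ValidationError("Y must have at least one trait column")
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2")

    c = C.values
    n = c.shape[0]
    eigval = np.linalg.eigvalsh(c)
    if eigval[0] <= 0 or eigval[-1] / eigval[0] > MAX_CONDITION:
        raise NumericalError("singular phylogenetic covariance")
    cinv = linalg.inv(c)
    cinv = (cinv + cinv.T) / 2
    ones_cinv = cinv.sum(axis=0)
    sum_cinv = float(ones_cinv.sum())
    denom_expect = (np.trace(c) - n / sum_cinv) / (n - 1)

    k_obs = _k_statistic(y, cinv, ones_cinv, denom_expect, sum_cinv)
    rng = np.random.default_rng(seed)
    # the observed arrangement is iteration 1 of n_perm, so min p = 1/n_perm
    count = 1
    for _ in range(n_perm - 1):
        k_perm = _k_statistic(
            y[rng.permutation(n)], cinv, ones_cinv, denom_expect, sum_cinv
        )
        if k_perm >= k_obs - 1e-12:
            count += 1
    return PhyloSignalResult(
        K_mult=float(k_obs),
        p_perm=count / n_perm,
        n_permutations=n_perm,
        seed=seed,
    )
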