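"""Nest-architecture morphospace: Gower dissimilarity + principal coordinates.

For all-nominal traits the Gower coefficient reduces to simple matching:
the dissimilarity between two species is the proportion of the five traits
on which they differ. Principal coordinates analysis (classical metric
scaling) double-centres the squared dissimilarities and eigendecomposes
the result; axes with eigenvalues above a relative tolerance are retained.

With 5 nominal traits carrying 17 states in total, the Gower matrix has at
most 17 - 5 = 12 positive eigenvalues, so the morphospace has at most 12
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .traits import NOMINAL_TRAITS, RecodedRecord

#: retain eigenvalues above EIG_TOL_FACTOR * max(eigenvalue)
EIG_TOL_FACTOR = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix in [0, 1] with species labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Morphospace:
    """PCoA ordination: coordinates, eigenvalues and variance shares.

    ``coords`` has one column per retained (non-zero) axis, ordered by
    descending eigenvalue; ``rel_var`` divides by the sum of positive
    eigenvalues. ``all_eigenvalues`` keeps the full spectrum (including
    negatives, which metric scaling of non-Euclidean dissimilarities can
    produce) for diagnostics.
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    rel_var: np.ndarray
    all_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pco{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coords, index=self.labels, columns=cols)


def gower(records: Sequence[RecodedRecord]) -> DistanceMatrix:
    """Gower (simple-matching) dissimilarity over the five nominal traits.

    d(i, j) = (number of traits on which i and j differ) / 5.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records")
    labels = [r.species_id for r in records]
    if len(set(labels)) != len(labels):
        dupes = sorted({s for s in labels if labels.count(s) > 1})
        raise ValidationError(f"duplicate species ids: {dupes}")
    states = np.array([r.nominal_states() for r in records], dtype=object)
    n_traits = len(NOMINAL_TRAITS)
    mism = np.zeros((len(records), len(records)))
    for t in range(n_traits):
        col = states[:, t]
        mism += (col[:, None] != col[None, :]).astype(float)
    return DistanceMatrix(labels=labels, values=mism / n_traits)


def pcoa(D: DistanceMatrix, tol_factor: float = EIG_TOL_FACTOR) -> Morphospace:
    """Principal coordinates analysis of a dissimilarity matrix.

    Double-centres B = -1/2 * J D^2 J (D^2 elementwise), eigendecomposes B,
    and retains axes with eigenvalue > tol_factor * max(eigenvalue). No
    correction (Lingoes/Cailliez) is applied for negative eigenvalues;
    they are reported in ``all_eigenvalues`` but excluded from coordinates.

    Eigenvector signs follow a deterministic convention: the entry of
    largest magnitude in each axis is positive.
    """
    d = D.values
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    max_eig = max(eigval[0], 0.0)
    keep = eigval > tol_factor * max_eig if max_eig > 0 else np.zeros(n, dtype=bool)
    lam = eigval[keep]
    vec = eigvec[:, keep]
    coords = vec * np.sqrt(lam)
    for col in range(coords.shape[1]):  # sign convention
        i = np.argmax(np.abs(coords[:, col]))
        if coords[i, col] < 0:
            coords[:, col] = -coords[:, col]
    pos_sum = eigval[eigval > 0].sum()
    rel_var = lam / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    return Morphospace(
        labels=list(D.labels),
        coords=coords,
        eigenvalues=lam,
        rel_var=rel_var,
        all_eigenvalues=eigval,
    )


def variance_table(m: Morphospace) -> pd.DataFrame:
    """Per-axis eigenvalue / variance-share table for the retained axes.

    ``rel_var`` divides by the sum of positive eigenvalues; ``rel_var_abs``
    divides by the sum of |eigenvalues| (the alternative convention when
    negative eigenvalues exist). ``cum_var`` accumulates ``rel_var``.
    """
    rows = []
    abs_sum = np.abs(m.all_eigenvalues).sum() if m.all_eigenvalues.size else np.nan
    cum = 0.0
    for i, (lam, rv) in enumerate(zip(m.eigenvalues, m.rel_var)):
        cum += rv
        rows.append(
            {
                "axis": i + 1,
                "eigenvalue": lam,
                "rel_var": rv,
                "rel_var_abs": lam / abs_sum if abs_sum > 0 else np.nan,
                "cum_var": cum,
            }
        )
    return pd.DataFrame(rows, columns=["axis", "eigenvalue", "rel_var", "rel_var_abs", "cum_var"])
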