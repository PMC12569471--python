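"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from nestarch.phylo import PhyloCovariance
from nestarch.traits import (
    ATTACHMENTS,
    HEIGHT_CLASSES,
    NEST_TYPES,
    SITES_RECODED,
    STRUCTURES,
    RecodedRecord,
)


def make_recoded(species_id, nest_type="cavity", structure="cup", site="vegetation",
                 attachment="basal", height_class="medium", gm_h=3.0, gm_m=20.0):
    return RecodedRecord(
        species_id=species_id,
        nest_type=nest_type,
        structure=structure,
        site=site,
        attachment=attachment,
        height_class=height_class,
        geo_mean_height_m=gm_h,
        geo_mean_mass_g=gm_m,
    )


def random_recoded(rng: np.random.Generator, n: int) -> list[RecodedRecord]:
    """Random valid recoded records (nominal traits drawn uniformly)."""
    out = []
    for i in range(n):
        out.append(
            make_recoded(
                f"sp{i:03d}",
                nest_type=rng.choice(NEST_TYPES),
                structure=rng.choice(STRUCTURES),
                site=rng.choice(SITES_RECODED),
                attachment=rng.choice(ATTACHMENTS),
                height_class=rng.choice(HEIGHT_CLASSES),
            )
        )
    return out


def all_trait_combinations() -> list[RecodedRecord]:
    """All 2*4*4*3*4 = 384 possible nominal-trait combinations."""
    combos = itertools.product(
        NEST_TYPES, STRUCTURES, SITES_RECODED, ATTACHMENTS, HEIGHT_CLASSES
    )
    return [
        make_recoded(f"c{i:03d}", nt, st, si, at, hc)
        for i, (nt, st, si, at, hc) in enumerate(combos)
    ]


def gower_oracle(records) -> np.ndarray:
    """Nested-loop mismatch-count oracle for the Gower matrix."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = records[i].nominal_states(), records[j].nominal_states()
            d[i, j] = sum(x != y for x, y in zip(a, b)) / 5
    return d


def star_covariance(n: int, depth: float = 1.0) -> PhyloCovariance:
    labels = [f"s{i:03d}" for i in range(n)]
    return PhyloCovariance(labels=labels, values=depth * np.eye(n))


def univariate_blomberg_k(y: np.ndarray, c: np.ndarray) -> float:
    """Independent scalar Blomberg's K (explicit-inverse algebra)."""
    n = len(y)
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    ahat = (ones @ cinv @ y) / (ones @ cinv @ ones)
    e = y - ahat
    mse0 = e @ e
    mse = e @ cinv @ e
    expected = (np.trace(c) - n / (ones @ cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def firth_logistic_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Independent Firth-penalized logistic oracle (Nelder-Mead on the
    penalized log-likelihood; no IRLS, no shared code with the package)."""
    from scipy.optimize import minimize

    n = len(y)
    M = np.column_stack([np.ones(n), X])

    def neg_penalized(b):
        eta = M @ b
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        w = p * (1 - p)
        _, logdet = np.linalg.slogdet(M.T @ (w[:, None] * M))
        return -(ll + 0.5 * logdet)

    res = minimize(
        neg_penalized,
        np.zeros(M.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 50000, "maxfev": 50000},
    )
    return res.x


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bd_tree_64():
    from nestarch.synthetic_data import SimConfig, sim_tree

    return sim_tree(SimConfig(seed=12345, n_tips=64))


@pytest.fixture(scope="session")
def bd_tree_128():
    from nestarch.synthetic_data import SimConfig, sim_tree

    return sim_tree(SimConfig(seed=54321, n_tips=128))


def bm_simulate(C: PhyloCovariance, k: int, rng: np.random.Generator) -> pd.DataFrame:
    """Brownian-motion tip data: one column per trait."""
    chol = np.linalg.cholesky(C.values + 1e-12 * np.eye(len(C.labels)))
    return pd.DataFrame(chol @ rng.standard_normal((len(C.labels), k)), index=C.labels)
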