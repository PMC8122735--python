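"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: AUC by
pair enumeration, the rank-sum p-value by enumerating all label
assignments, and the Youden threshold by exhaustive search. Tests compare
the implementation against these on small inputs.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from vocdx.simulate import (
    ChemicalSpec,
    CohortSpec,
    MarkerSpec,
    NoiseSpec,
    make_cohort,
    simulate_ims_cohort,
)


def auc_by_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as (wins + ties/2) / (n_pos * n_neg) over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ranksum_p_by_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all assignments.

    Two-sided p is twice the smaller tail probability of the observed U,
    capped at 1 (the convention of the exact test for untied data).
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(idx: tuple[int, ...]) -> float:
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return sum(1.0 for ai in a for bi in b if ai > bi) + 0.5 * sum(
            1.0 for ai in a for bi in b if ai == bi
        )

    observed = u_stat(tuple(range(n1)))
    us = [u_stat(idx) for idx in combinations(range(len(pooled)), n1)]
    total = comb(len(pooled), n1)
    p_ge = sum(1 for u in us if u >= observed) / total
    p_le = sum(1 for u in us if u <= observed) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def youden_by_search(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best (smallest) threshold by exhaustive search over unique scores,
    using the proba >= t prediction rule."""
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, None
    for t in sorted(np.unique(scores)):  # ascending: first max is smallest t
        pred = scores >= t
        j = (pred & (labels == 1)).sum() / n_pos - (pred & (labels == 0)).sum() / n_neg
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return make_cohort(CohortSpec(n_hcc=10, n_fibrosis=5, n_nonfibrosis=10, seed=7))


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseSpec:
    return NoiseSpec(baseline_level=0.0, additive_sd=0.0, rip_position=7.5, rip_intensity=1000.0)


@pytest.fixture(scope="session")
def one_marker() -> list[MarkerSpec]:
    return [MarkerSpec((300.0, 11.0), 500.0, {"HCC": 2.0}, (10.0, 0.2), 0.0)]


@pytest.fixture(scope="session")
def small_spectra(small_cohort, one_marker, quiet_noise):
    return simulate_ims_cohort(
        small_cohort, one_marker, noise=quiet_noise, grid=(32, 24), seed=7
    )


@pytest.fixture()
def toy_chemicals() -> list[ChemicalSpec]:
    return [
        ChemicalSpec("alpha", 2.0, 5e5, {"HCC": 2.5}, 0.05, 0.2),
        ChemicalSpec("beta", 5.0, 5e5, {}, 0.05, 0.2),
        ChemicalSpec("gamma", 9.0, 5e5, {"HCC": 0.4}, 0.05, 0.2),
    ]
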