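"""Independent oracles used by the test suite.

These re-derive expected values by routes independent of the library code:
exact rational enumeration for the Hardy-Weinberg test, direct conditional
Gaussian algebra for mixed-model imputation, and a per-pair loop for the
kinship estimator.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def _hwe_het_distribution(n: int, n_rare: int) -> dict[int, Fraction]:
    """Exact conditional distribution of the heterozygote count given the
    rare-allele count, via rational arithmetic."""
    n_common = 2 * n - n_rare
    dist: dict[int, Fraction] = {}
    denom = comb(2 * n, n_rare)
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = (n_common - h) // 2
        if hom_rare < 0 or hom_common < 0:
            continue
        ways = (
            Fraction(
                _factorial(n),
                _factorial(hom_rare) * _factorial(h) * _factorial(hom_common),
            )
            * 2**h
        )
        dist[h] = ways / denom
    return dist


@lru_cache(maxsize=None)
def _factorial(k: int) -> int:
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg exact p-value by exact-rational enumeration."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    dist = _hwe_het_distribution(n, rare)
    p_obs = dist[n_Aa]
    total = sum(p for p in dist.values() if p <= p_obs)
    return float(min(total, Fraction(1)))


def mar_conditional_means(y, batch_idx, is_ref, mu, alpha, d, sigma, sigma0):
    """Conditional means of missing entries in a plain Gaussian mixed model
    (no selection): direct normal conditioning, computed per batch."""
    y = np.asarray(y, dtype=float)
    out = y.copy()
    m0 = mu + alpha * np.asarray(is_ref, dtype=float)
    s2 = np.where(is_ref, sigma0**2, sigma**2)
    for b in np.unique(batch_idx):
        in_b = batch_idx == b
        obs = in_b & ~np.isnan(y)
        if d == 0:
            b_hat = 0.0
        else:
            prec = 1.0 / d**2 + np.sum(1.0 / s2[obs])
            b_hat = np.sum((y[obs] - m0[obs]) / s2[obs]) / prec
        miss = in_b & np.isnan(y)
        out[miss] = m0[miss] + b_hat
    return out


def kinship_loop(gi, gj) -> float:
    """Robust kinship, scalar loop implementation."""
    n11 = n02 = het_i = het_j = 0
    for a, b in zip(gi, gj):
        if np.isnan(a) or np.isnan(b):
            continue
        if a == 1 and b == 1:
            n11 += 1
        if abs(a - b) == 2:
            n02 += 1
        if a == 1:
            het_i += 1
        if b == 1:
            het_j += 1
    if het_i + het_j == 0:
        return float("nan")
    return (n11 - 2 * n02) / (het_i + het_j)
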