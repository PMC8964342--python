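"""Shared fixtures and independent numerical oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from msneutral import ChainSettings, immigration_from_m, simulate_neutral_metacommunity


def brute_force_stirling1(n: int, k: int) -> int:
    """Count permutations of n elements with exactly k cycles by enumeration."""
    if n == 0:
        return 1 if k == 0 else 0
    count = 0
    for perm in itertools.permutations(range(n)):
        seen = [False] * n
        cycles = 0
        for start in range(n):
            if not seen[start]:
                cycles += 1
                j = start
                while not seen[j]:
                    seen[j] = True
                    j = perm[j]
        if cycles == k:
            count += 1
    return count


def grid_cdf(logf, lo: float, hi: float, n: int = 6000):
    """Numerically normalized CDF of an unnormalized 1-D log-density."""
    x = np.linspace(lo, hi, n)
    lf = np.array([logf(v) for v in x])
    f = np.exp(lf - lf.max())
    cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(x))])
    return x, cdf / cdf[-1]


def ks_distance(draws: np.ndarray, x: np.ndarray, cdf: np.ndarray) -> float:
    """KS distance between an empirical sample and a gridded CDF."""
    d = np.sort(np.asarray(draws))
    emp = np.arange(1, d.size + 1) / d.size
    return float(np.max(np.abs(emp - np.interp(d, x, cdf))))


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def make_neutral_matrix(theta=50.0, m=0.05, J=1000, M=3, seed=0):
    rng = np.random.default_rng(seed)
    depths = np.full(M, J, dtype=np.int64)
    I = np.array([immigration_from_m(m, int(j)) for j in depths])
    return simulate_neutral_metacommunity(theta, I, depths, rng)


@pytest.fixture(scope="session")
def small_matrix():
    """A modest 3-site neutral metacommunity reused across tests."""
    return make_neutral_matrix(theta=30.0, m=0.1, J=500, M=3, seed=11)


@pytest.fixture
def quick_settings():
    """Short chain settings for smoke-level fits."""
    return ChainSettings(n_iterations=600, n_burnin=300, thinning=3, seed=5)
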