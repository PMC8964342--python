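"""Log-space Stirling-number and Chinese-restaurant-process combinatorics.

The number of distinct types observed after ``n`` exchangeable draws from a
Dirichlet process with concentration ``c`` follows the Antoniak distribution,

    P(S = k | c, n) = s(n, k) * c**k * Gamma(c) / Gamma(c + n),

where ``s(n, k)`` is the unsigned Stirling number of the first kind.  These
quantities appear in the conditional distributions of the multi-site neutral
model sampler, with ``n`` as large as a sample's read depth (thousands), so
everything here is computed in log space: linear-space Stirling numbers
overflow a double near n = 170.

The module keeps a single, lazily grown triangular table of ``log s(n, k)``
per process.  Callers must treat returned rows as read-only.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LogStirlingTable",
    "log_stirling1",
    "antoniak_pmf",
    "sample_crp_tables",
    "crp_table_counts",
    "expected_crp_tables",
]


class LogStirlingTable:
    """Triangular table of log unsigned Stirling numbers of the first kind.

    Row ``n`` holds ``log s(n, k)`` for ``k = 0..n`` (``-inf`` encodes a zero
    value).  Rows are built by the additive recurrence

        s(n, k) = s(n-1, k-1) + (n-1) * s(n-1, k)

    evaluated with ``logaddexp``, which is exact in log space up to rounding
    and stable for n in the tens of thousands.
    """

    def __init__(self) -> None:
        # row 0: s(0,0) = 1
        self._rows: list[np.ndarray] = [np.array([0.0])]

    @property
    def max_n(self) -> int:
        return len(self._rows) - 1

    def grow(self, max_n: int) -> None:
        """Extend the table so rows 0..max_n exist."""
        while self.max_n < max_n:
            n = self.max_n + 1
            prev = self._rows[-1]
            row = np.full(n + 1, -np.inf)
            row[n] = 0.0
            if n >= 2:
                # interior cells 1..n-1
                row[1:n] = np.logaddexp(prev[0 : n - 1], math.log(n - 1) + prev[1:n])
            self._rows.append(row)

    def row(self, n: int) -> np.ndarray:
        self.grow(n)
        return self._rows[n]

    def __call__(self, n: int, k: int) -> float:
        if n < 0 or k < 0:
            raise ValueError("Stirling-number arguments must be non-negative")
        if k > n:
            return -np.inf
        return float(self.row(n)[k])


_TABLE = LogStirlingTable()


def log_stirling1(n: int, k: int) -> float:
    """Return ``log s(n, k)`` for the unsigned Stirling number of the first kind.

    Served from a process-wide cache that grows monotonically with the largest
    ``n`` requested.  ``-inf`` is returned for structurally zero entries
    (``k > n``, or ``k = 0`` with ``n >= 1``).
    """
    return _TABLE(n, k)


def antoniak_pmf(theta: float, n_draws: int) -> np.ndarray:
    """Distribution of the number of distinct types in ``n_draws`` DP draws.

    Parameters
    ----------
    theta
        Concentration parameter of the Dirichlet process, > 0.
    n_draws
        Number of exchangeable draws, >= 1.

    Returns
    -------
    Probability vector indexed by ``S = 1..n_draws`` (entry 0 is ``P(S=1)``).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    row = _TABLE.row(n_draws)[1:]  # log s(n, k), k = 1..n
    k = np.arange(1, n_draws + 1)
    logp = row + k * math.log(theta) + gammaln(theta) - gammaln(theta + n_draws)
    p = np.exp(logp)
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-10):
        raise FloatingPointError(
            f"Antoniak pmf normalization drifted: sum = {total!r}"
        )
    return p


def crp_table_counts(
    n_customers: int, concentration: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized batch of CRP table counts (``size`` independent runs).

    Customer ``i`` (1-based) opens a new table with probability
    ``c / (c + i - 1)``; the count of opened tables is Antoniak-distributed.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_customers < 0:
        raise ValueError("n_customers must be non-negative")
    if n_customers == 0:
        return np.zeros(size, dtype=np.int64)
    p_new = concentration / (concentration + np.arange(n_customers))
    u = rng.random((size, n_customers))
    return (u < p_new).sum(axis=1).astype(np.int64)


def sample_crp_tables(
    n_customers: int, concentration: float, rng: np.random.Generator
) -> int:
    """Draw one Antoniak(concentration, n_customers) variate by sequential CRP.

    O(n) per draw and free of Stirling tables, so it remains cheap at read
    depths in the thousands.  Returns 0 iff ``n_customers`` is 0, otherwise a
    value in ``1..n_customers``.
    """
    return int(crp_table_counts(n_customers, concentration, 1, rng)[0])


def expected_crp_tables(n_customers: np.ndarray, concentration: np.ndarray) -> np.ndarray:
    """Expected CRP table count: sum_{i=1..n} c / (c + i - 1).

    Evaluated in closed form as ``c * (psi(c + n) - psi(c))``; vectorized over
    matching-shape arrays.  Used to initialize ancestral counts.
    """
    from scipy.special import digamma

    n = np.asarray(n_customers, dtype=float)
    c = np.asarray(concentration, dtype=float)
    out = c * (digamma(c + n) - digamma(c))
    return np.where(n > 0, out, 0.0)
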