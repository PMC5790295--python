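"""Fourth-order finite differences and quadrature on a uniform half-line grid.

The grid spans s = 0 (tip apex) to s = L with uniform spacing.  All physical
fields are either even or odd under reflection s -> -s through the apex, so
stencils at the first two nodes use reflected ghost values (f(-s) = p f(s),
parity p = +1 or -1) instead of one-sided differences; the distal boundary
uses one-sided 4th-order stencils.  Integration matrices implement a
cumulative composite 4th-order rule (cubic interpolation per interval).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

EVEN = 1
ODD = -1
NONE = 0  # no reflection symmetry: one-sided stencils at the left boundary


def fornberg_weights(x0: float, x: np.ndarray, m: int) -> np.ndarray:
    """Finite-difference weights for the m-th derivative at ``x0`` on nodes ``x``.

    Classic recursive algorithm (Fornberg 1988).  Returns weights for
    derivatives 0..m; only the last row is typically used.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    c = np.zeros((n, m + 1))
    c1 = 1.0
    c4 = x[0] - x0
    c[0, 0] = 1.0
    for i in range(1, n):
        mn = min(i, m)
        c2 = 1.0
        c5 = c4
        c4 = x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for k in range(mn, 0, -1):
                    c[i, k] = c1 * (k * c[i - 1, k - 1] - c5 * c[i - 1, k]) / c2
                c[i, 0] = -c1 * c5 * c[i - 1, 0] / c2
            for k in range(mn, 0, -1):
                c[j, k] = (c4 * c[j, k] - k * c[j, k - 1]) / c3
            c[j, 0] = c4 * c[j, 0] / c3
        c1 = c2
    return c[:, m]


@lru_cache(maxsize=64)
def diff_matrix(n: int, ds: float, parity: int) -> np.ndarray:
    """Dense n x n first-derivative matrix, 4th order.

    Interior: 5-point central.  Nodes 0 and 1: central stencil folded through
    the apex with the given parity.  Last two nodes: one-sided.
    """
    if n < 7:
        raise ValueError("need at least 7 grid nodes")
    if parity not in (EVEN, ODD, NONE):
        raise ValueError("parity must be +1 (even), -1 (odd) or 0 (none)")
    D = np.zeros((n, n))
    c = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / (12.0 * ds)
    for i in range(2, n - 2):
        D[i, i - 2:i + 3] = c
    x = np.arange(5, dtype=float) * ds
    if parity == NONE:
        # one-sided 5-point at the left boundary
        for i in (0, 1):
            D[i, :5] = fornberg_weights(i * ds, x, 1)
    else:
        # apex rows: fold ghost columns j<0 onto |j| with sign `parity`
        for i in (0, 1):
            for k, w in zip(range(i - 2, i + 3), c):
                if k < 0:
                    D[i, -k] += parity * w
                else:
                    D[i, k] += w
    # distal rows: one-sided 5-point
    for i in (n - 2, n - 1):
        idx = np.arange(n - 5, n)
        D[i, idx] = fornberg_weights((i - (n - 5)) * ds, x, 1)
    return D


@lru_cache(maxsize=64)
def cumint_matrix(n: int, ds: float, parity: int) -> np.ndarray:
    """Dense n x n cumulative-integration matrix: (Q f)_i ~ int_0^{s_i} f ds.

    Composite 4th-order rule: each interval integrates the cubic through the
    four surrounding nodes; the first interval folds a ghost node through the
    apex with the given parity, the last interval uses a one-sided cubic.
    """
    if n < 7:
        raise ValueError("need at least 7 grid nodes")
    if parity not in (EVEN, ODD, NONE):
        raise ValueError("parity must be +1 (even), -1 (odd) or 0 (none)")
    W = np.zeros((n - 1, n))  # W[i] = integral over [s_i, s_{i+1}]
    a = ds / 24.0
    for i in range(1, n - 2):
        W[i, i - 1:i + 3] = a * np.array([-1.0, 13.0, 13.0, -1.0])
    if parity == NONE:
        # first interval: one-sided cubic through the first four nodes
        W[0, :4] = a * np.array([9.0, 19.0, -5.0, 1.0])
    else:
        # first interval: ghost f_{-1} = parity * f_1
        W[0, 0] = 13.0 * a
        W[0, 1] = (13.0 - parity) * a
        W[0, 2] = -1.0 * a
    # last interval: one-sided cubic through the last four nodes
    W[n - 2, n - 4:n] = a * np.array([1.0, -5.0, 19.0, 9.0])
    Q = np.zeros((n, n))
    Q[1:] = np.cumsum(W, axis=0)
    return Q


def quad_weights(n: int, ds: float, parity: int) -> np.ndarray:
    """Weights w with w @ f ~ int_0^L f ds (last row of the cumulative rule)."""
    return cumint_matrix(n, ds, parity)[-1].copy()
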