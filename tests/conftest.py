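"""Shared fixtures: analytic shapes and cached simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

from tipshell import (
    DimensionlessParameters,
    NumericsConfig,
    ShellShape,
    TipSimulator,
)
from tipshell._fd import EVEN, cumint_matrix

#: coarse but converged settings for regime classification in tests
FAST_NUMERICS = NumericsConfig(n_grid=61, domain_len=6.0, first_chunk=0.25)


def smooth_tip_shape(n: int, L: float = 6.0, a: float = 1.3) -> ShellShape:
    """C-infinity tip meridian theta = (pi/2) tanh(s/a) with r by quadrature.

    Unlike the capped cylinder this has no curvature jump, so discrete
    operators converge at full order on it.
    """
    s = np.linspace(0.0, L, n)
    theta = np.pi / 2 * np.tanh(s / a)
    r = cumint_matrix(n, s[1] - s[0], EVEN) @ np.cos(theta)
    r[0] = 0.0
    return ShellShape.from_profile(s, r, theta)


@pytest.fixture(scope="session")
def run_cache():
    """Session-wide cache of run_to_outcome results keyed by parameters."""
    cache = {}

    def get(gamma, lam_ratio, numerics=FAST_NUMERICS, **kw):
        key = (gamma, lam_ratio, numerics, tuple(sorted(kw.items())))
        if key not in cache:
            p = DimensionlessParameters(gamma=gamma, lam_ratio=lam_ratio, **kw)
            cache[key] = TipSimulator(p, numerics).run()
        return cache[key]

    return get


@pytest.fixture(scope="session")
def stable_run(run_cache):
    """A representative STABLE trajectory (gamma=5, lam_ratio=0.2)."""
    rec = run_cache(5.0, 0.2)
    assert rec.outcome.value == "STABLE"
    return rec
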