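"""Shared independent oracles for the binding-equilibrium tests.

The grid-scan solver here deliberately avoids the package's root-finding
path: it evaluates the titrant conservation residual on a dense grid,
brackets the sign change, and refines by bisection on the raw mass-action
expressions.
"""

from __future__ import annotations

import numpy as np
import pytest


def grid_scan_two_site(e_total: float, s_total: float, kd1: float, kd2: float,
                       n_grid: int = 20001, n_bisect: int = 200):
    """Brute-force two-site equilibrium: dense scan + bisection on S_free.

    Returns (E, S_free, SE, ES, SES).
    """
    def residual(s):
        e = e_total / (1.0 + s / kd1 + s / kd2 + s * s / (kd1 * kd2))
        return s + e * (s / kd1 + s / kd2 + 2.0 * s * s / (kd1 * kd2)) - s_total

    if s_total == 0:
        s = 0.0
    else:
        grid = np.linspace(0.0, s_total, n_grid)
        r = residual(grid)
        idx = int(np.searchsorted(r > 0, True))  # first positive residual
        lo = grid[max(idx - 1, 0)]
        hi = grid[min(idx, n_grid - 1)]
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            if residual(mid) > 0:
                hi = mid
            else:
                lo = mid
        s = 0.5 * (lo + hi)
    e = e_total / (1.0 + s / kd1 + s / kd2 + s * s / (kd1 * kd2))
    return e, s, e * s / kd1, e * s / kd2, e * s * s / (kd1 * kd2)


@pytest.fixture
def two_site_oracle():
    return grid_scan_two_site
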