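"""Shared test utilities."""

import numpy as np

from taskdilemma import water_filling


def draw_interior_instance(rng, n, P=1.0):
    """Random eligible parameters whose optimum is strictly interior.

    Cost slopes are uniform on [0.5, 1.5] and motivations are ``b_i = c_i P
    (1 + u_i)`` with ``u_i`` uniform on [0.1, 1.0], redrawn until the
    water-filling solution has all-positive loads.  Equalization through
    load passing is guaranteed only under a positive maximizer: an individual
    whose optimal load is zero may empty out and, on sparse topologies,
    disconnect the flow of load between its neighbours.
    """
    while True:
        c = rng.uniform(0.5, 1.5, n)
        b = c * P * (1.0 + rng.uniform(0.1, 1.0, n))
        sol = water_filling(b, c, P)
        if sol.p_star.min() > 1e-3 * P:
            return b, c, sol
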