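"""Simulation of dual-label DNA fiber spreading assays.

Each replicating fiber is labeled first with IdU, then with CIdU, for equal
windows.  A fork that stalls during the first label and never resumes shows
no CIdU tract at all; that event occurs with probability ``stall_prob`` per
fiber.  Tract lengths of elongating forks are lognormal around the mean
elongation per labeling window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_fibers"]

FIBER_COLUMNS = ["idu_length", "cidu_length", "stalled"]


def simulate_fibers(
    n: int,
    stall_prob: float = 0.1,
    elongation: float = 10.0,
    length_cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n`` fiber records.

    Parameters
    ----------
    n: number of fibers.
    stall_prob: per-fiber probability that the fork stalls during the first
        labeling window (CIdU length 0).
    elongation: mean tract length per labeling window, micrometers.
    length_cv: coefficient of variation of the lognormal length noise
        (0 gives exact lengths).
    seed: RNG seed; fixed seed gives byte-identical tables.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= stall_prob <= 1.0:
        raise ValueError("stall_prob must be in [0, 1]")
    if elongation <= 0:
        raise ValueError("elongation must be positive")
    if length_cv < 0:
        raise ValueError("length_cv must be >= 0")

    rng = np.random.default_rng(seed)

    def lengths(size: int) -> np.ndarray:
        if length_cv == 0:
            return np.full(size, elongation)
        sigma2 = np.log1p(length_cv**2)
        return elongation * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)

    idu = lengths(n)
    stalled = rng.uniform(size=n) < stall_prob
    cidu = np.where(stalled, 0.0, lengths(n))
    return pd.DataFrame(
        {"idu_length": idu, "cidu_length": cidu, "stalled": stalled},
        columns=FIBER_COLUMNS,
    )
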