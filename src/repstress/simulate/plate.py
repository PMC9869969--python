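"""Simulation of two-drug viability plates under Loewe additivity.

The ground truth of each drug is a four-parameter logistic (4PL) viability
curve.  Combined viability at doses (d1, d2) is defined by the Loewe
condition d1/D1(E) + d2/D2(E) = 1, where D_i(E) is the single-agent dose of
drug i producing effect E — solved numerically per well.  Synergy and
antagonism are modeled as a single dose-potentiation factor alpha applied to
both doses before the Loewe solve (alpha > 1 potentiates, alpha < 1
antagonizes); single-agent wells are never potentiated, so the plate margins
always follow the per-drug 4PL truths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["FourPL", "CombinationPlateSpec", "simulate_combination_plate", "loewe_viability"]

#: Columns of the plate tables produced by :func:`simulate_combination_plate`.
PLATE_COLUMNS = ["dose_1", "dose_2", "replicate", "viability"]


@dataclass(frozen=True)
class FourPL:
    """Four-parameter logistic viability curve (decreasing with dose).

    ``viability(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill)``;
    ``ic50`` is the relative (midpoint) IC50 and ``hill`` > 0.
    """

    top: float = 1.0
    bottom: float = 0.0
    ic50: float = 1.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive (monotone decreasing curve)")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")

    def viability(self, dose: float | np.ndarray) -> float | np.ndarray:
        dose = np.asarray(dose, dtype=float)
        v = self.bottom + (self.top - self.bottom) / (1.0 + (dose / self.ic50) ** self.hill)
        return float(v) if v.ndim == 0 else v

    def inverse(self, viability: float) -> float:
        """Dose producing the given viability; inf/0 at the asymptotes."""
        if viability >= self.top:
            return 0.0
        if viability <= self.bottom:
            return np.inf
        frac = (self.top - viability) / (viability - self.bottom)
        return self.ic50 * frac ** (1.0 / self.hill)


def loewe_viability(d1: float, d2: float, curve1: FourPL, curve2: FourPL) -> float:
    """Viability at (d1, d2) under exact Loewe additivity.

    Solves d1/D1(v) + d2/D2(v) = 1 for the viability v by bracketed root
    finding between the shared response asymptotes.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be nonnegative")
    if d1 == 0 and d2 == 0:
        return min(curve1.top, curve2.top)
    if d2 == 0:
        return curve1.viability(d1)
    if d1 == 0:
        return curve2.viability(d2)

    lo = max(curve1.bottom, curve2.bottom)
    hi = min(curve1.top, curve2.top)

    def excess(v: float) -> float:
        return d1 / curve1.inverse(v) + d2 / curve2.inverse(v) - 1.0

    eps = 1e-12 * (hi - lo)
    return brentq(excess, lo + eps, hi - eps, xtol=1e-13, rtol=1e-14)


@dataclass(frozen=True)
class CombinationPlateSpec:
    """Design of a simulated two-drug checkerboard/ray plate.

    ``doses_1`` / ``doses_2`` are the single-agent dilution series (nonzero
    doses; a zero-dose control row is always added).  ``fixed_2`` are the
    fixed drug-2 doses at which the full drug-1 series is re-run (and
    symmetrically ``fixed_1``).  ``interaction`` is ``"additive"``,
    ``"synergy"`` or ``"antagonism"``; ``alpha`` is the dose-potentiation
    factor (must be > 1 for synergy, < 1 for antagonism, ignored for
    additive).  Gaussian noise of sd ``noise_sd`` is applied independently
    per replicate well and clipped at zero viability.
    """

    curve1: FourPL = FourPL(ic50=1.0)
    curve2: FourPL = FourPL(ic50=5.0)
    doses_1: tuple[float, ...] = (0.031, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    doses_2: tuple[float, ...] = (0.156, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
    fixed_1: tuple[float, ...] = (0.125, 0.25, 0.5)
    fixed_2: tuple[float, ...] = (0.625, 1.25, 2.5)
    interaction: str = "additive"
    alpha: float = 1.0
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction not in ("additive", "synergy", "antagonism"):
            raise ValueError(f"unknown interaction model {self.interaction!r}")
        if self.interaction == "synergy" and self.alpha <= 1:
            raise ValueError("synergy requires alpha > 1")
        if self.interaction == "antagonism" and not (0 < self.alpha < 1):
            raise ValueError("antagonism requires 0 < alpha < 1")
        if any(d < 0 for d in self.doses_1 + self.doses_2 + self.fixed_1 + self.fixed_2):
            raise ValueError("doses must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _true_viability(spec: CombinationPlateSpec, d1: float, d2: float) -> float:
    alpha = spec.alpha if spec.interaction != "additive" else 1.0
    if d1 > 0 and d2 > 0:
        return loewe_viability(alpha * d1, alpha * d2, spec.curve1, spec.curve2)
    return loewe_viability(d1, d2, spec.curve1, spec.curve2)


def simulate_combination_plate(spec: CombinationPlateSpec) -> pd.DataFrame:
    """Simulate the plate defined by ``spec``.

    Returns a long-format DataFrame with columns ``dose_1``, ``dose_2``,
    ``replicate``, ``viability`` covering the (0, 0) control, both
    single-agent series, and one full series of each drug at every fixed
    dose of the other.  Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    wells: list[tuple[float, float]] = [(0.0, 0.0)]
    wells += [(d, 0.0) for d in spec.doses_1]
    wells += [(0.0, d) for d in spec.doses_2]
    for f2 in spec.fixed_2:
        wells += [(d, f2) for d in spec.doses_1]
    for f1 in spec.fixed_1:
        wells += [(f1, d) for d in spec.doses_2]
    # drop duplicate wells while preserving order
    seen: set[tuple[float, float]] = set()
    wells = [wl for wl in wells if not (wl in seen or seen.add(wl))]

    rows = []
    for d1, d2 in wells:
        v_true = _true_viability(spec, d1, d2)
        for rep in range(1, spec.n_replicates + 1):
            v = v_true + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            rows.append((d1, d2, rep, max(v, 0.0)))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)
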