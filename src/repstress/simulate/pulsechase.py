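"""Simulation of an EdU pulse-chase experiment on an asynchronous culture.

The model: cells are distributed over G0/G1, S, and G2/M according to fixed
phase fractions.  S-phase cells carry a replication progress u drawn
uniformly on [0, 1), so their true DNA content is ``i_2n * (1 + u)`` and the
population average sits midway between the 2n and 4n peaks.  A short EdU
pulse labels exactly the cells in S phase.  During the recovery interval
each labeled cell advances its progress at ``replication_rate`` genome
fractions per unit time; a cell that reaches u = 1 holds at 4n for
``g2_duration`` and then divides instantaneously into two EdU-positive 2n
daughters.  A replication block (e.g. hydroxyurea) is ``replication_rate =
0``.  Measured DAPI is the true content times multiplicative lognormal
noise; EdU intensity is a two-component lognormal mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PulseChaseParams", "simulate_pulse_chase"]

#: Column order of the event tables produced by :func:`simulate_pulse_chase`.
EVENT_COLUMNS = [
    "dapi_total",
    "edu_mean",
    "timepoint",
    "truth_phase",
    "truth_progress",
    "truth_edu",
]


@dataclass(frozen=True)
class PulseChaseParams:
    """Ground-truth parameters of a pulse-chase simulation.

    Attributes
    ----------
    n_cells:
        Number of cells in the snapshot at labeling time.
    phase_fractions:
        (G0/G1, S, G2/M) proportions; must sum to 1.
    i_2n:
        True DAPI intensity of a 2n (G0/G1) cell, arbitrary units.
    replication_rate:
        Genome fraction replicated per recovery interval; 0 models a full
        replication block.
    recovery_time:
        Length of the recovery phase, in intervals.
    g2_duration:
        Time a cell that finishes S phase spends at 4n before dividing.
    dapi_cv:
        Coefficient of variation of the multiplicative lognormal DAPI
        measurement noise (0 disables noise).
    edu_signal_params:
        (positive mean, negative mean, spread) of natural-log EdU intensity
        for the labeled and unlabeled components.
    seed:
        Seed for the internal bit generator; fixed seed gives byte-identical
        tables.
    """

    n_cells: int = 20_000
    phase_fractions: tuple[float, float, float] = (0.50, 0.35, 0.15)
    i_2n: float = 100.0
    replication_rate: float = 0.125
    recovery_time: float = 7.0
    g2_duration: float = 3.0
    dapi_cv: float = 0.05
    edu_signal_params: tuple[float, float, float] = (7.0, 2.5, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if min(self.phase_fractions) < 0:
            raise ValueError("phase_fractions must be nonnegative")
        if self.i_2n <= 0:
            raise ValueError("i_2n must be positive")
        if self.replication_rate < 0:
            raise ValueError("replication_rate must be >= 0")
        if self.recovery_time < 0:
            raise ValueError("recovery_time must be >= 0")
        if self.g2_duration < 0:
            raise ValueError("g2_duration must be >= 0")
        if self.dapi_cv < 0:
            raise ValueError("dapi_cv must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _edu_intensity(
    rng: np.random.Generator, positive: np.ndarray, params: tuple[float, float, float]
) -> np.ndarray:
    mu_pos, mu_neg, spread = params
    mu = np.where(positive, mu_pos, mu_neg)
    return np.exp(rng.normal(mu, spread))


def simulate_pulse_chase(
    params: PulseChaseParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired event tables at labeling (t0) and after recovery.

    Returns
    -------
    (events_t0, events_t):
        DataFrames with columns ``dapi_total``, ``edu_mean``, ``timepoint``,
        ``truth_phase``, ``truth_progress`` (NaN outside S at labeling) and
        ``truth_edu``.  The table at the recovery time point contains two
        daughter events for every labeled cell that completed S phase and
        passed through G2 within the recovery window.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    f_g1, f_s, f_g2 = params.phase_fractions
    phase = rng.choice(["G0/G1", "S", "G2/M"], size=n, p=[f_g1, f_s, f_g2])
    in_s = phase == "S"
    progress = np.full(n, np.nan)
    progress[in_s] = rng.uniform(0.0, 1.0, in_s.sum())

    content0 = np.where(
        phase == "G0/G1", 1.0, np.where(phase == "G2/M", 2.0, 1.0 + progress)
    )
    truth_edu0 = in_s.copy()

    events_t0 = pd.DataFrame(
        {
            "dapi_total": params.i_2n
            * content0
            * _lognormal_factor(rng, params.dapi_cv, n),
            "edu_mean": _edu_intensity(rng, truth_edu0, params.edu_signal_params),
            "timepoint": "t0",
            "truth_phase": phase,
            "truth_progress": progress,
            "truth_edu": truth_edu0,
        }
    )

    # --- recovery dynamics; only EdU-labeled (S at t0) cells evolve -------
    rate, t_rec, t_g2 = params.replication_rate, params.recovery_time, params.g2_duration
    u0 = progress[in_s]
    if rate > 0:
        t_complete = (1.0 - u0) / rate
    else:
        t_complete = np.full(u0.shape, np.inf)
    still_s = t_complete > t_rec
    divided = t_complete + t_g2 <= t_rec
    in_g2 = ~still_s & ~divided

    # advance labeled cells in place, preserving the t0 event order;
    # unlabeled cells are a static snapshot during recovery
    s_idx = np.flatnonzero(in_s)
    u_new = np.where(still_s, u0 + rate * t_rec, 1.0)

    content_t = content0.copy()
    phase_t = phase.astype(object).copy()
    progress_t = progress.copy()
    edu_t = truth_edu0.copy()

    content_t[s_idx[still_s]] = 1.0 + u_new[still_s]
    progress_t[s_idx[still_s]] = u_new[still_s]
    content_t[s_idx[in_g2]] = 2.0
    phase_t[s_idx[in_g2]] = "G2/M"
    progress_t[s_idx[in_g2]] = 1.0
    content_t[s_idx[divided]] = 1.0
    phase_t[s_idx[divided]] = "G0/G1"
    progress_t[s_idx[divided]] = 1.0

    repeats = np.ones(n, dtype=int)
    repeats[s_idx[divided]] = 2  # mitosis: two EdU-positive 2n daughters
    content_t = np.repeat(content_t, repeats)
    phase_t = np.repeat(phase_t, repeats)
    progress_t = np.repeat(progress_t, repeats)
    edu_t = np.repeat(edu_t, repeats)
    m = len(content_t)

    events_t = pd.DataFrame(
        {
            "dapi_total": params.i_2n
            * content_t
            * _lognormal_factor(rng, params.dapi_cv, m),
            "edu_mean": _edu_intensity(rng, edu_t, params.edu_signal_params),
            "timepoint": "t_recovery",
            "truth_phase": phase_t,
            "truth_progress": progress_t,
            "truth_edu": edu_t,
        }
    )
    return events_t0, events_t
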