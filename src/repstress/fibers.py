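"""Statistics for dual-label (IdU then CIdU) DNA fiber assays.

A fiber labeled with IdU only — no CIdU tract — marks a replication fork
that stalled during the first labeling window and never resumed.  The
module summarizes tract lengths, per-fiber CIdU/IdU length ratios over
elongating fibers, and stalled-fork fractions with Wilson confidence
intervals, and provides the standard group comparisons (Mann-Whitney on
lengths and ratios, Fisher's exact test on stalled-vs-elongated counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.proportion import proportion_confint

__all__ = ["FiberSummary", "FiberComparison", "summarize_fibers", "compare_fiber_groups"]


@dataclass(frozen=True)
class FiberSummary:
    """Summary of one fiber table."""

    n_fibers: int
    median_idu_length: float
    ratios: np.ndarray  # per-fiber cidu/idu over elongating fibers
    stalled_fraction: float
    stalled_ci: tuple[float, float]  # 95% Wilson interval
    n_stalled: int

    @property
    def median_ratio(self) -> float:
        return float(np.median(self.ratios)) if len(self.ratios) else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_fibers": self.n_fibers,
            "median_idu_length": self.median_idu_length,
            "median_ratio": None if np.isnan(self.median_ratio) else self.median_ratio,
            "n_ratios": int(len(self.ratios)),
            "stalled_fraction": self.stalled_fraction,
            "stalled_ci_low": self.stalled_ci[0],
            "stalled_ci_high": self.stalled_ci[1],
            "n_stalled": self.n_stalled,
        }


def _as_table(records: pd.DataFrame) -> pd.DataFrame:
    required = {"idu_length", "cidu_length"}
    if not required.issubset(records.columns):
        raise ValueError(f"fiber table needs columns {sorted(required)}")
    if (records["idu_length"] < 0).any() or (records["cidu_length"] < 0).any():
        raise ValueError("fiber lengths must be nonnegative")
    return records


def summarize_fibers(
    records: pd.DataFrame,
    *,
    stall_threshold: float = 0.0,
) -> FiberSummary:
    """Summarize a fiber table.

    A fiber is stalled when its CIdU length is at or below
    ``stall_threshold`` (default 0, the simulator's convention; raise it
    for digitized real data).  Ratios are computed per fiber, only where
    both tracts have positive length.
    """
    records = _as_table(records)
    if len(records) == 0:
        raise ValueError("empty fiber table")
    idu = records["idu_length"].to_numpy(dtype=float)
    cidu = records["cidu_length"].to_numpy(dtype=float)
    if (idu == 0).all():
        raise ValueError("all IdU lengths are zero")

    stalled = cidu <= stall_threshold
    elongating = (idu > 0) & (cidu > 0) & ~stalled
    ratios = cidu[elongating] / idu[elongating]
    n, k = len(records), int(stalled.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return FiberSummary(
        n_fibers=n,
        median_idu_length=float(np.median(idu)),
        ratios=ratios,
        stalled_fraction=k / n,
        stalled_ci=(float(lo), float(hi)),
        n_stalled=k,
    )


@dataclass(frozen=True)
class FiberComparison:
    """Two-sided test results between two fiber groups."""

    p_idu_length: float
    p_ratio: float | None  # None when a group has no elongating fibers
    p_stalled: float
    ratio_test_note: str | None

    def to_dict(self) -> dict:
        return {
            "p_idu_length": self.p_idu_length,
            "p_ratio": self.p_ratio,
            "p_stalled": self.p_stalled,
            "ratio_test_note": self.ratio_test_note,
        }


def compare_fiber_groups(
    a: pd.DataFrame,
    b: pd.DataFrame,
    *,
    stall_threshold: float = 0.0,
) -> FiberComparison:
    """Compare two fiber tables.

    Mann-Whitney (two-sided, exact for small groups) on IdU lengths and on
    CIdU/IdU ratios of elongating fibers; Fisher's exact test on the
    stalled-vs-elongated contingency table.  The ratio test is skipped with
    a notice when either group has no elongating fibers.
    """
    sa = summarize_fibers(a, stall_threshold=stall_threshold)
    sb = summarize_fibers(b, stall_threshold=stall_threshold)

    p_len = float(
        mannwhitneyu(
            a["idu_length"], b["idu_length"], alternative="two-sided"
        ).pvalue
    )
    if len(sa.ratios) and len(sb.ratios):
        p_ratio: float | None = float(
            mannwhitneyu(sa.ratios, sb.ratios, alternative="two-sided").pvalue
        )
        note = None
    else:
        p_ratio = None
        note = "ratio test skipped: a group has no elongating fibers"

    table = [
        [sa.n_stalled, sa.n_fibers - sa.n_stalled],
        [sb.n_stalled, sb.n_fibers - sb.n_stalled],
    ]
    p_stalled = float(fisher_exact(table, alternative="two-sided")[1])
    return FiberComparison(
        p_idu_length=p_len, p_ratio=p_ratio, p_stalled=p_stalled, ratio_test_note=note
    )
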