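"""Dose-response fitting and isobole-based drug-combination analysis.

Single-agent viability curves are fitted with a four-parameter logistic
(4PL) on log10 dose, reporting the relative (midpoint) IC50.  Synergy
between two drugs is quantified by the method of isoboles: the 50%-effect
isobole is the set of dose pairs (d1, d2) producing the midpoint effect,
and each fixed-dose combination series contributes a combination-index
point

    CI = d1 / D1 + d2 / D2

where D1, D2 are the single-agent IC50s and d1 is the IC50 of drug 1 in
the presence of the fixed dose d2 (and symmetrically).  CI < 1 indicates
synergy, CI = 1 Loewe additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = [
    "DoseResponseCurve",
    "CombinationResult",
    "FitError",
    "fit_4pl",
    "ic50_fold_change",
    "combination_index",
    "sensitizing_dose",
]


class FitError(RuntimeError):
    """A dose-response fit is flagged and cannot be used downstream."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted 4PL viability curve with its relative (midpoint) IC50.

    ``viability(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill)``.
    ``converged`` is False for flagged fits (non-monotone input or
    optimizer failure); flagged curves carry ``ic50 = nan``.
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    residual_scale: float
    converged: bool
    message: str | None = None

    def __post_init__(self) -> None:
        if self.converged:
            if not self.ic50 > 0:
                raise ValueError("ic50 must be positive")
            if not self.top > self.bottom:
                raise ValueError("top must exceed bottom")

    @property
    def midpoint_viability(self) -> float:
        return 0.5 * (self.top + self.bottom)

    def viability(self, dose: float | np.ndarray) -> float | np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            v = self.bottom + (self.top - self.bottom) / (
                1.0 + (dose / self.ic50) ** self.hill
            )
        return float(v) if v.ndim == 0 else v

    def inverse(self, viability: float) -> float:
        """Dose at a given absolute viability level (nan outside range)."""
        if not self.converged:
            raise FitError(self.message or "flagged fit has no dose scale")
        if not (self.bottom < viability < self.top):
            return float("nan")
        frac = (self.top - viability) / (viability - self.bottom)
        return float(self.ic50 * frac ** (1.0 / self.hill))


def _model(logd: np.ndarray, top: float, bottom: float, logic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logic50)))


def fit_4pl(
    doses: np.ndarray,
    responses: np.ndarray,
    *,
    monotonicity_alpha: float = 0.05,
) -> DoseResponseCurve:
    """Least-squares 4PL fit on log10 dose.

    Zero-dose wells anchor the top plateau conceptually but are excluded
    from the log-domain fit (the free ``top`` parameter absorbs them).
    A significantly increasing viability trend (one-sided Spearman test on
    per-dose means at ``monotonicity_alpha``) flags the fit: no IC50 is
    reported and ``converged`` is False.

    Requires at least 4 distinct doses; responses are viability fractions
    (typically in [0, 1.5]).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same shape")
    if (doses < 0).any():
        raise ValueError("doses must be nonnegative")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")

    nz = doses > 0
    d, r = doses[nz], responses[nz]
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 distinct nonzero doses")

    means = pd.Series(r).groupby(pd.Series(d)).mean()
    if len(means) >= 3:
        rho, _ = spearmanr(means.index.to_numpy(), means.to_numpy())
        if rho > 0:
            # one-sided exact-ish check via the two-sided p halved
            p_two = spearmanr(means.index.to_numpy(), means.to_numpy()).pvalue
            if p_two / 2.0 < monotonicity_alpha:
                return DoseResponseCurve(
                    top=float("nan"),
                    bottom=float("nan"),
                    ic50=float("nan"),
                    hill=float("nan"),
                    residual_scale=float("nan"),
                    converged=False,
                    message="viability increases with dose beyond noise tolerance",
                )

    logd = np.log10(d)
    r_lo, r_hi = float(r.min()), float(r.max())
    half = 0.5 * (r_lo + r_hi)
    p0 = (
        float(means.iloc[0]),
        float(means.iloc[-1]),
        float(logd[np.argmin(np.abs(r - half))]),
        1.0,
    )
    lower = (-0.5, -0.5, logd.min() - 3.0, 0.05)
    upper = (2.0, 2.0, logd.max() + 3.0, 20.0)
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        popt, _ = curve_fit(
            _model,
            logd,
            r,
            p0=p0,
            bounds=(lower, upper),
            maxfev=20000,
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        return DoseResponseCurve(
            top=float("nan"),
            bottom=float("nan"),
            ic50=float("nan"),
            hill=float("nan"),
            residual_scale=float("nan"),
            converged=False,
            message=f"optimizer failure: {exc}",
        )
    top, bottom, logic50, hill = popt
    if top <= bottom:
        return DoseResponseCurve(
            top=float(top),
            bottom=float(bottom),
            ic50=float("nan"),
            hill=float(hill),
            residual_scale=float("nan"),
            converged=False,
            message="degenerate fit: top <= bottom",
        )
    resid = r - _model(logd, *popt)
    return DoseResponseCurve(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0**logic50),
        hill=float(hill),
        residual_scale=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )


def ic50_fold_change(
    curve_without: DoseResponseCurve, curve_with: DoseResponseCurve
) -> float:
    """IC50 fold-enhancement by a sensitizing dose.

    ``fold = ic50(without sensitizer) / ic50(with sensitizer)``; a fold of
    7 means the sensitizer made the drug 7-fold more potent.
    """
    for side, c in (("without", curve_without), ("with", curve_with)):
        if not c.converged:
            raise FitError(f"curve ({side} sensitizer) is flagged: {c.message}")
    return float(curve_without.ic50 / curve_with.ic50)


def sensitizing_dose(
    curve: DoseResponseCurve,
    *,
    loss_range: tuple[float, float] = (0.20, 0.45),
) -> float:
    """Dose of a sensitizer causing a mid-range viability loss.

    Returns the dose at which the fitted curve predicts a viability loss at
    the midpoint of ``loss_range`` (default 20%-45% loss, i.e. viability
    0.675 of the untreated level), the screen-design band for a fixed
    sub-lethal co-treatment concentration.
    """
    target = curve.top * (1.0 - 0.5 * (loss_range[0] + loss_range[1]))
    d = curve.inverse(target)
    if np.isnan(d):
        raise FitError("target viability outside the fitted response range")
    return d


# ---------------------------------------------------------------------------
# combination index


@dataclass(frozen=True)
class CombinationResult:
    """Combination index with its per-point isobole terms."""

    ci: float
    points: list[dict] = field(default_factory=list)
    n_points: int = 0
    dispersion: float = float("nan")  # sd over isobole points
    boot_sd: float | None = None  # bootstrap-over-wells sd, if computed
    d1_ic50: float = float("nan")
    d2_ic50: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ci > 0:
            raise ValueError("combination index must be positive")

    def to_dict(self) -> dict:
        return {
            "ci": self.ci,
            "n_points": self.n_points,
            "dispersion": self.dispersion,
            "boot_sd": self.boot_sd,
            "d1_ic50": self.d1_ic50,
            "d2_ic50": self.d2_ic50,
            "points": self.points,
            "notes": self.notes,
        }


def _series_groups(plate: pd.DataFrame, fixed_col: str, varied_col: str) -> list[float]:
    """Fixed doses of ``fixed_col`` at which ``varied_col`` spans a series."""
    out = []
    for fixed_dose, grp in plate[plate[fixed_col] > 0].groupby(fixed_col):
        if len(np.unique(grp.loc[grp[varied_col] > 0, varied_col])) >= 4:
            out.append(float(fixed_dose))
    return sorted(out)


def _ci_points(
    plate: pd.DataFrame,
    single1: DoseResponseCurve,
    single2: DoseResponseCurve,
    notes: list[str],
) -> list[dict]:
    points: list[dict] = []
    for fixed_col, varied_col, own, other, drug in (
        ("dose_2", "dose_1", single1, single2, 1),
        ("dose_1", "dose_2", single2, single1, 2),
    ):
        level = own.midpoint_viability
        for fx in _series_groups(plate, fixed_col, varied_col):
            grp = plate[(plate[fixed_col] == fx) & (plate[varied_col] > 0)]
            shifted = fit_4pl(grp[varied_col].to_numpy(), grp["viability"].to_numpy())
            if not shifted.converged:
                notes.append(
                    f"drug-{drug} series at fixed {fixed_col}={fx:g} flagged: "
                    f"{shifted.message}"
                )
                continue
            d_shift = shifted.inverse(level)
            if np.isnan(d_shift):
                notes.append(
                    f"fixed {fixed_col}={fx:g} alone exceeds the 50% effect level; "
                    "point excluded"
                )
                continue
            term_varied = d_shift / own.ic50
            term_fixed = fx / other.ic50
            points.append(
                {
                    "varied_drug": drug,
                    "fixed_dose": fx,
                    "shifted_ic50": d_shift,
                    "term_varied": term_varied,
                    "term_fixed": term_fixed,
                    "ci_point": term_varied + term_fixed,
                }
            )
    return points


def combination_index(
    plate: pd.DataFrame,
    *,
    n_boot: int = 199,
    seed: int = 0,
) -> CombinationResult:
    """Combination index of a two-drug plate by the method of isoboles.

    The plate (columns ``dose_1``, ``dose_2``, ``replicate``,
    ``viability``) must contain single-agent dilution series for both
    drugs and at least two fixed-dose combination series in total.  For
    each fixed dose ``d2`` of drug 2 the drug-1 series is fitted and
    inverted at drug 1's own midpoint effect level to give the shifted
    IC50 ``d1``, contributing the isobole point ``d1/D1 + d2/D2``
    (symmetrically for fixed ``d1``).  CI is the mean over valid points;
    dispersion is their standard deviation, plus a seeded nonparametric
    bootstrap over wells when ``n_boot > 0``.

    Points whose fixed dose alone already exceeds the midpoint effect are
    excluded with a notice; fewer than 2 valid points is an error.
    """
    for col in ("dose_1", "dose_2", "viability"):
        if col not in plate.columns:
            raise ValueError(f"plate is missing column {col!r}")

    def fit_singles(df: pd.DataFrame) -> tuple[DoseResponseCurve, DoseResponseCurve]:
        s1 = df[(df["dose_2"] == 0) & (df["dose_1"] > 0)]
        s2 = df[(df["dose_1"] == 0) & (df["dose_2"] > 0)]
        if len(np.unique(s1["dose_1"])) < 4 or len(np.unique(s2["dose_2"])) < 4:
            raise ValueError("plate lacks single-agent series for both drugs")
        c1 = fit_4pl(s1["dose_1"].to_numpy(), s1["viability"].to_numpy())
        c2 = fit_4pl(s2["dose_2"].to_numpy(), s2["viability"].to_numpy())
        if not (c1.converged and c2.converged):
            raise FitError("single-agent fit flagged")
        return c1, c2

    notes: list[str] = []
    c1, c2 = fit_singles(plate)
    points = _ci_points(plate, c1, c2, notes)
    if len(points) < 2:
        raise ValueError(
            f"fewer than 2 valid isobole points ({len(points)}); notes: {notes}"
        )
    ci_values = np.array([p["ci_point"] for p in points])

    boot_sd = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        groups = [grp.index.to_numpy() for _, grp in plate.groupby(["dose_1", "dose_2"])]
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            resampled = plate.loc[idx]
            try:
                b1, b2 = fit_singles(resampled)
                bpoints = _ci_points(resampled, b1, b2, [])
            except (ValueError, FitError):
                continue
            if len(bpoints) >= 2:
                reps.append(np.mean([p["ci_point"] for p in bpoints]))
        if len(reps) >= 2:
            boot_sd = float(np.std(reps, ddof=1))

    return CombinationResult(
        ci=float(ci_values.mean()),
        points=points,
        n_points=len(points),
        dispersion=float(ci_values.std(ddof=1)),
        boot_sd=boot_sd,
        d1_ic50=c1.ic50,
        d2_ic50=c2.ic50,
        notes=notes,
    )
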