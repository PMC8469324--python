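"""Log-linear dose–response fitting and effective-dose inversion.

The effect model is a straight line on the log10 dose scale,

    effect% = intercept + slope · log10(dose),

fitted by ordinary least squares either to group means (one point per dose)
or to per-animal effects (all animals as points).  The effective dose at
level L (e.g. ED30) is the inverse prediction

    log10(ED_L) = (L − intercept) / slope,    ED_L = 10^log10(ED_L),

with uncertainty propagated by the delta method through the inverse
prediction and the antilog: the gradient of log10(ED) with respect to
(intercept, slope) is (−1/slope, −log10(ED)/slope), its quadratic form with
the coefficient covariance gives Var(log10 ED), the confidence interval is
a t-band on the log scale exponentiated (hence asymmetric on the dose
scale), and the reported SE is the dose-scale delta-method value
ln(10)·ED·SE(log10 ED).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datamodel import DoseEffectRow, ValidationError

LN10 = math.log(10.0)


class EstimationError(ValueError):
    """Raised when a fit or an effective dose cannot be estimated."""


class ExtrapolationWarning(UserWarning):
    """Effective dose falls outside the fitted dose range."""


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of effect (%) on log10(dose)."""

    slope: float
    intercept: float
    cov: np.ndarray  # 2x2, order (intercept, slope)
    residual_df: int
    r2: float
    n_points: int
    log10_dose_min: float
    log10_dose_max: float
    label: str = ""

    def predict(self, log10_dose) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_dose, dtype=float)

    def predict_se(self, log10_dose) -> np.ndarray:
        """SE of the predicted mean effect at the given log10 doses."""
        x = np.atleast_1d(np.asarray(log10_dose, dtype=float))
        X = np.column_stack([np.ones_like(x), x])
        var = np.einsum("ij,jk,ik->i", X, self.cov, X)
        return np.sqrt(var)


@dataclass(frozen=True)
class EDEstimate:
    """Inverse-predicted effective dose with delta-method uncertainty."""

    level: float
    dose: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    source_label: str = ""
    extrapolated: bool = False

    @property
    def var(self) -> float:
        return self.se**2


def _as_xy(rows) -> tuple[np.ndarray, np.ndarray]:
    """Accept DoseEffectRow lists or (dose, effect) pair sequences."""
    doses, effects = [], []
    for r in rows:
        if isinstance(r, DoseEffectRow):
            doses.append(r.dose)
            effects.append(r.effect_pct)
        else:
            d, e = r
            doses.append(float(d))
            effects.append(float(e))
    return np.asarray(doses, dtype=float), np.asarray(effects, dtype=float)


def fit_dose_response(rows: Iterable, label: str = "") -> LinearFit:
    """OLS of % antinociception on log10(dose).

    ``rows`` is either a list of :class:`DoseEffectRow` (group-mean mode) or
    a sequence of (dose, effect_pct) pairs (per-animal mode, one pair per
    animal; replicated doses are allowed and implicitly weight by n).
    """
    doses, effects = _as_xy(list(rows))
    if np.any(doses <= 0):
        raise ValidationError("all doses must be > 0")
    if np.unique(doses).size < 3:
        raise EstimationError(
            f"need >= 3 distinct doses, got {np.unique(doses).size}"
        )
    x = np.log10(doses)
    X = sm.add_constant(x)
    res = sm.OLS(effects, X).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        cov=np.asarray(res.cov_params()),
        residual_df=int(res.df_resid),
        r2=float(res.rsquared),
        n_points=len(effects),
        log10_dose_min=float(x.min()),
        log10_dose_max=float(x.max()),
        label=label,
    )


def ed_x(fit: LinearFit, level: float = 30.0, alpha: float = 0.05) -> EDEstimate:
    """Effective dose at ``level`` % antinociception from a fitted line.

    Warns (:class:`ExtrapolationWarning`) when the estimate lies outside the
    fitted dose range rather than failing: tested dose series often start
    above the ED30.
    """
    if not 0 < level < 100:
        raise ValueError(f"level must be in (0, 100), got {level}")
    if fit.slope <= 0:
        raise EstimationError(
            "slope must be positive: effect must increase with dose"
        )
    log_ed = (level - fit.intercept) / fit.slope
    ed = 10.0**log_ed
    grad = np.array([-1.0 / fit.slope, -log_ed / fit.slope])
    var_log = float(grad @ fit.cov @ grad)
    se_log = math.sqrt(max(var_log, 0.0))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.residual_df)
    ci_low = 10.0 ** (log_ed - tcrit * se_log)
    ci_high = 10.0 ** (log_ed + tcrit * se_log)
    se_dose = LN10 * ed * se_log
    extrapolated = not (fit.log10_dose_min <= log_ed <= fit.log10_dose_max)
    if extrapolated:
        warnings.warn(
            f"ED{level:g} = {ed:.4g} mg/kg lies outside the fitted dose range "
            f"[{10**fit.log10_dose_min:.4g}, {10**fit.log10_dose_max:.4g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return EDEstimate(
        level=level,
        dose=ed,
        se=se_dose,
        ci_low=ci_low,
        ci_high=ci_high,
        df=fit.residual_df,
        source_label=fit.label,
        extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class CurveComparison:
    """Pointwise potency comparison of two fitted curves."""

    log10_doses: tuple[float, ...]
    difference: tuple[float, ...]  # predicted A − predicted B, % points
    se: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    a_higher: tuple[bool, ...]  # significant and A above B
    verdict: str


def compare_curves(
    fit_a: LinearFit,
    fit_b: LinearFit,
    log10_doses: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> CurveComparison:
    """Compare predicted effects of two curves at shared log10 doses.

    Differences are tested with Bonferroni-adjusted two-sided t-tests
    (df = sum of residual dfs).  Defaults to five evenly spaced points over
    the overlap of the fitted ranges.
    """
    lo = max(fit_a.log10_dose_min, fit_b.log10_dose_min)
    hi = min(fit_a.log10_dose_max, fit_b.log10_dose_max)
    if hi <= lo:
        raise ValueError("fitted dose ranges do not overlap")
    if log10_doses is None:
        log10_doses = np.linspace(lo, hi, 5)
    x = np.asarray(log10_doses, dtype=float)
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("requested doses outside the shared fitted range")

    diff = fit_a.predict(x) - fit_b.predict(x)
    se = np.sqrt(fit_a.predict_se(x) ** 2 + fit_b.predict_se(x) ** 2)
    df = fit_a.residual_df + fit_b.residual_df
    m = x.size
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2 * stats.t.sf(np.abs(t), df)
    p_raw = np.where((se == 0) & (diff != 0), 0.0, p_raw)
    p_adj = np.minimum(1.0, m * p_raw)
    a_higher = (p_adj < alpha) & (diff > 0)
    if a_higher.all():
        verdict = f"{fit_a.label or 'A'} higher at all compared doses"
    elif ((p_adj < alpha) & (diff < 0)).all():
        verdict = f"{fit_b.label or 'B'} higher at all compared doses"
    elif (p_adj >= alpha).all():
        verdict = "no significant difference at any compared dose"
    else:
        verdict = "mixed: significance differs across doses"
    return CurveComparison(
        log10_doses=tuple(float(v) for v in x),
        difference=tuple(float(v) for v in diff),
        se=tuple(float(v) for v in se),
        p_adjusted=tuple(float(v) for v in p_adj),
        a_higher=tuple(bool(v) for v in a_higher),
        verdict=verdict,
    )
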