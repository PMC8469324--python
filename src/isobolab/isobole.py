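"""Fixed-ratio isobolographic analysis of a two-drug combination.

Under Loewe additivity, the combination dose expected to produce the target
effect when drug A contributes a fraction f of its own effective dose and
drug B the complementary fraction is

    Z_add = f · ED_A + (1 − f) · ED_B,     Var(Z_add) = f²·V_A + (1 − f)²·V_B.

The experiment administers the combination as a halving dilution series
whose top level is exactly (f·ED_A, (1−f)·ED_B) — so the top total equals
Z_add — and estimates the experimental effective dose ED_E from the
combination's own dose–response curve.  Synergy is judged two ways at once:
a Student's t-test of ED_T (= Z_add) against ED_E, and the interaction
index

    γ = ED_E / ED_T,

with γ < 1 and a significant test ⇒ synergistic, γ > 1 and significant ⇒
antagonistic, otherwise additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .dose_response import EDEstimate


@dataclass(frozen=True)
class FixedRatioDesign:
    """Halving dilution series of a fixed-ratio combination arm.

    ``levels`` are (dose_a, dose_b, total) triples in mg/kg, largest first;
    each level halves both components.
    """

    f: float
    ed_a: EDEstimate
    ed_b: EDEstimate
    levels: tuple[tuple[float, float, float], ...]

    @property
    def proportion_a(self) -> float:
        """Share of drug A in every total dose of the series."""
        da, db, tot = self.levels[0]
        return da / tot


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of the theoretical-vs-experimental effective-dose test."""

    ed_theoretical: EDEstimate
    ed_experimental: EDEstimate
    gamma: float
    gamma_se: float
    t_stat: float
    df: int
    p_value: float
    classification: str  # synergistic | additive | antagonistic


def build_fixed_ratio_design(
    ed_a: EDEstimate, ed_b: EDEstimate, f: float = 0.5, n_levels: int = 6
) -> FixedRatioDesign:
    """Construct the combination dose series from the component EDs.

    The top level carries f·ED_A of drug A and (1−f)·ED_B of drug B; each
    subsequent level halves both.  Totals are kept at full precision
    (display rounding happens only at report time).
    """
    if ed_a.dose <= 0 or ed_b.dose <= 0:
        raise ValueError("component effective doses must be > 0")
    if not 0 < f < 1:
        raise ValueError(f"f must be in (0, 1), got {f}")
    if n_levels < 2:
        raise ValueError("need at least 2 dose levels")
    da, db = f * ed_a.dose, (1 - f) * ed_b.dose
    levels = []
    for k in range(n_levels):
        scale = 0.5**k
        levels.append((da * scale, db * scale, (da + db) * scale))
    return FixedRatioDesign(f=f, ed_a=ed_a, ed_b=ed_b, levels=tuple(levels))


def additive_ed(ed_a: EDEstimate, ed_b: EDEstimate, f: float = 0.5) -> EDEstimate:
    """Theoretical additive effective dose Z_add of the f:(1−f) combination."""
    if ed_a.level != ed_b.level:
        raise ValueError(
            f"component EDs are at different effect levels "
            f"({ed_a.level} vs {ed_b.level})"
        )
    if not 0 < f <= 1:
        raise ValueError(f"f must be in (0, 1], got {f}")
    z = f * ed_a.dose + (1 - f) * ed_b.dose
    var = f**2 * ed_a.var + (1 - f) ** 2 * ed_b.var
    se = math.sqrt(var)
    df = ed_a.df + ed_b.df
    tcrit = stats.t.ppf(0.975, df)
    return EDEstimate(
        level=ed_a.level,
        dose=z,
        se=se,
        ci_low=z - tcrit * se,
        ci_high=z + tcrit * se,
        df=df,
        source_label="theoretical additive",
    )


def test_additivity(
    ed_t: EDEstimate, ed_e: EDEstimate, alpha: float = 0.05
) -> tuple[float, int, float]:
    """Student's t-test of the theoretical vs experimental effective dose.

    Returns (t statistic, df, two-sided p).  df is the sum of the two
    estimates' dfs; the SE of the difference pools both delta-method SEs.
    """
    if ed_t.se < 0 or ed_e.se < 0:
        raise ValueError("standard errors must be non-negative")
    pooled = math.sqrt(ed_t.se**2 + ed_e.se**2)
    if pooled == 0:
        raise ValueError("both standard errors are zero; no test possible")
    t = (ed_t.dose - ed_e.dose) / pooled
    df = ed_t.df + ed_e.df
    p = float(2 * stats.t.sf(abs(t), df))
    return t, df, p


def interaction_index(ed_e: EDEstimate, ed_t: EDEstimate) -> tuple[float, float]:
    """γ = ED_E / ED_T with first-order (delta) ratio SE."""
    if ed_t.dose <= 0:
        raise ValueError("theoretical ED must be > 0")
    gamma = ed_e.dose / ed_t.dose
    rel = (ed_e.se / ed_e.dose) ** 2 + (ed_t.se / ed_t.dose) ** 2
    return gamma, gamma * math.sqrt(rel)


def classify_interaction(gamma: float, p_value: float, alpha: float = 0.05) -> str:
    """Classify the interaction from γ and the additivity test.

    Departure from additivity is only declared when the t-test is
    significant; γ alone never classifies.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if p_value < alpha:
        if gamma < 1:
            return "synergistic"
        if gamma > 1:
            return "antagonistic"
    return "additive"


def analyze_interaction(
    ed_a: EDEstimate,
    ed_b: EDEstimate,
    ed_experimental: EDEstimate,
    f: float = 0.5,
    alpha: float = 0.05,
) -> InteractionResult:
    """Full fixed-ratio interaction analysis from three effective doses."""
    ed_t = additive_ed(ed_a, ed_b, f)
    t, df, p = test_additivity(ed_t, ed_experimental, alpha)
    gamma, gamma_se = interaction_index(ed_experimental, ed_t)
    return InteractionResult(
        ed_theoretical=ed_t,
        ed_experimental=ed_experimental,
        gamma=gamma,
        gamma_se=gamma_se,
        t_stat=t,
        df=df,
        p_value=p,
        classification=classify_interaction(gamma, p, alpha),
    )


def isobologram_coordinates(
    ed_a: EDEstimate,
    ed_b: EDEstimate,
    ed_t: EDEstimate,
    ed_e: EDEstimate,
    f: float = 0.5,
) -> list[dict]:
    """Plot-ready isobologram points in (dose_B, dose_A) axes.

    The additivity line joins (ED_B, 0) and (0, ED_A); the theoretical
    point sits at its f-weighted interior point; the experimental total is
    decomposed onto the fixed ray in the design's component ratio.  CI
    bounds are carried on the total-dose scale.
    """
    rho_a = f * ed_a.dose / (f * ed_a.dose + (1 - f) * ed_b.dose)
    return [
        {
            "role": "additivity_line_drug_a_axis",
            "dose_b_mg_kg": 0.0,
            "dose_a_mg_kg": ed_a.dose,
            "ci_low_total": ed_a.ci_low,
            "ci_high_total": ed_a.ci_high,
        },
        {
            "role": "additivity_line_drug_b_axis",
            "dose_b_mg_kg": ed_b.dose,
            "dose_a_mg_kg": 0.0,
            "ci_low_total": ed_b.ci_low,
            "ci_high_total": ed_b.ci_high,
        },
        {
            "role": "theoretical",
            "dose_b_mg_kg": (1 - f) * ed_b.dose,
            "dose_a_mg_kg": f * ed_a.dose,
            "ci_low_total": ed_t.ci_low,
            "ci_high_total": ed_t.ci_high,
        },
        {
            "role": "experimental",
            "dose_b_mg_kg": (1 - rho_a) * ed_e.dose,
            "dose_a_mg_kg": rho_a * ed_e.dose,
            "ci_low_total": ed_e.ci_low,
            "ci_high_total": ed_e.ci_high,
        },
    ]
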