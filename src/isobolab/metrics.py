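"""Reduction of flinch time courses to AUCs and % antinociception.

The behavioural endpoint is the area under the flinches-per-minute vs time
curve (trapezoidal rule), split into phase 1 (0–15 min, nociceptive) and
phase 2 (15–60 min, inflammatory).  Antinociception of a treated group is
expressed relative to the vehicle group's mean AUC:

    % antinociception = (AUC_vehicle − AUC_treated) / AUC_vehicle × 100

Phase percentages use phase-specific vehicle denominators, so a drug acting
only on the inflammatory phase scores 0% in phase 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import FlinchTimeCourse, RunConfig, TreatmentGroup


class ComputationError(ValueError):
    """Raised when a quantity is undefined for the given inputs."""


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal AUCs (flinch·min) of one time course, by phase."""

    phase1: float
    phase2: float
    overall: float


@dataclass(frozen=True)
class AntinociceptionSummary:
    """Per-group antinociception relative to vehicle.

    ``effects_overall`` keeps the per-animal overall percentages so that
    downstream ANOVA can operate on animal-level data; the group effect is
    their mean and ``se_overall`` their SEM.
    """

    group_label: str
    dose: float
    effect_phase1: float
    effect_phase2: float
    effect_overall: float
    se_overall: float
    n: int
    auc_vehicle_ref: float
    auc_mean: float
    effects_overall: tuple[float, ...] = ()


def trapezoid_auc(times, counts, window: tuple[float, float]) -> float:
    """Integrate the piecewise-linear flinch-rate curve over ``window``.

    Window endpoints falling between grid points are linearly interpolated,
    so adjacent windows sharing a boundary partition the full integral
    exactly.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError(f"window must satisfy t1 > t0, got [{t0}, {t1}]")
    if t.size < 2:
        raise ValueError("need at least 2 observations")
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] outside observed range [{t[0]}, {t[-1]}]"
        )
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    yy = np.interp(tt, t, y)
    return float(np.trapezoid(yy, tt))


def split_phase_aucs(
    tc: FlinchTimeCourse, boundary: float = 15.0, end: float = 60.0
) -> AUCResult:
    """Phase-1, phase-2 and overall AUC of one animal's time course.

    The boundary observation contributes to both windows, so
    phase1 + phase2 == overall exactly.
    """
    start = tc.times[0]
    end = min(end, tc.times[-1])
    p1 = trapezoid_auc(tc.times, tc.counts, (start, boundary))
    p2 = trapezoid_auc(tc.times, tc.counts, (boundary, end))
    return AUCResult(phase1=p1, phase2=p2, overall=p1 + p2)


def percent_antinociception(auc_vehicle_mean: float, auc_treated: float) -> float:
    """% antinociception of a treated AUC against the vehicle mean AUC.

    Negative values (AUC above vehicle, hyperalgesia) are returned as-is.
    """
    if auc_vehicle_mean <= 0:
        raise ComputationError(
            f"vehicle mean AUC must be > 0, got {auc_vehicle_mean}"
        )
    return (auc_vehicle_mean - auc_treated) / auc_vehicle_mean * 100.0


def summarize_group(
    group: TreatmentGroup,
    vehicle: TreatmentGroup,
    config: RunConfig = RunConfig(),
) -> AntinociceptionSummary:
    """Antinociception of ``group`` relative to ``vehicle``.

    Per-animal AUCs are converted to per-animal percentages against the
    vehicle *mean* AUC (phase-specific denominators), then averaged; the
    SEM of the per-animal overall percentages is reported.
    """
    if not vehicle.is_vehicle:
        raise ValueError(f"reference group {vehicle.label!r} is not flagged vehicle")
    b, e = config.phase_boundary, config.observation_end

    veh = [split_phase_aucs(tc, b, e) for tc in vehicle.members]
    ref1 = float(np.mean([a.phase1 for a in veh]))
    ref2 = float(np.mean([a.phase2 for a in veh]))
    ref = float(np.mean([a.overall for a in veh]))

    trt = [split_phase_aucs(tc, b, e) for tc in group.members]
    eff1 = [percent_antinociception(ref1, a.phase1) for a in trt]
    eff2 = [percent_antinociception(ref2, a.phase2) for a in trt]
    eff = [percent_antinociception(ref, a.overall) for a in trt]

    n = group.n
    sem = float(np.std(eff, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return AntinociceptionSummary(
        group_label=group.label,
        dose=group.total_dose,
        effect_phase1=float(np.mean(eff1)),
        effect_phase2=float(np.mean(eff2)),
        effect_overall=float(np.mean(eff)),
        se_overall=sem,
        n=n,
        auc_vehicle_ref=ref,
        auc_mean=float(np.mean([a.overall for a in trt])),
        effects_overall=tuple(eff),
    )


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    comparisons: tuple[tuple[str, float, float], ...]
    """(group label, raw p, Bonferroni-adjusted p) for each group vs control."""


def anova_bonferroni(
    summaries: list[AntinociceptionSummary], control_label: str
) -> AnovaResult:
    """One-way ANOVA on per-animal effects + Bonferroni vs-control t-tests.

    Pairwise comparisons use the pooled within-group variance (classical
    post-hoc t); adjusted p = min(1, m·p_raw) with m = number of
    comparisons against the control.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    by_label = {s.group_label: s for s in summaries}
    if control_label not in by_label:
        raise ValueError(f"control group {control_label!r} not among summaries")
    groups = [np.asarray(s.effects_overall, dtype=float) for s in summaries]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2 animals for ANOVA")

    f_stat, p_value = stats.f_oneway(*groups)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df_w = n_total - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    if ms_within == 0.0:
        means = [g.mean() for g in groups]
        if max(means) == min(means):
            # all observations identical: no signal
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value = np.inf, 0.0

    control = by_label[control_label]
    others = [s for s in summaries if s.group_label != control_label]
    m = len(others)
    comps = []
    c = np.asarray(control.effects_overall, dtype=float)
    for s in others:
        g = np.asarray(s.effects_overall, dtype=float)
        se = np.sqrt(ms_within * (1 / g.size + 1 / c.size))
        if se == 0.0:
            p_raw = 1.0 if g.mean() == c.mean() else 0.0
        else:
            t = (g.mean() - c.mean()) / se
            p_raw = float(2 * stats.t.sf(abs(t), df_w))
        comps.append((s.group_label, p_raw, min(1.0, m * p_raw)))
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        df_between=k - 1,
        df_within=df_w,
        comparisons=tuple(comps),
    )
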