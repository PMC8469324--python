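"""End-to-end orchestration: summaries → fits → isobole → report.

Two entry points cover the two kinds of available input:

- :func:`analyze_tables` (table mode): three group-level dose–effect tables
  (drug A, drug B, combination), e.g. the published group means.
- :func:`analyze_timecourses` (time-course mode): raw per-animal flinch
  time courses including a vehicle arm, reduced to per-animal % effects
  first.

Both converge on the same fixed-ratio analysis: OLS fits on log10(dose),
inverse prediction at the target level, theoretical additive ED, Student's
t-test, interaction index and classification.
"""

from __future__ import annotations

import logging

from .datamodel import DoseEffectRow, RunConfig, TreatmentGroup
from .dose_response import ed_x, fit_dose_response
from .isobole import (
    analyze_interaction,
    build_fixed_ratio_design,
    isobologram_coordinates,
)
from .metrics import summarize_group

log = logging.getLogger("isobolab")


def _interaction_bundle(rows_a, rows_b, rows_combo, config: RunConfig) -> dict:
    fit_a = fit_dose_response(rows_a, label="drug A")
    fit_b = fit_dose_response(rows_b, label="drug B")
    fit_combo = fit_dose_response(rows_combo, label="combination")

    level, alpha, f = config.effect_level, config.alpha, config.proportion_f
    ed_a = ed_x(fit_a, level, alpha)
    ed_b = ed_x(fit_b, level, alpha)
    ed_e = ed_x(fit_combo, level, alpha)

    design = build_fixed_ratio_design(ed_a, ed_b, f)
    interaction = analyze_interaction(ed_a, ed_b, ed_e, f, alpha)

    for name, ed in (("drug A", ed_a), ("drug B", ed_b), ("experimental", ed_e)):
        log.info("ED%g %s = %.4g ± %.4g mg/kg", level, name, ed.dose, ed.se)
    log.info(
        "ED%gT = %.4g ± %.4g, gamma = %.4g ± %.4g, t = %.3f (df %d, p = %.4g) -> %s",
        level,
        interaction.ed_theoretical.dose,
        interaction.ed_theoretical.se,
        interaction.gamma,
        interaction.gamma_se,
        interaction.t_stat,
        interaction.df,
        interaction.p_value,
        interaction.classification,
    )
    return {
        "config": config,
        "fits": {"drug_a": fit_a, "drug_b": fit_b, "combination": fit_combo},
        "ed_a": ed_a,
        "ed_b": ed_b,
        "design": design,
        "interaction": interaction,
        "isobologram": isobologram_coordinates(
            ed_a, ed_b, interaction.ed_theoretical, interaction.ed_experimental, f
        ),
    }


def analyze_tables(
    rows_a: list[DoseEffectRow],
    rows_b: list[DoseEffectRow],
    rows_combo: list[DoseEffectRow],
    config: RunConfig = RunConfig(),
) -> dict:
    """Fixed-ratio interaction analysis from three dose–effect tables."""
    for name, rows in (("drug A", rows_a), ("drug B", rows_b), ("combination", rows_combo)):
        if not rows:
            raise ValueError(f"missing dose–effect table for the {name} arm")
    return _interaction_bundle(rows_a, rows_b, rows_combo, config)


def split_arms(
    groups: list[TreatmentGroup],
) -> tuple[TreatmentGroup, list, list, list]:
    """Partition study groups into (vehicle, drug-A, drug-B, combination) arms."""
    vehicles = [g for g in groups if g.is_vehicle]
    if len(vehicles) != 1:
        raise ValueError(f"expected exactly one vehicle group, found {len(vehicles)}")
    vehicle = vehicles[0]
    rest = [g for g in groups if not g.is_vehicle]
    arm_a = [g for g in rest if g.dose_a > 0 and g.dose_b == 0]
    arm_b = [g for g in rest if g.dose_b > 0 and g.dose_a == 0]
    combo = [g for g in rest if g.dose_a > 0 and g.dose_b > 0]
    return vehicle, arm_a, arm_b, combo


def analyze_timecourses(
    groups: list[TreatmentGroup], config: RunConfig = RunConfig()
) -> dict:
    """Full analysis from raw flinch time courses.

    Per-animal % effects are computed against the vehicle mean AUC, and the
    dose–response lines are fitted in per-animal mode (every animal one
    point).
    """
    vehicle, arm_a, arm_b, combo = split_arms(groups)
    for name, arm in (("drug A", arm_a), ("drug B", arm_b), ("combination", combo)):
        if not arm:
            raise ValueError(f"missing {name} arm in the study")

    summaries = {}
    per_animal = {}
    for key, arm in (("drug_a", arm_a), ("drug_b", arm_b), ("combination", combo)):
        arm_summaries = [summarize_group(g, vehicle, config) for g in arm]
        summaries[key] = arm_summaries
        per_animal[key] = [
            (s.dose, eff) for s in arm_summaries for eff in s.effects_overall
        ]

    bundle = _interaction_bundle(
        per_animal["drug_a"], per_animal["drug_b"], per_animal["combination"], config
    )
    bundle["summaries"] = [s for arm in summaries.values() for s in arm]
    return bundle
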