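"""Synthetic formalin-test studies with known ground truth.

The generator emulates the structure of a rat formalin experiment: a
biphasic vehicle flinch intensity (an early exponential nociceptive spike
plus a broad Gaussian inflammatory bump),

    λ(t) = a1·exp(−t/τ1) + a2·exp(−(t − μ2)² / (2σ2²)),

dose-dependent multiplicative suppression whose single-drug margins are
linear in log10(dose) on the % scale, a fixed-ratio combination following
Loewe additivity modulated by a potency factor ψ (ψ = 1 additive, ψ < 1
synergistic: the summed dose fractions need only reach ψ), and Poisson
observation noise on each 1-min flinch count.

Default single-drug lines are refits of published group-mean formalin-test
curves for acetylsalicylic acid (drug A) and pomegranate peel extract
(drug B), so default simulations live in a realistic dose regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FlinchTimeCourse, TreatmentGroup

DEFAULT_GRID = tuple(range(0, 61, 5))

_EFFECT_CAP = 0.99  # suppression never reaches 100%: counts stay Poisson


class SimulationError(RuntimeError):
    """Raised when the ground-truth model cannot be evaluated."""


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a synthetic formalin study.

    a1, tau1
        Phase-1 peak (flinches/min) and exponential decay time (min).
    a2, mu2, sigma2
        Phase-2 peak (flinches/min), peak time and width (min).
    slope_*, intercept_*
        Single-drug suppression lines, % antinociception per log10(mg/kg).
    psi
        Loewe potency factor; 1 = additive, <1 = synergistic.
    """

    a1: float = 6.0
    tau1: float = 4.0
    a2: float = 4.0
    mu2: float = 35.0
    sigma2: float = 12.0
    slope_a: float = 22.79
    intercept_a: float = 9.70
    slope_b: float = 35.26
    intercept_b: float = -31.85
    psi: float = 1.0
    n_per_group: int = 6
    grid: tuple[float, ...] = DEFAULT_GRID
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("intensity amplitudes must be >= 0")
        if self.tau1 <= 0 or self.sigma2 <= 0:
            raise ValueError("intensity time scales must be > 0")
        if self.psi <= 0:
            raise ValueError("psi must be > 0")
        if self.slope_a <= 0 or self.slope_b <= 0:
            raise ValueError("suppression slopes must be > 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def vehicle_intensity(t, params: SimulationParams) -> np.ndarray | float:
    """Expected vehicle flinch rate λ(t), flinches/min, on [0, 60]."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or np.any(arr > 60):
        raise ValueError("t must lie within the 0–60 min observation window")
    lam = params.a1 * np.exp(-arr / params.tau1) + params.a2 * np.exp(
        -((arr - params.mu2) ** 2) / (2 * params.sigma2**2)
    )
    return float(lam) if np.isscalar(t) else lam


def _single_drug_effect(dose: float, slope: float, intercept: float) -> float:
    if dose <= 0:
        return 0.0
    pct = intercept + slope * math.log10(dose)
    return min(max(pct, 0.0), 100 * _EFFECT_CAP) / 100.0


def _equieffective_dose(effect: float, slope: float, intercept: float) -> float:
    """Single-drug dose whose line reaches ``effect`` (fraction)."""
    return 10.0 ** ((100.0 * effect - intercept) / slope)


def effect_fraction(dose_a: float, dose_b: float, params: SimulationParams) -> float:
    """True suppression fraction in [0, 0.99) at the given dose pair.

    Single drugs follow their clamped log-linear lines.  For a combination
    the Loewe additive-equivalent effect E* solves

        dose_a / D_A(E*) + dose_b / D_B(E*) = ψ,

    where D_X(E) is drug X's equieffective dose; E* is found by bisection
    (the left side is strictly decreasing in E).
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_b == 0:
        return _single_drug_effect(dose_a, params.slope_a, params.intercept_a)
    if dose_a == 0:
        return _single_drug_effect(dose_b, params.slope_b, params.intercept_b)

    def excess(e: float) -> float:
        da = _equieffective_dose(e, params.slope_a, params.intercept_a)
        db = _equieffective_dose(e, params.slope_b, params.intercept_b)
        return dose_a / da + dose_b / db - params.psi

    lo, hi = 1e-9, _EFFECT_CAP
    if excess(lo) <= 0:
        return 0.0  # doses too small to register any effect
    if excess(hi) >= 0:
        return _EFFECT_CAP
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            return 0.5 * (lo + hi)
    raise SimulationError("bisection for the Loewe effect did not converge")


def simulate_study(
    params: SimulationParams,
    dose_groups: list[tuple[str, float, float]],
    rng: np.random.Generator | None = None,
) -> list[TreatmentGroup]:
    """Draw one full study: Poisson counts for every group and animal.

    ``dose_groups`` is a list of (label, dose_a, dose_b); exactly one entry
    must be the vehicle (0, 0), which is flagged ``is_vehicle``.  Counts at
    grid time t are Poisson with mean λ(t)·(1 − E(dose_a, dose_b)).
    """
    vehicle_labels = [lab for lab, da, db in dose_groups if da == 0 and db == 0]
    if len(vehicle_labels) != 1:
        raise ValueError("dose_groups must contain exactly one (0, 0) vehicle arm")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    grid = np.asarray(params.grid, dtype=float)
    lam = vehicle_intensity(grid, params)
    groups = []
    for label, da, db in dose_groups:
        mean = lam * (1.0 - effect_fraction(da, db, params))
        counts = rng.poisson(mean, size=(params.n_per_group, grid.size))
        members = [
            FlinchTimeCourse(
                animal_id=f"{label}-{i + 1:02d}",
                group_label=label,
                dose_a=da,
                dose_b=db,
                times=tuple(grid),
                counts=tuple(int(c) for c in counts[i]),
            )
            for i in range(params.n_per_group)
        ]
        groups.append(
            TreatmentGroup(
                label=label,
                members=tuple(members),
                is_vehicle=(da == 0 and db == 0),
            )
        )
    return groups


def standard_study_design(
    params: SimulationParams,
    f: float = 0.5,
    level: float = 30.0,
    effect_targets: tuple[float, ...] = (10.0, 22.0, 34.0, 46.0, 58.0, 70.0),
    max_combo_levels: int = 6,
) -> list[tuple[str, float, float]]:
    """Default study design: vehicle, two single-drug series, combination.

    Single-drug doses are placed at equi-effect targets spanning the linear
    range of each suppression line, bracketing the ED.  The combination arm
    is the fixed-ratio halving series topping at the additive dose
    (f·ED_A, (1−f)·ED_B); dilution stops once the expected effect floors at
    zero, keeping one zero-effect level as a no-effect anchor — further
    floored levels carry no dose–response information and only flatten the
    fitted line.
    """
    ed_a = ground_truth_ed(params, "A", level)
    ed_b = ground_truth_ed(params, "B", level)
    groups: list[tuple[str, float, float]] = [("vehicle", 0.0, 0.0)]
    for i, tgt in enumerate(effect_targets):
        groups.append(
            (f"A-{i + 1}",
             _equieffective_dose(tgt / 100, params.slope_a, params.intercept_a),
             0.0)
        )
        groups.append(
            (f"B-{i + 1}",
             0.0,
             _equieffective_dose(tgt / 100, params.slope_b, params.intercept_b))
        )
    da, db = f * ed_a, (1 - f) * ed_b
    for i in range(max_combo_levels):
        s = 0.5**i
        groups.append((f"combo-{i + 1}", da * s, db * s))
        if effect_fraction(da * s, db * s, params) == 0.0:
            break  # one floored level retained as the no-effect anchor
    return groups


def ground_truth_ed(
    params: SimulationParams,
    drug: str,
    level: float = 30.0,
    f: float = 0.5,
) -> float:
    """True dose (mg/kg) at which the generating model reaches ``level`` %.

    ``drug`` is "A", "B" or "combination".  Single drugs invert the line in
    closed form; the combination bisects on total dose along the fixed ray
    whose top-level composition is (f·ED_A, (1−f)·ED_B).
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    target = level / 100.0
    if drug == "A":
        return _equieffective_dose(target, params.slope_a, params.intercept_a)
    if drug == "B":
        return _equieffective_dose(target, params.slope_b, params.intercept_b)
    if drug != "combination":
        raise ValueError(f"drug must be 'A', 'B' or 'combination', got {drug!r}")

    ed_a = _equieffective_dose(target, params.slope_a, params.intercept_a)
    ed_b = _equieffective_dose(target, params.slope_b, params.intercept_b)
    rho_a = f * ed_a / (f * ed_a + (1 - f) * ed_b)

    def eff(total: float) -> float:
        return effect_fraction(total * rho_a, total * (1 - rho_a), params)

    lo, hi = 1e-12, 1.0
    while eff(hi) < target:
        hi *= 2
        if hi > 1e12:
            raise SimulationError(f"no total dose reaches {level}% in-model")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if eff(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
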