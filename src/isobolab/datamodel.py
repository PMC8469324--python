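"""Domain types for formalin-test time courses and dose–effect tables.

The formalin test records, for each animal, the number of paw flinches in a
1-min observation window every 5 min for one hour.  Times are the start
minutes of each window (0, 5, ..., 60); counts are treated as flinches/min
rates at those times when integrating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class FlinchTimeCourse:
    """One animal's flinch counts over the observation grid.

    Parameters
    ----------
    animal_id : str
        Opaque identifier, unique within its treatment group.
    group_label : str
        Label of the treatment group the animal belongs to.
    dose_a, dose_b : float
        Dose of each combination component, mg/kg (0 for vehicle or
        single-drug arms).
    times : tuple of float
        Observation minutes, strictly increasing, within [0, 60].
    counts : tuple of int
        Flinches in the 1-min window starting at each time.
    """

    animal_id: str
    group_label: str
    dose_a: float
    dose_b: float
    times: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.dose_a < 0 or self.dose_b < 0:
            raise ValidationError("doses must be non-negative")
        if len(self.times) != len(self.counts):
            raise ValidationError("times and counts must have equal length")
        if len(self.times) < 2:
            raise ValidationError("a time course needs at least 2 observations")
        if any(t1 >= t2 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValidationError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > 60:
            raise ValidationError("times must lie within [0, 60] min")
        if any(c < 0 for c in self.counts):
            raise ValidationError("flinch counts must be non-negative")

    @property
    def total_dose(self) -> float:
        return self.dose_a + self.dose_b


@dataclass(frozen=True)
class TreatmentGroup:
    """A set of animals sharing one treatment (doses of A and B)."""

    label: str
    members: tuple[FlinchTimeCourse, ...]
    is_vehicle: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValidationError(f"group {self.label!r} has no animals")
        ref = self.members[0]
        for m in self.members[1:]:
            if m.dose_a != ref.dose_a or m.dose_b != ref.dose_b:
                raise ValidationError(
                    f"group {self.label!r}: members have inconsistent doses"
                )

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def dose_a(self) -> float:
        return self.members[0].dose_a

    @property
    def dose_b(self) -> float:
        return self.members[0].dose_b

    @property
    def total_dose(self) -> float:
        return self.dose_a + self.dose_b


@dataclass(frozen=True)
class DoseEffectRow:
    """One dose level of a group-level dose–effect table.

    ``effect_pct`` is % antinociception (may be negative: hyperalgesia).
    ``log10_dose`` is derived from ``dose`` when not supplied.
    """

    dose: float
    effect_pct: float
    log10_dose: float | None = None
    se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValidationError(f"dose must be > 0, got {self.dose}")
        if self.log10_dose is None:
            object.__setattr__(self, "log10_dose", math.log10(self.dose))
        elif abs(self.log10_dose - math.log10(self.dose)) > 1e-9:
            raise ValidationError(
                f"log10_dose {self.log10_dose} inconsistent with dose {self.dose}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration.

    effect_level
        Target % antinociception for the effective dose (30 -> ED30).
    proportion_f
        Fraction of drug A in the fixed-ratio combination design.
    alpha
        Two-sided significance level for all tests.
    phase_boundary, observation_end
        Phase-1/phase-2 split and end of observation, minutes.
    """

    effect_level: float = 30.0
    proportion_f: float = 0.5
    alpha: float = 0.05
    phase_boundary: float = 15.0
    observation_end: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.effect_level < 100:
            raise ValidationError("effect_level must be in (0, 100)")
        if not 0 <= self.proportion_f <= 1:
            raise ValidationError("proportion_f must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.phase_boundary < self.observation_end:
            raise ValidationError("phase_boundary must lie inside the observation window")
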