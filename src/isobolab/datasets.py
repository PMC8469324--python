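"""Published group-mean antinociception tables used in table mode.

These are the group-level dose–effect tables (n = 6 rats per group,
intragastric dosing, 2% formalin) from a published study of acetylsalicylic
acid (ASA, drug A), pomegranate peel extract (PoPEx, drug B) and their 1:1
fixed-ratio combination.  Raw per-animal flinch data were never deposited,
so these group means are the finest-grained real inputs available; the
table-mode pipeline reproduces the study's isobolographic conclusion from
them alone.

Each tuple row is (dose mg/kg, phase-1 %, phase-2 %, overall %).
"""

from __future__ import annotations

from .datamodel import DoseEffectRow

ASA_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (3.16, 3.42, 10.71, 14.78),
    (10.00, 4.47, 33.94, 38.77),
    (31.62, 4.99, 41.73, 46.85),
    (100.00, 6.47, 49.60, 56.02),
    (316.22, 7.26, 55.04, 62.43),
    (562.34, 9.94, 62.55, 72.94),
)

POPEX_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (10.00, 1.62, 3.23, 4.83),
    (31.62, 6.01, 19.92, 25.99),
    (100.00, 6.99, 22.09, 28.69),
    (316.22, 7.22, 50.23, 57.81),
    (562.34, 7.32, 55.58, 60.92),
    (1000.00, 7.03, 72.80, 80.22),
)

COMBINATION_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (34.00, 25.52, 36.31, 62.80),
    (17.00, 10.93, 39.21, 50.60),
    (8.51, 12.99, 35.09, 48.70),
    (4.27, 10.35, 33.17, 43.51),
    (2.12, 8.96, 24.47, 33.48),
    (1.06, 7.83, 22.57, 30.41),
)

#: Printed halving dose series of the combination arm:
#: (dose ASA, dose PoPEx, total) mg/kg, as displayed to 2 decimals.
COMBINATION_DESIGN_TABLE: tuple[tuple[float, float, float], ...] = (
    (4.00, 30.00, 34.00),
    (2.00, 15.00, 17.00),
    (1.00, 7.50, 8.51),
    (0.50, 3.75, 4.25),
    (0.25, 1.87, 2.12),
    (0.12, 0.93, 1.06),
)

GROUP_N = 6  # animals per treatment group in the source study


def _rows(table, column: str) -> list[DoseEffectRow]:
    idx = {"phase1": 1, "phase2": 2, "overall": 3}[column]
    return [
        DoseEffectRow(dose=r[0], effect_pct=r[idx], n=GROUP_N)
        for r in sorted(table)
    ]


def asa_rows(column: str = "overall") -> list[DoseEffectRow]:
    """ASA dose–effect rows (drug A); ``column`` in {phase1, phase2, overall}."""
    return _rows(ASA_TABLE, column)


def popex_rows(column: str = "overall") -> list[DoseEffectRow]:
    """PoPEx dose–effect rows (drug B)."""
    return _rows(POPEX_TABLE, column)


def combination_rows(column: str = "overall") -> list[DoseEffectRow]:
    """1:1 fixed-ratio combination dose–effect rows (total dose)."""
    return _rows(COMBINATION_TABLE, column)
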