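import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isobolab as il
from isobolab import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GRID = tuple(range(0, 61, 5))


def make_timecourse(counts, animal="a1", group="g", dose_a=0.0, dose_b=0.0, times=GRID):
    return il.FlinchTimeCourse(
        animal_id=animal,
        group_label=group,
        dose_a=dose_a,
        dose_b=dose_b,
        times=times,
        counts=counts,
    )


def make_group(count_rows, label="g", dose_a=0.0, dose_b=0.0, is_vehicle=False):
    members = [
        make_timecourse(row, animal=f"{label}-{i}", group=label,
                        dose_a=dose_a, dose_b=dose_b)
        for i, row in enumerate(count_rows)
    ]
    return il.TreatmentGroup(label=label, members=tuple(members), is_vehicle=is_vehicle)


@pytest.fixture(scope="session")
def asa_rows():
    return datasets.asa_rows()


@pytest.fixture(scope="session")
def popex_rows():
    return datasets.popex_rows()


@pytest.fixture(scope="session")
def combo_rows():
    return datasets.combination_rows()


@pytest.fixture(scope="session")
def table_mode_results(asa_rows, popex_rows, combo_rows):
    """Table-mode analysis of the published group means (shared, read-only)."""
    return il.analyze_tables(asa_rows, popex_rows, combo_rows, il.RunConfig())


@pytest.fixture
def vehicle_group():
    rng = np.random.default_rng(7)
    params = il.SimulationParams(seed=7)
    lam = il.vehicle_intensity(np.asarray(GRID, float), params)
    rows = [tuple(int(c) for c in rng.poisson(lam)) for _ in range(6)]
    return make_group(rows, label="vehicle", is_vehicle=True)
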