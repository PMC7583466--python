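import numpy as np
import pandas as pd
import pytest

from avipref.simulate import GeneratorConfig, generate_dataset


@pytest.fixture
def routes2():
    return pd.DataFrame(
        {
            "route_id": ["r1", "r2"],
            "length_km": [2.0, 2.49],
            "income_class": ["low", "high"],
            "median_income": [40_000, 90_000],
        }
    )


@pytest.fixture
def tiny_inventory(routes2):
    """Two species, equal counts; basal-area totals 3 vs 1 m^2."""
    dbh_a = 200.0 / np.sqrt(np.pi) * np.sqrt(1.5)  # 1.5 m^2 each
    dbh_b = 200.0 / np.sqrt(np.pi) * np.sqrt(0.5)  # 0.5 m^2 each
    return pd.DataFrame(
        {
            "route_id": ["r1", "r2", "r1", "r2"],
            "species": ["A", "A", "B", "B"],
            "origin": ["native", "native", "nonnative", "nonnative"],
            "dbh_cm": [dbh_a, dbh_a, dbh_b, dbh_b],
            "position_m": [10.0, 20.0, 500.0, 700.0],
        }
    )


def make_detection(
    route_id="r1",
    visit_id=1,
    bird_species="Yellow-rumped Warbler",
    group="migratory",
    trees=("Chinese elm",),
    flock_size=1,
    flock_members=None,
    sex_distinct=False,
    position_m=0.0,
):
    return {
        "route_id": route_id,
        "visit_id": visit_id,
        "bird_species": bird_species,
        "group": group,
        "trees": list(trees),
        "flock_size": flock_size,
        "flock_members": list(flock_members) if flock_members else [bird_species],
        "sex_distinct": sex_distinct,
        "position_m": position_m,
        "substrate": "leaf",
        "duration_s": 60.0,
    }


@pytest.fixture
def detections_frame():
    def build(rows):
        return pd.DataFrame([make_detection(**r) for r in rows])

    return build


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic survey shared across tests."""
    return generate_dataset(GeneratorConfig(), seed=20260926)
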