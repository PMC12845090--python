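import numpy as np
import pandas as pd
import pytest

from wdindex.schema import CoefficientTable, Component, ComponentSchema, ReferenceStats


@pytest.fixture
def mixed_schema():
    """Small schema exercising all three aggregation kinds."""
    return ComponentSchema(
        [
            Component("sugar", "sugar", "g/day"),
            Component("fruit", "fruit", "g/day", "group_same_unit", ("apple", "orange")),
            Component(
                "micros", "micros", "z-units", "group_mixed_unit", ("vit_c", "zinc")
            ),
            Component("red_meat", "red meat", "g/day", food_group_18="red meat"),
        ]
    )


@pytest.fixture
def mixed_intakes():
    """5-subject intake matrix for the mixed schema (hand-pickable numbers)."""
    rng = np.random.default_rng(42)
    idx = pd.Index([f"s{i}" for i in range(1, 6)], name="subject_id")
    return pd.DataFrame(
        {
            "sugar": [10.0, 20.0, 30.0, 25.0, 15.0],
            "apple": [50.0, 80.0, 20.0, 60.0, 40.0],
            "orange": [30.0, 10.0, 70.0, 20.0, 90.0],
            "vit_c": [60.0, 90.0, 120.0, 75.0, 100.0],
            "zinc": [8.0, 12.0, 6.0, 10.0, 9.0],
            "red_meat": [100.0, 40.0, 150.0, 60.0, 20.0],
        },
        index=idx,
    )


@pytest.fixture
def mixed_coefficients():
    return CoefficientTable(
        pd.Series({"sugar": -0.8, "fruit": 0.9, "micros": 0.5, "red_meat": -0.6})
    ).centralize()


@pytest.fixture
def mixed_global_ref():
    """Synthetic 'global' statistics covering every reference id of mixed_schema."""
    mean = pd.Series(
        {"sugar": 25.0, "fruit": 100.0, "vit_c": 80.0, "zinc": 10.0, "red_meat": 70.0}
    )
    sd = pd.Series(
        {"sugar": 10.0, "fruit": 40.0, "vit_c": 25.0, "zinc": 3.0, "red_meat": 50.0}
    )
    return ReferenceStats(mean=mean, sd=sd, source="global")


def schema_as_dicts(schema):
    """Plain-dict view of a schema for the loop oracles."""
    return [
        {
            "component_id": c.component_id,
            "aggregation": c.aggregation,
            "members": list(c.members),
        }
        for c in schema
    ]
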