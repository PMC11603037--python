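import numpy as np
import pandas as pd
import pytest

from trapod.data import FeatureSpec


@pytest.fixture
def toy_specs():
    return [
        FeatureSpec("bp", domain="vital_signs", valid_range=(0, 300),
                    missing_indicator=True),
        FeatureSpec("hr", domain="vital_signs", missing_indicator=True),
        FeatureSpec("propofol", domain="inputs", valid_range=(0, 1000),
                    cumulative=True),
        FeatureSpec("nibp_map", domain="vital_signs"),
        FeatureSpec("ibp_map", domain="vital_signs"),
        FeatureSpec("map_combined", domain="vital_signs",
                    composite_of=("nibp_map", "ibp_map")),
        FeatureSpec("age", domain="demographics", time_variance="static"),
    ]


@pytest.fixture
def toy_events():
    rows = [
        # surgery s1 (patient p1): bp at 0,1,2 valued 1,2,3
        ("s1", "p1", "bp", 0.0, 1.0),
        ("s1", "p1", "bp", 1.0, 2.0),
        ("s1", "p1", "bp", 2.0, 3.0),
        ("s1", "p1", "hr", 4.0, 70.0),
        ("s1", "p1", "propofol", 0.5, 2.0),
        ("s1", "p1", "propofol", 7.0, 3.0),
        ("s1", "p1", "nibp_map", 1.0, 80.0),
        ("s1", "p1", "ibp_map", 2.0, 90.0),
        # surgery s2 (patient p2): sparse
        ("s2", "p2", "bp", 4.0, 120.0),
        ("s2", "p2", "bp", 10.0, 125.0),
    ]
    return pd.DataFrame(
        rows, columns=["surgery_id", "patient_id", "feature_name",
                       "t_offset_min", "value"]
    )


@pytest.fixture
def toy_statics():
    return pd.DataFrame(
        {
            "surgery_id": ["s1", "s2"],
            "patient_id": ["p1", "p2"],
            "age": [60.0, 45.0],
            "op_length_min": [120.0, 90.0],
        }
    )


@pytest.fixture
def toy_nudesc():
    return pd.DataFrame(
        {
            "surgery_id": ["s1", "s2", "s2"],
            "assess_time_min": [40.0, 35.0, 60.0],
            "c1": [0, 0, 0],
            "c2": [1, 0, 0],
            "c3": [0, 0, 0],
            "c4": [0, 0, 0],
            "c5": [0, 0, 0],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests (session-scoped: the
    generator is deterministic, so reuse is safe)."""
    from trapod.simulate import default_config, generate_cohort

    cfg = default_config(seed=7, n_patients=120)
    return generate_cohort(cfg)
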