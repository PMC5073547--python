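import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def _hand_cohort() -> pd.DataFrame:
    """Twelve-patient cohort, two regions, built for hand computation.

    back:  cases (score, pcs<=33) {6,5,3}, controls {2,7,1}
           pairwise AUC = 6 wins / 9 pairs = 2/3
    neck:  cases {4,8}, controls {4,0,2,5}
           pairwise AUC = (0.5+1+1+0 + 4) / 8 = 0.8125
    """
    rows = []
    back = [(6, 20.0), (5, 30.0), (2, 50.0), (7, 40.0), (1, 80.0), (3, 33.0)]
    neck = [(4, 45.0), (4, 25.0), (0, 70.0), (8, 10.0), (2, 34.0), (5, 66.5)]
    for region, data in (("back", back), ("neck", neck)):
        for j, (score, pcs) in enumerate(data):
            items = [1] * score + [0] * (8 - score)
            rows.append(
                {
                    "id": f"{region}{j}",
                    "service": "other",
                    "region": region,
                    **{f"item_{k + 1}": items[k] for k in range(8)},
                    "pcs_6m": pcs,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_cohort():
    return _hand_cohort()
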